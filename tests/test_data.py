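"""Data containers, similarity kernels and graph assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from dgnmda import (
    AssociationMatrix,
    SimilarityView,
    build_feature_matrix,
    build_graph,
    build_heterogeneous_adjacency,
    compute_gip_similarity,
    fuse_similarities,
    hop_distances,
    load_associations,
    load_similarity,
    normalize_adjacency,
    sparsify_similarity,
)
from dgnmda.data import save_similarity

from conftest import random_association, random_similarity


# ---------------------------------------------------------------- I/O


def test_load_associations_builds_sorted_binary_matrix(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("m1\td1\nm1\td2\nm2\td1\n")
    assoc = load_associations(p)
    assert assoc.mirna_ids == ["m1", "m2"]
    assert assoc.disease_ids == ["d1", "d2"]
    assert assoc.values.tolist() == [[1, 1], [1, 0]]


def test_load_associations_duplicate_pair_idempotent(tmp_path):
    once, twice = tmp_path / "once.tsv", tmp_path / "twice.tsv"
    once.write_text("m1\td1\nm2\td1\n")
    twice.write_text("m1\td1\nm1\td1\nm2\td1\n")
    assert (load_associations(once).values == load_associations(twice).values).all()


def test_load_associations_header_and_label_column(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("mirna_id\tdisease_id\tlabel\nm1\td1\t1\nm2\td1\t0\n")
    assoc = load_associations(p)
    assert assoc.values[assoc.mirna_ids.index("m2"), 0] == 0
    assert assoc.values.sum() == 1


def test_load_associations_empty_file_errors(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("")
    with pytest.raises((ValueError, Exception)):
        load_associations(p)


def test_similarity_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    view = random_similarity(rng, 5, "mirna")
    path = tmp_path / "sim.csv"
    save_similarity(view, path, ids=[f"m{i}" for i in range(5)])
    back = load_similarity(path, "mirna")
    assert np.allclose(back.values, view.values)
    assert back.ids == [f"m{i}" for i in range(5)]


def test_similarity_asymmetry_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(",a,b\na,1.0,0.2\nb,0.9,1.0\n")
    with pytest.raises(ValueError, match="symmetric"):
        load_similarity(path, "mirna")


# ---------------------------------------------------------------- GIP


def test_gip_hand_value_two_orthogonal_profiles():
    # profiles (1,0) and (0,1): gamma = 2/2 = 1, distance^2 = 2
    assoc = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.eye(2, dtype=int))
    sim = compute_gip_similarity(assoc, "mirna")
    assert np.isclose(sim.values[0, 1], np.exp(-2.0))
    assert np.allclose(np.diag(sim.values), 1.0)


def test_gip_identical_profiles_give_unit_similarity():
    values = np.array([[1, 0, 1], [1, 0, 1]], dtype=int)
    assoc = AssociationMatrix(["m1", "m2"], ["d1", "d2", "d3"], values)
    sim = compute_gip_similarity(assoc, "mirna")
    assert np.isclose(sim.values[0, 1], 1.0)


def test_gip_all_zero_matrix_errors():
    assoc = AssociationMatrix(["m1"], ["d1"], np.zeros((1, 1), dtype=int))
    with pytest.raises(ValueError, match="bandwidth"):
        compute_gip_similarity(assoc, "mirna")


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 10_000))
def test_gip_symmetric_unit_diagonal_bounded(seed):
    rng = np.random.default_rng(seed)
    assoc = random_association(rng, 5, 4)
    for family in ("mirna", "disease"):
        sim = compute_gip_similarity(assoc, family)
        v = sim.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() > 0 and v.max() <= 1 + 1e-12
        # exact 1 off-diagonal iff profiles equal
        profiles = assoc.values if family == "mirna" else assoc.values.T
        for i in range(v.shape[0]):
            for j in range(i):
                equal = (profiles[i] == profiles[j]).all()
                assert np.isclose(v[i, j], 1.0) == equal


# ---------------------------------------------------------------- fusion


def test_fuse_similarities_modes():
    a = SimilarityView("mirna", "functional", np.array([[1.0, 0.2], [0.2, 1.0]]))
    b = SimilarityView("mirna", "gip", np.array([[1.0, 0.6], [0.6, 1.0]]))
    assert np.isclose(fuse_similarities(a, b, "mean").values[0, 1], 0.4)
    zero = SimilarityView("mirna", "functional", np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert np.isclose(fuse_similarities(zero, b, "prefer_a_nonzero").values[0, 1], 0.6)
    same = fuse_similarities(a, a, "mean")
    assert np.allclose(same.values, a.values)


def test_fuse_size_mismatch_errors():
    a = SimilarityView("mirna", "functional", np.eye(2))
    b = SimilarityView("mirna", "gip", np.eye(3))
    with pytest.raises(ValueError):
        fuse_similarities(a, b)


# ---------------------------------------------------------------- adjacency


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 10_000))
def test_block_adjacency_symmetric_zero_diagonal_blocks(seed):
    rng = np.random.default_rng(seed)
    m, n = int(rng.integers(1, 6)), int(rng.integers(1, 6))
    assoc = random_association(rng, m, n)
    adj = build_heterogeneous_adjacency(assoc)
    assert adj.shape == (m + n, m + n)
    assert (adj == adj.T).all()
    assert not adj[:m, :m].any() and not adj[m:, m:].any()
    assert (adj[:m, m:] == assoc.values).all()


def test_single_pair_block_adjacency():
    assoc = AssociationMatrix(["m1"], ["d1"], np.array([[1]]))
    assert build_heterogeneous_adjacency(assoc).tolist() == [[0, 1], [1, 0]]


def test_normalize_adjacency_hand_values():
    assert np.allclose(normalize_adjacency(np.zeros((1, 1))), [[1.0]])
    two = normalize_adjacency(np.array([[0, 1], [1, 0]]))
    assert np.allclose(two, [[0.5, 0.5], [0.5, 0.5]])


def test_normalize_adjacency_permutation_equivariant():
    rng = np.random.default_rng(2)
    a = (rng.random((6, 6)) < 0.4).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    perm = rng.permutation(6)
    p = np.eye(6)[perm]
    assert np.allclose(p @ normalize_adjacency(a) @ p.T, normalize_adjacency(p @ a @ p.T))


def test_normalize_adjacency_spectral_radius_bounded():
    rng = np.random.default_rng(3)
    a = (rng.random((8, 8)) < 0.3).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    eig = np.linalg.eigvalsh(normalize_adjacency(a))
    assert np.abs(eig).max() <= 1 + 1e-6


# ---------------------------------------------------------------- features


def test_feature_matrix_layouts():
    rng = np.random.default_rng(4)
    assoc = random_association(rng, 2, 3)
    m_sim = random_similarity(rng, 2, "mirna")
    d_sim = random_similarity(rng, 3, "disease")
    full = build_feature_matrix(m_sim, d_sim, assoc, "block_with_assoc")
    assert full.shape == (5, 5)
    assert np.allclose(full[:2, 2:], assoc.values)
    diag = build_feature_matrix(m_sim, d_sim, assoc, "block_diagonal")
    assert not diag[:2, 2:].any()
    zero_assoc = AssociationMatrix(
        assoc.mirna_ids, assoc.disease_ids, np.zeros_like(assoc.values)
    )
    assert np.allclose(
        build_feature_matrix(m_sim, d_sim, zero_assoc, "block_with_assoc"),
        build_feature_matrix(m_sim, d_sim, zero_assoc, "block_diagonal"),
    )


def test_identity_similarities_zero_assoc_give_identity_features():
    assoc = AssociationMatrix(["m1", "m2"], ["d1"], np.zeros((2, 1), dtype=int))
    m_sim = SimilarityView("mirna", "functional", np.eye(2))
    d_sim = SimilarityView("disease", "semantic", np.eye(1))
    assert np.allclose(build_feature_matrix(m_sim, d_sim, assoc), np.eye(3))


# ---------------------------------------------------------------- distances


def test_hop_distances_path_and_sentinel():
    path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    d = hop_distances(path, cap=10)
    assert d[0, 2] == 2 and d[0, 0] == 0
    disconnected = np.zeros((2, 2), dtype=int)
    assert hop_distances(disconnected, cap=10)[0, 1] == 10
    with pytest.raises(ValueError):
        hop_distances(path, cap=0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000))
def test_hop_distances_match_networkx_and_triangle_inequality(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    a = (rng.random((n, n)) < 0.3).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    cap = 50
    d = hop_distances(a, cap=cap)
    g = nx.from_numpy_array(a)
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for i in range(n):
        for j in range(n):
            expected = lengths[i].get(j, cap)
            assert d[i, j] == min(expected, cap)
    reach = d < cap
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if reach[i, j] and reach[j, k]:
                    assert d[i, k] <= d[i, j] + d[j, k]


# ---------------------------------------------------------------- sparsify


def test_sparsify_tie_breaks_toward_lower_index():
    sim = SimilarityView("mirna", "functional", np.eye(3))
    nbrs = sparsify_similarity(sim, top_k=1)
    # all off-diagonal ties at 0: each node initially picks its lowest-index other
    assert 1 in nbrs[0] or 0 in nbrs[1]
    assert all(i not in nbrs[i] for i in range(3))


def test_sparsify_argmax_and_union_symmetry():
    v = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.8], [0.1, 0.8, 1.0]])
    nbrs = sparsify_similarity(SimilarityView("mirna", "functional", v), top_k=1)
    assert 1 in nbrs[0]  # argmax of row 0
    # union symmetrisation: 0 picks 1, so 0 in nbrs[1] even though 1's top pick is 0/2
    assert 0 in nbrs[1]


def test_sparsify_topk_too_large_warns_keeps_all():
    sim = SimilarityView("mirna", "functional", np.eye(3))
    with pytest.warns(UserWarning):
        nbrs = sparsify_similarity(sim, top_k=5)
    assert all(len(s) == 2 for s in nbrs)


# ---------------------------------------------------------------- build_graph


def test_build_graph_invariants():
    rng = np.random.default_rng(5)
    assoc = random_association(rng, 4, 3)
    g = build_graph(assoc, random_similarity(rng, 4, "mirna"), random_similarity(rng, 3, "disease"), top_k=2)
    assert g.adjacency.shape == (7, 7)
    assert (g.hop_distance == g.hop_distance.T).all()
    assert (np.diag(g.hop_distance) == 0).all()
    for i, nb in enumerate(g.neighbor_lists):
        assert len(nb) >= 1
    # similarity-only mode keeps association partners out of the lists
    m = assoc.n_mirna
    for i in range(m):
        assert all(j < m for j in g.neighbor_lists[i])


def test_build_graph_association_mode_includes_links():
    rng = np.random.default_rng(6)
    assoc = random_association(rng, 4, 3)
    g = build_graph(
        assoc,
        random_similarity(rng, 4, "mirna"),
        random_similarity(rng, 3, "disease"),
        top_k=2,
        neighbor_edges="similarity+association",
    )
    i, j = np.argwhere(assoc.values == 1)[0]
    assert 4 + j in g.neighbor_lists[i]
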