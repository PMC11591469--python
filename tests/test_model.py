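"""Model/Results behaviour: determinism, training dynamics, prediction."""

import numpy as np
import pytest

from dgnmda import DGNMDAModel, RunConfig
from dgnmda.model import init_states, load_checkpoint, mlp_score

from conftest import FIXTURE_DIM


def quick_config(**kw):
    base = dict(dim=16, max_epochs=15, patience=15, folds=5)
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="module")
def small_model(fixture_data):
    assoc, m_sim, d_sim, _, _ = fixture_data
    return DGNMDAModel(assoc, m_sim, d_sim, quick_config())


def test_identical_seed_gives_bit_identical_score_table(small_model):
    r1 = small_model.fit(seed=5, protocol="single")
    r2 = small_model.fit(seed=5, protocol="single")
    assert r1.score_table.equals(r2.score_table)
    r3 = small_model.fit(seed=6, protocol="single")
    assert not r1.score_table["score"].equals(r3.score_table["score"])


def test_training_reduces_loss_on_fixture(small_model):
    res = small_model.fit(seed=1, protocol="single")
    hist = res.histories[0]
    assert min(h["loss"] for h in hist) < hist[0]["loss"]


def test_all_parameters_receive_gradient(fixture_data):
    from dgnmda.autodiff import Tensor
    from dgnmda.model import forward_embedding, score_logits
    from dgnmda.protocol import negative_undersample, split_and_folds

    assoc, m_sim, d_sim, _, _ = fixture_data
    cfg = quick_config(dropout=0.0)
    model = DGNMDAModel(assoc, m_sim, d_sim, cfg)
    fold = split_and_folds(negative_undersample(assoc, 1), 0.2, 5, 1)[0]
    graph, _ = model._build_fold_graph(fold)
    states = init_states(cfg, graph.features.shape[1], 42)
    h = forward_embedding(graph, cfg, states, training=True)
    y = np.array([[p[2]] for p in fold.train_pairs], float)
    loss = score_logits(h, fold.train_pairs, graph.n_mirna, states.mlp).bce_with_logits(y)
    loss.backward()
    dead = [n for n, p in states.named_params() if p.grad is None or not np.any(p.grad)]
    assert dead == []


@pytest.mark.parametrize("variant", ["dgn-a", "dgn-b", "dgn-c", "dgn-d"])
def test_ablation_variants_train_and_emit_metrics(fixture_data, variant):
    assoc, m_sim, d_sim, _, _ = fixture_data
    model = DGNMDAModel(assoc, m_sim, d_sim, quick_config(variant=variant, max_epochs=5))
    res = model.fit(seed=2, protocol="single")
    for m in res.fold_metrics + res.test_metrics:
        assert 0 <= m["AUC"] <= 1 and 0 <= m["AUPRC"] <= 1
    assert res.embeddings[0].shape == (assoc.n_mirna + assoc.n_disease, 16)


def test_view_combinations_run(fixture_data):
    assoc, m_sim, d_sim, _, _ = fixture_data
    for views in ("MS+DS", "MG+DG"):
        model = DGNMDAModel(assoc, m_sim, d_sim, quick_config(views=views, max_epochs=3))
        res = model.fit(seed=1, protocol="single")
        assert np.isfinite(res.score_table["score"]).all()


def test_views_requiring_missing_similarity_error(fixture_data):
    assoc, m_sim, _, _, _ = fixture_data
    with pytest.raises(ValueError, match="disease similarity"):
        DGNMDAModel(assoc, m_sim, None, quick_config(views="MS+DS"))
    # GIP-only views work without precomputed similarity inputs
    model = DGNMDAModel(assoc, None, None, quick_config(views="MG+DG", max_epochs=2))
    model.fit(seed=1, protocol="single")


def test_summary_contains_metrics_table(small_model):
    res = small_model.fit(seed=3, protocol="single")
    text = res.summary()
    assert "AUC" in text and "val mean" in text and "fold 0" in text


def test_rank_candidates_contracts(small_model, fixture_data):
    assoc = fixture_data[0]
    res = small_model.fit(seed=4, protocol="single")
    disease = assoc.disease_ids[0]
    full = res.rank_candidates(disease, k=assoc.n_mirna, exclude_known=False)
    assert sorted(full.mirna_id) == sorted(assoc.mirna_ids)  # full permutation
    known = set(np.flatnonzero(res.train_assocs[0].values[:, 0] == 1))
    masked = res.rank_candidates(disease, k=assoc.n_mirna, exclude_known=True)
    assert len(masked) == assoc.n_mirna - len(known)
    assert not known & {assoc.mirna_ids.index(m) for m in masked.mirna_id}
    top20 = res.rank_candidates(disease, k=20)
    assert len(top20) == 20 and list(top20["rank"]) == list(range(1, 21))
    with pytest.raises(KeyError):
        res.rank_candidates("no-such-disease")


def test_new_disease_mode_excludes_its_edges(fixture_data):
    assoc, m_sim, d_sim, _, _ = fixture_data
    target = assoc.disease_ids[assoc.values.sum(axis=0).argmax()]
    j = assoc.disease_ids.index(target)
    model = DGNMDAModel(assoc, m_sim, d_sim, quick_config(max_epochs=3))
    res = model.fit(seed=1, protocol="single", new_disease=target)
    assert not res.train_assocs[0].values[:, j].any()
    ranking = res.rank_candidates(target, k=20, exclude_known=True)
    assert len(ranking) == 20  # nothing is "known" for a new disease


def test_untrained_model_scores_near_chance(fixture_model):
    aucs = [
        fixture_model.fit(seed=s, protocol="single", max_epochs=0).test_metrics[0]["AUC"]
        for s in (1, 2, 3)
    ]
    assert abs(np.mean(aucs) - 0.5) <= 0.1


def test_checkpoint_round_trip(tmp_path, small_model):
    res = small_model.fit(seed=7, protocol="single")
    res.save(tmp_path)
    assert (tmp_path / "scores.tsv").exists()
    assert (tmp_path / "metrics.json").exists()
    graph, _ = small_model._build_fold_graph(res.folds[0])
    loaded = load_checkpoint(tmp_path / "checkpoint_fold0.npz", res.config, graph.features.shape[1])
    for (n1, p1), (n2, p2) in zip(res.states[0].named_params(), loaded.named_params()):
        assert n1 == n2
        assert np.array_equal(p1.value, p2.value)


def test_mlp_score_zero_weights_give_half():
    mlp = {"W1": np.zeros((8, 4)), "b1": np.zeros(4), "W2": np.zeros((4, 1)), "b2": np.zeros(1)}
    assert mlp_score(np.ones(8), mlp) == 0.5
    mlp["b2"] = np.array([50.0])
    assert mlp_score(np.ones(8), mlp) > 0.999999


def test_runconfig_rejects_unknown_keys(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("dim: 32\nbogus_key: 1\n")
    with pytest.raises(ValueError, match="bogus_key"):
        RunConfig.from_file(p)
    p.write_text("dim: 32\nvariant: dgn-a\n")
    cfg = RunConfig.from_file(p)
    assert cfg.dim == 32 and cfg.variant == "dgn-a"
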