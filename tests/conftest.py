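import numpy as np
import pytest

from dgnmda import (
    DGNMDAModel,
    RunConfig,
    SyntheticSpec,
    generate_latent_bipartite,
    generate_similarities,
)

# Scaled-down model width for test-time training runs; the package
# default (512) matches the reference configuration for full-size data.
FIXTURE_DIM = 64


@pytest.fixture(scope="session")
def fixture_spec() -> SyntheticSpec:
    return SyntheticSpec()  # M=60, N=40, rank 4, density 0.1, seed 7


@pytest.fixture(scope="session")
def fixture_data(fixture_spec):
    assoc, u, v = generate_latent_bipartite(fixture_spec)
    m_sim = generate_similarities(
        u, fixture_spec.sim_noise, fixture_spec.child_seed(2), "mirna", "functional"
    )
    d_sim = generate_similarities(
        v, fixture_spec.sim_noise, fixture_spec.child_seed(3), "disease", "semantic"
    )
    return assoc, m_sim, d_sim, u, v


@pytest.fixture(scope="session")
def fixture_model(fixture_data):
    assoc, m_sim, d_sim, _, _ = fixture_data
    cfg = RunConfig(dim=FIXTURE_DIM, patience=60, max_epochs=600)
    return DGNMDAModel(assoc, m_sim, d_sim, cfg)


def random_association(rng: np.random.Generator, m: int, n: int):
    """Random binary association matrix with at least one link."""
    from dgnmda import AssociationMatrix

    values = (rng.random((m, n)) < 0.4).astype(np.int8)
    if values.sum() == 0:
        values[rng.integers(m), rng.integers(n)] = 1
    mirnas = [f"m{i:02d}" for i in range(m)]
    diseases = [f"d{j:02d}" for j in range(n)]
    return AssociationMatrix(mirnas, diseases, values)


def random_similarity(rng: np.random.Generator, size: int, family: str):
    from dgnmda import SimilarityView

    raw = rng.random((size, size))
    sym = 0.5 * (raw + raw.T)
    np.fill_diagonal(sym, 1.0)
    return SimilarityView(family, "functional", sym)
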