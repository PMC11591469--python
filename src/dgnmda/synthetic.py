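"""Seeded synthetic miRNA-disease datasets with low-rank latent structure.

The generator encodes the premise the method relies on: associations
and similarities share a common latent cause.  Latent factors
U (M x r) and V (N x r) are drawn with unit-normal entries; a pair
(i, j) is a positive with probability ``sigmoid(scale * U_i.V_j /
sqrt(r) + c)``, the intercept c calibrated by bisection so the expected
positive fraction hits the target density.  "Functional"/"semantic"
similarity views are cosine similarities of the same latent rows mapped
to [0, 1] and perturbed with clipped Gaussian noise, so similarity
structure genuinely predicts associations.  GIP kernel views are
computed downstream from the generated association matrix itself.

One global seed spawns per-component child seeds through a fixed
counter scheme, so individual stages are reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data import AssociationMatrix, SimilarityView, save_similarity

__all__ = ["SyntheticSpec", "generate_latent_bipartite", "generate_similarities", "make_fixture"]


@dataclass
class SyntheticSpec:
    m: int = 60
    n: int = 40
    rank: int = 4
    density: float = 0.1
    sim_noise: float = 0.05
    seed: int = 7
    scale: float = 3.0  # latent logit scale; sets how separable the signal is

    def __post_init__(self):
        if not (1 <= self.rank <= min(self.m, self.n)):
            raise ValueError("rank must lie in [1, min(M, N)]")
        if not (0 < self.density <= 0.5):
            raise ValueError("density must lie in (0, 0.5]")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be nonnegative")

    def child_seed(self, component: int) -> int:
        # fixed counter scheme; keep well below 2**31
        return (self.seed * 1000 + component) % (2**31 - 1)


def _ids(prefix: str, count: int) -> list[str]:
    width = len(str(count - 1))
    return [f"{prefix}-{i:0{width}d}" for i in range(count)]


def generate_latent_bipartite(
    spec: SyntheticSpec,
) -> tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """Draw the association matrix and return it with its hidden factors."""
    rng = np.random.default_rng(spec.child_seed(1))
    u = rng.standard_normal((spec.m, spec.rank))
    v = rng.standard_normal((spec.n, spec.rank))
    logits = spec.scale * (u @ v.T) / np.sqrt(spec.rank)

    def mean_p(c: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(logits + c)))).mean())

    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < spec.density:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    if abs(mean_p(c) - spec.density) > 0.1 * spec.density:
        raise RuntimeError("density calibration failed after 100 bisection steps")
    probs = 1.0 / (1.0 + np.exp(-(logits + c)))
    values = (rng.random((spec.m, spec.n)) < probs).astype(np.int8)
    realized = values.mean()
    # allow binomial fluctuation on small grids; 10% of target otherwise
    tol = max(0.1 * spec.density, 4.0 * np.sqrt(spec.density * (1 - spec.density) / (spec.m * spec.n)))
    if abs(realized - spec.density) > tol:
        raise RuntimeError(
            f"realized density {realized:.4f} misses target {spec.density} beyond tolerance {tol:.4f}"
        )
    assoc = AssociationMatrix(_ids("mir", spec.m), _ids("dis", spec.n), values)
    return assoc, u, v


def generate_similarities(
    factors: np.ndarray, sim_noise: float, seed: int, family: str, source: str
) -> SimilarityView:
    """Cosine similarity of latent rows mapped to [0, 1] plus clipped noise."""
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(factors, axis=1, keepdims=True)
    unit = factors / np.maximum(norms, 1e-12)
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    sim = (cos + 1.0) / 2.0
    if sim_noise > 0:
        sim = sim + rng.normal(0.0, sim_noise, size=sim.shape)
    sim = np.clip(sim, 0.0, 1.0)
    sim = 0.5 * (sim + sim.T)
    np.fill_diagonal(sim, 1.0)
    return SimilarityView(family, source, sim)


def make_fixture(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Write the association TSV, two similarity CSVs and a manifest.

    Nodes without any positive link are still recorded (as zero-label
    rows) so the loaded matrix round-trips bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assoc, u, v = generate_latent_bipartite(spec)
    m_sim = generate_similarities(u, spec.sim_noise, spec.child_seed(2), "mirna", "functional")
    d_sim = generate_similarities(v, spec.sim_noise, spec.child_seed(3), "disease", "semantic")

    assoc_path = out / "associations.tsv"
    lines = ["mirna_id\tdisease_id\tlabel"]
    for i, j in np.argwhere(assoc.values == 1):
        lines.append(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\t1")
    for i in np.flatnonzero(assoc.values.sum(axis=1) == 0):
        lines.append(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[0]}\t0")
    for j in np.flatnonzero(assoc.values.sum(axis=0) == 0):
        lines.append(f"{assoc.mirna_ids[0]}\t{assoc.disease_ids[j]}\t0")
    assoc_path.write_text("\n".join(lines) + "\n")

    m_path, d_path = out / "mirna_similarity.csv", out / "disease_similarity.csv"
    save_similarity(m_sim, m_path, ids=assoc.mirna_ids)
    save_similarity(d_sim, d_path, ids=assoc.disease_ids)
    manifest = out / "fixture_manifest.json"
    manifest.write_text(json.dumps({"spec": asdict(spec), "positives": int(assoc.values.sum())}, indent=2))
    return {
        "associations": assoc_path,
        "mirna_similarity": m_path,
        "disease_similarity": d_path,
        "manifest": manifest,
    }
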