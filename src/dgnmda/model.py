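"""Model and Results objects tying the dual-encoder pipeline together.

:class:`DGNMDAModel` is constructed from an association matrix plus
optional precomputed similarity views and a :class:`RunConfig`;
``fit(seed)`` executes the full protocol — balanced negative
undersampling, stratified 8:2 split, stratified k-fold cross-validation,
per-fold training of the dual encoder with Adam and early stopping on
validation AUC — and returns a :class:`DGNMDAResults` carrying per-fold
metrics, the score table, trained parameters and a run manifest.

Leakage control: for every fold the held-out (validation and test)
positive edges are removed from the association matrix before the
heterogeneous graph and the GIP kernels are built, so message passing
never sees a label it is asked to predict.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autodiff import Adam, Tensor, parameter
from .data import (
    AssociationMatrix,
    SimilarityView,
    build_graph,
    compute_gip_similarity,
    fuse_similarities,
    load_associations,
    load_similarity,
)
from .gating import GatingConfig, GatingState, concat_linear_fusion, fuse_multilayer, init_gating_state
from .gcan import GCANConfig, GCANState, encode_gcan, init_gcan_state
from .gct import GCTConfig, GCTState, encode_gct, init_gct_state
from .protocol import (
    FoldSplit,
    evaluate,
    make_score_table,
    negative_undersample,
    split_and_folds,
)

__all__ = ["RunConfig", "DGNMDAModel", "DGNMDAResults", "ModelStates", "mlp_score"]

VARIANTS = ("full", "dgn-a", "dgn-b", "dgn-c", "dgn-d")
VIEWS = ("MS+DS", "MS+DG", "MG+DS", "MG+DG", "ALL")


@dataclass
class RunConfig:
    """Flat run configuration; every knob of the protocol and the model."""

    dim: int = 512
    heads: int = 4
    gcn_pre_layers: int = 1
    gcan_att_layers: int = 2
    gct_conv_layers: int = 2
    gating_depth: int = 2
    gating_recursion: str = "with_transformer"
    dropout: float = 0.5
    leaky_relu_slope: float = 0.2
    top_k: int = 10
    distance_cap: int = 10
    neighbor_edges: str = "similarity"  # GCAN neighbourhood source
    feature_layout: str = "block_with_assoc"
    fusion_mode: str = "mean"  # similarity-view fusion for "ALL"
    folds: int = 5
    test_fraction: float = 0.2
    lr: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 300
    patience: int = 30
    threshold: float = 0.5
    variant: str = "full"
    views: str = "ALL"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.views not in VIEWS:
            raise ValueError(f"views must be one of {VIEWS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value document")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Parameter container


@dataclass
class ModelStates:
    """All learnable parameters for one variant, checkpointable by name."""

    gcan: GCANState | None
    gct: GCTState
    gating: GatingState | None
    concat_w: Tensor | None
    mlp: dict[str, Tensor]

    def named_params(self):
        if self.gcan is not None:
            yield from self.gcan.named_params()
        yield from self.gct.named_params()
        if self.gating is not None:
            yield from self.gating.named_params()
        if self.concat_w is not None:
            yield "fusion.W_c", self.concat_w
        for k, v in self.mlp.items():
            yield f"mlp.{k}", v

    def params(self) -> list[Tensor]:
        return [t for _, t in self.named_params()]

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {name: t.value.copy() for name, t in self.named_params()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for name, t in self.named_params():
            t.value = np.array(arrays[name], dtype=np.float64)


def _xavier(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _encoder_configs(config: RunConfig) -> tuple[GCANConfig, GCTConfig, GatingConfig]:
    gcan_cfg = GCANConfig(
        gcn_layers=config.gcn_pre_layers,
        att_layers=config.gcan_att_layers,
        heads=config.heads,
        dim=config.dim,
        leaky_relu_slope=config.leaky_relu_slope,
        dropout=config.dropout,
        use_gcn_pre=config.variant != "dgn-b",
    )
    gct_cfg = GCTConfig(
        conv_layers=config.gct_conv_layers,
        heads=config.heads,
        dim=config.dim,
        dropout=config.dropout,
        distance_cap=config.distance_cap,
        use_attention=config.variant != "dgn-a",
        use_graph_conv=config.variant != "dgn-d",
        use_gaussian_bias=config.variant != "dgn-d",
    )
    gate_cfg = GatingConfig(
        depth=config.gating_depth,
        dim=config.dim,
        dropout=config.dropout,
        recursion=config.gating_recursion,
    )
    return gcan_cfg, gct_cfg, gate_cfg


def init_states(config: RunConfig, in_dim: int, seed: int) -> ModelStates:
    """Seeded Xavier initialisation of every parameter the variant uses."""
    rng = np.random.default_rng(seed)
    gcan_cfg, gct_cfg, gate_cfg = _encoder_configs(config)
    d = config.dim
    gcan = None if config.variant == "dgn-d" else init_gcan_state(gcan_cfg, in_dim, rng)
    gct = init_gct_state(gct_cfg, in_dim, rng)
    gating = init_gating_state(gate_cfg, rng) if config.variant in ("full", "dgn-a", "dgn-b") else None
    concat_w = parameter(_xavier(rng, 2 * d, d)) if config.variant == "dgn-c" else None
    mlp = {
        "W1": parameter(_xavier(rng, 2 * d, d)),
        "b1": parameter(np.zeros(d)),
        "W2": parameter(_xavier(rng, d, 1)),
        "b2": parameter(np.zeros(1)),
    }
    return ModelStates(gcan, gct, gating, concat_w, mlp)


def mlp_score(pair_vec: np.ndarray, mlp: dict[str, np.ndarray]) -> float:
    """Association probability of one pair vector through the 2D -> D -> 1 MLP."""
    hidden = np.maximum(pair_vec @ mlp["W1"] + mlp["b1"], 0.0)
    z = float((hidden @ mlp["W2"] + mlp["b2"]).item())
    return float(1.0 / (1.0 + np.exp(-z)))


# ---------------------------------------------------------------------------
# Forward pass


def forward_embedding(
    graph,
    config: RunConfig,
    states: ModelStates,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    """Variant-dispatched forward pass to the final fused embedding."""
    gcan_cfg, gct_cfg, gate_cfg = _encoder_configs(config)
    h_tr = encode_gct(graph, gct_cfg, states.gct, rng=rng, training=training)
    if config.variant == "dgn-d":
        return h_tr
    h_ag = encode_gcan(graph, gcan_cfg, states.gcan, rng=rng, training=training)
    if config.variant == "dgn-c":
        return concat_linear_fusion(h_ag, h_tr, states.concat_w)
    return fuse_multilayer(h_ag, h_tr, gate_cfg, states.gating, rng=rng, training=training)


def score_logits(h: Tensor, pairs, n_mirna: int, mlp: dict[str, Tensor]) -> Tensor:
    """Logits of the MLP scorer for a list of (i, j, label) pairs."""
    mi = np.array([p[0] for p in pairs], dtype=np.intp)
    dj = np.array([n_mirna + p[1] for p in pairs], dtype=np.intp)
    pair_vec = h.gather_rows(mi).concat(h.gather_rows(dj), axis=1)
    hidden = (pair_vec @ mlp["W1"] + mlp["b1"]).relu()
    return hidden @ mlp["W2"] + mlp["b2"]


# ---------------------------------------------------------------------------
# Model / Results


class DGNMDAModel:
    """Dual heterogeneous graph encoder model over one association dataset."""

    def __init__(
        self,
        assoc: AssociationMatrix,
        mirna_sim: SimilarityView | None = None,
        disease_sim: SimilarityView | None = None,
        config: RunConfig | None = None,
    ):
        self.assoc = assoc
        self.mirna_sim = self._align(mirna_sim, assoc.mirna_ids)
        self.disease_sim = self._align(disease_sim, assoc.disease_ids)
        self.config = config or RunConfig()
        if self.config.views in ("MS+DS", "MS+DG", "ALL") and self.mirna_sim is None:
            raise ValueError(f"views {self.config.views} require a miRNA similarity input")
        if self.config.views in ("MS+DS", "MG+DS", "ALL") and self.disease_sim is None:
            raise ValueError(f"views {self.config.views} require a disease similarity input")

    @staticmethod
    def _align(view: SimilarityView | None, ids: list[str]) -> SimilarityView | None:
        if view is None:
            return None
        if view.ids and list(view.ids) != list(ids):
            if set(ids) - set(view.ids):
                raise ValueError("similarity ids do not cover the association ids")
            order = [view.ids.index(x) for x in ids]
            return SimilarityView(view.node_family, view.source, view.values[np.ix_(order, order)], ids=list(ids))
        if view.size != len(ids):
            raise ValueError("similarity size inconsistent with association ids")
        return view

    @classmethod
    def from_files(
        cls,
        associations,
        mirna_sim=None,
        disease_sim=None,
        config: RunConfig | None = None,
    ) -> "DGNMDAModel":
        assoc = load_associations(associations)
        m_sim = load_similarity(mirna_sim, "mirna", "functional") if mirna_sim else None
        d_sim = load_similarity(disease_sim, "disease", "semantic") if disease_sim else None
        return cls(assoc, m_sim, d_sim, config)

    # -- similarity views per fold ---------------------------------

    def _fold_similarities(self, assoc_train: AssociationMatrix):
        views = self.config.views
        gip_m = compute_gip_similarity(assoc_train, "mirna")
        gip_d = compute_gip_similarity(assoc_train, "disease")
        if views == "ALL":
            m = fuse_similarities(self.mirna_sim, gip_m, self.config.fusion_mode)
            d = fuse_similarities(self.disease_sim, gip_d, self.config.fusion_mode)
        else:
            m_code, d_code = views.split("+")
            m = self.mirna_sim if m_code == "MS" else gip_m
            d = self.disease_sim if d_code == "DS" else gip_d
        return m, d

    def _build_fold_graph(self, fold: FoldSplit, new_disease_idx: int | None = None):
        held_out = [(i, j) for i, j, lab in fold.val_pairs + fold.test_pairs if lab == 1]
        assoc_train = self.assoc.mask_pairs(held_out)
        if new_disease_idx is not None:
            assoc_train.values[:, new_disease_idx] = 0
        m_sim, d_sim = self._fold_similarities(assoc_train)
        graph = build_graph(
            assoc_train,
            m_sim,
            d_sim,
            top_k=self.config.top_k,
            distance_cap=self.config.distance_cap,
            feature_layout=self.config.feature_layout,
            neighbor_edges=self.config.neighbor_edges,
        )
        return graph, assoc_train

    # -- training ---------------------------------------------------

    def _train_fold(self, fold: FoldSplit, seed: int, new_disease_idx: int | None = None):
        cfg = self.config
        graph, assoc_train = self._build_fold_graph(fold, new_disease_idx)
        states = init_states(cfg, graph.features.shape[1], seed)
        opt = Adam(states.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        drop_rng = np.random.default_rng(seed + 1)
        y_train = np.array([[p[2]] for p in fold.train_pairs], dtype=np.float64)
        y_val = np.array([p[2] for p in fold.val_pairs])

        def val_auc() -> float:
            h = forward_embedding(graph, cfg, states, training=False)
            z = score_logits(h, fold.val_pairs, graph.n_mirna, states.mlp).value[:, 0]
            from sklearn.metrics import roc_auc_score

            return float(roc_auc_score(y_val, z))

        best = {"auc": -np.inf, "arrays": states.to_arrays(), "epoch": 0}
        history = []
        waited = 0
        for epoch in range(cfg.max_epochs):
            opt.zero_grad()
            h = forward_embedding(graph, cfg, states, rng=drop_rng, training=True)
            logits = score_logits(h, fold.train_pairs, graph.n_mirna, states.mlp)
            loss = logits.bce_with_logits(y_train)
            if not np.isfinite(loss.value):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            auc = val_auc()
            history.append({"epoch": epoch, "loss": float(loss.value), "val_auc": auc})
            if auc > best["auc"]:
                best = {"auc": auc, "arrays": states.to_arrays(), "epoch": epoch}
                waited = 0
            else:
                waited += 1
                if waited >= cfg.patience:
                    break
        states.load_arrays(best["arrays"])
        h = forward_embedding(graph, cfg, states, training=False)
        return states, graph, assoc_train, h.value, history

    def fit(
        self,
        seed: int = 0,
        protocol: str = "cv",
        new_disease: str | None = None,
        max_epochs: int | None = None,
    ) -> "DGNMDAResults":
        """Run the full pipeline and return a results object.

        ``protocol="cv"`` trains one model per fold; ``protocol="single"``
        trains only fold 0 (fast path for prediction / ablation runs).
        ``max_epochs=0`` scores with untrained, freshly initialised
        parameters (random-scorer diagnostics).
        """
        cfg = copy.deepcopy(self.config)
        if max_epochs is not None:
            cfg.max_epochs = max_epochs
        model = DGNMDAModel.__new__(DGNMDAModel)
        model.__dict__.update(self.__dict__)
        model.config = cfg

        nd_idx = None
        if new_disease is not None:
            if new_disease not in self.assoc.disease_ids:
                raise KeyError(f"unknown disease id {new_disease!r}")
            nd_idx = self.assoc.disease_ids.index(new_disease)
            sampling_assoc = self.assoc.copy()
            sampling_assoc.values[:, nd_idx] = 0
        else:
            sampling_assoc = self.assoc

        pairs = negative_undersample(sampling_assoc, seed)
        folds = split_and_folds(pairs, cfg.test_fraction, cfg.folds, seed)
        if protocol == "single":
            folds = folds[:1]
        elif protocol != "cv":
            raise ValueError("protocol must be 'cv' or 'single'")

        rows, fold_metrics, test_metrics, states_list, embeddings, histories, train_assocs = (
            [],
            [],
            [],
            [],
            [],
            [],
            [],
        )
        for k, fold in enumerate(folds):
            fold_seed = seed * 1000 + k
            states, graph, assoc_train, h, history = model._train_fold(fold, fold_seed, nd_idx)
            for split, plist in (("val", fold.val_pairs), ("test", fold.test_pairs)):
                z = score_logits(
                    Tensor(h), plist, graph.n_mirna, states.mlp
                ).value[:, 0]
                scores = 1.0 / (1.0 + np.exp(-z))
                labels = np.array([p[2] for p in plist])
                metrics = evaluate(scores, labels, cfg.threshold)
                (fold_metrics if split == "val" else test_metrics).append(metrics)
                for (i, j, lab), s in zip(plist, scores):
                    rows.append(
                        (self.assoc.mirna_ids[i], self.assoc.disease_ids[j], lab, float(s), k, split)
                    )
            states_list.append(states)
            embeddings.append(h)
            histories.append(history)
            train_assocs.append(assoc_train)

        table = make_score_table(rows)
        manifest = {
            "config": asdict(cfg),
            "seed": seed,
            "protocol": protocol,
            "new_disease": new_disease,
            "input_digests": {
                "associations": _digest(self.assoc.values),
                "mirna_sim": _digest(self.mirna_sim.values) if self.mirna_sim else None,
                "disease_sim": _digest(self.disease_sim.values) if self.disease_sim else None,
            },
        }
        return DGNMDAResults(
            model=self,
            config=cfg,
            seed=seed,
            folds=folds,
            fold_metrics=fold_metrics,
            test_metrics=test_metrics,
            score_table=table,
            states=states_list,
            embeddings=embeddings,
            histories=histories,
            train_assocs=train_assocs,
            manifest=manifest,
        )


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class DGNMDAResults:
    """Fitted-model results: metrics, scores, parameters, diagnostics."""

    model: DGNMDAModel
    config: RunConfig
    seed: int
    folds: list[FoldSplit]
    fold_metrics: list[dict]
    test_metrics: list[dict]
    score_table: pd.DataFrame
    states: list[ModelStates]
    embeddings: list[np.ndarray]
    histories: list[list[dict]]
    train_assocs: list[AssociationMatrix]
    manifest: dict

    def mean_metrics(self, split: str = "val") -> dict[str, tuple[float, float]]:
        src = self.fold_metrics if split == "val" else self.test_metrics
        keys = src[0].keys()
        return {k: (float(np.mean([m[k] for m in src])), float(np.std([m[k] for m in src]))) for k in keys}

    def summary(self) -> str:
        lines = [
            "DGNMDA results",
            "=" * 64,
            f"variant: {self.config.variant}   views: {self.config.views}   seed: {self.seed}",
            f"folds: {len(self.folds)}   dim: {self.config.dim}   heads: {self.config.heads}",
            "-" * 64,
            f"{'metric':<10}{'val mean':>10}{'val sd':>9}{'test mean':>11}{'test sd':>9}",
        ]
        val, test = self.mean_metrics("val"), self.mean_metrics("test")
        for k in val:
            lines.append(f"{k:<10}{val[k][0]:>10.4f}{val[k][1]:>9.4f}{test[k][0]:>11.4f}{test[k][1]:>9.4f}")
        lines.append("-" * 64)
        for f, m in enumerate(self.fold_metrics):
            lines.append(f"fold {f}: val AUC {m['AUC']:.4f}  AUPRC {m['AUPRC']:.4f}")
        return "\n".join(lines)

    # -- prediction -------------------------------------------------

    def rank_candidates(
        self, disease_id: str, k: int = 20, exclude_known: bool = True, fold: int = 0
    ) -> pd.DataFrame:
        """Top-k candidate miRNAs for one disease by predicted score.

        Scores every miRNA against the query disease with the fold's
        trained model; optionally masks miRNAs whose association with
        the disease was in that fold's training positives.  Ties break
        toward the lexicographically smaller miRNA id.
        """
        assoc = self.model.assoc
        if disease_id not in assoc.disease_ids:
            raise KeyError(f"unknown disease id {disease_id!r}")
        j = assoc.disease_ids.index(disease_id)
        h = self.embeddings[fold]
        mlp = {k_: t.value for k_, t in self.states[fold].mlp.items()}
        known = set(np.flatnonzero(self.train_assocs[fold].values[:, j] == 1))
        rows = []
        for i, mid in enumerate(assoc.mirna_ids):
            if exclude_known and i in known:
                continue
            vec = np.concatenate([h[i], h[assoc.n_mirna + j]])
            rows.append((mid, disease_id, mlp_score(vec, mlp)))
        df = pd.DataFrame(rows, columns=["mirna_id", "disease_id", "score"])
        df = df.sort_values(["score", "mirna_id"], ascending=[False, True], kind="mergesort")
        df = df.head(k).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    # -- persistence ------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.score_table.to_csv(out / "scores.tsv", sep="\t", index=False)
        metrics = {
            "per_fold_val": self.fold_metrics,
            "per_fold_test": self.test_metrics,
            "mean_val": {k: v for k, v in self.mean_metrics("val").items()},
            "mean_test": {k: v for k, v in self.mean_metrics("test").items()},
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        for f, states in enumerate(self.states):
            np.savez(out / f"checkpoint_fold{f}.npz", **states.to_arrays())
            np.save(out / f"embedding_fold{f}.npy", self.embeddings[f])


def load_checkpoint(path, config: RunConfig, in_dim: int) -> ModelStates:
    """Rebuild a ModelStates container from a named-entry checkpoint file."""
    arrays = dict(np.load(path))
    states = init_states(config, in_dim, seed=0)
    states.load_arrays(arrays)
    return states
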