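"""Sub-range segmentation of the case set and segmented model ensembles.

Two schemes are provided.  RVS (real-values sorting) partitions the cases by
the true target concentration — an oracle scheme that quantifies the
potential of segmentation but cannot route unseen cases.  PVS
(predicted-values sorting) first trains a full-range stage-1 model, sorts the
cases by its predictions, trains one sub-model per sub-range, and routes new
cases by comparing their stage-1 prediction to the stored boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .data_prep import CaseTable, SplitAssignment, split_train_valid_test
from .errors import DegenerateSegmentError, UnroutableModelError
from .mlp import MLPModel, TrainConfig, fit_best_of_restarts

__all__ = [
    "SubrangePartition",
    "DegenerateMarker",
    "SegmentedModel",
    "sort_and_partition",
    "fit_full",
    "fit_rvs",
    "fit_pvs",
    "route_case",
    "predict_segmented",
]

RVS, PVS, FULL = "RVS", "PVS", "FULL"


def child_seed(master: int, *key: int) -> int:
    """Deterministic derived seed for one stage of the pipeline."""
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0])


@dataclass(frozen=True)
class SubrangePartition:
    """Equal-count contiguous partition of cases sorted by a key value.

    ``assignment[i]`` is the 0-based sub-range of case i; ``boundaries`` holds
    the key value at the lower edge of each non-first block.  Sub-range sizes
    differ by at most one (extra cases go to the lowest-index blocks).
    """

    k: int
    sizes: tuple[int, ...]
    boundaries: np.ndarray  # (k - 1,)
    assignment: np.ndarray  # (n,)
    sort_key: str  # "real" | "predicted"

    def indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == j)


def sort_and_partition(key_values, k: int, sort_key: str = "real") -> SubrangePartition:
    """Stable-sort cases by key and cut into k equal contiguous blocks.

    When n is not divisible by k, the remainder is spread one extra case per
    block starting from the lowest sub-range.  Boundaries are the key values
    of the first case of each non-first block.
    """
    values = np.asarray(key_values, dtype=float)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot cut {n} cases into {k} sub-ranges")
    base, rem = divmod(n, k)
    sizes = tuple(base + 1 if j < rem else base for j in range(k))
    order = np.argsort(values, kind="stable")
    assignment = np.empty(n, dtype=int)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for j in range(k):
        assignment[order[offsets[j] : offsets[j + 1]]] = j
    boundaries = values[order[offsets[1:-1]]]
    return SubrangePartition(
        k=k,
        sizes=sizes,
        boundaries=boundaries,
        assignment=assignment,
        sort_key=sort_key,
    )


@dataclass(frozen=True)
class DegenerateMarker:
    """Placeholder for a sub-range whose target had no variability.

    Carries the constant target value observed there, which is returned as
    the prediction for cases routed to this sub-range.
    """

    value: float
    n: int


@dataclass
class SegmentedModel:
    """A full-range model or an RVS/PVS ensemble of sub-range models."""

    mode: str  # RVS | PVS | FULL
    k: int
    submodels: list  # MLPModel or DegenerateMarker, length k
    boundaries: np.ndarray  # (k-1,) on the routing key scale
    target: str
    stage1: MLPModel | None = None
    subrange_spans: list = field(default_factory=list)  # (low, high) key spans
    splits: list = field(default_factory=list)  # per-sub-range SplitAssignment
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in (RVS, PVS, FULL):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.submodels) != self.k:
            raise ValueError("submodel count != k")
        if self.mode == PVS and self.stage1 is None:
            raise ValueError("PVS model requires a stage-1 model")

    @property
    def degenerate_indices(self) -> list[int]:
        return [
            j for j, m in enumerate(self.submodels) if isinstance(m, DegenerateMarker)
        ]

    def to_dict(self) -> dict:
        def enc(m):
            if isinstance(m, DegenerateMarker):
                return {"degenerate": True, "value": m.value, "n": m.n}
            return {"degenerate": False, "model": m.to_dict()}

        return {
            "mode": self.mode,
            "k": self.k,
            "target": self.target,
            "boundaries": np.asarray(self.boundaries, dtype=float).tolist(),
            "stage1": self.stage1.to_dict() if self.stage1 is not None else None,
            "submodels": [enc(m) for m in self.submodels],
            "subrange_spans": [[float(a), float(b)] for a, b in self.subrange_spans],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentedModel":
        def dec(e):
            if e["degenerate"]:
                return DegenerateMarker(value=float(e["value"]), n=int(e["n"]))
            return MLPModel.from_dict(e["model"])

        return cls(
            mode=d["mode"],
            k=int(d["k"]),
            submodels=[dec(e) for e in d["submodels"]],
            boundaries=np.asarray(d["boundaries"], dtype=float),
            target=d["target"],
            stage1=MLPModel.from_dict(d["stage1"]) if d["stage1"] else None,
            subrange_spans=[tuple(s) for s in d.get("subrange_spans", [])],
            provenance=dict(d.get("provenance", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SegmentedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_submodels(
    table: CaseTable, partition: SubrangePartition, cfg: TrainConfig, key: np.ndarray
):
    """Train one sub-model per partition block; constant blocks get markers."""
    submodels, spans, splits = [], [], []
    for j in range(partition.k):
        idx = partition.indices(j)
        block_key = key[idx]
        spans.append((float(block_key.min()), float(block_key.max())))
        sub = table.subset(idx, note=f"subrange {j + 1}/{partition.k}")
        if np.ptp(sub.y) == 0:
            submodels.append(DegenerateMarker(value=float(sub.y[0]), n=sub.n))
            splits.append(None)
            continue
        split = split_train_valid_test(sub, seed=child_seed(cfg.seed, 1, j))
        sub_cfg = replace(cfg, seed=child_seed(cfg.seed, 2, j))
        try:
            submodels.append(fit_best_of_restarts(sub, split, sub_cfg))
        except DegenerateSegmentError:
            # variability in the block but not in its training split
            submodels.append(DegenerateMarker(value=float(np.median(sub.y)), n=sub.n))
            splits.append(None)
            continue
        splits.append(split)
    return submodels, spans, splits


def fit_full(table: CaseTable, cfg: TrainConfig) -> SegmentedModel:
    """Train the single full-range model (the k = 1 ensemble)."""
    split = split_train_valid_test(table, seed=child_seed(cfg.seed, 1, 0))
    model = fit_best_of_restarts(table, split, replace(cfg, seed=child_seed(cfg.seed, 2, 0)))
    y = table.y
    return SegmentedModel(
        mode=FULL,
        k=1,
        submodels=[model],
        boundaries=np.empty(0),
        target=table.target,
        subrange_spans=[(float(y.min()), float(y.max()))],
        splits=[split],
        provenance={**table.provenance, "seed": cfg.seed, "n": table.n},
    )


def fit_rvs(table: CaseTable, k: int, cfg: TrainConfig) -> SegmentedModel:
    """Train the oracle ensemble: partition by real target values.

    Each sub-range gets its own 70/15/15 split (seed derived from the master
    seed and the sub-range index) and its own best-of-restarts model.
    Sub-ranges with constant targets become degenerate markers.
    """
    partition = sort_and_partition(table.y, k, sort_key="real")
    submodels, spans, splits = _fit_submodels(table, partition, cfg, table.y)
    return SegmentedModel(
        mode=RVS,
        k=k,
        submodels=submodels,
        boundaries=partition.boundaries.copy(),
        target=table.target,
        subrange_spans=spans,
        splits=splits,
        provenance={**table.provenance, "seed": cfg.seed, "n": table.n},
    )


def fit_pvs(
    table: CaseTable, k: int, cfg: TrainConfig, stage1: MLPModel | None = None
) -> SegmentedModel:
    """Train the practical ensemble: partition by stage-1 predicted values.

    Step 1 trains (or reuses) a full-range stage-1 model and predicts every
    case; step 2 sorts and partitions on those predictions; step 3 trains one
    sub-model per sub-range.  Boundaries live on the stage-1 predicted scale
    and are kept for routing unseen cases.
    """
    if stage1 is None:
        split0 = split_train_valid_test(table, seed=child_seed(cfg.seed, 0, 0))
        stage1 = fit_best_of_restarts(
            table, split0, replace(cfg, seed=child_seed(cfg.seed, 0, 1))
        )
    preds = stage1.predict(table)
    partition = sort_and_partition(preds, k, sort_key="predicted")
    submodels, spans, splits = _fit_submodels(table, partition, cfg, preds)
    return SegmentedModel(
        mode=PVS,
        k=k,
        submodels=submodels,
        boundaries=partition.boundaries.copy(),
        target=table.target,
        stage1=stage1,
        subrange_spans=spans,
        splits=splits,
        provenance={**table.provenance, "seed": cfg.seed, "n": table.n},
    )


def _route_key(boundaries: np.ndarray, key: np.ndarray) -> np.ndarray:
    # half-open intervals [b[i-1], b[i]); below the first boundary -> 0,
    # at or above the last -> k-1
    return np.searchsorted(boundaries, key, side="right")


def route_case(model: SegmentedModel, cases) -> np.ndarray:
    """Assign cases to sub-ranges by their stage-1 predicted value.

    Only PVS ensembles can route unseen cases; RVS would need the unknown
    real target and raises :class:`UnroutableModelError`.
    """
    if model.mode != PVS:
        raise UnroutableModelError(
            f"{model.mode} models cannot route unseen cases"
        )
    p = model.stage1.predict(cases)
    return _route_key(model.boundaries, p)


def predict_segmented(
    model: SegmentedModel, cases, real_targets=None
) -> np.ndarray:
    """Route each case to its sub-range model and predict.

    PVS routes by stage-1 prediction.  RVS routes by the provided
    ``real_targets`` (evaluation/oracle use only).  Cases landing in a
    degenerate sub-range get that sub-range's constant target value.
    """
    if model.mode == PVS:
        idx = route_case(model, cases)
    elif model.k == 1:
        idx = None
    else:
        if real_targets is None:
            raise UnroutableModelError(
                "RVS prediction requires real target values for routing"
            )
        idx = _route_key(model.boundaries, np.asarray(real_targets, dtype=float))

    if idx is None:
        sub = model.submodels[0]
        if isinstance(sub, DegenerateMarker):
            n = len(cases.frame) if isinstance(cases, CaseTable) else len(cases)
            return np.full(n, sub.value)
        return sub.predict(cases)

    frame = cases.frame if isinstance(cases, CaseTable) else cases
    out = np.empty(len(frame), dtype=float)
    for j, sub in enumerate(model.submodels):
        mask = idx == j
        if not mask.any():
            continue
        if isinstance(sub, DegenerateMarker):
            out[mask] = sub.value
        else:
            out[mask] = sub.predict(frame.iloc[np.flatnonzero(mask)] if hasattr(frame, "iloc") else frame[mask])
    return out
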