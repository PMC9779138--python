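"""Error measures, per-sub-range reports and comparison tables.

MAE and RMSE are computed against the real concentrations.  The "overall"
aggregate over a segmented model is the arithmetic mean of the per-sub-range
errors (equal-count sub-ranges make this an equal-weight average); sub-ranges
excluded as degenerate do not enter the mean, and if every sub-range is
excluded the overall value is not estimated (``None``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .data_prep import CaseTable, SPLIT_LABELS
from .segmentation import (
    FULL,
    PVS,
    DegenerateMarker,
    SegmentedModel,
    sort_and_partition,
)

__all__ = [
    "mae",
    "rmse",
    "overall_error",
    "pct_change",
    "round_half_up",
    "SubrangeRow",
    "ErrorReport",
    "ComparisonTable",
    "evaluate",
    "compare_to_full",
    "write_report_csv",
    "write_report_json",
    "write_comparison_csv",
]


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) == 0:
        raise ValueError("empty input")
    return x, y


def mae(x, y) -> float:
    """Mean absolute error (1/n)·Σ|xᵢ − yᵢ| between real x and predicted y."""
    x, y = _check_pair(x, y)
    return float(np.mean(np.abs(x - y)))


def rmse(x, y) -> float:
    """Root-mean-squared error sqrt(Σ(xᵢ − yᵢ)²/n)."""
    x, y = _check_pair(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def overall_error(per_subrange_errors, excluded=()) -> float | None:
    """Equal-weight mean of sub-range errors, skipping excluded indices.

    Returns ``None`` ("not estimated") when every sub-range is excluded.
    """
    values = list(per_subrange_errors)
    excluded = set(excluded)
    included = [v for i, v in enumerate(values) if i not in excluded]
    if not included:
        return None
    return float(np.mean(included))


def pct_change(sub_overall: float, full_overall: float) -> float:
    """Percentage change of a sub-range overall error vs the full-range one."""
    if full_overall <= 0:
        raise ValueError("full-range error must be positive")
    return 100.0 * (sub_overall - full_overall) / full_overall


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SubrangeRow:
    label: str
    low: float
    high: float
    n: int
    mae: float | None
    rmse: float | None
    excluded: bool = False


@dataclass
class ErrorReport:
    """Per-sub-range and overall MAE/RMSE for one evaluated model."""

    mode: str
    k: int
    target: str
    rows: list[SubrangeRow]
    overall_mae: float | None
    overall_rmse: float | None
    excluded: list[int] = field(default_factory=list)
    split_errors: dict = field(default_factory=dict)
    pooled_mae: float | None = None
    pooled_rmse: float | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "target": self.target,
            "rows": [
                {
                    "label": r.label,
                    "low": r.low,
                    "high": r.high,
                    "n": r.n,
                    "mae": r.mae,
                    "rmse": r.rmse,
                    "excluded": r.excluded,
                }
                for r in self.rows
            ],
            "overall_mae": self.overall_mae,
            "overall_rmse": self.overall_rmse,
            "excluded": self.excluded,
            "split_errors": self.split_errors,
            "pooled_mae": self.pooled_mae,
            "pooled_rmse": self.pooled_rmse,
        }


@dataclass
class ComparisonTable:
    """Percentage changes of overall errors vs the same-mode k = 1 run."""

    rows: list[dict]


def evaluate(model: SegmentedModel, table: CaseTable) -> ErrorReport:
    """Compute per-sub-range and overall MAE/RMSE of a model on a case table.

    Cases are sorted and cut into the model's k equal sub-ranges by the
    model's own key (real target for RVS/FULL, stage-1 prediction for PVS),
    so per-row n values match the full sub-range sizes.  Errors are computed
    over all cases in each sub-range; when the table is the training table,
    per-split (train/valid/test) pooled errors are reported as supplementary
    figures.
    """
    y = table.y
    if model.mode == PVS:
        key = model.stage1.predict(table)
        sort_key = "predicted"
    else:
        key = y
        sort_key = "real"
    partition = sort_and_partition(key, model.k, sort_key=sort_key)

    rows: list[SubrangeRow] = []
    excluded: list[int] = []
    maes: list[float | None] = []
    rmses: list[float | None] = []
    abs_sum = 0.0
    sq_sum = 0.0
    n_pooled = 0
    split_acc = {lab: {"abs": 0.0, "sq": 0.0, "n": 0} for lab in SPLIT_LABELS}

    for j in range(model.k):
        idx = partition.indices(j)
        block_key = key[idx]
        y_block = y[idx]
        sub = model.submodels[j]
        label = f"{model.mode}-{j + 1}/{model.k}"
        if isinstance(sub, DegenerateMarker):
            rows.append(
                SubrangeRow(
                    label=label,
                    low=float(block_key.min()),
                    high=float(block_key.max()),
                    n=len(idx),
                    mae=None,
                    rmse=None,
                    excluded=True,
                )
            )
            excluded.append(j)
            maes.append(None)
            rmses.append(None)
            continue
        preds = sub.predict(table.frame.iloc[idx])
        m = mae(y_block, preds)
        r = rmse(y_block, preds)
        rows.append(
            SubrangeRow(
                label=label,
                low=float(block_key.min()),
                high=float(block_key.max()),
                n=len(idx),
                mae=m,
                rmse=r,
            )
        )
        maes.append(m)
        rmses.append(r)
        abs_sum += m * len(idx)
        sq_sum += r * r * len(idx)
        n_pooled += len(idx)

        split = model.splits[j] if j < len(model.splits) else None
        if split is not None and len(split.labels) == len(idx):
            for lab in SPLIT_LABELS:
                mask = split.mask(lab)
                if mask.any():
                    d = y_block[mask] - preds[mask]
                    split_acc[lab]["abs"] += float(np.sum(np.abs(d)))
                    split_acc[lab]["sq"] += float(np.sum(d * d))
                    split_acc[lab]["n"] += int(mask.sum())

    included = [i for i in range(model.k) if i not in excluded]
    o_mae = overall_error(maes, excluded=excluded) if included else None
    o_rmse = overall_error(rmses, excluded=excluded) if included else None

    pooled_mae = abs_sum / n_pooled if n_pooled else None
    pooled_rmse = float(np.sqrt(sq_sum / n_pooled)) if n_pooled else None
    # equal-weight mean of row RMSEs can never exceed the pooled RMSE
    if o_rmse is not None and pooled_rmse is not None:
        assert o_rmse <= pooled_rmse + 1e-9

    split_errors = {}
    for lab, acc in split_acc.items():
        if acc["n"]:
            split_errors[lab] = {
                "mae": acc["abs"] / acc["n"],
                "rmse": float(np.sqrt(acc["sq"] / acc["n"])),
                "n": acc["n"],
            }

    return ErrorReport(
        mode=model.mode,
        k=model.k,
        target=model.target,
        rows=rows,
        overall_mae=o_mae,
        overall_rmse=o_rmse,
        excluded=excluded,
        split_errors=split_errors,
        pooled_mae=pooled_mae,
        pooled_rmse=pooled_rmse,
    )


def compare_to_full(reports) -> ComparisonTable:
    """Build percentage-change rows for each report vs its mode's k = 1 run.

    ``reports`` maps (mode, k) to :class:`ErrorReport`.  FULL reports serve
    as the k = 1 baseline for modes lacking their own k = 1 entry.
    """
    rows = []
    full_by_mode = {}
    for (mode, k), rep in reports.items():
        if k == 1:
            full_by_mode[mode] = rep
    fallback = full_by_mode.get(FULL)
    for (mode, k), rep in sorted(reports.items()):
        base = full_by_mode.get(mode, fallback)
        if base is None or base.overall_mae is None or rep.overall_mae is None:
            d_mae = d_rmse = None
        else:
            d_mae = pct_change(rep.overall_mae, base.overall_mae)
            d_rmse = pct_change(rep.overall_rmse, base.overall_rmse)
        rows.append(
            {
                "target": rep.target,
                "mode": mode,
                "k": k,
                "delta_mae_pct": d_mae,
                "delta_rmse_pct": d_rmse,
            }
        )
    return ComparisonTable(rows=rows)


def _fmt(v, nd=4):
    return "" if v is None else f"{v:.{nd}f}"


def write_report_csv(report: ErrorReport, path) -> None:
    """Write a report mirroring the per-sub-range table layout."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["model", "subrange_low", "subrange_high", "n",
             "MAE", "overall_MAE", "RMSE", "overall_RMSE"]
        )
        for r in report.rows:
            w.writerow(
                [
                    r.label,
                    _fmt(r.low),
                    _fmt(r.high),
                    r.n,
                    _fmt(r.mae) if not r.excluded else "-",
                    _fmt(report.overall_mae),
                    _fmt(r.rmse) if not r.excluded else "-",
                    _fmt(report.overall_rmse),
                ]
            )


def write_report_json(report: ErrorReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def write_comparison_csv(table: ComparisonTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["target", "mode", "k", "delta_MAE_pct", "delta_RMSE_pct"])
        for row in table.rows:
            w.writerow(
                [
                    row["target"],
                    row["mode"],
                    row["k"],
                    _fmt(row["delta_mae_pct"], 1),
                    _fmt(row["delta_rmse_pct"], 1),
                ]
            )
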