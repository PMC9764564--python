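"""Integrate metrics across the cost grid into per-subject AUC summaries.

Thresholded-graph metrics depend on the (arbitrary) choice of cost, so the
subject-level quantity entering group statistics is the area under the
metric-versus-cost curve, computed with the trapezoidal rule on the full
grid.  Subjects whose curve contains an unresolved NaN (e.g. an undefined
path length at extreme sparsity) are rejected here: silent imputation would
bias the group comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MetricCurve", "AucValue", "auc", "curves_from_metrics", "auc_table"]

#: column order of the long-format metric table produced by the metrics stage
METRIC_COLUMNS = ("subject_id", "cost", "metric", "node", "value")


@dataclass(frozen=True)
class MetricCurve:
    """One metric as a function of cost (``node`` is None for global metrics)."""

    metric_name: str
    costs: tuple[float, ...]
    values: tuple[float, ...]
    node: Optional[int] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.costs) != len(self.values):
            raise ValidationError(
                f"{self.metric_name}: {len(self.costs)} costs but "
                f"{len(self.values)} values"
            )
        if any(b <= a for a, b in zip(self.costs, self.costs[1:])):
            raise ValidationError(f"{self.metric_name}: costs must be strictly increasing")


@dataclass(frozen=True)
class AucValue:
    metric_name: str
    auc: float
    node: Optional[int] = None
    subject_id: Optional[str] = None


def auc(curve: MetricCurve) -> AucValue:
    """Trapezoidal integral of the curve over its cost grid."""
    if len(curve.costs) < 2:
        raise ValidationError(
            f"{curve.metric_name}: AUC needs at least 2 grid points, got {len(curve.costs)}"
        )
    values = np.asarray(curve.values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValidationError(
            f"{curve.metric_name}"
            + (f" (node {curve.node})" if curve.node is not None else "")
            + f": not-a-value at cost {curve.costs[bad]:g}; resolve upstream or "
            "exclude the subject"
        )
    area = float(np.trapezoid(values, np.asarray(curve.costs)))
    return AucValue(metric_name=curve.metric_name, auc=area, node=curve.node,
                    subject_id=curve.subject_id)


def curves_from_metrics(table: pd.DataFrame) -> list[MetricCurve]:
    """Build one curve per (metric, node) from a single subject's long table.

    The table must contain columns ``subject_id, cost, metric, node, value``
    with the *same* cost set for every metric/node; a missing (cost, metric)
    cell is an error.  Row order does not matter; output ordering is
    deterministic (metric name, then node).
    """
    missing_cols = set(METRIC_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValidationError(f"metric table missing columns {sorted(missing_cols)}")
    subjects = table["subject_id"].unique()
    if len(subjects) != 1:
        raise ValidationError(
            f"curves_from_metrics expects one subject per call, got {len(subjects)}"
        )
    subject = subjects[0]
    all_costs = np.sort(table["cost"].unique())
    curves: list[MetricCurve] = []
    grouped = table.groupby(["metric", "node"], dropna=False, sort=True)
    for (metric, node), chunk in grouped:
        chunk = chunk.sort_values("cost")
        costs = chunk["cost"].to_numpy(dtype=float)
        if len(costs) != len(all_costs) or not np.array_equal(costs, all_costs):
            missing = sorted(set(np.round(all_costs, 9)) - set(np.round(costs, 9)))
            raise ValidationError(
                f"{subject}: metric {metric!r}"
                + ("" if pd.isna(node) else f" node {int(node)}")
                + f" is missing costs {missing[:5]}"
            )
        curves.append(MetricCurve(
            metric_name=str(metric),
            costs=tuple(costs),
            values=tuple(chunk["value"].to_numpy(dtype=float)),
            node=None if pd.isna(node) else int(node),
            subject_id=str(subject),
        ))
    return curves


def auc_table(metric_table: pd.DataFrame, *, on_nan: str = "error",
              log=None) -> pd.DataFrame:
    """AUC per (subject, metric, node) from the full long metric table.

    ``on_nan="error"`` aborts on any unresolved NaN; ``on_nan="exclude"``
    drops the offending (subject, metric) with a log line instead.
    """
    if on_nan not in ("error", "exclude"):
        raise ValidationError("on_nan must be 'error' or 'exclude'")
    rows = []
    for subject, chunk in metric_table.groupby("subject_id", sort=True):
        for curve in curves_from_metrics(chunk):
            try:
                value = auc(curve)
            except ValidationError:
                if on_nan == "error":
                    raise
                if log is not None:
                    log.info(
                        "excluding subject %s metric %s (node %s): NaN in curve",
                        subject, curve.metric_name, curve.node,
                    )
                continue
            rows.append({
                "subject_id": subject,
                "metric": value.metric_name,
                "node": value.node,
                "auc": value.auc,
            })
    frame = pd.DataFrame(rows, columns=["subject_id", "metric", "node", "auc"])
    frame["node"] = frame["node"].astype("Float64")
    return frame
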