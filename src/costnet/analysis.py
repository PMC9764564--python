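"""In-memory cohort analysis: simulated cohort -> metric AUC table.

The disk-based pipeline stages exchange long-format TSVs, which is the right
interface for auditable runs but wasteful for simulation studies that analyse
tens of cohorts.  This module computes the same quantities directly on a
:class:`~costnet.synthetic.Cohort`, assembling columns as arrays and
integrating metric-versus-cost curves with the trapezoidal rule on the grid.
Its output feeds :mod:`costnet.inference` unchanged, and the test suite
checks it against the file-based route on a common cohort.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as gm
from .errors import ValidationError
from .io import phenotypes_to_frame
from .motion import summarize_motion
from .network import CostGrid, pearson_matrix, threshold_series
from .synthetic import Cohort

__all__ = ["subject_auc_values", "cohort_auc_table", "cohort_phenotype_frame"]

FAST_METRICS = ("global_efficiency", "local_efficiency",
                "nodal_efficiency", "nodal_degree", "betweenness")


def subject_auc_values(series, grid: CostGrid,
                       metrics: Sequence[str] = FAST_METRICS[:4], *,
                       edge_sign: str = "positive") -> dict[str, np.ndarray]:
    """AUC of each requested metric for one subject's time series.

    Returns scalars (0-d arrays) for global metrics and length-N vectors for
    nodal ones, integrated over the cost grid.
    """
    unknown = set(metrics) - set(FAST_METRICS)
    if unknown:
        raise ValidationError(f"unknown metrics {sorted(unknown)}")
    matrix = pearson_matrix(series)
    nets = threshold_series(matrix, grid, edge_sign=edge_sign)
    costs = np.asarray(list(grid))
    per_cost: dict[str, list] = {m: [] for m in metrics}
    need_dist = {"global_efficiency", "nodal_efficiency"} & set(metrics)
    for net in nets:
        dist = gm.shortest_distances(net) if need_dist else None
        if "nodal_efficiency" in metrics or "global_efficiency" in metrics:
            ne = gm.nodal_efficiency(net, dist)
            if "nodal_efficiency" in metrics:
                per_cost["nodal_efficiency"].append(ne)
            if "global_efficiency" in metrics:
                per_cost["global_efficiency"].append(ne.mean())
        if "local_efficiency" in metrics:
            e_loc, _ = gm.local_efficiency(net)
            per_cost["local_efficiency"].append(e_loc)
        if "nodal_degree" in metrics:
            per_cost["nodal_degree"].append(gm.nodal_degree(net).astype(float))
        if "betweenness" in metrics:
            per_cost["betweenness"].append(gm.betweenness(net))
    return {
        metric: np.trapezoid(np.asarray(values), costs, axis=0)
        for metric, values in per_cost.items()
    }


def cohort_auc_table(cohort: Cohort, grid: CostGrid | None = None,
                     metrics: Sequence[str] = FAST_METRICS[:4], *,
                     edge_sign: str = "positive") -> pd.DataFrame:
    """Long AUC table (subject_id, metric, node, auc) for a whole cohort."""
    if grid is None:
        grid = CostGrid.default()
    subject_col: list[str] = []
    metric_col: list[str] = []
    node_col: list[float] = []
    auc_col: list[float] = []
    for phenotype in cohort.phenotypes:
        subject = phenotype.subject_id
        values = subject_auc_values(cohort.timeseries[subject], grid, metrics,
                                    edge_sign=edge_sign)
        for metric in metrics:
            auc = np.atleast_1d(values[metric])
            if auc.size == 1:
                subject_col.append(subject)
                metric_col.append(metric)
                node_col.append(np.nan)
                auc_col.append(float(auc[0]))
            else:
                subject_col.extend([subject] * auc.size)
                metric_col.extend([metric] * auc.size)
                node_col.extend(range(1, auc.size + 1))
                auc_col.extend(auc.tolist())
    frame = pd.DataFrame({
        "subject_id": subject_col,
        "metric": metric_col,
        "node": pd.array(node_col, dtype="Float64"),
        "auc": auc_col,
    })
    return frame


def cohort_phenotype_frame(cohort: Cohort) -> pd.DataFrame:
    """Phenotype frame with motion summaries recomputed from the traces."""
    frame = phenotypes_to_frame(cohort.phenotypes)
    summaries = {s: summarize_motion(t) for s, t in cohort.motion.items()}
    frame["mean_rms"] = [summaries[s].mean_rms for s in frame["subject_id"]]
    frame["mean_fd"] = [summaries[s].mean_fd for s in frame["subject_id"]]
    return frame
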