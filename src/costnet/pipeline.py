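"""End-to-end orchestration: cohort directory in, inference tables out.

Stages communicate only through documented text interfaces inside the run
directory, so each one is independently runnable and testable:

``connectivity/<subject>.tsv``  N x N correlation matrices (construct)
``phenotypes_qc.tsv``           phenotypes with motion summaries merged (qc)
``metrics.tsv``                 long table subject_id/cost/metric/node/value
``metrics_meta.json``           conventions: edge sign, null count, seed, ...
``auc.tsv``                     subject_id/metric/node/auc
``omnibus.tsv`` ``posthoc.tsv`` ``demographics.tsv`` ``normality.tsv``
``correlations.tsv``            inference outputs
``report.txt``                  human-readable summary (published-table shape)
``manifest.json``               config echo, versions, per-stage row counts

Outputs carry no timestamps, so re-running an identical config reproduces
the directory byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import auc_table
from .errors import ConnectomeError, ValidationError
from .inference import (DEFAULT_PAIRS, clinical_correlations, demographic_tests,
                        normality_tests, omnibus_ancova, posthoc_pairwise)
from .io import (load_atlas, phenotypes_to_frame, read_matrix, read_motion,
                 read_phenotypes, read_timeseries, write_matrix)
from .metrics import (betweenness, characteristic_path_length,
                      clustering_coefficient, global_efficiency,
                      local_efficiency, nodal_degree, nodal_efficiency,
                      random_null_ensemble, shortest_distances,
                      small_worldness)
from .motion import summarize_motion
from .network import CostGrid, pearson_matrix, threshold_series
from .synthetic import CohortSpec, synthesize_cohort

log = logging.getLogger("costnet")

GLOBAL_METRICS = ("global_efficiency", "local_efficiency", "clustering_cp",
                  "path_length_lp", "gamma", "lambda", "sigma")
NODAL_METRICS = ("nodal_efficiency", "nodal_degree", "betweenness")
DEFAULT_METRICS = ("global_efficiency", "local_efficiency", "small_world",
                   "nodal_efficiency", "nodal_degree", "betweenness")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    cohort_dir: str
    out_dir: str
    cost_min: float = 0.05
    cost_max: float = 0.40
    cost_step: float = 0.01
    edge_sign: str = "positive"
    metrics: tuple[str, ...] = DEFAULT_METRICS
    n_null: int = 100
    null_seed: int = 0
    covariates: tuple[str, ...] = ("age", "sex", "motion")
    motion_measure: str = "rms"      # 'rms' or 'fd'
    welch: bool = False
    alpha: float = 0.05
    expected_nodes: int = 90

    def __post_init__(self) -> None:
        if self.edge_sign not in ("positive", "absolute"):
            raise ValidationError("edge_sign must be 'positive' or 'absolute'")
        if self.motion_measure not in ("rms", "fd"):
            raise ValidationError("motion_measure must be 'rms' or 'fd'")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        known = set(DEFAULT_METRICS)
        unknown = set(self.metrics) - known
        if unknown:
            raise ValidationError(f"unknown metrics {sorted(unknown)}; known: {sorted(known)}")
        if "small_world" in self.metrics and self.n_null < 1:
            raise ValidationError("small_world metrics need n_null >= 1")
        self.metrics = tuple(self.metrics)
        self.covariates = tuple(self.covariates)
        # validates bounds/step
        self.grid()

    def grid(self) -> CostGrid:
        return CostGrid.from_bounds(self.cost_min, self.cost_max, self.cost_step)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("metrics", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["metrics"] = list(self.metrics)
        payload["covariates"] = list(self.covariates)
        return payload


# ---------------------------------------------------------------------------
# per-subject computation
# ---------------------------------------------------------------------------

def _null_seed_for(base_seed: int, subject_id: str, cost_index: int) -> int:
    # crc32 keeps the derived seed stable across processes (unlike hash())
    subject_key = zlib.crc32(subject_id.encode("utf-8"))
    seq = np.random.SeedSequence((base_seed, subject_key, cost_index))
    return int(seq.generate_state(1)[0] % (2 ** 31))


def subject_metric_table(subject_id: str, matrix, config: RunConfig) -> pd.DataFrame:
    """Long-format metric table for one subject across the cost grid."""
    from .network import ConnectivityMatrix

    if not isinstance(matrix, ConnectivityMatrix):
        matrix = ConnectivityMatrix(values=matrix)
    grid = config.grid()
    nets = threshold_series(matrix, grid, edge_sign=config.edge_sign)
    rows: list[dict] = []

    def add(cost: float, metric: str, node: Optional[int], value: float) -> None:
        rows.append({"subject_id": subject_id, "cost": cost, "metric": metric,
                     "node": node, "value": value})

    for ci, (cost, net) in enumerate(zip(grid, nets)):
        dist = None
        if {"global_efficiency", "nodal_efficiency"} & set(config.metrics):
            dist = shortest_distances(net)
        if "global_efficiency" in config.metrics:
            add(cost, "global_efficiency", None, global_efficiency(net, dist))
        if "local_efficiency" in config.metrics:
            e_loc, _ = local_efficiency(net)
            add(cost, "local_efficiency", None, e_loc)
        if "nodal_efficiency" in config.metrics:
            for node, value in enumerate(nodal_efficiency(net, dist), start=1):
                add(cost, "nodal_efficiency", node, float(value))
        if "nodal_degree" in config.metrics:
            for node, value in enumerate(nodal_degree(net), start=1):
                add(cost, "nodal_degree", node, float(value))
        if "betweenness" in config.metrics:
            for node, value in enumerate(betweenness(net), start=1):
                add(cost, "betweenness", node, float(value))
        if "small_world" in config.metrics:
            nulls = random_null_ensemble(
                net, n_null=config.n_null,
                seed=_null_seed_for(config.null_seed, subject_id, ci),
            )
            gamma, lam, sigma = small_worldness(net, nulls)
            cp, _ = clustering_coefficient(net)
            add(cost, "clustering_cp", None, cp)
            add(cost, "path_length_lp", None, characteristic_path_length(net))
            add(cost, "gamma", None, gamma)
            add(cost, "lambda", None, lam)
            add(cost, "sigma", None, sigma)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _subject_files(directory: Path) -> list[Path]:
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise ValidationError(f"no .tsv files found in {directory}")
    return files


def stage_construct(config: RunConfig) -> int:
    """Time series -> per-subject correlation matrices."""
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir) / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas() if config.expected_nodes == 90 else None
    n = 0
    for path in _subject_files(cohort / "timeseries"):
        try:
            series = read_timeseries(path, expected_nodes=config.expected_nodes,
                                     atlas=atlas)
            matrix = pearson_matrix(series)
        except ConnectomeError as exc:
            raise type(exc)(f"construct stage, subject {path.stem}: {exc}") from exc
        write_matrix(matrix.values, out / path.name)
        n += 1
    log.info("construct: %d subjects", n)
    return n


def stage_qc(config: RunConfig) -> pd.DataFrame:
    """Merge motion summaries into the phenotype table (written as TSV)."""
    cohort = Path(config.cohort_dir)
    phenotypes = read_phenotypes(cohort / "phenotypes.tsv")
    frame = phenotypes_to_frame(phenotypes)
    motion_dir = cohort / "motion"
    if motion_dir.is_dir():
        summaries = {}
        for path in _subject_files(motion_dir):
            trace = read_motion(path)
            summaries[trace.subject_id] = summarize_motion(trace)
        frame["mean_rms"] = [
            summaries[s].mean_rms if s in summaries else frame.loc[i, "mean_rms"]
            for i, s in enumerate(frame["subject_id"])
        ]
        frame["mean_fd"] = [
            summaries[s].mean_fd if s in summaries else frame.loc[i, "mean_fd"]
            for i, s in enumerate(frame["subject_id"])
        ]
    if "motion" in config.covariates:
        col = "mean_rms" if config.motion_measure == "rms" else "mean_fd"
        if frame[col].isna().any():
            missing = frame.loc[frame[col].isna(), "subject_id"].tolist()
            raise ValidationError(
                f"qc stage: motion covariate {col} unavailable for {missing}; "
                "provide motion files or phenotype values"
            )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "phenotypes_qc.tsv", sep="\t", index=False)
    log.info("qc: %d subjects", len(frame))
    return frame


def stage_metrics(config: RunConfig) -> pd.DataFrame:
    """Thresholded-graph metrics for every subject across the cost grid."""
    out = Path(config.out_dir)
    conn_dir = out / "connectivity"
    tables = []
    for path in _subject_files(conn_dir):
        matrix = read_matrix(path)
        try:
            tables.append(subject_metric_table(path.stem, matrix, config))
        except ConnectomeError as exc:
            raise type(exc)(f"metrics stage, subject {path.stem}: {exc}") from exc
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    meta = {
        "edge_sign": config.edge_sign,
        "cost_grid": list(config.grid()),
        "clustering": "onnela, weights rescaled by max edge weight",
        "edge_length": "1/weight",
        "null_model": "maslov-sneppen degree-preserving swaps, weights shuffled",
        "n_null": config.n_null,
        "null_seed": config.null_seed,
        "relative_rms": "rms of frame-to-frame translation delta norms",
        "motion_covariate": config.motion_measure,
    }
    with open(out / "metrics_meta.json", "w", encoding="utf-8") as handle:
        json.dump(meta, handle, indent=1, sort_keys=True)
    log.info("metrics: %d rows", len(table))
    return table


def stage_auc(config: RunConfig) -> pd.DataFrame:
    out = Path(config.out_dir)
    table = pd.read_csv(out / "metrics.tsv", sep="\t")
    aucs = auc_table(table, on_nan="exclude", log=log)
    aucs.to_csv(out / "auc.tsv", sep="\t", index=False)
    log.info("auc: %d rows", len(aucs))
    return aucs


def stage_infer(config: RunConfig) -> dict[str, pd.DataFrame]:
    out = Path(config.out_dir)
    aucs = pd.read_csv(out / "auc.tsv", sep="\t")
    pheno = pd.read_csv(out / "phenotypes_qc.tsv", sep="\t",
                        dtype={"subject_id": str, "group": str, "sex": str})
    results = {
        "demographics": demographic_tests(pheno),
        "normality": normality_tests(pheno),
        "omnibus": omnibus_ancova(aucs, pheno, covariates=config.covariates,
                                  motion_measure=config.motion_measure),
        "posthoc": posthoc_pairwise(aucs, pheno, covariates=config.covariates,
                                    motion_measure=config.motion_measure,
                                    welch=config.welch),
        "correlations": clinical_correlations(aucs, pheno),
    }
    for name, frame in results.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        log.info("infer: %s %d rows", name, len(frame))
    return results


def stage_report(config: RunConfig) -> str:
    """Render a text report shaped like the published summary tables."""
    out = Path(config.out_dir)
    atlas = load_atlas() if config.expected_nodes == 90 else None
    lines: list[str] = ["costnet group analysis report", "=" * 31, ""]

    def table_section(title: str, frame: pd.DataFrame) -> None:
        lines.append(title)
        lines.append("-" * len(title))
        if frame.empty:
            lines.append("(empty)")
        else:
            lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")

    demographics = pd.read_csv(out / "demographics.tsv", sep="\t")
    table_section("Demographic and clinical comparisons", demographics)
    normality = pd.read_csv(out / "normality.tsv", sep="\t")
    table_section("Normality screen (Jarque-Bera)", normality)

    omnibus = pd.read_csv(out / "omnibus.tsv", sep="\t")
    global_omni = omnibus[omnibus["node"].isna()]
    table_section("Global metrics: covariate-adjusted omnibus", global_omni)

    posthoc = pd.read_csv(out / "posthoc.tsv", sep="\t")
    global_post = posthoc[posthoc["node"].isna()]
    table_section("Global metrics: pairwise post-hoc", global_post)

    nodal = posthoc[posthoc["node"].notna()
                    & (posthoc["p_bonferroni"] < config.alpha)].copy()
    if atlas is not None and not nodal.empty:
        labels = {node.index: node.abbreviation for node in atlas}
        nodal["region"] = [labels.get(int(n), str(int(n))) for n in nodal["node"]]
    title = f"Nodes surviving Bonferroni-corrected p < {config.alpha:g}"
    table_section(title, nodal.sort_values(["metric", "pair", "p_bonferroni"]))

    correlations = pd.read_csv(out / "correlations.tsv", sep="\t")
    significant = correlations[correlations["p_value"] < config.alpha]
    lines.append("Clinical correlations")
    lines.append("---------------------")
    lines.append(f"{len(significant)} of {len(correlations)} metric/scale "
                 f"correlations reach uncorrected p < {config.alpha:g}")
    lines.append("")
    text = "\n".join(lines)
    (out / "report.txt").write_text(text, encoding="utf-8")
    return text


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write a provenance manifest; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    counts["construct_subjects"] = stage_construct(config)
    counts["qc_subjects"] = len(stage_qc(config))
    counts["metric_rows"] = len(stage_metrics(config))
    counts["auc_rows"] = len(stage_auc(config))
    results = stage_infer(config)
    counts.update({f"{k}_rows": len(v) for k, v in results.items()})
    stage_report(config)
    manifest = {
        "config": config.to_dict(),
        "software": {"costnet": __version__},
        "row_counts": counts,
        "stages": ["construct", "qc", "metrics", "auc", "infer", "report"],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return out


def synthesize(spec: CohortSpec, outdir: Path | str):
    """Convenience wrapper matching the CLI subcommand."""
    return synthesize_cohort(spec, outdir)
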