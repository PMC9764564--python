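"""Synthetic three-group cohorts with planted network effects.

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline can be exercised with known ground truth:

* a shared small-world template (Watts-Strogatz ring lattice, k neighbours,
  rewiring probability p) whose edges carry weights around a base
  correlation;
* group structure imposed as multipliers on that template — a global
  attenuation of every edge weight in both patient groups (lower efficiency
  than controls) and per-node multipliers in the depressed group only
  (decreased basal-ganglia-like nodes, increased frontal/parietal-like
  nodes);
* ROI time series drawn from a zero-mean Gaussian whose covariance is the
  group template plus shared diagonal loading (one loading constant for the
  whole cohort, chosen so every group covariance has smallest eigenvalue at
  the configured floor; sharing it keeps the planted weight ratios visible
  after correlation normalisation);
* phenotypes and head-motion traces drawn around the published cohort
  demographics, with motion traces rescaled to hit each subject's drawn
  FD/RMS summary and to pass the 2.5 mm / 2.5 degree inclusion gate.

Everything is driven by one integer seed; identical spec + seed reproduces
the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import (MotionParams, RoiTimeSeries, SubjectPhenotype,
                 write_motion, write_phenotypes, write_timeseries)
from .motion import motion_gate

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "TABLE1_PHENOTYPES",
    "template_network",
    "group_templates",
    "shared_diagonal_loading",
    "simulate_timeseries",
    "simulate_phenotypes",
    "simulate_motion",
    "simulate_cohort",
    "synthesize_cohort",
]

#: published cohort demographics: (mean, sd) per group, plus sex counts (M, F)
TABLE1_PHENOTYPES = {
    "D-AD": {
        "n": 24, "sex": (17, 7), "age": (71.2, 5.3), "duration": (15.7, 10.2),
        "education": (9.7, 2.5), "mmse": (20.5, 2.9), "hamd": (12.7, 2.5),
        "dnpi": (5.82, 1.5), "rms": (0.08, 0.06), "fd": (0.29, 0.18),
    },
    "nD-AD": {
        "n": 20, "sex": (10, 10), "age": (74.2, 5.5), "duration": (14.8, 7.4),
        "education": (9.0, 2.2), "mmse": (20.0, 2.5), "hamd": (3.35, 1.9),
        "dnpi": (1.21, 0.51), "rms": (0.08, 0.08), "fd": (0.28, 0.15),
    },
    "NC": {
        "n": 20, "sex": (11, 9), "age": (70.8, 3.3), "duration": None,
        "education": (8.7, 2.1), "mmse": (29.1, 0.8), "hamd": (1.30, 0.9),
        "dnpi": (0.60, 0.6), "rms": (0.06, 0.03), "fd": (0.24, 0.12),
    },
}

#: scale bounds used when clipping phenotype draws
_SCALE_BOUNDS = {
    "age": (45.0, 95.0), "duration": (1.0, 120.0), "education": (0.0, 25.0),
    "mmse": (0.0, 30.0), "hamd": (0.0, 52.0), "dnpi": (0.0, 12.0),
    "rms": (0.005, 2.0), "fd": (0.01, 2.0),
}

GROUP_ORDER = ("D-AD", "nD-AD", "NC")
PATIENT_GROUPS = ("D-AD", "nD-AD")

# 1-based atlas indices of the planted node sets (defaults):
# decreased — putamen L/R, pallidum L/R, right superior temporal gyrus
# increased — right superior parietal, right orbital and medial-orbital
#             superior frontal gyri
DEFAULT_DECREASED_NODES = (73, 74, 75, 76, 82)
DEFAULT_INCREASED_NODES = (60, 6, 26)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_per_group: tuple[int, int, int] = (24, 20, 20)   # D-AD, nD-AD, NC
    n_nodes: int = 90
    n_timepoints: int = 190
    n_dummy_volumes: int = 10      # motion traces cover these extra frames
    lattice_neighbors: int = 8
    rewiring_prob: float = 0.10
    base_edge_weight: float = 0.30
    weight_jitter: float = 0.03    # sd of template edge weights
    global_attenuation: float = 0.85
    decreased_nodes: tuple[int, ...] = DEFAULT_DECREASED_NODES
    decreased_multiplier: float = 0.6
    increased_nodes: tuple[int, ...] = DEFAULT_INCREASED_NODES
    increased_multiplier: float = 1.4
    noise_sd: float = 0.2          # measurement noise, fraction of signal sd
    ar_coeff: float = 0.0          # optional AR(1) coefficient of the latents
    signal_scale: float = 1.0
    eig_floor: float = 0.05
    t_repeat: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_neighbors % 2 or not 0 < self.lattice_neighbors < self.n_nodes:
            raise ValidationError(
                "lattice_neighbors must be even and smaller than n_nodes"
            )
        for name in ("global_attenuation", "decreased_multiplier",
                     "increased_multiplier"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for idx in self.decreased_nodes + self.increased_nodes:
            if not 1 <= idx <= self.n_nodes:
                raise ValidationError(f"planted node index {idx} outside 1..{self.n_nodes}")
        if not 0 <= self.ar_coeff < 1:
            raise ValidationError("ar_coeff must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for recovery bookkeeping."""

    templates: dict[str, np.ndarray]
    decreased_nodes: tuple[int, ...]
    increased_nodes: tuple[int, ...]
    diag_loading: float
    expected_directions: dict[str, str]
    spec: CohortSpec


@dataclass
class Cohort:
    """A fully simulated cohort held in memory."""

    spec: CohortSpec
    phenotypes: list[SubjectPhenotype]
    timeseries: dict[str, RoiTimeSeries]
    motion: dict[str, MotionParams]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _base_template(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Watts-Strogatz topology with weights drawn around the base weight."""
    topo_seed = int(rng.integers(0, 2 ** 31 - 1))
    graph = nx.watts_strogatz_graph(
        spec.n_nodes, spec.lattice_neighbors, spec.rewiring_prob, seed=topo_seed
    )
    w = np.zeros((spec.n_nodes, spec.n_nodes))
    for a, b in sorted(graph.edges()):
        weight = rng.normal(spec.base_edge_weight, spec.weight_jitter)
        weight = max(weight, 0.05 * spec.base_edge_weight)
        w[a, b] = w[b, a] = weight
    return w


def _node_multipliers(spec: CohortSpec) -> np.ndarray:
    m = np.ones(spec.n_nodes)
    m[[i - 1 for i in spec.decreased_nodes]] = spec.decreased_multiplier
    m[[i - 1 for i in spec.increased_nodes]] = spec.increased_multiplier
    return m


def _apply_group(spec: CohortSpec, base: np.ndarray, group: str) -> np.ndarray:
    if group not in GROUP_ORDER:
        raise ValidationError(f"unknown group {group!r}")
    w = base.copy()
    if group in PATIENT_GROUPS:
        w *= spec.global_attenuation
    if group == "D-AD":
        m = _node_multipliers(spec)
        w *= np.outer(m, m)   # each endpoint contributes its multiplier
    return w


def template_network(spec: CohortSpec, group: str) -> np.ndarray:
    """Weighted N x N template for one group (shared topology across groups)."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    return _apply_group(spec, _base_template(spec, rng), group)


def group_templates(spec: CohortSpec) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    base = _base_template(spec, rng)
    return {g: _apply_group(spec, base, g) for g in GROUP_ORDER}


def shared_diagonal_loading(spec: CohortSpec,
                            templates: dict[str, np.ndarray]) -> float:
    """One loading constant for the whole cohort.

    d = eig_floor - min over groups of lambda_min(signal_scale * template);
    sharing d across groups keeps planted weight *ratios* intact after
    correlation normalisation (a per-group d would cancel the global
    attenuation, because correlations are scale invariant).
    """
    lam_min = min(
        float(np.linalg.eigvalsh(spec.signal_scale * t)[0])
        for t in templates.values()
    )
    return spec.eig_floor - min(lam_min, 0.0)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def simulate_timeseries(template: np.ndarray, spec: CohortSpec, *,
                        rng: np.random.Generator,
                        diag_loading: Optional[float] = None,
                        subject_id: str = "sim") -> RoiTimeSeries:
    """T draws from N(0, signal_scale * template + d * I) plus white noise.

    ``diag_loading`` defaults to the per-template value; cohort generation
    passes the shared cohort-wide constant instead.
    """
    template = np.asarray(template, dtype=float)
    if not np.allclose(template, template.T, atol=1e-10):
        raise ValidationError("template must be symmetric")
    if diag_loading is None:
        lam_min = float(np.linalg.eigvalsh(spec.signal_scale * template)[0])
        diag_loading = spec.eig_floor - min(lam_min, 0.0)
    sigma = spec.signal_scale * template + diag_loading * np.eye(len(template))
    chol = np.linalg.cholesky(sigma)
    latent = rng.standard_normal((spec.n_timepoints, len(template)))
    if spec.ar_coeff > 0:
        phi = spec.ar_coeff
        innov_scale = np.sqrt(1.0 - phi ** 2)
        for t in range(1, latent.shape[0]):
            latent[t] = phi * latent[t - 1] + innov_scale * latent[t]
    values = latent @ chol.T
    if spec.noise_sd > 0:
        values = values + (spec.noise_sd * np.sqrt(diag_loading)
                           ) * rng.standard_normal(values.shape)
    return RoiTimeSeries(subject_id=subject_id, values=values,
                         t_repeat=spec.t_repeat)


# ---------------------------------------------------------------------------
# phenotypes and motion
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, spec_pair: tuple[float, float],
          bounds_key: str, n: int) -> np.ndarray:
    mean, sd = spec_pair
    lo, hi = _SCALE_BOUNDS[bounds_key]
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def _sex_labels(n: int, table_counts: tuple[int, int],
                rng: np.random.Generator) -> list[str]:
    n_male = int(round(n * table_counts[0] / sum(table_counts)))
    labels = ["M"] * n_male + ["F"] * (n - n_male)
    rng.shuffle(labels)
    return labels


def simulate_phenotypes(spec: CohortSpec, *,
                        rng: Optional[np.random.Generator] = None
                        ) -> list[SubjectPhenotype]:
    """Group-structured phenotype draws around the published demographics.

    Variables are drawn independently (no planted age-group confound) and
    clipped to valid scale ranges; sex counts match the published margins.
    Motion summaries (mean RMS / mean FD) are drawn here and later used as
    the targets the simulated motion traces are scaled to.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    records: list[SubjectPhenotype] = []
    for group, n in zip(GROUP_ORDER, spec.n_per_group):
        params = TABLE1_PHENOTYPES[group]
        sex = _sex_labels(n, params["sex"], rng)
        age = _draw(rng, params["age"], "age", n)
        education = _draw(rng, params["education"], "education", n)
        mmse = _draw(rng, params["mmse"], "mmse", n)
        hamd = _draw(rng, params["hamd"], "hamd", n)
        dnpi = _draw(rng, params["dnpi"], "dnpi", n)
        rms = _draw(rng, params["rms"], "rms", n)
        fd = _draw(rng, params["fd"], "fd", n)
        duration = (_draw(rng, params["duration"], "duration", n)
                    if params["duration"] else [None] * n)
        tag = group.replace("-", "")
        for i in range(n):
            records.append(SubjectPhenotype(
                subject_id=f"sub-{tag}{i + 1:02d}",
                group=group, age=float(age[i]), sex=sex[i],
                education=float(education[i]),
                duration_months=None if duration[i] is None else float(duration[i]),
                mmse=float(mmse[i]), hamd=float(hamd[i]), dnpi=float(dnpi[i]),
                mean_rms=float(rms[i]), mean_fd=float(fd[i]),
            ))
    return records


def _ou_positions(rng: np.random.Generator, n_frames: int, rho: float
                  ) -> np.ndarray:
    """Mean-reverting (AR(1)) position trace starting at zero, unit innovations."""
    innovations = rng.standard_normal((n_frames - 1, 3))
    positions = np.zeros((n_frames, 3))
    for t in range(1, n_frames):
        positions[t] = rho * positions[t - 1] + innovations[t - 1]
    return positions


def simulate_motion(spec: CohortSpec, phenotype: SubjectPhenotype, *,
                    rng: np.random.Generator) -> MotionParams:
    """Mean-reverting 6-parameter trace scaled to the subject's FD/RMS targets.

    Translation deltas are scaled so the relative RMS equals the subject's
    drawn summary exactly; rotation deltas absorb the remaining framewise
    displacement.  Positions follow a mean-reverting (rather than free random
    walk) process, mimicking a head that keeps returning toward rest, which
    also keeps cumulative excursions inside the 2.5 mm / 2.5 degree gate
    (redraw-then-damp fallbacks cover extreme draws).
    """
    n_frames = spec.n_timepoints + spec.n_dummy_volumes
    target_rms = phenotype.mean_rms if phenotype.mean_rms else 0.05
    target_fd = phenotype.mean_fd if phenotype.mean_fd else 0.25
    for _ in range(10):
        pos_trans = _ou_positions(rng, n_frames, rho=0.90)
        pos_rot = _ou_positions(rng, n_frames, rho=0.90)
        d_trans = np.diff(pos_trans, axis=0)
        d_rot = np.diff(pos_rot, axis=0)
        rms_raw = float(np.sqrt(((d_trans ** 2).sum(axis=1)).mean()))
        scale_t = target_rms / rms_raw
        fd_trans = float(np.abs(d_trans).sum(axis=1).mean()) * scale_t
        remaining = max(target_fd - fd_trans, 0.02 * target_fd)
        fd_rot_raw = float(np.abs(d_rot).sum(axis=1).mean())
        scale_r = remaining / (50.0 * fd_rot_raw)
        positions = np.hstack([pos_trans * scale_t, pos_rot * scale_r])
        trace = MotionParams(subject_id=phenotype.subject_id, values=positions)
        passed, _ = motion_gate(trace)
        if passed:
            return trace
    # extreme draws are damped until they fit (targets then degrade gracefully)
    for _ in range(100):
        positions *= 0.9
        trace = MotionParams(subject_id=phenotype.subject_id, values=positions)
        passed, _ = motion_gate(trace)
        if passed:
            return trace
    raise ValidationError(f"{phenotype.subject_id}: could not build a gated motion trace")


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a complete cohort (phenotypes, motion, time series) in memory."""
    templates = group_templates(spec)
    diag = shared_diagonal_loading(spec, templates)
    phenotypes = simulate_phenotypes(spec)
    motion_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    ts_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 3)))
    motion: dict[str, MotionParams] = {}
    timeseries: dict[str, RoiTimeSeries] = {}
    for phenotype in phenotypes:
        motion[phenotype.subject_id] = simulate_motion(spec, phenotype, rng=motion_rng)
        timeseries[phenotype.subject_id] = simulate_timeseries(
            templates[phenotype.group], spec, rng=ts_rng, diag_loading=diag,
            subject_id=phenotype.subject_id,
        )
    ground_truth = GroundTruth(
        templates=templates,
        decreased_nodes=spec.decreased_nodes,
        increased_nodes=spec.increased_nodes,
        diag_loading=diag,
        expected_directions={
            "global": "NC > D-AD and NC > nD-AD in global and local efficiency",
            "decreased": "D-AD < nD-AD at the decreased nodes",
            "increased": "D-AD > nD-AD at the increased nodes",
        },
        spec=spec,
    )
    return Cohort(spec=spec, phenotypes=phenotypes, timeseries=timeseries,
                  motion=motion, ground_truth=ground_truth)


def synthesize_cohort(spec: CohortSpec, outdir: Path | str) -> Cohort:
    """Simulate a cohort and write it as a cohort directory.

    Layout: ``timeseries/<subject>.tsv`` (T x N), ``motion/<subject>.tsv``
    (T x 6), ``phenotypes.tsv`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec)
    for subject_id, series in cohort.timeseries.items():
        write_timeseries(series, outdir / "timeseries" / f"{subject_id}.tsv")
    for subject_id, trace in cohort.motion.items():
        write_motion(trace, outdir / "motion" / f"{subject_id}.tsv")
    write_phenotypes(cohort.phenotypes, outdir / "phenotypes.tsv")
    gt = cohort.ground_truth
    payload = {
        "spec": dataclasses.asdict(spec),
        "decreased_nodes": list(gt.decreased_nodes),
        "increased_nodes": list(gt.increased_nodes),
        "diag_loading": gt.diag_loading,
        "expected_directions": gt.expected_directions,
        "templates": {g: np.round(t, 8).tolist() for g, t in gt.templates.items()},
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
    return cohort
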