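"""Group-level statistics on metric AUC values.

The inferential layer mirrors the classical covariate-adjusted three-group
workflow: Jarque-Bera normality screens and ANOVA / chi-square tests on
demographics; an ANCOVA omnibus test (partial F on the two group indicators,
adjusting for age, sex and head motion) per metric and per node; pairwise
post-hoc two-sample t-tests on covariate-residualised AUC values with
Bonferroni correction; and Pearson correlations between network AUCs and
clinical scores within the patient groups.

The Bonferroni family is 90 nodes within each nodal metric and the three
group pairs for each global metric.  Post-hoc covariate handling regresses
the covariates out of the full sample once and t-tests the residuals (pooled
variance by default, Welch by flag).

Everything is vectorised across response columns: the same design matrix is
solved once against all metric/node AUC vectors.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError
from .io import GROUP_LABELS, SubjectPhenotype, phenotypes_to_frame

__all__ = [
    "jarque_bera",
    "omnibus_ancova",
    "posthoc_pairwise",
    "demographic_tests",
    "normality_tests",
    "clinical_correlations",
    "partial_f_test",
    "residualize",
    "pooled_t",
    "DEFAULT_PAIRS",
]

DEFAULT_COVARIATES = ("age", "sex", "motion")
DEFAULT_PAIRS = (("D-AD", "nD-AD"), ("D-AD", "NC"), ("nD-AD", "NC"))

#: continuous phenotype variables compared across all three groups
_ANOVA_VARIABLES = ("age", "education", "mmse", "hamd", "dnpi",
                    "mean_rms", "mean_fd")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def jarque_bera(values: Sequence[float]) -> tuple[float, float]:
    """Jarque-Bera normality test: JB = (n/6)(S^2 + K^2/4), chi2(2) tail."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValidationError("Jarque-Bera needs at least 4 observations")
    if np.ptp(values) == 0:
        raise ValidationError("Jarque-Bera is undefined for a constant sample")
    result = stats.jarque_bera(values)
    return float(result.statistic), float(result.pvalue)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # walk columns to name the first one that adds no rank
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            raise ComputationError(
                f"design matrix is rank deficient at column {names[j - 1]!r} "
                "(constant or collinear covariate)"
            )
    raise ComputationError("design matrix is rank deficient")


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0)


def partial_f_test(Y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Extra-sum-of-squares F test of the columns dropped in ``X_reduced``.

    ``Y`` may hold many response columns; returns per-column F and p plus the
    (df_between, df_within) shared by all columns.  Columns with no residual
    variance under the full model and no explained difference report F = 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X_full.shape[0]:
        Y = Y.T
    n, p_full = X_full.shape
    q = p_full - X_reduced.shape[1]
    df_within = n - p_full
    if df_within <= 0:
        raise ComputationError("not enough observations for the full model")
    rss_full = _rss(Y, X_full)
    rss_red = _rss(Y, X_reduced)
    num = np.maximum(rss_red - rss_full, 0.0) / q
    scale = np.maximum(rss_red, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / (rss_full / df_within)
    # degenerate columns: no residual variance at all -> nothing to test
    degenerate = rss_full <= 1e-12 * scale
    F = np.where(degenerate & (num <= 1e-12 * scale), 0.0, F)
    F = np.where(np.isnan(F), 0.0, F)
    p = stats.f.sf(F, q, df_within)
    return F, p, q, df_within


def residualize(Y: np.ndarray, X_cov: np.ndarray) -> np.ndarray:
    """Residuals of ``Y`` after regressing out ``X_cov`` (intercept included)."""
    beta, *_ = np.linalg.lstsq(X_cov, Y, rcond=None)
    return Y - X_cov @ beta


def pooled_t(y1: np.ndarray, y2: np.ndarray, *, welch: bool = False
             ) -> tuple[np.ndarray, np.ndarray, float | np.ndarray]:
    """Two-sample t per response column; pooled variance unless ``welch``."""
    y1 = np.atleast_2d(np.asarray(y1, dtype=float))
    y2 = np.atleast_2d(np.asarray(y2, dtype=float))
    n1, n2 = y1.shape[0], y2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 observations for a t-test")
    m1, m2 = y1.mean(axis=0), y2.mean(axis=0)
    v1 = y1.var(axis=0, ddof=1)
    v2 = y2.var(axis=0, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(diff, float(n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 <= 0
    if np.any(degenerate):
        t = t.copy()
        t[degenerate] = np.sign(diff[degenerate]) * np.where(
            diff[degenerate] == 0, 0.0, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, df


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _as_frame(phenotypes) -> pd.DataFrame:
    if isinstance(phenotypes, pd.DataFrame):
        return phenotypes.copy()
    if phenotypes and isinstance(phenotypes[0], SubjectPhenotype):
        return phenotypes_to_frame(phenotypes)
    raise ValidationError("phenotypes must be a DataFrame or list of SubjectPhenotype")


def _motion_column(motion_measure: str) -> str:
    if motion_measure not in ("rms", "fd"):
        raise ValidationError("motion_measure must be 'rms' or 'fd'")
    return "mean_rms" if motion_measure == "rms" else "mean_fd"


def _covariate_matrix(pheno: pd.DataFrame, covariates: Sequence[str],
                      motion_measure: str) -> tuple[np.ndarray, list[str]]:
    columns: list[np.ndarray] = [np.ones(len(pheno))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "age":
            values = pheno["age"].to_numpy(dtype=float)
        elif cov == "sex":
            values = (pheno["sex"].to_numpy() == "F").astype(float)
        elif cov == "motion":
            col = _motion_column(motion_measure)
            if col not in pheno.columns or pheno[col].isna().any():
                missing = (pheno.loc[pheno[col].isna(), "subject_id"].tolist()
                           if col in pheno.columns else "all")
                raise ValidationError(
                    f"motion covariate {col!r} missing for subjects {missing}; "
                    "supply motion files or phenotype values"
                )
            values = pheno[col].to_numpy(dtype=float)
        else:
            if cov not in pheno.columns:
                raise ValidationError(f"unknown covariate {cov!r}")
            values = pheno[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"covariate {cov!r} contains non-finite values")
        columns.append(values)
        names.append(cov)
    return np.column_stack(columns), names


def _group_dummies(pheno: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    groups = pheno["group"].to_numpy()
    present = [g for g in GROUP_LABELS if g in set(groups)]
    if len(present) < 2:
        raise ValidationError("need at least two groups for a group comparison")
    # last present label is the reference level
    dummies = np.column_stack([(groups == g).astype(float) for g in present[:-1]])
    return dummies, [f"group[{g}]" for g in present[:-1]]


def _pivot_auc(auc_table: pd.DataFrame, pheno: pd.DataFrame
               ) -> tuple[np.ndarray, list[tuple[str, Optional[int]]], pd.DataFrame]:
    """Wide Y matrix aligned to phenotype rows, plus (metric, node) keys."""
    required = {"subject_id", "metric", "node", "auc"}
    if not required <= set(auc_table.columns):
        raise ValidationError(f"AUC table must have columns {sorted(required)}")
    key = (auc_table["metric"].astype(str) + "\t"
           + auc_table["node"].map(lambda v: "" if pd.isna(v) else str(int(v))))
    wide = auc_table.assign(_key=key).pivot(index="subject_id", columns="_key",
                                            values="auc")
    wide = wide.reindex(sorted(wide.columns), axis=1)
    missing = set(pheno["subject_id"]) - set(wide.index)
    if missing:
        raise ValidationError(f"AUC values missing for subjects {sorted(missing)[:5]}")
    if wide.isna().any().any():
        col = wide.columns[wide.isna().any()][0]
        raise ValidationError(f"AUC table has missing cells for {col.replace(chr(9), ' node ')}")
    pheno = pheno[pheno["subject_id"].isin(wide.index)].reset_index(drop=True)
    wide = wide.loc[pheno["subject_id"]]
    keys = []
    for column in wide.columns:
        metric, _, node = column.partition("\t")
        keys.append((metric, None if node == "" else int(node)))
    return wide.to_numpy(dtype=float), keys, pheno


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def omnibus_ancova(auc_table: pd.DataFrame, phenotypes,
                   covariates: Sequence[str] = DEFAULT_COVARIATES, *,
                   motion_measure: str = "rms") -> pd.DataFrame:
    """Covariate-adjusted three-group omnibus F test per (metric, node).

    Fits ``auc ~ intercept + group indicators + covariates`` and tests the
    group indicators jointly via the extra-sum-of-squares partial F.  Pass
    ``covariates=()`` for a classical one-way ANOVA.
    """
    pheno = _as_frame(phenotypes)
    Y, keys, pheno = _pivot_auc(auc_table, pheno)
    X_cov, cov_names = _covariate_matrix(pheno, covariates, motion_measure)
    dummies, dummy_names = _group_dummies(pheno)
    X_full = np.column_stack([X_cov[:, :1], dummies, X_cov[:, 1:]])
    names = ["intercept"] + dummy_names + cov_names[1:]
    _check_full_rank(X_full, names)
    X_reduced = np.column_stack([X_cov[:, :1], X_cov[:, 1:]])
    F, p, df_between, df_within = partial_f_test(Y, X_full, X_reduced)
    return pd.DataFrame({
        "metric": [k[0] for k in keys],
        "node": pd.array([k[1] for k in keys], dtype="Float64"),
        "f_stat": F,
        "p_value": p,
        "df_between": df_between,
        "df_within": df_within,
        "covariates_used": [",".join(covariates)] * len(keys),
    })


def default_family_sizes(keys: Iterable[tuple[str, Optional[int]]],
                         n_pairs: int) -> dict[str, int]:
    """Bonferroni family per metric: node count for nodal metrics, the
    number of group pairs for global metrics."""
    counts: dict[str, set] = {}
    for metric, node in keys:
        counts.setdefault(metric, set()).add(node)
    return {
        metric: (n_pairs if nodes == {None} else len(nodes))
        for metric, nodes in counts.items()
    }


def posthoc_pairwise(auc_table: pd.DataFrame, phenotypes,
                     pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
                     covariates: Sequence[str] = DEFAULT_COVARIATES, *,
                     motion_measure: str = "rms", welch: bool = False,
                     family_sizes: Optional[dict[str, int]] = None
                     ) -> pd.DataFrame:
    """Pairwise post-hoc t-tests on covariate-residualised AUC values.

    Covariates are regressed out of the *full* sample once; each pair is then
    compared with a two-sample t-test (pooled variance unless ``welch``) and
    Bonferroni-corrected over the per-metric family.
    """
    pheno = _as_frame(phenotypes)
    Y, keys, pheno = _pivot_auc(auc_table, pheno)
    X_cov, cov_names = _covariate_matrix(pheno, covariates, motion_measure)
    _check_full_rank(X_cov, cov_names)
    resid = residualize(Y, X_cov)
    groups = pheno["group"].to_numpy()
    if family_sizes is None:
        family_sizes = default_family_sizes(keys, n_pairs=len(pairs))
    rows = []
    for g1, g2 in pairs:
        mask1 = groups == g1
        mask2 = groups == g2
        if mask1.sum() < 2 or mask2.sum() < 2:
            raise ValidationError(f"pair ({g1}, {g2}): each group needs >= 2 subjects")
        t, p, _ = pooled_t(resid[mask1], resid[mask2], welch=welch)
        means1 = resid[mask1].mean(axis=0)
        means2 = resid[mask2].mean(axis=0)
        for j, (metric, node) in enumerate(keys):
            family = family_sizes[metric]
            rows.append({
                "metric": metric,
                "node": node,
                "pair": f"{g1} vs {g2}",
                "t_stat": float(t[j]),
                "p_raw": float(p[j]),
                "p_bonferroni": min(1.0, float(p[j]) * family),
                "direction": int(np.sign(means1[j] - means2[j])),
                "family_size": family,
            })
    frame = pd.DataFrame(rows)
    frame["node"] = frame["node"].astype("Float64")
    return frame


def demographic_tests(phenotypes) -> pd.DataFrame:
    """Classical group comparisons of the phenotype table.

    One-way ANOVA across the three groups for continuous variables, a
    Pearson chi-square on the sex-by-group contingency table, and a pooled
    two-sample t-test for disease duration (patients only).
    """
    pheno = _as_frame(phenotypes)
    rows = []
    groups = [pheno[pheno["group"] == g] for g in GROUP_LABELS]
    for variable in _ANOVA_VARIABLES:
        if variable not in pheno.columns:
            continue
        samples = [g[variable].dropna().to_numpy(dtype=float) for g in groups]
        if any(len(s) < 2 for s in samples):
            continue
        f_stat, p = stats.f_oneway(*samples)
        rows.append({"variable": variable, "test": "ANOVA-F",
                     "statistic": float(f_stat), "p_value": float(p)})
    # sex: 2 x 3 contingency
    table = np.array([
        [int(((g["sex"] == s)).sum()) for g in groups] for s in ("M", "F")
    ])
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ComputationError("chi-square expected cell count of zero in sex table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    rows.append({"variable": "sex", "test": "chi-square",
                 "statistic": float(chi2), "p_value": float(p)})
    if "duration_months" in pheno.columns:
        d1 = pheno.loc[pheno["group"] == "D-AD", "duration_months"].dropna()
        d2 = pheno.loc[pheno["group"] == "nD-AD", "duration_months"].dropna()
        if len(d1) >= 2 and len(d2) >= 2:
            t, p = stats.ttest_ind(d1, d2, equal_var=True)
            rows.append({"variable": "duration_months", "test": "t",
                         "statistic": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)


def normality_tests(phenotypes) -> pd.DataFrame:
    """Jarque-Bera screen of each continuous phenotype variable (all groups)."""
    pheno = _as_frame(phenotypes)
    rows = []
    for variable in _ANOVA_VARIABLES + ("duration_months",):
        if variable not in pheno.columns:
            continue
        values = pheno[variable].dropna().to_numpy(dtype=float)
        if len(values) < 4 or np.ptp(values) == 0:
            continue
        jb, p = jarque_bera(values)
        rows.append({"variable": variable, "test": "Jarque-Bera",
                     "statistic": jb, "p_value": p})
    return pd.DataFrame(rows)


def clinical_correlations(auc_table: pd.DataFrame, phenotypes,
                          scales: Sequence[str] = ("mmse", "dnpi", "hamd"),
                          groups: Sequence[str] = ("D-AD", "nD-AD")
                          ) -> pd.DataFrame:
    """Pearson correlation of each metric AUC with each clinical scale.

    Computed within each requested group; constant scales within a group are
    flagged not-computable (NaN) rather than failing the run.
    """
    pheno = _as_frame(phenotypes)
    Y, keys, pheno = _pivot_auc(auc_table, pheno)
    rows = []
    for group in groups:
        mask = (pheno["group"] == group).to_numpy()
        for scale in scales:
            if scale not in pheno.columns:
                continue
            values = pheno.loc[mask, scale].to_numpy(dtype=float)
            ok = np.isfinite(values)
            for j, (metric, node) in enumerate(keys):
                y = Y[mask, j][ok]
                x = values[ok]
                if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(y, x)
                rows.append({
                    "metric": metric, "node": node, "clinical_scale": scale,
                    "group": group, "r": float(r) if np.isfinite(r) else np.nan,
                    "p_value": float(p) if np.isfinite(p) else np.nan,
                })
    frame = pd.DataFrame(rows)
    frame["node"] = frame["node"].astype("Float64")
    return frame
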