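import numpy as np
import pandas as pd
import pytest
from scipy import stats

from costnet.errors import ComputationError, ValidationError
from costnet.inference import (clinical_correlations, demographic_tests,
                               jarque_bera, normality_tests, omnibus_ancova,
                               partial_f_test, pooled_t, posthoc_pairwise,
                               residualize)


def make_phenotypes(rng, n_per_group=(8, 7, 7)):
    rows = []
    for group, n in zip(("D-AD", "nD-AD", "NC"), n_per_group):
        for i in range(n):
            rows.append({
                "subject_id": f"{group}-{i}", "group": group,
                "age": float(rng.uniform(65, 80)),
                "sex": "M" if rng.random() < 0.5 else "F",
                "mmse": float(rng.uniform(18, 30)),
                "hamd": float(rng.uniform(0, 15)),
                "dnpi": float(rng.uniform(0, 8)),
                "mean_rms": float(rng.uniform(0.02, 0.15)),
                "mean_fd": float(rng.uniform(0.1, 0.4)),
            })
    return pd.DataFrame(rows)


def make_auc(pheno, values_by_metric):
    rows = []
    for _, subject in pheno.iterrows():
        for metric, values in values_by_metric.items():
            value = values[subject["subject_id"]]
            if np.ndim(value) == 0:
                rows.append({"subject_id": subject["subject_id"],
                             "metric": metric, "node": np.nan,
                             "auc": float(value)})
            else:
                for node, v in enumerate(value, start=1):
                    rows.append({"subject_id": subject["subject_id"],
                                 "metric": metric, "node": node,
                                 "auc": float(v)})
    return pd.DataFrame(rows)


class TestJarqueBera:
    def test_formula_against_manual_moments(self, rng):
        x = rng.standard_normal(200) ** 2  # skewed sample
        n = len(x)
        centred = x - x.mean()
        s = (centred ** 3).mean() / (centred ** 2).mean() ** 1.5
        k = (centred ** 4).mean() / (centred ** 2).mean() ** 2 - 3
        expected = n / 6 * (s ** 2 + k ** 2 / 4)
        jb, p = jarque_bera(x)
        assert jb == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected, 2), rel=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(60)
        jb1, _ = jarque_bera(x)
        jb2, _ = jarque_bera(5.0 * x - 3.0)
        assert jb1 == pytest.approx(jb2, rel=1e-9)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            jarque_bera(np.full(10, 2.0))


class TestOmnibus:
    def test_identical_values_give_f_zero(self, rng):
        pheno = make_phenotypes(rng)
        auc = make_auc(pheno, {"ge": {s: 1.0 for s in pheno.subject_id}})
        result = omnibus_ancova(auc, pheno, covariates=())
        assert result.loc[0, "f_stat"] == 0.0
        assert result.loc[0, "p_value"] == pytest.approx(1.0)

    def test_no_covariates_equals_classic_anova(self, rng):
        pheno = make_phenotypes(rng)
        values = {s: rng.normal() for s in pheno.subject_id}
        auc = make_auc(pheno, {"ge": values})
        result = omnibus_ancova(auc, pheno, covariates=())
        samples = [np.array([values[s] for s in pheno.loc[pheno.group == g,
                                                          "subject_id"]])
                   for g in ("D-AD", "nD-AD", "NC")]
        f_ref, p_ref = stats.f_oneway(*samples)
        assert result.loc[0, "f_stat"] == pytest.approx(f_ref, rel=1e-10)
        assert result.loc[0, "p_value"] == pytest.approx(p_ref, rel=1e-10)

    def test_partial_f_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        pheno = make_phenotypes(rng, n_per_group=(4, 4, 4))
        values = {s: rng.normal() for s in pheno.subject_id}
        auc = make_auc(pheno, {"ge": values})
        result = omnibus_ancova(auc, pheno)
        y = np.array([values[s] for s in pheno.subject_id])
        dummies = np.column_stack([
            (pheno.group == "D-AD").astype(float),
            (pheno.group == "nD-AD").astype(float),
        ])
        covs = np.column_stack([
            pheno.age, (pheno.sex == "F").astype(float), pheno.mean_rms,
        ])
        full = sm.OLS(y, sm.add_constant(np.column_stack([dummies, covs]))).fit()
        restriction = np.zeros((2, 6))
        restriction[0, 1] = restriction[1, 2] = 1.0
        f_test = full.f_test(restriction)
        assert result.loc[0, "f_stat"] == pytest.approx(float(f_test.fvalue),
                                                        rel=1e-8)
        assert result.loc[0, "p_value"] == pytest.approx(float(f_test.pvalue),
                                                         rel=1e-8)

    def test_planted_shift_is_detected(self, rng):
        # a 3-residual-SD group shift must be essentially always significant
        pheno = make_phenotypes(rng, n_per_group=(20, 20, 20))
        rejected = 0
        reps = 100
        shift = (pheno.group == "D-AD").to_numpy(dtype=float) * 3.0
        for _ in range(reps):
            values = dict(zip(pheno.subject_id, rng.standard_normal(60) + shift))
            auc = make_auc(pheno, {"ge": values})
            result = omnibus_ancova(auc, pheno)
            rejected += result.loc[0, "p_value"] < 0.001
        assert rejected >= 99

    def test_rank_deficiency_names_column(self, rng):
        pheno = make_phenotypes(rng)
        pheno["mean_rms"] = 0.1  # constant covariate -> collinear with intercept
        auc = make_auc(pheno, {"ge": {s: rng.normal() for s in pheno.subject_id}})
        with pytest.raises(ComputationError, match="motion"):
            omnibus_ancova(auc, pheno)

    def test_row_order_invariance(self, rng):
        pheno = make_phenotypes(rng)
        values = {s: rng.normal() for s in pheno.subject_id}
        auc = make_auc(pheno, {"ge": values})
        base = omnibus_ancova(auc, pheno)
        shuffled = omnibus_ancova(auc.sample(frac=1.0, random_state=1),
                                  pheno.sample(frac=1.0, random_state=2))
        assert base.loc[0, "f_stat"] == pytest.approx(shuffled.loc[0, "f_stat"])


class TestPosthoc:
    def test_pooled_t_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        t, p, df = pooled_t(x[:, None], y[:, None])
        # (xbar - ybar) / (s_p * sqrt(1/n1 + 1/n2)), s_p^2 = 5/3
        s_p = np.sqrt(5 / 3)
        expected = -2.0 / (s_p * np.sqrt(0.5))
        assert t[0] == pytest.approx(expected, rel=1e-12)
        assert t[0] == pytest.approx(-2.1908902300206643, rel=1e-12)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=True)
        assert t[0] == pytest.approx(t_ref) and p[0] == pytest.approx(p_ref)

    def test_identical_groups_not_significant(self, rng):
        pheno = make_phenotypes(rng)
        auc = make_auc(pheno, {"ge": {s: 5.0 for s in pheno.subject_id}})
        result = posthoc_pairwise(auc, pheno, covariates=())
        assert np.all(result["t_stat"] == 0.0)
        assert np.all(result["p_bonferroni"] == 1.0)

    def test_bonferroni_cap_and_family_sizes(self, rng):
        pheno = make_phenotypes(rng)
        nodal = {s: rng.standard_normal(90) for s in pheno.subject_id}
        glob = {s: rng.normal() for s in pheno.subject_id}
        auc = make_auc(pheno, {"ne": nodal, "ge": glob})
        result = posthoc_pairwise(auc, pheno, covariates=())
        families = result.groupby("metric")["family_size"].unique()
        assert families["ne"].tolist() == [90]
        assert families["ge"].tolist() == [3]
        np.testing.assert_allclose(
            result["p_bonferroni"],
            np.minimum(1.0, result["p_raw"] * result["family_size"]),
        )
        assert min(1.0, 0.02 * 90) == 1.0  # capped, never reported above 1

    def test_direction_matches_adjusted_means(self, rng):
        pheno = make_phenotypes(rng)
        X = np.column_stack([np.ones(len(pheno)), pheno.age,
                             (pheno.sex == "F").astype(float), pheno.mean_rms])
        values = {s: rng.normal() for s in pheno.subject_id}
        auc = make_auc(pheno, {"ge": values})
        result = posthoc_pairwise(auc, pheno)
        y = np.array([values[s] for s in pheno.subject_id])[:, None]
        resid = residualize(y, X)[:, 0]
        for _, row in result.iterrows():
            g1, g2 = row["pair"].split(" vs ")
            diff = (resid[pheno.group == g1].mean()
                    - resid[pheno.group == g2].mean())
            assert row["direction"] == np.sign(diff)


class TestDemographics:
    def test_sex_chi_square_against_expected_count_oracle(self):
        rows = []
        for group, (m, f) in (("D-AD", (17, 7)), ("nD-AD", (10, 10)),
                              ("NC", (11, 9))):
            for i in range(m + f):
                rows.append({"subject_id": f"{group}{i}", "group": group,
                             "age": 70.0, "sex": "M" if i < m else "F"})
        pheno = pd.DataFrame(rows)
        table = np.array([[17, 10, 11], [7, 10, 9]], dtype=float)
        expected = table.sum(1)[:, None] * table.sum(0)[None, :] / table.sum()
        chi2_oracle = ((table - expected) ** 2 / expected).sum()
        result = demographic_tests(pheno)
        row = result[result.variable == "sex"].iloc[0]
        assert row["statistic"] == pytest.approx(chi2_oracle, rel=1e-10)

    def test_identical_groups_give_f_zero(self):
        rows = []
        for group in ("D-AD", "nD-AD", "NC"):
            for i in range(5):
                rows.append({"subject_id": f"{group}{i}", "group": group,
                             "age": 70.0 + i, "sex": "M" if i % 2 else "F"})
        result = demographic_tests(pd.DataFrame(rows))
        age = result[result.variable == "age"].iloc[0]
        assert age["statistic"] == pytest.approx(0.0, abs=1e-10)

    def test_proportional_sex_table_chi_square_zero(self):
        rows = []
        for group in ("D-AD", "nD-AD", "NC"):
            for i in range(10):
                rows.append({"subject_id": f"{group}{i}", "group": group,
                             "age": 70.0 + (i % 3), "sex": "M" if i < 5 else "F"})
        result = demographic_tests(pd.DataFrame(rows))
        row = result[result.variable == "sex"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_normality_screen_runs_on_phenotypes(self, rng):
        pheno = make_phenotypes(rng)
        result = normality_tests(pheno)
        assert {"age", "mmse"} <= set(result.variable)
        assert np.all(result.statistic >= 0)


class TestCorrelations:
    def test_perfect_correlation(self, rng):
        pheno = make_phenotypes(rng)
        values = {s: float(pheno.loc[pheno.subject_id == s, "mmse"].iloc[0])
                  for s in pheno.subject_id}
        auc = make_auc(pheno, {"ge": values})
        result = clinical_correlations(auc, pheno, scales=("mmse",))
        assert np.allclose(result["r"], 1.0)

    def test_affine_invariance(self, rng):
        pheno = make_phenotypes(rng)
        values = {s: rng.normal() for s in pheno.subject_id}
        auc1 = make_auc(pheno, {"ge": values})
        auc2 = make_auc(pheno, {"ge": {k: 3 * v + 1 for k, v in values.items()}})
        r1 = clinical_correlations(auc1, pheno, scales=("hamd",))["r"]
        r2 = clinical_correlations(auc2, pheno, scales=("hamd",))["r"]
        np.testing.assert_allclose(r1, r2, rtol=1e-10)

    def test_constant_scale_flagged_not_fatal(self, rng):
        pheno = make_phenotypes(rng)
        pheno["hamd"] = 4.0
        auc = make_auc(pheno, {"ge": {s: rng.normal() for s in pheno.subject_id}})
        result = clinical_correlations(auc, pheno, scales=("hamd",))
        assert result["r"].isna().all()

    def test_type_one_error_calibration(self, rng):
        # independent AUC and scale: |r| exceeds the 5% critical value ~5%
        n, reps = 20, 1000
        critical = stats.t.ppf(0.975, n - 2)
        hits = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r ** 2))
            hits += abs(t) > critical
        assert 0.03 < hits / reps < 0.07
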