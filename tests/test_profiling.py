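import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from calseg import (
    ModelSpec,
    SurveyDesign,
    collinearity_check,
    fit_all_clusters,
    fit_membership,
    spec_from_data,
)
from calseg.profiling import SeparationError, encode_design


def simulate_logit(rng, n=400, beta=(-0.3, 0.8)):
    x = rng.integers(0, 2, n)
    eta = beta[0] + beta[1] * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    data = pd.DataFrame({"x": np.where(x == 1, "yes", "no")})
    return y, data


def iid_design(n, weight=None):
    """One PSU per observation, one stratum: the classical iid setting."""
    return SurveyDesign(
        weight=np.ones(n) if weight is None else weight,
        psu=np.arange(n),
        stratum=np.zeros(n, dtype=int),
    )


class TestFitMembership:
    def test_matches_independent_ml_fit(self, rng):
        y, data = simulate_logit(rng)
        n = len(y)
        spec = ModelSpec("c", {"x": (("no", "yes"), "no")})
        m = fit_membership(y, spec, data, iid_design(n))

        X = sm.add_constant((data["x"] == "yes").astype(float).to_numpy())
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(m.coefficients, ref.params, atol=1e-6)

    def test_sandwich_equals_scaled_robust_covariance(self, rng):
        # with one PSU per row in one stratum the linearized covariance is
        # the HC0 sandwich times n/(n-p) (the stratum and df corrections)
        y, data = simulate_logit(rng)
        n = len(y)
        spec = ModelSpec("c", {"x": (("no", "yes"), "no")})
        m = fit_membership(y, spec, data, iid_design(n))

        X = sm.add_constant((data["x"] == "yes").astype(float).to_numpy())
        ref = sm.Logit(y, X).fit(disp=0, cov_type="HC0")
        p = X.shape[1]
        np.testing.assert_allclose(
            m.covariance, np.asarray(ref.cov_params()) * n / (n - p), atol=1e-6
        )

    def test_two_by_two_closed_form_odds_ratio(self):
        # cells (x=1,y=1)=10, (x=1,y=0)=20, (x=0,y=1)=20, (x=0,y=0)=10
        y = np.array([1] * 10 + [0] * 20 + [1] * 20 + [0] * 10, dtype=float)
        x = ["yes"] * 30 + ["no"] * 30
        data = pd.DataFrame({"x": x})
        spec = ModelSpec("c", {"x": (("no", "yes"), "no")})
        m = fit_membership(y, spec, data, iid_design(60))
        i = m.term_names.index("x=yes")
        assert m.odds_ratios[i] == pytest.approx(0.25, rel=1e-6)
        assert m.coefficients[i] == pytest.approx(np.log(0.25), abs=1e-6)

    def test_weight_scale_invariance(self, rng):
        y, data = simulate_logit(rng)
        n = len(y)
        w = rng.random(n) + 0.5
        spec = ModelSpec("c", {"x": (("no", "yes"), "no")})
        psu = rng.integers(0, 20, n)
        stratum = psu // 5
        a = fit_membership(y, spec, data,
                           SurveyDesign(weight=w, psu=psu, stratum=stratum))
        b = fit_membership(y, spec, data,
                           SurveyDesign(weight=w * 1000, psu=psu, stratum=stratum))
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-10)
        np.testing.assert_allclose(a.covariance, b.covariance, atol=1e-10)

    def test_design_df(self):
        d = SurveyDesign(
            weight=np.ones(12),
            psu=np.array([0, 0, 1, 1, 2, 2, 0, 0, 1, 1, 2, 2]),
            stratum=np.array([0] * 6 + [1] * 6),
        )
        assert d.df == 6 - 2

    def test_singleton_psu_stratum_collapsed(self, caplog):
        d = SurveyDesign(
            weight=np.ones(6),
            psu=np.array([0, 0, 1, 1, 9, 9]),
            stratum=np.array([0, 0, 0, 0, 7, 7]),
        )
        assert d.n_strata == 1  # stratum 7 had one PSU and was merged

    def test_separation_raises(self, rng):
        y = np.array([0.0] * 20 + [1.0] * 20)
        data = pd.DataFrame({"x": ["no"] * 20 + ["yes"] * 20})
        spec = ModelSpec("c", {"x": (("no", "yes"), "no")})
        with pytest.raises(SeparationError):
            fit_membership(y, spec, data, iid_design(40))

    def test_empty_cell_rejected(self):
        data = pd.DataFrame({"x": ["no"] * 5})
        spec = ModelSpec("c", {"x": (("no", "yes"), "no")})
        with pytest.raises(ValueError, match="empty covariate cell.*'yes'"):
            encode_design(data, spec)

    def test_zero_effect_coverage(self, rng):
        """The design-based 95% CI for a null covariate covers OR=1 at
        close to the nominal rate."""
        from scipy import stats

        hits = 0
        reps = 40
        for _ in range(reps):
            n = 600
            z = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n)  # no true effect
            eta = -0.2 + 0.7 * z
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            data = pd.DataFrame({
                "z": np.where(z == 1, "b", "a"),
                "x": np.where(x == 1, "b", "a"),
            })
            psu = rng.integers(0, 30, n)
            design = SurveyDesign(weight=np.ones(n), psu=psu,
                                  stratum=psu // 10)
            spec = ModelSpec("c", {"z": (("a", "b"), "a"),
                                   "x": (("a", "b"), "a")})
            m = fit_membership(y, spec, data, design)
            i = m.term_names.index("x=b")
            half = stats.t.ppf(0.975, m.df) * m.std_errors[i]
            lo, hi = m.coefficients[i] - half, m.coefficients[i] + half
            hits += lo <= 0.0 <= hi
        assert hits >= 33  # ~95% nominal, allowing binomial noise


class TestFitAllClusters:
    def test_combined_table_shape(self, rng):
        n = 300
        data = pd.DataFrame({
            "x": rng.choice(["a", "b", "c"], n),
            "z": rng.choice(["u", "v"], n),
        })
        labels = rng.integers(0, 3, n)
        design = iid_design(n)
        spec = spec_from_data("all", data)
        models, table = fit_all_clusters(labels, spec, data, design)
        assert len(models) == 3
        # one row per non-reference level: (3-1) + (2-1) = 3
        assert table.shape[0] == 3
        for c in range(3):
            assert f"OR_{c}" in table.columns and f"p_{c}" in table.columns

    def test_failed_cluster_does_not_stop_others(self, rng):
        n = 200
        x = rng.integers(0, 2, n)
        data = pd.DataFrame({"x": np.where(x == 1, "b", "a")})
        # cluster 0: all x=a, cluster 1: all x=b (separated); cluster 2 mixed
        labels = x.copy()
        mixed = rng.random(n) < 0.3
        labels[mixed] = 2
        design = iid_design(n)
        spec = spec_from_data("all", data)
        models, table = fit_all_clusters(labels, spec, data, design)
        assert isinstance(models[0], SeparationError)
        assert isinstance(models[1], SeparationError)
        assert hasattr(models[2], "odds_ratios")
        assert np.isnan(table["OR_0"].iloc[0])
        assert np.isfinite(table["OR_2"].iloc[0])


class TestCollinearity:
    def test_orthogonal_design_unit_vifs(self):
        n = 80
        a = np.tile(["x", "y"], n // 2)
        b = np.repeat(["u", "v"], n // 2)
        data = pd.DataFrame({"a": a, "b": b})
        spec = spec_from_data("c", data)
        out = collinearity_check(data, spec)
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-9)
        assert not out["flag"].any()

    def test_duplicated_column_flagged_singular(self):
        a = np.tile(["x", "y"], 40)
        data = pd.DataFrame({"a": a, "b": a})
        spec = spec_from_data("c", data)
        with pytest.warns(UserWarning, match="collinearity"):
            out = collinearity_check(data, spec)
        assert np.isinf(out["vif"]).all()
        assert out["flag"].all()

    def test_correlated_pair_vif_closed_form(self, rng):
        # two binary covariates with correlation ~0.9: VIF ~ 1/(1-0.81)
        n = 4000
        a = rng.integers(0, 2, n)
        flip = rng.random(n) < 0.05
        b = np.where(flip, 1 - a, a)
        data = pd.DataFrame({"a": np.where(a == 1, "y", "n"),
                             "b": np.where(b == 1, "y", "n")})
        spec = spec_from_data("c", data)
        out = collinearity_check(data, spec)
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        np.testing.assert_allclose(out["vif"], 1 / (1 - r2), rtol=1e-6)
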