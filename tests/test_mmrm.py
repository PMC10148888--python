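import numpy as np
import pandas as pd
import pytest
from helpers import oracle_reml_fit

from pwmmrm.mmrm import MMRM, build_design, effect_size
from pwmmrm.simulate import SimConfig, generate_trial


def _complete_trial(arm_sizes=(12, 10, 11), weeks=(4, 8), seed=0, **kw):
    cfg = SimConfig(arm_sizes=arm_sizes, visit_weeks=weeks, dropout_hazard=0.0, **kw)
    return generate_trial(cfg, seed=seed)[0]


def _random_weights(ds, seed=0, lo=0.5, hi=5.0):
    rng = np.random.default_rng(seed)
    return pd.Series(
        rng.uniform(lo, hi, ds.n_subjects), index=[r.subject_id for r in ds.subjects]
    )


class TestDesign:
    def test_column_accounting_two_arms_two_visits(self):
        ds = _complete_trial(arm_sizes=(8, 1, 8), weeks=(4, 8))
        ds = ds.subset([r.subject_id for r in ds.subjects if r.arm != "active_25mg"])
        d = build_design(ds.changes_frame(), "placebo")
        n = ds.n_subjects
        # 2 visit intercepts + 2 arm:visit + baseline + baseline:visit
        assert d.p == 6
        assert sum(p.y.size for p in d.patterns) == 2 * n

    def test_missing_visit_contributes_single_row(self, tiny_dataset):
        d = build_design(tiny_dataset.changes_frame(), "placebo")
        sizes = {sid: pat.y.shape[1] for pat in d.patterns for sid in pat.subject_ids}
        assert sizes["P3"] == 2 and sizes["P1"] == 3

    def test_unobserved_visit_dropped_with_warning(self, tiny_dataset):
        fr = tiny_dataset.changes_frame()
        fr = fr[fr.visit != "week4"]
        with pytest.warns(UserWarning, match="week4"):
            d = build_design(fr, "placebo", visit_order=("week2", "week4", "week8"))
        assert d.visit_labels == ("week2", "week8")

    def test_nonpositive_weight_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            build_design(tiny_dataset.changes_frame(), "placebo", weights={"P1": 0.0})


class TestClosedFormEquivalence:
    def test_single_visit_matches_ols_ancova(self):
        """With T=1 and unit weights the fit is exactly OLS ANCOVA with the
        REML (divide by n-p) residual variance."""
        ds = _complete_trial(arm_sizes=(12, 11, 13), weeks=(8,), seed=2)
        fit = MMRM.from_dataset(ds).fit()
        fr = ds.changes_frame()
        X = np.column_stack(
            [
                np.ones(len(fr)),
                (fr.arm == "active_12.5mg").astype(float),
                (fr.arm == "active_25mg").astype(float),
                fr.baseline - fr.baseline.mean(),
            ]
        )
        y = fr["change"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (len(y) - 4)
        assert fit.params["visit[week8]"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.params["active_12.5mg:visit[week8]"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.params["active_25mg:visit[week8]"] == pytest.approx(beta[2], abs=1e-8)
        assert fit.params["baseline_c"] == pytest.approx(beta[3], abs=1e-8)
        assert fit.sigma[0, 0] == pytest.approx(sigma2, abs=1e-8)

    def test_final_visit_contrast_agrees_with_per_visit_ancova(self):
        """Complete data, equal weights: the week-8 treatment x visit
        coefficient equals the covariate-adjusted arm difference from an
        ANCOVA restricted to week 8 (the classical MMRM/ANCOVA agreement)."""
        ds = _complete_trial(arm_sizes=(15, 14, 16), weeks=(2, 4, 8), seed=4)
        fit = MMRM.from_dataset(ds).fit()
        fr = ds.changes_frame()
        w8 = fr[fr.visit == "week8"]
        # center baseline at the same grand mean as the repeated-measures fit
        grand = fr.groupby("subject_id")["baseline"].first().mean()
        X = np.column_stack(
            [
                np.ones(len(w8)),
                (w8.arm == "active_12.5mg").astype(float),
                (w8.arm == "active_25mg").astype(float),
                w8.baseline - grand,
            ]
        )
        beta, *_ = np.linalg.lstsq(X, w8["change"].to_numpy(float), rcond=None)
        assert fit.params["active_12.5mg:visit[week8]"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.params["active_25mg:visit[week8]"] == pytest.approx(beta[2], abs=1e-8)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,hazard", [(0, 0.0), (1, 0.15), (2, 0.25)])
    def test_matches_generic_optimizer(self, seed, hazard):
        cfg = SimConfig(arm_sizes=(7, 6, 7), visit_weeks=(2, 4, 8), dropout_hazard=hazard)
        ds, _ = generate_trial(cfg, seed=seed)
        model = MMRM.from_dataset(ds, weights=_random_weights(ds, seed))
        fit = model.fit()
        llf_oracle, beta_oracle = oracle_reml_fit(model.design)
        assert fit.llf == pytest.approx(llf_oracle, abs=1e-6)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_oracle, atol=1e-6)


class TestWeightSemantics:
    def test_scale_invariance_of_estimates(self):
        ds = _complete_trial(arm_sizes=(10, 9, 10), weeks=(2, 4, 8), seed=5)
        w = _random_weights(ds, seed=1)
        base = MMRM.from_dataset(ds, weights=w).fit()
        for c in (0.1, 7.3):
            scaled = MMRM.from_dataset(ds, weights=w * c).fit()
            assert np.abs(base.params - scaled.params).max() < 1e-8
            assert np.abs(base.bse - scaled.bse).max() < 1e-8
            e0 = base.treatment_effect("active_25mg")
            e1 = scaled.treatment_effect("active_25mg")
            assert abs(e0.p - e1.p) < 1e-8

    def test_unit_weights_equal_no_weights(self):
        ds = _complete_trial(seed=6)
        f0 = MMRM.from_dataset(ds).fit()
        f1 = MMRM.from_dataset(
            ds, weights={r.subject_id: 3.0 for r in ds.subjects}
        ).fit()
        assert np.abs(f0.params - f1.params).max() < 1e-10


@pytest.fixture(scope="module")
def fit():
    ds = _complete_trial(arm_sizes=(14, 13, 15), weeks=(2, 4, 8), seed=7)
    return MMRM.from_dataset(ds).fit()


class TestResults:

    def test_sigma_positive_definite(self, fit):
        assert np.linalg.eigvalsh(fit.sigma).min() > 0
        np.testing.assert_allclose(fit.sigma, fit.sigma.T)

    def test_ls_mean_difference_equals_contrast(self, fit):
        lsm = fit.ls_means("week8").set_index("arm")["ls_mean"]
        eff = fit.treatment_effect("active_25mg")
        assert lsm["active_25mg"] - lsm["placebo"] == pytest.approx(eff.te, abs=1e-12)

    def test_ls_mean_ses_positive(self, fit):
        assert (fit.ls_means()["se"] > 0).all()

    def test_self_contrast_is_null(self, fit):
        eff = fit.treatment_effect("placebo")
        assert eff.te == 0.0 and eff.p == 1.0 and eff.effect_size == 0.0

    def test_missing_arm_rejected(self, fit):
        with pytest.raises(ValueError):
            fit.treatment_effect("no_such_arm")

    def test_satterthwaite_df_bounded_by_residual(self, fit):
        eff = fit.treatment_effect("active_25mg", df_method="satterthwaite")
        assert 1.0 <= eff.df <= fit.resid_df

    def test_summary_renders(self, fit):
        text = fit.summary()
        assert "REML" in text and "active_25mg_vs_placebo" in text

    def test_intercept_only_ls_mean_is_weighted_mean(self):
        # one arm, one visit: the LS mean must equal the weighted mean change
        cfg = SimConfig(
            arms=("placebo",), arm_sizes=(15,), visit_weeks=(8,),
            baseline_mean=(23.8,), baseline_sd=(3.2,), drug_effect_week8=(0.0,),
            dropout_hazard=0.0,
        )
        ds, _ = generate_trial(cfg, seed=3)
        w = _random_weights(ds, seed=4)
        fr = ds.changes_frame()[["subject_id", "arm", "visit", "week", "change"]]
        fr["baseline"] = 0.0  # drop the covariate's influence entirely
        fit = MMRM(fr, placebo_arm="placebo", weights=w).fit()
        ww = w[fr.subject_id].to_numpy()
        expected = float(np.average(fr["change"], weights=ww))
        assert fit.ls_means("week8")["ls_mean"].iloc[0] == pytest.approx(expected, abs=1e-8)


class TestEffectSize:
    @pytest.mark.parametrize(
        "te,se,n1,n2,expected",
        [(2.0, 1.0, 2, 2, 2.0), (1.0, 0.5, 50, 50, 0.4), (0.0, 1.0, 10, 10, 0.0)],
    )
    def test_arithmetic(self, te, se, n1, n2, expected):
        assert effect_size(te, se, n1, n2) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            effect_size(1.0, 0.0, 5, 5)
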