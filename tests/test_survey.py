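import dataclasses

import numpy as np
import pytest

from whtrcut.cutpoint import auc_mann_whitney, derive_cutoff, sweep_table
from whtrcut.diagnostics import confusion_at_cutoff, summarize
from whtrcut.simulate import SimulationConfig, compute_ground_truth, simulate_cohort
from whtrcut.survey import (GridSpec, SurveyDesign,
                            SurveyWeightedCutpointClassifier,
                            weighted_auc_concordance, weighted_confusion,
                            weighted_grid_search, weighted_rate_variance,
                            weighted_summary)


def iid_design(n):
    """Unit weights, single stratum, one PSU per record: the reduction case."""
    return SurveyDesign(np.ones(n))


@pytest.fixture
def marker_data(rng):
    x = rng.normal(0.58, 0.05, 800)
    y = rng.random(800) < 0.25 + 0.5 * (x > 0.58)
    return x, y


class TestDesign:
    def test_weight_validation(self):
        with pytest.raises(ValueError):
            SurveyDesign(np.array([1.0, -2.0]))
        with pytest.raises(ValueError):
            SurveyDesign(np.array([1.0, np.inf]))
        with pytest.raises(ValueError):
            SurveyDesign(np.ones(3), strata=["a", "b"])

    def test_gridspec_validation(self):
        with pytest.raises(ValueError):
            GridSpec(coarse_lo=0.6, coarse_hi=0.5)
        with pytest.raises(ValueError):
            GridSpec(fine_step=0.01, coarse_step=0.01)
        grid = GridSpec().coarse_grid()
        assert grid[0] == 0.50 and grid[-1] == 0.60 and len(grid) == 11


class TestWeightedConfusion:
    def test_reduces_to_unweighted(self, marker_data):
        x, y = marker_data
        tw = weighted_confusion(x, y, iid_design(x.size), 0.58)
        tu = confusion_at_cutoff(x, y, 0.58)
        assert (tw.tp, tw.fp, tw.fn, tw.tn) == (tu.tp, tu.fp, tu.fn, tu.tn)

    def test_scale_invariance(self, marker_data, rng):
        x, y = marker_data
        w = rng.uniform(1, 5, x.size)
        t1 = weighted_confusion(x, y, SurveyDesign(w), 0.58)
        t2 = weighted_confusion(x, y, SurveyDesign(2 * w), 0.58)
        assert t2.tp == pytest.approx(2 * t1.tp)
        assert summarize(t1).sensitivity.value == pytest.approx(
            summarize(t2).sensitivity.value)

    def test_misaligned_design_rejected(self, marker_data):
        x, y = marker_data
        with pytest.raises(ValueError, match="aligned"):
            weighted_confusion(x, y, iid_design(10), 0.58)


class TestRateVariance:
    def test_ratio_of_total_to_itself_has_zero_variance(self, rng):
        y = (rng.random(200) < 0.4).astype(float)
        r, v = weighted_rate_variance(y, y, iid_design(200))
        assert r == 1.0 and v == 0.0

    def test_iid_limit_matches_binomial(self, rng):
        n = 30000
        y = (rng.random(n) < 0.3).astype(float)
        r, v = weighted_rate_variance(y, np.ones(n), iid_design(n))
        assert v == pytest.approx(r * (1 - r) / n, rel=0.05)

    def test_homogeneous_psus_shrink_design_variance(self, rng):
        # identical composition in every PSU: between-PSU variance vanishes
        block = (rng.random(50) < 0.4).astype(float)
        y = np.tile(block, 20)
        psu = np.repeat(np.arange(20), 50)
        des = SurveyDesign(np.ones(1000), strata=np.zeros(1000), psus=psu)
        _, v_design = weighted_rate_variance(y, np.ones(1000), des)
        p = y.mean()
        assert v_design <= p * (1 - p) / 1000
        assert v_design == pytest.approx(0.0, abs=1e-12)

    def test_lonely_psu_warns_but_estimates(self, rng):
        y = (rng.random(60) < 0.5).astype(float)
        strata = np.array([0] * 40 + [1] * 20)
        psu = np.array([0] * 20 + [1] * 20 + [0] * 20)
        des = SurveyDesign(np.ones(60), strata, psu)
        with pytest.warns(UserWarning, match="single PSU"):
            _, v = weighted_rate_variance(y, np.ones(60), des)
        assert np.isfinite(v) and v >= 0


class TestWeightedSummary:
    def test_point_estimates_reduce_to_unweighted(self, marker_data):
        x, y = marker_data
        sw = weighted_summary(x, y, iid_design(x.size), 0.58)
        su = summarize(confusion_at_cutoff(x, y, 0.58))
        for f in ("sensitivity", "specificity", "youden_j", "ppv", "npv",
                  "plr", "nlr", "odds_ratio"):
            assert getattr(sw, f).value == pytest.approx(
                getattr(su, f).value, abs=1e-10)
        assert not sw.iid_cis

    def test_intervals_bracket_estimates(self, marker_data, rng):
        x, y = marker_data
        des = SurveyDesign(rng.uniform(1, 3, x.size),
                           strata=np.repeat([0, 1], x.size // 2),
                           psus=np.tile(np.repeat(np.arange(8), x.size // 16), 2))
        s = weighted_summary(x, y, des, 0.58)
        for f in ("sensitivity", "specificity", "plr", "nlr", "odds_ratio"):
            est = getattr(s, f)
            assert est.lo <= est.value <= est.hi


class TestGridSearch:
    def test_uniform_weights_match_unweighted_on_the_grid(self, marker_data):
        x, y = marker_data
        grid = GridSpec()
        res = weighted_grid_search(x, y, iid_design(x.size), grid)
        # stage-by-stage agreement with the unweighted sweep on the same grids
        coarse_ref = sweep_table(x, y, res.coarse_table["cutoff"].to_numpy())
        assert np.allclose(res.coarse_table["youden_j"], coarse_ref["youden_j"])
        fine_ref = sweep_table(x, y, res.fine_table["cutoff"].to_numpy())
        best = fine_ref.loc[fine_ref["youden_j"].idxmax()]
        assert res.youden_j == pytest.approx(best["youden_j"], abs=1e-12)
        assert abs(res.cutoff - best["cutoff"]) <= grid.fine_step + 1e-9
        assert res.youden_j == pytest.approx(
            res.summary.sensitivity.value + res.summary.specificity.value - 1)

    def test_boundary_triggers_widening(self, rng):
        x = rng.normal(0.70, 0.05, 1500)          # optimum far above 0.60
        y = x + rng.normal(0, 0.02, 1500) > 0.70
        with pytest.warns(UserWarning, match="boundary"):
            res = weighted_grid_search(x, y, iid_design(1500), GridSpec())
        assert res.boundary_widened
        assert res.cutoff > 0.60
        assert abs(res.cutoff - 0.70) < 0.02

    def test_both_stage_tables_retained(self, marker_data):
        x, y = marker_data
        res = weighted_grid_search(x, y, iid_design(x.size))
        assert res.coarse_table is not None and len(res.coarse_table) == 11
        assert res.fine_table is not None and len(res.fine_table) == 21

    def test_zero_weight_class_rejected(self):
        with pytest.raises(ValueError, match="positive weight"):
            weighted_grid_search([0.5, 0.6], [True, True], iid_design(2))


class TestWeightedAuc:
    def test_equals_mann_whitney_under_uniform_weights(self, marker_data):
        x, y = marker_data
        a_mw = auc_mann_whitney(x, y).value
        a_con = weighted_auc_concordance(x, y, iid_design(x.size)).value
        assert abs(a_mw - a_con) < 1e-6

    def test_binary_indicator_closed_form(self, rng):
        x = (rng.random(1000) < 0.5).astype(float)
        y = rng.random(1000) < 0.2 + 0.4 * x
        w = rng.uniform(1, 4, 1000)
        des = SurveyDesign(w)
        auc = weighted_auc_concordance(x, y, des).value
        s = weighted_summary(x, y, des, 0.5)
        expected = (s.sensitivity.value + s.specificity.value) / 2
        assert auc == pytest.approx(expected, abs=1e-10)

    def test_null_predictor_near_half(self, rng):
        x = rng.normal(size=1500)
        y = rng.random(1500) < 0.3
        assert abs(weighted_auc_concordance(x, y, iid_design(1500)).value - 0.5) < 0.04


def test_oversampling_bias_corrected_by_weights(small_cfg):
    """With a strongly oversampled high-risk subgroup the unweighted
    prevalence is biased upward; the design-weighted estimate tracks the
    population value."""
    cfg = dataclasses.replace(
        small_cfg, oversample_factor=4.0, race_latent_shifts=(0.0, 1.0, 0.0, 0.0),
        missingness_rate=0.0, n_per_psu=800, seed=99)
    cohort, _ = simulate_cohort(cfg, compute_truth=False)
    truth = compute_ground_truth(cfg, n_mc=300_000)
    from whtrcut.mets import classify_cohort

    d = classify_cohort(cohort)
    y = d["mets"].astype(bool).to_numpy()
    w = d["weight"].to_numpy(float)
    unweighted = y.mean()
    weighted = (w * y).sum() / w.sum()
    assert unweighted - truth.true_prevalence > 0.015
    assert abs(weighted - truth.true_prevalence) < abs(
        unweighted - truth.true_prevalence) / 2


def test_weighted_estimator_api(marker_data):
    x, y = marker_data
    est = SurveyWeightedCutpointClassifier()
    est.fit(x, y, sample_weight=np.ones_like(x))
    assert 0.49 <= est.cutoff_ <= 0.61
    np.testing.assert_array_equal(est.predict(x), x > est.cutoff_)
    assert est.get_params()["fine_step"] == 0.001
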