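import numpy as np
import pytest
from sklearn.base import clone

from whtrcut.cutpoint import (YoudenCutpointClassifier, auc_mann_whitney,
                              derive_cutoff, sweep_table)


def brute_force_best(x, y):
    """Independent oracle: evaluate J of 'x > c' at every unique value by
    direct comparison, return (smallest argmax cutoff, max J)."""
    best_c, best_j = None, -np.inf
    for c in np.unique(x):
        pos = x > c
        sens = (pos & y).sum() / y.sum()
        spec = (~pos & ~y).sum() / (~y).sum()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    return best_c, best_j


def pairwise_auc(x, y):
    cases, noncases = x[y], x[~y]
    wins = (cases[:, None] > noncases[None, :]).sum()
    ties = (cases[:, None] == noncases[None, :]).sum()
    return (wins + 0.5 * ties) / (cases.size * noncases.size)


def test_perfectly_separated_toy_data():
    res = derive_cutoff([0.4, 0.5, 0.6, 0.7], [False, False, True, True])
    assert res.cutoff == 0.5
    assert res.youden_j == pytest.approx(1.0)
    assert not res.degenerate


def test_anticorrelated_marker_is_degenerate():
    # cases all *below* non-cases: '>' positivity cannot discriminate
    res = derive_cutoff([0.4, 0.45, 0.6, 0.7], [True, True, False, False])
    assert res.youden_j == pytest.approx(0.0, abs=1e-12)
    assert res.degenerate


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both"):
        derive_cutoff([0.5, 0.6], [True, True])
    with pytest.raises(ValueError, match="both"):
        auc_mann_whitney([0.5, 0.6], [False, False])


def test_matches_brute_force_on_random_data(rng):
    for _ in range(50):
        n = rng.integers(20, 120)
        x = np.round(rng.normal(0.58, 0.05, n), 3)  # rounding makes ties
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            continue
        res = derive_cutoff(x, y)
        c, j = brute_force_best(x, y)
        assert res.cutoff == pytest.approx(c)
        assert res.youden_j == pytest.approx(j)


def test_tie_break_rules(rng):
    # duplicate J maxima: 'lowest' keeps the smaller cutoff,
    # 'specificity' the larger
    x = np.array([0.40, 0.50, 0.60, 0.70])
    y = np.array([False, True, False, True])
    low = derive_cutoff(x, y, tie_break="lowest")
    high = derive_cutoff(x, y, tie_break="specificity")
    assert low.tie and high.tie
    assert low.cutoff == 0.40 and high.cutoff == 0.60
    assert low.youden_j == pytest.approx(high.youden_j)


def test_sweep_table_extremes(rng):
    x = rng.uniform(0.45, 0.7, 200)
    y = rng.random(200) < 0.3
    tab = sweep_table(x, y, [x.min() - 1e-9, x.max()])
    assert tab["sensitivity"].iloc[0] == 1 and tab["specificity"].iloc[0] == 0
    assert tab["sensitivity"].iloc[1] == 0 and tab["specificity"].iloc[1] == 1


def test_sweep_consistent_with_derivation(rng):
    x = rng.normal(0.58, 0.05, 300)
    y = rng.random(300) < (x > 0.58) * 0.5 + 0.1
    res = derive_cutoff(x, y)
    row = sweep_table(x, y, [res.cutoff]).iloc[0]
    assert row["youden_j"] == pytest.approx(res.youden_j)
    assert res.youden_j == pytest.approx(res.sweep["youden_j"].max())


def test_auc_perfect_and_null(rng):
    assert auc_mann_whitney([1, 2, 3, 4], [False, False, True, True]).value == 1.0
    x = rng.normal(size=2000)
    y = rng.random(2000) < 0.3          # independent labels
    est = auc_mann_whitney(x, y)
    assert abs(est.value - 0.5) < 0.03
    assert est.lo < 0.5 < est.hi


def test_auc_equals_pairwise_count(rng):
    x = np.round(rng.normal(0.58, 0.04, 200), 3)
    y = rng.random(200) < 0.4
    est = auc_mann_whitney(x, y)
    assert abs(est.value - pairwise_auc(x, y)) < 1e-12


def test_delong_interval_brackets_estimate(rng):
    y = rng.random(500) < 0.4
    x = rng.normal(0, 1, 500) + y * 1.0
    est = auc_mann_whitney(x, y)
    assert 0 <= est.lo < est.value < est.hi <= 1


def test_auc_equals_trapezoid_area_under_empirical_roc(rng):
    """The Mann-Whitney AUC (ties 1/2) equals the trapezoidal area under
    the empirical ROC built from the per-cutoff sweep, on 100 random
    datasets -- ties in the marker produce the diagonal segments."""
    for _ in range(100):
        n = int(rng.integers(30, 200))
        x = np.round(rng.normal(0.58, 0.05, n), 3)
        y = rng.random(n) < 0.35
        if y.all() or not y.any():
            continue
        tab = sweep_table(x, y, np.unique(x))
        fpr = np.concatenate([[1.0], 1 - tab["specificity"].to_numpy()])
        tpr = np.concatenate([[1.0], tab["sensitivity"].to_numpy()])
        area = -np.trapezoid(tpr, fpr)  # fpr runs 1 -> 0
        assert auc_mann_whitney(x, y).value == pytest.approx(area, abs=1e-12)


def test_sex_stratified_equals_presplit(default_run):
    d = default_run.classified
    male = d[d["sex"] == "male"]
    res_split = derive_cutoff(male["whtr"].to_numpy(float),
                              male["mets"].astype(bool).to_numpy(),
                              sex_stratum="male")
    x = d["whtr"].to_numpy(float)
    y = d["mets"].astype(bool).to_numpy()
    mask = (d["sex"] == "male").to_numpy()
    res_masked = derive_cutoff(x[mask], y[mask], sex_stratum="male")
    assert res_masked.cutoff == res_split.cutoff
    assert res_masked.youden_j == pytest.approx(res_split.youden_j)


class TestEstimatorApi:
    def test_fit_predict_and_params(self, rng):
        x = rng.normal(0.58, 0.05, 300)
        y = x + rng.normal(0, 0.03, 300) > 0.58
        est = YoudenCutpointClassifier(tie_break="lowest")
        assert clone(est).get_params()["tie_break"] == "lowest"
        est.fit(x.reshape(-1, 1), y)
        assert hasattr(est, "cutoff_") and hasattr(est, "youden_j_")
        pred = est.predict(x.reshape(-1, 1))
        np.testing.assert_array_equal(pred, x > est.cutoff_)
        assert est.youden_j_ == pytest.approx(est.result_.youden_j)
        est.set_params(compute_auc=False)
        assert est.get_params()["compute_auc"] is False

    def test_rejects_multicolumn_input(self, rng):
        with pytest.raises(ValueError, match="single"):
            YoudenCutpointClassifier().fit(rng.normal(size=(10, 2)),
                                           np.repeat([True, False], 5))
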