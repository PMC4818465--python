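"""Survey-weighted cutpoint analysis under stratified, clustered sampling.

Estimators here are design-based: population totals are estimated by
weighted sums, rates by ratios of weighted totals, and variances by
Taylor linearization — per-observation linearized scores are summed to
primary-sampling-unit (PSU) totals and the between-PSU variance is
accumulated within strata with the usual n_h/(n_h - 1) scaling.  A
stratum containing a single PSU is treated as a certainty unit: its PSU
total is centred at the grand mean of all PSU totals (with a warning)
so small simulated designs remain estimable.

The cutoff search mirrors a two-stage grid procedure: a coarse sweep
(default 0.50–0.60 in steps of 0.01) locates the neighbourhood of the
maximal Youden J, then a fine sweep (default +/-0.01 in steps of 0.001)
around the coarse argmax pins down the reported cutoff.  If the coarse
argmax lands on a grid boundary the grid is widened once and the sweep
rerun before warning.

The weighted AUC follows the survey-logistic route: a weight-
incorporating logistic model of the outcome on the predictor is fitted
and the AUC is the weighted concordance of its fitted probabilities over
case/non-case pairs, each pair weighted by the product of the two
participants' weights, ties counted 1/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin

from .cutpoint import CutpointResult, YoudenCutpointClassifier, _rates_at_cutoffs, _validate_xy
from .diagnostics import ConfusionTable, DiagnosticSummary, Estimate

__all__ = [
    "SurveyDesign",
    "GridSpec",
    "weighted_confusion",
    "weighted_rate_variance",
    "weighted_summary",
    "weighted_grid_search",
    "weighted_auc_concordance",
    "SurveyWeightedCutpointClassifier",
]

_Z95 = 1.959963984540054


@dataclass
class SurveyDesign:
    """Per-participant sampling weights with stratum and PSU labels.

    Weights must be strictly positive and finite.  When strata/PSUs are
    not given, a single stratum with one PSU per record is assumed —
    under that default with unit weights every estimator in this module
    reduces exactly to its unweighted counterpart.
    """

    weights: np.ndarray
    strata: np.ndarray | None = None
    psus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        n = self.weights.size
        if n == 0:
            raise ValueError("empty design")
        if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be strictly positive and finite")
        self.strata = (np.zeros(n, dtype=object) if self.strata is None
                       else np.asarray(self.strata, dtype=object).ravel())
        self.psus = (np.arange(n, dtype=object) if self.psus is None
                     else np.asarray(self.psus, dtype=object).ravel())
        if self.strata.size != n or self.psus.size != n:
            raise ValueError("strata and psus must match the weight vector length")
        # PSU labels are interpreted nested within stratum
        self._cluster = [pd.Series(self.strata, name="stratum"),
                         pd.Series(self.psus, name="psu")]

    def __len__(self) -> int:
        return self.weights.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(df["weight"].to_numpy(float),
                   df["stratum"].to_numpy(object),
                   df["psu"].to_numpy(object))

    def subset(self, mask) -> "SurveyDesign":
        mask = np.asarray(mask, dtype=bool)
        return SurveyDesign(self.weights[mask], self.strata[mask], self.psus[mask])


@dataclass(frozen=True)
class GridSpec:
    """Two-stage cutoff grid: coarse range/step and fine half-width/step."""

    coarse_lo: float = 0.50
    coarse_hi: float = 0.60
    coarse_step: float = 0.01
    fine_halfwidth: float = 0.01
    fine_step: float = 0.001

    def __post_init__(self) -> None:
        if not self.coarse_lo < self.coarse_hi:
            raise ValueError("coarse_lo must be below coarse_hi")
        if min(self.coarse_step, self.fine_step, self.fine_halfwidth) <= 0:
            raise ValueError("steps and half-width must be positive")
        if self.fine_step >= self.coarse_step:
            raise ValueError("fine_step must be smaller than coarse_step")

    def coarse_grid(self) -> np.ndarray:
        n = int(round((self.coarse_hi - self.coarse_lo) / self.coarse_step))
        return np.round(self.coarse_lo + self.coarse_step * np.arange(n + 1), 12)

    def fine_grid(self, center: float) -> np.ndarray:
        n = int(round(2 * self.fine_halfwidth / self.fine_step))
        return np.round(center - self.fine_halfwidth
                        + self.fine_step * np.arange(n + 1), 12)


def _check_alignment(x, design: SurveyDesign) -> None:
    if len(design) != x.size:
        raise ValueError("design is not aligned with the data "
                         f"({len(design)} weights vs {x.size} records)")


def weighted_confusion(whtr, mets, design: SurveyDesign, cutoff: float) -> ConfusionTable:
    """Design-weighted 2x2 table at a cutoff (cells are weight sums)."""
    x, y, _ = _validate_xy(whtr, mets)
    _check_alignment(x, design)
    w = design.weights
    pos = x > cutoff
    return ConfusionTable(tp=float(w[pos & y].sum()), fp=float(w[pos & ~y].sum()),
                          fn=float(w[~pos & y].sum()), tn=float(w[~pos & ~y].sum()),
                          weighted=True)


def _cluster_variance(scores: np.ndarray, design: SurveyDesign) -> float:
    """Stratified between-PSU variance of a total, from per-observation
    linearized scores (weights already folded in)."""
    totals = pd.Series(scores).groupby(design._cluster).sum()
    var = 0.0
    lonely = []
    grand_mean = float(totals.mean())
    for h, t in totals.groupby(level=0):
        n_h = len(t)
        if n_h == 1:
            lonely.append(h)
            var += float((t.iloc[0] - grand_mean) ** 2)
        else:
            var += n_h / (n_h - 1) * float(((t - t.mean()) ** 2).sum())
    if lonely:
        warnings.warn(f"stratum(s) {lonely} contain a single PSU; treated as "
                      "certainty units centred at the grand PSU mean")
    return var


def weighted_rate_variance(numerator, denominator, design: SurveyDesign
                           ) -> tuple[float, float]:
    """Ratio of weighted totals R = X_hat/Y_hat and its linearized variance.

    ``numerator`` and ``denominator`` are per-observation values (usually
    0/1 indicators); the linearized score of R is w_i (x_i - R y_i)/Y_hat.
    """
    num = np.asarray(numerator, dtype=float).ravel()
    den = np.asarray(denominator, dtype=float).ravel()
    _check_alignment(num, design)
    w = design.weights
    y_hat = float((w * den).sum())
    if y_hat <= 0:
        raise ValueError("denominator total must be positive")
    r = float((w * num).sum()) / y_hat
    scores = w * (num - r * den) / y_hat
    return r, _cluster_variance(scores, design)


def _ratio_scores(num, den, design) -> tuple[float, np.ndarray]:
    w = design.weights
    y_hat = float((w * den).sum())
    r = float((w * num).sum()) / y_hat
    return r, w * (num - r * den) / y_hat


def _interval(est: float, var: float, lo_cap=0.0, hi_cap=1.0) -> Estimate:
    se = math.sqrt(max(var, 0.0))
    return Estimate(est, max(est - _Z95 * se, lo_cap), min(est + _Z95 * se, hi_cap))


def _log_interval(est: float, var_log: float) -> Estimate:
    se = math.sqrt(max(var_log, 0.0))
    return Estimate(est, est * math.exp(-_Z95 * se), est * math.exp(_Z95 * se))


def weighted_summary(whtr, mets, design: SurveyDesign, cutoff: float
                     ) -> DiagnosticSummary:
    """Design-based diagnostic suite at a cutoff.

    Point estimates are ratios of weighted totals; every 95 % interval is
    Taylor-linearized with the stratified-cluster variance, including the
    derived measures (J on the natural scale; PLR, NLR and the odds ratio
    on the log scale via the chain rule on the sens/spec scores, which
    keeps the sens–spec design covariance).
    """
    x, y, _ = _validate_xy(whtr, mets)
    _check_alignment(x, design)
    pos = x > cutoff
    yf = y.astype(float)
    posf = pos.astype(float)

    sens, z_sens = _ratio_scores(posf * yf, yf, design)
    spec, z_spec = _ratio_scores((1 - posf) * (1 - yf), 1 - yf, design)
    ppv, z_ppv = _ratio_scores(posf * yf, posf, design)
    npv, z_npv = _ratio_scores((1 - posf) * (1 - yf), 1 - posf, design)

    def v(z):
        return _cluster_variance(z, design)

    j = sens + spec - 1.0
    j_est = Estimate(j, *_interval(j, v(z_sens + z_spec), -1.0, 1.0)[1:])

    plr = sens / (1.0 - spec) if spec < 1 else math.inf
    nlr = (1.0 - sens) / spec if spec > 0 else math.nan
    undefined = []
    if math.isfinite(plr) and plr > 0:
        plr_est = _log_interval(plr, v(z_sens / sens + z_spec / (1.0 - spec)))
    else:
        plr_est, _ = Estimate(plr, math.nan, math.nan), undefined.append("plr")
    if math.isfinite(nlr) and nlr > 0:
        nlr_est = _log_interval(nlr, v(-z_sens / (1.0 - sens) - z_spec / spec))
    else:
        nlr_est, _ = Estimate(nlr, math.nan, math.nan), undefined.append("nlr")
    if math.isfinite(plr) and math.isfinite(nlr) and plr > 0 and nlr > 0:
        odds = plr / nlr
        z_logor = (z_sens * (1.0 / sens + 1.0 / (1.0 - sens))
                   + z_spec * (1.0 / spec + 1.0 / (1.0 - spec)))
        or_est = _log_interval(odds, v(z_logor))
    else:
        or_est, _ = Estimate(math.nan, math.nan, math.nan), undefined.append("odds_ratio")

    return DiagnosticSummary(
        sensitivity=_interval(sens, v(z_sens)),
        specificity=_interval(spec, v(z_spec)),
        youden_j=j_est,
        ppv=_interval(ppv, v(z_ppv)),
        npv=_interval(npv, v(z_npv)),
        plr=plr_est, nlr=nlr_est, odds_ratio=or_est,
        iid_cis=False, undefined=tuple(undefined),
    )


@dataclass
class WeightedCutpointResult(CutpointResult):
    """Two-stage grid-search outcome; retains both stage tables."""

    coarse_table: pd.DataFrame | None = None
    fine_table: pd.DataFrame | None = None
    boundary_widened: bool = False


def _grid_sweep(x, y, w, grid) -> pd.DataFrame:
    sens, spec = _rates_at_cutoffs(x, y, grid, w)
    return pd.DataFrame({"cutoff": grid, "sensitivity": sens,
                         "specificity": spec, "youden_j": sens + spec - 1.0})


def weighted_grid_search(whtr, mets, design: SurveyDesign,
                         grid: GridSpec | None = None,
                         compute_auc: bool = True,
                         sex_stratum: str = "all") -> WeightedCutpointResult:
    """Two-stage survey-weighted Youden search (coarse then fine grid).

    Ties in J resolve to the smallest cutoff.  A coarse argmax on a grid
    boundary triggers one widen-and-rerun of the coarse stage (by the
    full grid span on the offending side), then a warning.
    """
    x, y, _ = _validate_xy(whtr, mets)
    _check_alignment(x, design)
    w = design.weights
    if not (w[y].sum() > 0 and w[~y].sum() > 0):
        raise ValueError("both outcome classes must carry positive weight")
    grid = grid or GridSpec()

    widened = False
    for _attempt in range(2):
        coarse = grid.coarse_grid()
        ct = _grid_sweep(x, y, w, coarse)
        k = int(np.argmax(ct["youden_j"].to_numpy() - 1e-12 * np.arange(len(ct))))
        # (epsilon ramp keeps the smallest cutoff on exact ties)
        c_star = float(ct["cutoff"].iloc[k])
        on_boundary = k in (0, len(ct) - 1)
        if not on_boundary or widened:
            break
        span = grid.coarse_hi - grid.coarse_lo
        grid = replace(grid,
                       coarse_lo=grid.coarse_lo - (span if k == 0 else 0.0),
                       coarse_hi=grid.coarse_hi + (0.0 if k == 0 else span))
        widened = True
    if widened and on_boundary:
        warnings.warn("coarse-grid argmax remained on the boundary after widening")

    fine = grid.fine_grid(c_star)
    ft = _grid_sweep(x, y, w, fine)
    jf = ft["youden_j"].to_numpy()
    kf = int(np.argmax(jf - 1e-12 * np.arange(len(ft))))
    tie = bool((jf >= jf[kf] - 1e-12).sum() > 1)
    cutoff = float(ft["cutoff"].iloc[kf])

    summary = weighted_summary(x, y, design, cutoff)
    table = weighted_confusion(x, y, design, cutoff)
    auc = weighted_auc_concordance(x, y, design) if compute_auc else None
    return WeightedCutpointResult(
        cutoff=cutoff, youden_j=float(jf[kf]), summary=summary, auc=auc,
        n=float(x.size), sex_stratum=sex_stratum, tie=tie,
        degenerate=bool(jf[kf] <= 1e-12), sweep=ft, table=table,
        coarse_table=ct, fine_table=ft, boundary_widened=widened,
    )


def weighted_auc_concordance(predictor, mets, design: SurveyDesign) -> Estimate:
    """Weighted AUC via logistic-model concordance.

    Fits a weight-incorporating logistic regression of the outcome on the
    predictor, then computes the weighted concordance of the fitted
    probabilities: over all case/non-case pairs, the pair weight is the
    product of the two participants' weights and ties count 1/2.  The
    interval is a linearized one treating PSUs as the resampling unit is
    not attempted here; the point estimate is returned with a NaN CI.
    """
    x, y, _ = _validate_xy(predictor, mets)
    _check_alignment(x, design)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    w = design.weights
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y.astype(float), X, family=sm.families.Binomial(),
                         freq_weights=w).fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        raise RuntimeError(f"logistic fit failed for predictor: {exc}") from exc
    if not fit.converged:
        raise RuntimeError("logistic model for the predictor did not converge")
    p = np.asarray(fit.fittedvalues, dtype=float)
    auc = _weighted_concordance(p, y, w)
    return Estimate(auc, math.nan, math.nan)


def _weighted_concordance(score, y, w) -> float:
    """P_w(score_case > score_noncase) + 1/2 P_w(tie), pair weights w_i w_j."""
    order = np.argsort(score, kind="mergesort")
    s, yy, ww = score[order], y[order], w[order]
    # collapse to unique score values with case / non-case weight per value
    uniq, idx = np.unique(s, return_index=True)
    case_w = np.add.reduceat(np.where(yy, ww, 0.0), idx)
    non_w = np.add.reduceat(np.where(yy, 0.0, ww), idx)
    cum_non_below = np.concatenate([[0.0], np.cumsum(non_w)[:-1]])
    total_case, total_non = case_w.sum(), non_w.sum()
    conc = float((case_w * (cum_non_below + 0.5 * non_w)).sum())
    return conc / (total_case * total_non)


class SurveyWeightedCutpointClassifier(ClassifierMixin, BaseEstimator):
    """Survey-weighted Youden threshold classifier (two-stage grid search).

    Parameters mirror :class:`GridSpec`; ``fit`` accepts the design via
    ``sample_weight``, ``strata`` and ``psu`` fit parameters.  With no
    weights the fit degenerates gracefully to unit weights.

    Attributes follow :class:`~whtrcut.cutpoint.YoudenCutpointClassifier`:
    ``cutoff_``, ``youden_j_``, ``summary_``, ``auc_``, ``result_``.
    """

    def __init__(self, coarse_lo: float = 0.50, coarse_hi: float = 0.60,
                 coarse_step: float = 0.01, fine_halfwidth: float = 0.01,
                 fine_step: float = 0.001, compute_auc: bool = True):
        self.coarse_lo = coarse_lo
        self.coarse_hi = coarse_hi
        self.coarse_step = coarse_step
        self.fine_halfwidth = fine_halfwidth
        self.fine_step = fine_step
        self.compute_auc = compute_auc

    def _grid(self) -> GridSpec:
        return GridSpec(self.coarse_lo, self.coarse_hi, self.coarse_step,
                        self.fine_halfwidth, self.fine_step)

    def fit(self, X, y, sample_weight=None, strata=None, psu=None):
        x = YoudenCutpointClassifier._marker(X)
        design = SurveyDesign(np.ones_like(x) if sample_weight is None
                              else sample_weight, strata, psu)
        self.result_ = weighted_grid_search(x, y, design, self._grid(),
                                            compute_auc=self.compute_auc)
        self.cutoff_ = self.result_.cutoff
        self.youden_j_ = self.result_.youden_j
        self.summary_ = self.result_.summary
        self.auc_ = self.result_.auc
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    _marker = staticmethod(YoudenCutpointClassifier._marker)
    decision_function = YoudenCutpointClassifier.decision_function
    predict = YoudenCutpointClassifier.predict
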