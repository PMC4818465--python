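"""Diagnostic-accuracy measures from 2x2 classification tables.

The 2x2 table cross-classifies a binary screening call (waist-to-height
ratio above a cutoff) against metabolic-syndrome status.  Cells may be
plain counts or sums of sampling weights; the point-estimate formulas are
identical, but the closed-form confidence intervals here assume iid counts
and are flagged accordingly on weighted input (design-based intervals live
in :mod:`whtrcut.survey`).

Interval methods: Wilson score for proportions (sensitivity, specificity,
PPV, NPV), log-scale normal intervals for the likelihood ratios, Woolf's
log interval for the odds ratio (0.5 added to every cell only when one is
zero), and a normal interval for Youden's J from the summed Wald variances
of sensitivity and specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Estimate",
    "ConfusionTable",
    "DiagnosticSummary",
    "confusion_at_cutoff",
    "summarize",
    "predictive_values_from_rates",
    "youden_j",
]

_Z95 = 1.959963984540054  # two-sided 95 % normal quantile


class Estimate(NamedTuple):
    """Point estimate with a 95 % confidence interval."""

    value: float
    lo: float
    hi: float

    def round(self, ndigits: int = 2) -> "Estimate":
        return Estimate(*(round(v, ndigits) for v in self))


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's index J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of screening call vs. disease status.

    Cells are nonnegative reals: plain counts for unweighted analyses,
    sums of sampling weights for design-based ones.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    weighted: bool = False

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any((not math.isfinite(c)) or c < 0 for c in cells):
            raise ValueError(f"cells must be finite and >= 0, got {cells}")
        if self.total <= 0:
            raise ValueError("empty table")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_cases(self) -> float:
        return self.tp + self.fn

    @property
    def n_noncases(self) -> float:
        return self.fp + self.tn

    @property
    def degenerate(self) -> bool:
        """True when one disease class is absent (no cases or no non-cases)."""
        return self.n_cases == 0 or self.n_noncases == 0

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.total


@dataclass(frozen=True)
class DiagnosticSummary:
    """The full measure suite for one cutoff: sens/spec, J, predictive
    values, likelihood ratios and the diagnostic odds ratio, each with a
    95 % interval.  Undefined measures (zero denominators) carry NaN and
    are listed in ``undefined``; ``iid_cis`` is False when the table held
    weight sums, in which case the intervals here are not design-based.
    """

    sensitivity: Estimate
    specificity: Estimate
    youden_j: Estimate
    ppv: Estimate
    npv: Estimate
    plr: Estimate
    nlr: Estimate
    odds_ratio: Estimate
    iid_cis: bool = True
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("sensitivity", "specificity", "youden_j", "ppv", "npv",
                     "plr", "nlr", "odds_ratio"):
            est: Estimate = getattr(self, name)
            out[name] = est.value
            out[f"{name}_lo"] = est.lo
            out[f"{name}_hi"] = est.hi
        return out


def confusion_at_cutoff(whtr, mets, cutoff: float, weights=None) -> ConfusionTable:
    """Cross-classify ``whtr > cutoff`` (strict) against ``mets``.

    With ``weights`` the cells are sums of weights rather than counts.
    """
    whtr = np.asarray(whtr, dtype=float)
    mets = np.asarray(mets, dtype=bool)
    if whtr.shape != mets.shape:
        raise ValueError("whtr and mets must have equal length")
    if weights is None:
        w = np.ones_like(whtr)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != whtr.shape:
            raise ValueError("weights must match data length")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        weighted = True
    pos = whtr > cutoff
    return ConfusionTable(
        tp=float(w[pos & mets].sum()),
        fp=float(w[pos & ~mets].sum()),
        fn=float(w[~pos & mets].sum()),
        tn=float(w[~pos & ~mets].sum()),
        weighted=weighted,
    )


def _ratio(num: float, den: float, undefined: list[str], name: str) -> float:
    if den <= 0:
        undefined.append(name)
        return math.nan
    return num / den


def _wilson(successes: float, total: float) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _log_interval(value: float, se_log: float) -> tuple[float, float]:
    return (value * math.exp(-_Z95 * se_log), value * math.exp(_Z95 * se_log))


def summarize(table: ConfusionTable, prevalence: float | None = None) -> DiagnosticSummary:
    """Full diagnostic summary of a 2x2 table.

    ``prevalence`` overrides the table's own case fraction for the
    predictive values (useful when the table comes from a design whose
    sample prevalence is not the population one); by default PPV/NPV are
    computed directly from the table cells.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    undefined: list[str] = []

    sens = _ratio(tp, tp + fn, undefined, "sensitivity")
    spec = _ratio(tn, tn + fp, undefined, "specificity")
    j = sens + spec - 1.0

    if prevalence is None:
        ppv = _ratio(tp, tp + fp, undefined, "ppv")
        npv = _ratio(tn, tn + fn, undefined, "npv")
    else:
        ppv, npv = predictive_values_from_rates(sens, spec, prevalence)

    # likelihood ratios; infinite when spec == 1 or sens == 1 exactly
    plr = sens / (1.0 - spec) if spec < 1.0 else math.inf
    nlr = (1.0 - sens) / spec if spec > 0 else math.nan
    if not math.isfinite(plr):
        undefined.append("plr")
    if nlr == 0.0 or not math.isfinite(nlr):
        undefined.append("nlr")

    if fp * fn > 0:
        odds = (tp * tn) / (fp * fn)
        se_or = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn) if tp * tn > 0 else math.nan
    elif min(tp, fp, fn, tn) == 0 and (tp * tn > 0 or fp * fn > 0):
        # Woolf with 0.5 continuity correction, only when a cell is zero
        a, b, c, d = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        odds = (a * d) / (b * c)
        se_or = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        undefined.append("odds_ratio")
    else:
        odds, se_or = math.nan, math.nan
        undefined.append("odds_ratio")

    def prop_ci(p: float, successes: float, total: float) -> Estimate:
        if not math.isfinite(p):
            return Estimate(p, math.nan, math.nan)
        lo, hi = _wilson(successes, total)
        return Estimate(p, lo, hi)

    sens_est = prop_ci(sens, tp, tp + fn)
    spec_est = prop_ci(spec, tn, tn + fp)
    if prevalence is None:
        ppv_est = prop_ci(ppv, tp, tp + fp)
        npv_est = prop_ci(npv, tn, tn + fn)
    else:
        ppv_est = Estimate(ppv, math.nan, math.nan)
        npv_est = Estimate(npv, math.nan, math.nan)

    # Wald variance sum for J
    var_j = 0.0
    for p, n in ((sens, tp + fn), (spec, tn + fp)):
        var_j += p * (1 - p) / n if (n > 0 and math.isfinite(p)) else math.nan
    j_est = Estimate(j, max(j - _Z95 * math.sqrt(var_j), -1.0),
                     min(j + _Z95 * math.sqrt(var_j), 1.0)) if math.isfinite(var_j) \
        else Estimate(j, math.nan, math.nan)

    # Simel-style log-method intervals for the likelihood ratios
    if math.isfinite(plr) and plr > 0 and tp > 0 and fp > 0:
        se_log_plr = math.sqrt((1 - sens) / tp + spec / fp)
        plr_est = Estimate(plr, *_log_interval(plr, se_log_plr))
    else:
        plr_est = Estimate(plr, math.nan, math.nan)
    if math.isfinite(nlr) and nlr > 0 and fn > 0 and tn > 0:
        se_log_nlr = math.sqrt(sens / fn + (1 - spec) / tn)
        nlr_est = Estimate(nlr, *_log_interval(nlr, se_log_nlr))
    else:
        nlr_est = Estimate(nlr, math.nan, math.nan)

    if math.isfinite(odds) and math.isfinite(se_or) and odds > 0:
        or_est = Estimate(odds, *_log_interval(odds, se_or))
    else:
        or_est = Estimate(odds, math.nan, math.nan)

    return DiagnosticSummary(
        sensitivity=sens_est, specificity=spec_est, youden_j=j_est,
        ppv=ppv_est, npv=npv_est, plr=plr_est, nlr=nlr_est,
        odds_ratio=or_est, iid_cis=not table.weighted,
        undefined=tuple(dict.fromkeys(undefined)),
    )


def predictive_values_from_rates(sensitivity: float, specificity: float,
                                 prevalence: float) -> tuple[float, float]:
    """PPV and NPV from sensitivity, specificity and a prevalence, by Bayes:

    ppv = sens*p / (sens*p + (1-spec)(1-p))
    npv = spec(1-p) / (spec(1-p) + (1-sens)p)

    Degenerate prevalences 0 and 1 return the limit values.
    """
    p = float(prevalence)
    if not 0.0 <= p <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    pos = sensitivity * p + (1.0 - specificity) * (1.0 - p)
    neg = specificity * (1.0 - p) + (1.0 - sensitivity) * p
    ppv = sensitivity * p / pos if pos > 0 else 0.0
    npv = specificity * (1.0 - p) / neg if neg > 0 else 1.0
    return ppv, npv
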