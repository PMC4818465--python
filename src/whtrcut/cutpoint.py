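"""Unweighted ROC cutpoint analysis.

The optimal screening threshold for a continuous marker (here the
waist-to-height ratio) against a binary outcome (metabolic syndrome) is
the value c maximising Youden's J(c) = sensitivity(c) + specificity(c) - 1,
with positivity defined as marker strictly greater than c throughout the
package.  The candidate set is every unique observed marker value, so the
search is exhaustive over distinct empirical ROC points.

AUC is the Mann–Whitney two-sample statistic (probability that a random
case outranks a random non-case, ties counted 1/2), computed from
midranks, with a DeLong variance for the 95 % interval.

`YoudenCutpointClassifier` packages the search as a scikit-learn
classifier so it composes with pipelines and model selection;
:func:`derive_cutoff` is the underlying function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .diagnostics import ConfusionTable, DiagnosticSummary, Estimate, summarize

__all__ = [
    "CutpointResult",
    "derive_cutoff",
    "auc_mann_whitney",
    "sweep_table",
    "YoudenCutpointClassifier",
]

_Z95 = 1.959963984540054


def _validate_xy(whtr, mets, weights=None):
    x = np.asarray(whtr, dtype=float).ravel()
    y = np.asarray(mets, dtype=bool).ravel()
    if x.shape != y.shape:
        raise ValueError("whtr and mets must have equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("whtr contains non-finite values")
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape:
            raise ValueError("weights must match data length")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
    else:
        w = None
    return x, y, w


def _rates_at_cutoffs(x, y, cutoffs, w=None):
    """Vectorised sensitivity/specificity of 'x > c' for many cutoffs.

    Uses sorted cumulative (weight) sums, O((n + k) log n).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if w is None:
        w = np.ones_like(x)
    sens = np.empty_like(cutoffs)
    spec = np.empty_like(cutoffs)
    for mask, out, upper in ((y, sens, True), (~y, spec, False)):
        v = x[mask]
        wv = w[mask]
        order = np.argsort(v, kind="mergesort")
        v, wv = v[order], wv[order]
        cw = np.concatenate([[0.0], np.cumsum(wv)])
        total = cw[-1]
        idx = np.searchsorted(v, cutoffs, side="right")
        above = total - cw[idx]  # weight with value > c
        out[:] = above / total if upper else (total - above) / total
    return sens, spec


@dataclass
class CutpointResult:
    """Outcome of a cutpoint derivation.

    ``cutoff`` maximises Youden's J over the candidate set; ``summary``
    is the full diagnostic suite at that cutoff; ``sweep`` retains the
    per-candidate sens/spec/J table.  ``tie`` marks several candidates
    sharing the maximal J (resolved per the tie-break rule);
    ``degenerate`` marks a best J of zero, i.e. the marker carries no
    discrimination in the '>' direction.
    """

    cutoff: float
    youden_j: float
    summary: DiagnosticSummary
    auc: Estimate | None
    n: float
    sex_stratum: str = "all"
    tie: bool = False
    degenerate: bool = False
    sweep: pd.DataFrame | None = None
    table: ConfusionTable | None = None

    def as_dict(self) -> dict:
        out = {"cutoff": self.cutoff, "youden_j": self.youden_j,
               "n": self.n, "sex_stratum": self.sex_stratum,
               "tie": self.tie, "degenerate": self.degenerate}
        if self.auc is not None:
            out.update(auc=self.auc.value, auc_lo=self.auc.lo, auc_hi=self.auc.hi)
        out.update(self.summary.as_dict())
        return out


def sweep_table(whtr, mets, cutoffs, weights=None) -> pd.DataFrame:
    """Sensitivity, specificity and Youden J of 'whtr > c' at each cutoff."""
    x, y, w = _validate_xy(whtr, mets, weights)
    cutoffs = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if cutoffs.size == 0:
        raise ValueError("cutoffs must be non-empty")
    sens, spec = _rates_at_cutoffs(x, y, cutoffs, w)
    return pd.DataFrame({"cutoff": cutoffs, "sensitivity": sens,
                         "specificity": spec, "youden_j": sens + spec - 1.0})


def _argmax_with_ties(cutoffs, j, tie_break):
    jmax = j.max()
    ties = np.flatnonzero(j >= jmax - 1e-12)
    tie = len(ties) > 1
    if tie_break == "lowest":
        k = ties[0]           # smallest cutoff: preserves sensitivity
    elif tie_break == "specificity":
        k = ties[-1]          # largest cutoff: preserves specificity
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return k, tie


def derive_cutoff(whtr, mets, tie_break: str = "lowest",
                  candidates: str = "observed", compute_auc: bool = True,
                  sex_stratum: str = "all") -> CutpointResult:
    """Exhaustive Youden-optimal cutoff over the observed marker values.

    ``candidates="midpoints"`` searches midpoints between consecutive
    unique values instead (equivalent classifications under strict '>',
    only the reported cutoff value shifts).
    """
    x, y, _ = _validate_xy(whtr, mets)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    cand = np.unique(x)
    if candidates == "midpoints":
        cand = np.concatenate([[cand[0]], (cand[:-1] + cand[1:]) / 2.0]) \
            if cand.size > 1 else cand
    elif candidates != "observed":
        raise ValueError(f"unknown candidates mode {candidates!r}")
    sweep = sweep_table(x, y, cand)
    j = sweep["youden_j"].to_numpy()
    k, tie = _argmax_with_ties(cand, j, tie_break)
    cutoff = float(sweep["cutoff"].iloc[k])
    table = _confusion(x, y, cutoff)
    auc = auc_mann_whitney(x, y) if compute_auc else None
    return CutpointResult(
        cutoff=cutoff, youden_j=float(j[k]), summary=summarize(table),
        auc=auc, n=float(x.size), sex_stratum=sex_stratum, tie=tie,
        degenerate=bool(j[k] <= 1e-12), sweep=sweep, table=table,
    )


def _confusion(x, y, cutoff) -> ConfusionTable:
    pos = x > cutoff
    return ConfusionTable(tp=float((pos & y).sum()), fp=float((pos & ~y).sum()),
                          fn=float((~pos & y).sum()), tn=float((~pos & ~y).sum()))


def auc_mann_whitney(whtr, mets) -> Estimate:
    """Rank-based AUC (ties 1/2) with a DeLong 95 % interval."""
    x, y, _ = _validate_xy(whtr, mets)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    cases, noncases = x[y], x[~y]
    m, n = cases.size, noncases.size
    all_rank = rankdata(np.concatenate([cases, noncases]))
    tx, ty = all_rank[:m], all_rank[m:]
    auc = (tx.sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components (placement values)
    v10 = (tx - rankdata(cases)) / n
    v01 = 1.0 - (ty - rankdata(noncases)) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = math.sqrt(var)
    return Estimate(float(auc), max(auc - _Z95 * se, 0.0), min(auc + _Z95 * se, 1.0))


class YoudenCutpointClassifier(ClassifierMixin, BaseEstimator):
    """Single-marker threshold classifier fitted by the Youden index.

    ``fit(X, y)`` takes a single-column (or 1-d) marker and a binary
    outcome, sweeps every unique observed value as a candidate threshold
    and keeps the J-maximising one; ``predict`` then calls a sample
    positive when its marker strictly exceeds the fitted cutoff.

    Parameters
    ----------
    tie_break : {"lowest", "specificity"}
        Candidate kept when several share the maximal J.  "lowest"
        favours sensitivity, "specificity" the converse.
    candidates : {"observed", "midpoints"}
        Search the observed values or midpoints between them.
    compute_auc : bool
        Also compute the Mann–Whitney AUC with a DeLong interval.

    Attributes
    ----------
    cutoff_ : float          fitted threshold
    youden_j_ : float        J at the fitted threshold
    summary_ : DiagnosticSummary   measure suite at the threshold
    auc_ : Estimate or None  marker AUC
    result_ : CutpointResult full derivation record (incl. sweep table)
    classes_ : ndarray       [False, True]
    """

    def __init__(self, tie_break: str = "lowest", candidates: str = "observed",
                 compute_auc: bool = True):
        self.tie_break = tie_break
        self.candidates = candidates
        self.compute_auc = compute_auc

    @staticmethod
    def _marker(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single marker column")
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValueError("X must be 1-d or a single-column 2-d array")
        return x

    def fit(self, X, y):
        x = self._marker(X)
        self.result_ = derive_cutoff(
            x, y, tie_break=self.tie_break, candidates=self.candidates,
            compute_auc=self.compute_auc)
        self.cutoff_ = self.result_.cutoff
        self.youden_j_ = self.result_.youden_j
        self.summary_ = self.result_.summary
        self.auc_ = self.result_.auc
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "cutoff_")
        return self._marker(X) - self.cutoff_

    def predict(self, X):
        return self.decision_function(X) > 0
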