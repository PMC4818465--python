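"""Logistic-regression validation of a derived cutoff.

The adjusted model predicts metabolic syndrome from the indicator
``whtr > cutoff`` plus race (reference: nonHispanic Caucasian), smoking
days, age and — in pooled fits — sex.  Unweighted fits use maximum
likelihood with Wald inference; weighted fits maximise the
weight-incorporating pseudo-likelihood and report design-based
(stratified, PSU-clustered) sandwich standard errors.

External validation re-applies already-derived cutoffs to a second,
independently collected cohort: contingency tables with the full
diagnostic suite (unweighted full/male/female at the respective cutoffs
and a weighted full-sample table when a design is present) plus the
covariate-adjusted logistic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import RACE_LEVELS
from .diagnostics import confusion_at_cutoff, summarize
from .survey import SurveyDesign, weighted_confusion, weighted_summary

__all__ = ["LogisticFitResult", "fit_validation_model", "external_validate",
           "format_p"]

_Z95 = 1.959963984540054
_RACE_REF = RACE_LEVELS[0]


def format_p(p: float) -> str:
    """Report very small p-values as '<0.0001'."""
    if not np.isfinite(p):
        return "NA"
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


@dataclass
class LogisticFitResult:
    """Odds-ratio table of an adjusted logistic fit.

    ``table`` has one row per term (plus a 'Ref' row for the reference
    race): odds ratio, 95 % CI, p-value.  ``separation`` marks a fit
    rescued by an L2-penalized fallback after (quasi-)separation; its
    intervals are then NaN.
    """

    table: pd.DataFrame
    converged: bool
    weighted: bool
    separation: bool
    n: int

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]

    def as_records(self) -> list[dict]:
        recs = []
        for _, row in self.table.iterrows():
            r = dict(row)
            r["p_display"] = "Ref" if row["term"] == _RACE_REF else format_p(row["p_value"])
            recs.append(r)
        return recs


def _design_matrix(df: pd.DataFrame, cutoff: float, include_sex: bool,
                   include_covariates: bool = True
                   ) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=df.index)
    X["whtr_cutoff"] = (df["whtr"] > cutoff).astype(float)
    if include_covariates:
        for lev in RACE_LEVELS[1:]:
            X[lev] = (df["race"] == lev).astype(float)
        X["smoking_days"] = df["smoking_days"].astype(float)
        X["age"] = df["age"].astype(float)
        if include_sex:
            X["sex_female"] = (df["sex"] == "female").astype(float)
    return X, list(X.columns)


def _cluster_sandwich(X: np.ndarray, y: np.ndarray, p: np.ndarray,
                      w: np.ndarray, design: SurveyDesign) -> np.ndarray:
    """Design-based covariance of pseudo-ML logistic coefficients:
    bread = inverse weighted Fisher information, meat = stratified
    between-PSU covariance of the per-PSU score totals."""
    info = X.T @ (X * (w * p * (1 - p))[:, None])
    bread = np.linalg.inv(info)
    scores = X * (w * (y - p))[:, None]
    totals = pd.DataFrame(scores).groupby(design._cluster).sum()
    meat = np.zeros((X.shape[1], X.shape[1]))
    grand = totals.mean(axis=0).to_numpy()
    for _, t in totals.groupby(level=0):
        tt = t.to_numpy()
        n_h = tt.shape[0]
        if n_h == 1:
            d = tt[0] - grand
            meat += np.outer(d, d)
        else:
            d = tt - tt.mean(axis=0)
            meat += n_h / (n_h - 1) * (d.T @ d)
    return bread @ meat @ bread


def fit_validation_model(classified: pd.DataFrame, cutoff: float,
                         design: SurveyDesign | None = None,
                         sex_stratum: str = "all",
                         include_covariates: bool = True) -> LogisticFitResult:
    """Adjusted logistic model of metabolic syndrome on the cutoff
    indicator, race, smoking, age (and sex for pooled fits).

    Expects a classified cohort table (columns ``whtr`` and ``mets``
    present and non-missing along with the covariates); ``sex_stratum``
    restricts to one sex and drops the sex term.
    ``include_covariates=False`` fits the indicator alone (its odds
    ratio then equals the 2x2-table odds ratio exactly).
    """
    df = classified
    if sex_stratum != "all":
        mask = (df["sex"] == sex_stratum).to_numpy(dtype=bool)
        df = df[mask]
        design = design.subset(mask) if design is not None else None
    needed = (["whtr", "mets", "race", "smoking_days", "age", "sex"]
              if include_covariates else ["whtr", "mets"])
    ok = df[needed].notna().all(axis=1).to_numpy(dtype=bool)
    if not ok.all():
        df = df[ok]
        design = design.subset(ok) if design is not None else None
    y = df["mets"].astype(bool).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    Xdf, terms = _design_matrix(df, cutoff, include_sex=sex_stratum == "all",
                                include_covariates=include_covariates)
    X = sm.add_constant(Xdf.to_numpy(dtype=float))
    colnames = ["intercept"] + terms

    separation = False
    if design is None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            if not converged or np.max(np.abs(fit.params)) > 30:
                raise np.linalg.LinAlgError("suspected separation")
            params, cov = fit.params, fit.cov_params()
        except Exception:
            separation = True
            params, cov, converged = _penalized_fallback(X, y), None, True
            warnings.warn("separation detected; L2-penalized fallback fit "
                          "(point estimates only)")
    else:
        w = design.weights
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
            fit = glm.fit(maxiter=200)
        converged = bool(fit.converged)
        if not converged or np.max(np.abs(fit.params)) > 30:
            separation = True
            params, cov = _penalized_fallback(X, y, w), None
            warnings.warn("separation detected in weighted fit; L2-penalized "
                          "fallback (point estimates only)")
        else:
            params = np.asarray(fit.params)
            p_hat = np.asarray(fit.fittedvalues)
            cov = _cluster_sandwich(X, y, p_hat, w, design)

    rows = []
    for i, name in enumerate(colnames):
        if name == "intercept":
            continue
        beta = params[i]
        if cov is not None:
            se = float(np.sqrt(np.asarray(cov)[i, i]))
            zval = beta / se if se > 0 else np.inf
            pv = 2 * stats.norm.sf(abs(zval))
            lo, hi = np.exp(beta - _Z95 * se), np.exp(beta + _Z95 * se)
        else:
            pv, lo, hi = np.nan, np.nan, np.nan
        rows.append({"term": name, "odds_ratio": float(np.exp(beta)),
                     "ci_lo": float(lo), "ci_hi": float(hi), "p_value": float(pv)})
        if name == "whtr_cutoff" and include_covariates:
            rows.append({"term": _RACE_REF, "odds_ratio": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "p_value": np.nan})
    return LogisticFitResult(table=pd.DataFrame(rows), converged=converged,
                             weighted=design is not None,
                             separation=separation, n=int(len(df)))


def _penalized_fallback(X: np.ndarray, y: np.ndarray, w=None) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1.0, fit_intercept=False, max_iter=1000)
    lr.fit(X, y.astype(int), sample_weight=w)
    return lr.coef_.ravel()


def external_validate(external_classified: pd.DataFrame,
                      cutoffs: dict[str, float],
                      design: SurveyDesign | None = None) -> dict:
    """Apply already-derived cutoffs to an external classified cohort.

    ``cutoffs`` maps 'full', 'male', 'female' to the derivation-sample
    cutoffs.  Produces unweighted full/male/female tables at the
    respective cutoffs, a weighted full-sample table when a design is
    given, and adjusted logistic fits at the full-sample cutoff.  Rows
    with missing outcome are dropped; with sex unavailable the
    sex-specific tables are skipped with a warning.
    """
    df = external_classified
    ok = df["mets"].notna() & df["whtr"].notna()
    df = df[ok.to_numpy(dtype=bool)]
    if design is not None:
        design = design.subset(ok.to_numpy(dtype=bool))
    if len(df) == 0:
        raise ValueError("external cohort has no classified records")
    x = df["whtr"].to_numpy(float)
    y = df["mets"].astype(bool).to_numpy()

    report: dict = {"n": int(len(df)), "cutoffs": dict(cutoffs), "tables": {}}

    def entry(table, summary):
        return {"table": {"tp": table.tp, "fp": table.fp,
                          "fn": table.fn, "tn": table.tn},
                "youden_j": summary.youden_j.value, **summary.as_dict()}

    t = confusion_at_cutoff(x, y, cutoffs["full"])
    report["tables"]["unweighted_full"] = entry(t, summarize(t))

    sex_known = df["sex"].notna().to_numpy(dtype=bool)
    if sex_known.any():
        for sex in ("male", "female"):
            if cutoffs.get(sex) is None:
                continue
            m = (df["sex"] == sex).to_numpy(dtype=bool)
            if m.sum() and y[m].any() and not y[m].all():
                ts = confusion_at_cutoff(x[m], y[m], cutoffs[sex])
                report["tables"][f"unweighted_{sex}"] = entry(ts, summarize(ts))
    else:
        warnings.warn("sex unavailable in the external cohort; "
                      "sex-specific tables skipped")

    if design is not None:
        tw = weighted_confusion(x, y, design, cutoffs["full"])
        sw = weighted_summary(x, y, design, cutoffs["full"])
        report["tables"]["weighted_full"] = entry(tw, sw)

    if not sex_known.any():
        warnings.warn("sex unavailable; adjusted model fitted without covariates")
    fit = fit_validation_model(df, cutoffs["full"], design=None,
                               include_covariates=bool(sex_known.any()))
    report["adjusted_model_unweighted"] = fit.as_records()
    report["adjusted_model_unweighted_meta"] = {
        "converged": fit.converged, "separation": fit.separation, "n": fit.n}
    if design is not None:
        fitw = fit_validation_model(df, cutoffs["full"], design=design,
                                    include_covariates=bool(sex_known.any()))
        report["adjusted_model_weighted"] = fitw.as_records()
        report["adjusted_model_weighted_meta"] = {
            "converged": fitw.converged, "separation": fitw.separation, "n": fitw.n}
    return report
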