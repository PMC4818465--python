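"""Modified NCEP/ATP III metabolic-syndrome construct.

Five binary risk components, syndrome = three or more present:

* high waist circumference — men > 102 cm, women > 88 cm (strict);
* elevated blood pressure — SBP >= 135 or DBP >= 85 mm Hg by default
  (``bp_threshold="standard"`` switches SBP to the usual ATP III 130);
* hyperglycemia — HbA1c > 5.7 % (strict), a pre-diabetes proxy for
  fasting glucose >= 100 mg/dl;
* high triglycerides — men in the top three, women in the top two
  within-sex decile ranks (decile 10 = highest values);
* low HDL — men in the bottom two, women in the bottom three deciles.

The decile rules stand in for absolute lipid thresholds when only decile
ranks of TG and HDL are available; by construction they target high-TG
prevalences of 30 % (men) / 20 % (women) and low-HDL prevalences of 20 %
(men) / 30 % (women).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort

__all__ = [
    "classify_waist", "classify_bp", "classify_glycemia", "classify_lipids",
    "compute_deciles", "classify_mets", "classify_cohort",
    "RISK_COLUMNS",
]

RISK_COLUMNS = ("high_wc", "high_bp", "high_glycemia", "high_tg", "low_hdl")

_WAIST_THRESHOLD = {"male": 102.0, "female": 88.0}
_SBP_THRESHOLD = {"paper": 135.0, "standard": 130.0}
_DBP_THRESHOLD = 85.0
_HBA1C_THRESHOLD = 5.7
_TG_HIGH_MIN_DECILE = {"male": 8, "female": 9}   # top 3 / top 2
_HDL_LOW_MAX_DECILE = {"male": 2, "female": 3}   # bottom 2 / bottom 3


def _as_series(x) -> pd.Series:
    return x if isinstance(x, pd.Series) else pd.Series(np.atleast_1d(x))


def _masked(out: pd.Series, missing: pd.Series) -> pd.Series:
    """Boolean result with pd.NA where an input was missing."""
    return out.astype("boolean").mask(missing)


def classify_waist(waist_cm, sex):
    """High waist circumference: men > 102 cm, women > 88 cm (strict)."""
    w, s = _as_series(waist_cm).astype(float), _as_series(sex)
    bad = ~s.isin(list(_WAIST_THRESHOLD)) & s.notna()
    if bad.any():
        raise ValueError(f"unknown sex label {s[bad].iloc[0]!r}")
    if s.isna().any() and w[s.isna()].notna().any():
        raise ValueError("sex is required to classify waist circumference")
    thr = s.map(_WAIST_THRESHOLD).astype(float)
    return _masked(w > thr, w.isna() | s.isna())


def classify_bp(sbp, dbp, bp_threshold: str = "paper"):
    """Elevated blood pressure: SBP >= threshold OR DBP >= 85 mm Hg.

    A missing SBP or DBP yields a missing result (it propagates to the
    complete-case filter rather than defaulting to False).
    """
    s, d = _as_series(sbp).astype(float), _as_series(dbp).astype(float)
    thr = _SBP_THRESHOLD[bp_threshold]
    return _masked((s >= thr) | (d >= _DBP_THRESHOLD), s.isna() | d.isna())


def classify_glycemia(hba1c_pct):
    """Hyperglycemia: HbA1c > 5.7 % (strict)."""
    h = _as_series(hba1c_pct).astype(float)
    return _masked(h > _HBA1C_THRESHOLD, h.isna())


def classify_lipids(tg_decile, hdl_decile, sex):
    """(high_tg, low_hdl) from within-sex decile ranks (10 = highest).

    high_tg: men decile >= 8, women >= 9.  low_hdl: men <= 2, women <= 3.
    """
    tg, hdl, s = _as_series(tg_decile), _as_series(hdl_decile), _as_series(sex)
    for name, col in (("tg_decile", tg), ("hdl_decile", hdl)):
        vals = col.dropna()
        if len(vals) and (((vals < 1) | (vals > 10)).any()
                          or (vals != vals.round()).any()):
            raise ValueError(f"{name} must be integers in [1, 10]")
    tg_min = s.map(_TG_HIGH_MIN_DECILE).astype(float)
    hdl_max = s.map(_HDL_LOW_MAX_DECILE).astype(float)
    high_tg = _masked(tg >= tg_min, tg.isna() | s.isna())
    low_hdl = _masked(hdl <= hdl_max, hdl.isna() | s.isna())
    return high_tg, low_hdl


def compute_deciles(values, group=None) -> pd.Series:
    """Rank-based decile (1–10) of each value within its group.

    Ties share the lower decile (min-rank convention); with n a multiple
    of 10 and no ties each decile holds exactly 10 % of the group.  Needs
    at least 10 non-missing values per group; an all-equal group collapses
    into decile 1 with a warning.
    """
    v = _as_series(values).astype(float)
    g = pd.Series("all", index=v.index) if group is None else _as_series(group)
    out = pd.Series(np.nan, index=v.index)
    for lev, idx in v.groupby(g, dropna=False).groups.items():
        x = v.loc[idx]
        obs = x.dropna()
        if len(obs) < 10:
            raise ValueError(f"group {lev!r} has fewer than 10 non-missing values")
        if obs.nunique() == 1:
            warnings.warn(f"all values equal in group {lev!r}; single decile")
        ranks = rankdata(obs.to_numpy(), method="min")
        dec = np.floor((ranks - 1) * 10 / len(obs)).astype(int) + 1
        out.loc[obs.index] = dec
    return out


def classify_mets(high_wc, high_bp, high_glycemia, high_tg, low_hdl) -> pd.DataFrame:
    """Aggregate the five components: n_factors and mets = (n_factors >= 3).

    Any missing component makes n_factors and mets missing for that row.
    """
    comps = {name: _as_series(x).astype("boolean")
             for name, x in zip(RISK_COLUMNS,
                                (high_wc, high_bp, high_glycemia, high_tg, low_hdl))}
    df = pd.DataFrame(comps)
    any_na = df.isna().any(axis=1)
    n = df.sum(axis=1).astype("Int64").mask(any_na)
    df["n_factors"] = n
    df["mets"] = (n >= 3).astype("boolean").mask(any_na)
    return df


def classify_cohort(cohort: Cohort, bp_threshold: str = "paper",
                    decile_mode: str = "precomputed") -> pd.DataFrame:
    """Classify every participant; returns the cohort table with the five
    component columns, n_factors, mets and whtr appended.

    ``decile_mode``: "precomputed" trusts the tg_decile/hdl_decile columns
    as released; "sex" or "pooled" would be used when raw lipid values are
    stored in those columns and deciles must be (re)computed here.
    """
    d = cohort.data.copy()
    if decile_mode not in ("precomputed", "sex", "pooled"):
        raise ValueError(f"unknown decile_mode {decile_mode!r}")
    if decile_mode != "precomputed":
        grp = d["sex"] if decile_mode == "sex" else None
        d["tg_decile"] = compute_deciles(d["tg_decile"], grp)
        d["hdl_decile"] = compute_deciles(d["hdl_decile"], grp)
    high_tg, low_hdl = classify_lipids(d["tg_decile"], d["hdl_decile"], d["sex"])
    prof = classify_mets(
        classify_waist(d["waist_cm"], d["sex"]),
        classify_bp(d["sbp"], d["dbp"], bp_threshold),
        classify_glycemia(d["hba1c_pct"]),
        high_tg, low_hdl,
    )
    prof.index = d.index
    out = pd.concat([d, prof], axis=1)
    out["whtr"] = out["waist_cm"] / out["height_cm"]
    return out
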