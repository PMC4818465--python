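"""Cohort table I/O, schema enforcement, complete-case filtering and
descriptive complete-vs-incomplete comparisons.

A cohort is a pandas DataFrame with one row per participant and canonical
columns (id, sex, age, race, smoking_days, height_cm, waist_cm, sbp, dbp,
hba1c_pct, tg_decile, hdl_decile, plus optional survey-design columns
weight, stratum, psu).  Files are delimited text with a header; a schema
mapping renames source columns onto the canonical names, so native survey
dialects never leak into the analysis code.

Missingness convention: an empty cell, "NA" or "NaN" (any case) reads as
missing.  Any other non-numeric token in a numeric column is a parse
error naming the row — values are never silently coerced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "SchemaError",
    "CohortParseError",
    "Cohort",
    "DEFAULT_SCHEMA",
    "load_schema",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
    "compare_samples",
]

NUMERIC_FIELDS = (
    "age", "smoking_days", "height_cm", "waist_cm", "sbp", "dbp",
    "hba1c_pct", "tg_decile", "hdl_decile", "weight",
)
LABEL_FIELDS = ("id", "stratum", "psu")
CATEGORY_FIELDS = ("sex", "race")
ALL_FIELDS = LABEL_FIELDS[:1] + CATEGORY_FIELDS + NUMERIC_FIELDS + LABEL_FIELDS[1:]
DESIGN_FIELDS = ("weight", "stratum", "psu")

MISSING_TOKENS = {"", "na", "nan"}

#: identity column mapping plus the conventional sex recodings
DEFAULT_SCHEMA: dict = {
    "columns": {f: f for f in ALL_FIELDS},
    "sex_codes": {"1": "male", "2": "female", "m": "male", "f": "female",
                  "male": "male", "female": "female"},
}

RACE_LEVELS = (
    "nonHispanic Caucasian",
    "nonHispanic African American",
    "nonHispanic Asian/Native American",
    "Hispanic",
)


class SchemaError(ValueError):
    """A mapped column is absent from the file header."""


class CohortParseError(ValueError):
    """A numeric column holds a token that is neither numeric nor a
    recognised missing marker."""


@dataclass
class Cohort:
    """Ordered participant table with unique ids.

    ``design_present`` is true iff weight, stratum and psu are non-missing
    for every record, i.e. the survey-weighted analyses are possible.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ALL_FIELDS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table lacks columns: {missing}")
        if self.data["id"].duplicated().any():
            dup = self.data["id"][self.data["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate participant id: {dup!r}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def design_present(self) -> bool:
        d = self.data
        return bool(len(d)) and not (
            d["weight"].isna().any() | d["stratum"].isna().any() | d["psu"].isna().any()
        )

    def whtr(self) -> pd.Series:
        """Waist-to-height ratio, waist_cm / height_cm (unitless)."""
        return self.data["waist_cm"] / self.data["height_cm"]


def load_schema(path: str | Path | None) -> dict:
    """Read a schema config (YAML / plain ``key: value`` text).  Top-level
    keys: ``columns`` (canonical-field -> source-column) and optional
    ``sex_codes``.  Unmapped canonical fields default to their own names."""
    schema = {"columns": dict(DEFAULT_SCHEMA["columns"]),
              "sex_codes": dict(DEFAULT_SCHEMA["sex_codes"])}
    if path is None:
        return schema
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if "columns" in user or "sex_codes" in user:
        schema["columns"].update(user.get("columns") or {})
        schema["sex_codes"].update(
            {str(k).lower(): v for k, v in (user.get("sex_codes") or {}).items()})
    else:  # flat key: column form
        schema["columns"].update(user)
    unknown = set(schema["columns"]) - set(ALL_FIELDS)
    if unknown:
        raise SchemaError(f"schema maps unknown fields: {sorted(unknown)}")
    return schema


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path: str | Path, schema: dict | str | Path | None = None,
                delimiter: str | None = None) -> Cohort:
    """Read a delimited cohort file into a typed :class:`Cohort`.

    Raises :class:`SchemaError` if a mapped column is missing from the
    header and :class:`CohortParseError` (with the 1-based data row
    number) for non-numeric garbage in a numeric column.
    """
    path = Path(path)
    if schema is None or isinstance(schema, (str, Path)):
        schema = load_schema(schema)
    delimiter = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    cols = schema["columns"]
    absent = [src for src in cols.values() if src not in raw.columns]
    if absent:
        raise SchemaError(f"mapped column(s) not in file header: {absent}")

    out = pd.DataFrame(index=raw.index)
    for canon, src in cols.items():
        col = raw[src].str.strip()
        is_missing = col.str.lower().isin(MISSING_TOKENS)
        if canon in NUMERIC_FIELDS:
            parsed = pd.to_numeric(col.mask(is_missing), errors="coerce")
            bad = parsed.isna() & ~is_missing
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise CohortParseError(
                    f"non-numeric value {col[bad.idxmax()]!r} in column "
                    f"{src!r} (field {canon}), data row {row}")
            out[canon] = parsed
        elif canon == "sex":
            codes = schema["sex_codes"]
            mapped = col.str.lower().map(codes)
            bad = mapped.isna() & ~is_missing
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise CohortParseError(
                    f"unrecognised sex code {col[bad.idxmax()]!r}, data row {row}")
            out[canon] = mapped
        else:
            out[canon] = col.mask(is_missing)
    return Cohort(out)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write the canonical columns with a header; missing cells are empty."""
    cohort.data.to_csv(path, sep=delimiter, index=False, na_rep="")


def complete_case_filter(cohort: Cohort, required: list[str]) -> tuple[Cohort, Cohort]:
    """Partition into (complete, incomplete) on the ``required`` fields.

    A record is complete when every required field is non-missing; the two
    parts are disjoint and exhaust the input.
    """
    unknown = set(required) - set(ALL_FIELDS)
    if unknown:
        raise ValueError(f"unknown field(s) in required list: {sorted(unknown)}")
    d = cohort.data
    ok = pd.Series(True, index=d.index)
    for f in required:
        ok &= d[f].notna()
    return Cohort(d[ok]), Cohort(d[~ok])


def _prop_test(x1: float, n1: int, x2: float, n2: int) -> float:
    """Two-sample pooled z-test for proportions, no continuity correction."""
    if min(n1, n2) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = proportions_ztest([x1, x2], [n1, n2])
    return 1.0 if np.isnan(p) and x1 / n1 == x2 / n2 else float(p)


def compare_samples(complete: Cohort, incomplete: Cohort,
                    categorical: dict[str, object] | None = None,
                    continuous: list[str] | None = None) -> pd.DataFrame:
    """Descriptive comparison of the retained vs. removed participants.

    ``categorical`` maps a variable to a level list (or to a callable
    returning a boolean Series, for derived indicators such as "smoker");
    each level gets count, percent in both groups and a two-sample pooled
    z-test p-value.  ``continuous`` variables get mean, standard error and
    a Welch t-test p-value.  Layout is long: one row per level/variable.
    """
    if len(complete) == 0 or len(incomplete) == 0:
        raise ValueError("both cohorts must be non-empty")
    if categorical is None:
        categorical = {"sex": ["male", "female"], "race": list(RACE_LEVELS)}
    if continuous is None:
        continuous = ["age", "smoking_days"]

    rows = []
    a, b = complete.data, incomplete.data
    for var, levels in categorical.items():
        if callable(levels):
            ia, ib = levels(a).astype(bool), levels(b).astype(bool)
            rows.append(_cat_row(var, var, ia, ib))
            continue
        for lev in levels:
            ia, ib = a[var] == lev, b[var] == lev
            rows.append(_cat_row(var, str(lev), ia, ib))
    for var in continuous:
        xa = a[var].dropna().to_numpy(float)
        xb = b[var].dropna().to_numpy(float)
        if np.allclose(xa.mean(), xb.mean()) and np.allclose(xa.var(), xb.var()):
            p = 1.0  # identical summaries: no evidence of difference
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append({
            "variable": var, "level": "", "kind": "continuous",
            "complete_count": len(xa),
            "complete_stat": xa.mean(),
            "complete_se": xa.std(ddof=1) / np.sqrt(len(xa)),
            "incomplete_count": len(xb),
            "incomplete_stat": xb.mean(),
            "incomplete_se": xb.std(ddof=1) / np.sqrt(len(xb)),
            "p_value": p,
        })
    return pd.DataFrame(rows)


def _cat_row(var: str, level: str, ia: pd.Series, ib: pd.Series) -> dict:
    na, nb = len(ia), len(ib)
    xa, xb = int(ia.sum()), int(ib.sum())
    return {
        "variable": var, "level": level, "kind": "categorical",
        "complete_count": xa, "complete_stat": xa / na,
        "complete_se": np.sqrt(xa / na * (1 - xa / na) / na),
        "incomplete_count": xb, "incomplete_stat": xb / nb,
        "incomplete_se": np.sqrt(xb / nb * (1 - xb / nb) / nb),
        "p_value": _prop_test(xa, na, xb, nb),
    }
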