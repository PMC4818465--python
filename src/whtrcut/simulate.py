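"""Synthetic survey cohorts with known ground truth.

The generator emulates the structure of a large young-adult health survey
with a stratified, clustered, unequal-probability design: participants
live in primary sampling units (PSUs) nested in strata, one demographic
subgroup is oversampled (its records carry correspondingly smaller
weights), and every biomarker is driven by a single latent adiposity
score so the five metabolic-syndrome components are positively dependent
and the waist-to-height ratio is an informative but imperfect marker.

Generative model, per participant with sex s and latent score
Z = stratum offset + race shift + PSU effect + Normal(0, latent_sd):

* height ~ Normal(mu_s, sd_s) cm;
* waist  = r_s * height + k_s * exp(U) cm with U = lam_s Z + nu_s eps —
  the lognormal term makes waist (hence WHtR) right-skewed, as observed
  in adult cohorts (mean WHtR above its median);
* SBP/DBP, HbA1c linear in Z with Gaussian noise (slopes scaled per sex
  by ``link_scale`` so component coupling can differ between sexes);
* TG and HDL are continuous latent values linear in Z, released only as
  within-sex decile ranks, exactly as the construct expects.

Default parameter values were calibrated once, by simulation, so the
realized margins sit near a reference young-adult cohort: metabolic
syndrome prevalence ~23 % (28 % men / 20 % women), mean WHtR ~0.58 with
median ~0.56, high-waist prevalence ~37 % men / ~65 % women,
hypertension ~20 %, hyperglycemia ~33 %.  The decile rules fix high-TG at
30 %/20 % and low-HDL at 20 %/30 % by construction.

Ground truth (population optimal cutoff, prevalence, AUC) is computed by
a brute-force Monte-Carlo oracle over the same generative model, never
assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RACE_LEVELS, Cohort

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "oracle_optimal_cutoff",
    "population_sample",
    "write_ground_truth",
    "read_ground_truth",
]

_SEXES = ("male", "female")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative and design parameters; see the module docstring.

    Per-sex pairs are ordered (male, female).  All counts must be >= 1,
    probabilities in [0, 1] and spreads positive.
    """

    # survey design
    n_strata: int = 4
    psus_per_stratum: int = 8
    n_per_psu: int = 500
    population_size: float = 1_000_000.0
    stratum_pop_shares: tuple = (0.4, 0.3, 0.2, 0.1)
    stratum_shift: float = 0.10        # latent offsets span [-shift, +shift]
    psu_sd: float = 0.15               # PSU random effect on the latent scale
    oversample_group: int = 1          # index into RACE_LEVELS
    oversample_factor: float = 2.0     # inclusion-probability multiplier

    # demographics
    p_male: float = 0.44
    race_probs: tuple = (0.59, 0.19, 0.07, 0.15)
    race_latent_shifts: tuple = (0.0, 0.25, 0.0, 0.0)
    age_mean: float = 28.65
    age_sd: float = 1.60
    age_range: tuple = (24.55, 33.60)
    smoking_prob: float = 0.357

    # latent adiposity and biomarkers
    latent_sd: float = 1.0
    height_mean: tuple = (177.6, 163.2)
    height_sd: tuple = (7.0, 6.5)
    whtr_base: tuple = (0.5185, 0.4999)      # r_s: waist/height floor
    waist_scale: tuple = (7.5, 9.15)         # k_s (cm)
    waist_latent_loading: tuple = (0.58, 0.30)   # lam_s
    waist_noise: tuple = (0.54, 0.80)        # nu_s
    sbp_mean: tuple = (125.5, 117.8)
    dbp_mean: tuple = (75.5, 73.6)
    sbp_slope: float = 2.8
    dbp_slope: float = 1.7
    bp_sd: tuple = (10.0, 8.0)               # (sbp, dbp) residual sd
    bp_noise_corr: float = 0.5
    hba1c_mean: tuple = (5.40, 5.47)
    hba1c_slope: float = 0.18
    hba1c_sd: float = 0.50
    tg_slope: float = 0.90
    hdl_slope: float = 0.70
    link_scale: tuple = (3.3, 0.72)          # per-sex multiplier on slopes

    # data degradation and modes
    missingness_rate: float = 0.06
    outcome_mode: str = "components"         # components | independent | threshold
    outcome_param: float | None = None
    seed: int = 12345

    def __post_init__(self) -> None:
        if min(self.n_strata, self.psus_per_stratum, self.n_per_psu) < 1:
            raise ValueError("counts must be >= 1")
        if len(self.stratum_pop_shares) != self.n_strata:
            raise ValueError("stratum_pop_shares must have n_strata entries")
        if not math.isclose(sum(self.race_probs), 1.0, abs_tol=1e-9):
            raise ValueError("race_probs must sum to 1")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must be in [0, 1]")
        if self.oversample_factor < 1.0:
            raise ValueError("oversample_factor must be >= 1")
        for name in ("latent_sd", "psu_sd"):
            if getattr(self, name) < 0 or (name == "latent_sd" and self.latent_sd == 0):
                raise ValueError(f"{name} must be positive")
        if self.outcome_mode not in ("components", "independent", "threshold"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")

    @property
    def n_sample(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.n_per_psu

    def scale_links(self, factor: float) -> "SimulationConfig":
        """All component couplings to the latent score multiplied by
        ``factor`` (used for monotone-effect checks)."""
        return replace(
            self,
            waist_latent_loading=tuple(v * factor for v in self.waist_latent_loading),
            sbp_slope=self.sbp_slope * factor,
            dbp_slope=self.dbp_slope * factor,
            hba1c_slope=self.hba1c_slope * factor,
            tg_slope=self.tg_slope * factor,
            hdl_slope=self.hdl_slope * factor,
        )

    def stratum_offsets(self) -> np.ndarray:
        if self.n_strata == 1:
            return np.zeros(1)
        return np.linspace(-self.stratum_shift, self.stratum_shift, self.n_strata)


@dataclass(frozen=True)
class GroundTruth:
    """Population quantities under a :class:`SimulationConfig`, computed
    by the Monte-Carlo oracle (never assumed)."""

    true_optimal_cutoff: float
    true_prevalence: float
    true_auc: float
    true_youden_j: float
    degenerate: bool = False
    grid_resolution: float = 0.001
    n_mc: int = 1_000_000


def _weighted_decile_ranks(values: np.ndarray, sex_codes: np.ndarray,
                           weights: np.ndarray) -> np.ndarray:
    """Decile rank (1-10) of each value against weighted within-sex
    quantile thresholds; a value on a boundary takes the lower decile."""
    out = np.zeros(values.size, dtype=float)
    for code in (0, 1):
        mask = sex_codes == code
        v, w = values[mask], weights[mask]
        order = np.argsort(v, kind="mergesort")
        cum = np.cumsum(w[order]) / w.sum()
        thresholds = v[order][np.searchsorted(cum, np.arange(1, 10) / 10.0)]
        out[mask] = np.searchsorted(thresholds, v, side="left") + 1
    return out


def _per_sex(pair, sex_codes: np.ndarray) -> np.ndarray:
    """Broadcast a (male, female) pair over a 0/1 sex-code array."""
    return np.where(sex_codes == 0, pair[0], pair[1])


def _biomarkers(cfg: SimulationConfig, rng: np.random.Generator,
                sex_codes: np.ndarray, z: np.ndarray) -> pd.DataFrame:
    """Height, waist, BP, HbA1c and continuous lipid values given the
    latent score; the only randomness left is measurement-level noise."""
    n = z.size
    ls = _per_sex(cfg.link_scale, sex_codes)

    height = rng.normal(_per_sex(cfg.height_mean, sex_codes),
                        _per_sex(cfg.height_sd, sex_codes))
    u = (_per_sex(cfg.waist_latent_loading, sex_codes) * z
         + _per_sex(cfg.waist_noise, sex_codes) * rng.normal(size=n))
    waist = (_per_sex(cfg.whtr_base, sex_codes) * height
             + _per_sex(cfg.waist_scale, sex_codes) * np.exp(u))

    e1 = rng.normal(size=n)
    e2 = cfg.bp_noise_corr * e1 + math.sqrt(1 - cfg.bp_noise_corr ** 2) * rng.normal(size=n)
    sbp = _per_sex(cfg.sbp_mean, sex_codes) + ls * cfg.sbp_slope * z + cfg.bp_sd[0] * e1
    dbp = _per_sex(cfg.dbp_mean, sex_codes) + ls * cfg.dbp_slope * z + cfg.bp_sd[1] * e2

    hba1c = (_per_sex(cfg.hba1c_mean, sex_codes) + ls * cfg.hba1c_slope * z
             + cfg.hba1c_sd * rng.normal(size=n))
    tg_value = ls * cfg.tg_slope * z + rng.normal(size=n)
    hdl_value = -ls * cfg.hdl_slope * z + rng.normal(size=n)

    return pd.DataFrame({
        "sex_code": sex_codes, "height_cm": height, "waist_cm": waist,
        "sbp": sbp, "dbp": dbp, "hba1c_pct": hba1c,
        "tg_value": tg_value, "hdl_value": hdl_value,
    })


def _mets_from_quantiles(cfg: SimulationConfig, df: pd.DataFrame,
                         rng: np.random.Generator) -> np.ndarray:
    """Population metabolic-syndrome status.  TG/HDL components use
    within-sex quantile thresholds equivalent to the decile rules (men:
    TG top 30 % / HDL bottom 20 %; women: TG top 20 % / HDL bottom 30 %)."""
    whtr = df["waist_cm"].to_numpy() / df["height_cm"].to_numpy()
    if cfg.outcome_mode == "independent":
        p = 0.2335 if cfg.outcome_param is None else cfg.outcome_param
        return rng.random(len(df)) < p
    if cfg.outcome_mode == "threshold":
        c = 0.58 if cfg.outcome_param is None else cfg.outcome_param
        return whtr > c

    s = df["sex_code"].to_numpy()
    male, female = s == 0, s == 1
    waist_thr = np.where(male, 102.0, 88.0)
    high_wc = df["waist_cm"].to_numpy() > waist_thr
    high_bp = (df["sbp"].to_numpy() >= 135.0) | (df["dbp"].to_numpy() >= 85.0)
    high_gly = df["hba1c_pct"].to_numpy() > 5.7

    tg = df["tg_value"].to_numpy()
    hdl = df["hdl_value"].to_numpy()
    high_tg = np.zeros(len(df), bool)
    low_hdl = np.zeros(len(df), bool)
    for mask, tg_q, hdl_q in ((male, 0.7, 0.2), (female, 0.8, 0.3)):
        if mask.any():
            high_tg[mask] = tg[mask] > np.quantile(tg[mask], tg_q)
            low_hdl[mask] = hdl[mask] <= np.quantile(hdl[mask], hdl_q)
    n_factors = (high_wc.astype(int) + high_bp + high_gly + high_tg + low_hdl)
    return n_factors >= 3


def population_sample(cfg: SimulationConfig, n: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw n individuals from the *population* implied by the config:
    strata at their population shares, races untilted, PSU effects
    integrated out as fresh draws.  Used by the oracle."""
    stratum = rng.choice(cfg.n_strata, size=n, p=np.asarray(cfg.stratum_pop_shares))
    race = rng.choice(len(RACE_LEVELS), size=n, p=np.asarray(cfg.race_probs))
    sex_codes = (rng.random(n) >= cfg.p_male).astype(int)
    z = (cfg.stratum_offsets()[stratum]
         + np.asarray(cfg.race_latent_shifts)[race]
         + rng.normal(0.0, cfg.psu_sd, size=n)
         + rng.normal(0.0, cfg.latent_sd, size=n))
    df = _biomarkers(cfg, rng, sex_codes, z)
    df["whtr"] = df["waist_cm"] / df["height_cm"]
    df["mets"] = _mets_from_quantiles(cfg, df, rng)
    return df


def oracle_optimal_cutoff(cfg: SimulationConfig, grid_resolution: float = 0.001,
                          n_mc: int = 1_000_000, seed: int | None = None
                          ) -> tuple[float, float, bool]:
    """Brute-force population Youden optimum of 'WHtR > c'.

    Evaluates population sensitivity and specificity on a Monte-Carlo
    sample of the generative model over a fine grid of c spanning the
    0.1–99.9 percentile range of WHtR; returns (cutoff, max J,
    degenerate flag).  The degenerate flag marks a maximal J so close to
    zero that no cutoff discriminates (e.g. independent outcome mode).
    """
    if grid_resolution <= 0:
        raise ValueError("grid_resolution must be positive")
    from .cutpoint import _rates_at_cutoffs  # local import avoids cycle at import time

    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(1)[0])
    df = population_sample(cfg, n_mc, rng)
    x = df["whtr"].to_numpy()
    y = df["mets"].to_numpy()
    lo, hi = np.quantile(x, [0.001, 0.999])
    k = int(np.ceil((hi - lo) / grid_resolution))
    grid = lo + grid_resolution * np.arange(k + 1)
    sens, spec = _rates_at_cutoffs(x, y, grid)
    j = sens + spec - 1.0
    kbest = int(np.argmax(j))
    return float(grid[kbest]), float(j[kbest]), bool(j[kbest] < 0.02)


def _true_auc(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata
    m = int(y.sum())
    n = y.size - m
    r = rankdata(x)
    return float((r[y].sum() - m * (m + 1) / 2.0) / (m * n))


def compute_ground_truth(cfg: SimulationConfig, grid_resolution: float = 0.001,
                         n_mc: int = 1_000_000) -> GroundTruth:
    """Prevalence, AUC and optimal cutoff of the population model by
    Monte Carlo (a dedicated deterministic substream of the config seed)."""
    ss = np.random.SeedSequence(cfg.seed).spawn(12)
    rng = np.random.default_rng(ss[10])
    df = population_sample(cfg, n_mc, rng)
    x = df["whtr"].to_numpy()
    y = df["mets"].to_numpy()
    from .cutpoint import _rates_at_cutoffs

    lo, hi = np.quantile(x, [0.001, 0.999])
    grid = lo + grid_resolution * np.arange(int(np.ceil((hi - lo) / grid_resolution)) + 1)
    sens, spec = _rates_at_cutoffs(x, y, grid)
    j = sens + spec - 1.0
    k = int(np.argmax(j))
    return GroundTruth(
        true_optimal_cutoff=float(grid[k]),
        true_prevalence=float(y.mean()),
        true_auc=_true_auc(x, y),
        true_youden_j=float(j[k]),
        degenerate=bool(j[k] < 0.02),
        grid_resolution=grid_resolution,
        n_mc=n_mc,
    )


def simulate_cohort(cfg: SimulationConfig | None = None,
                    compute_truth: bool = True,
                    truth_n_mc: int = 1_000_000
                    ) -> tuple[Cohort, GroundTruth | None]:
    """Draw one survey sample (cohort) plus its population ground truth.

    Sampling: every stratum contributes ``psus_per_stratum`` PSUs of
    ``n_per_psu`` participants.  The designated race group's inclusion
    probability is multiplied by ``oversample_factor``, so its sample
    share is tilted upward and its records carry proportionally smaller
    weights; weights are inverse inclusion probabilities and sum to
    (approximately) the population size.  Missingness is applied
    independently per analysis field at ``missingness_rate`` (design
    columns are never missing).  A single seed drives everything through
    per-stage substreams, so the same seed reproduces the same cohort.
    """
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed).spawn(12)
    r_design, r_demo, r_latent, r_bio, r_outcome, r_miss = (
        np.random.default_rng(ss[i]) for i in (0, 1, 2, 3, 4, 5))

    H, P, m = cfg.n_strata, cfg.psus_per_stratum, cfg.n_per_psu
    n = cfg.n_sample
    stratum = np.repeat(np.arange(H), P * m)
    psu_within = np.repeat(np.tile(np.arange(P), H), m)
    psu_effects = r_design.normal(0.0, cfg.psu_sd, size=H * P)
    psu_flat = stratum * P + psu_within

    # race sampled from the oversampling-tilted mixture
    q = np.asarray(cfg.race_probs, dtype=float)
    f = np.ones_like(q)
    f[cfg.oversample_group] = cfg.oversample_factor
    tilt = q * f / (q * f).sum()
    race = r_demo.choice(len(RACE_LEVELS), size=n, p=tilt)
    sex_codes = (r_demo.random(n) >= cfg.p_male).astype(int)
    age = np.clip(r_demo.normal(cfg.age_mean, cfg.age_sd, size=n), *cfg.age_range)
    smoker = r_demo.random(n) < cfg.smoking_prob
    days = np.where(r_demo.random(n) < 0.5, 30, r_demo.integers(1, 30, size=n))
    smoking_days = np.where(smoker, days, 0)

    z = (cfg.stratum_offsets()[stratum]
         + np.asarray(cfg.race_latent_shifts)[race]
         + psu_effects[psu_flat]
         + r_latent.normal(0.0, cfg.latent_sd, size=n))
    bio = _biomarkers(cfg, r_bio, sex_codes, z)

    sex = np.asarray(_SEXES, dtype=object)[sex_codes]

    # inverse-inclusion-probability weights
    shares = np.asarray(cfg.stratum_pop_shares, dtype=float)
    n_h = P * m
    base = shares[stratum] * cfg.population_size / n_h
    weights = base * (q * f).sum() / f[race]

    # released decile ranks are population-representative: thresholds are
    # weighted within-sex quantiles, ties share the lower decile
    tg_decile = _weighted_decile_ranks(bio["tg_value"].to_numpy(), sex_codes, weights)
    hdl_decile = _weighted_decile_ranks(bio["hdl_value"].to_numpy(), sex_codes, weights)

    data = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "sex": sex,
        "race": np.asarray(RACE_LEVELS, dtype=object)[race],
        "age": np.round(age, 2),
        "smoking_days": smoking_days.astype(float),
        "height_cm": np.round(bio["height_cm"], 1),
        "waist_cm": np.round(bio["waist_cm"], 1),
        "sbp": np.round(bio["sbp"], 0),
        "dbp": np.round(bio["dbp"], 0),
        "hba1c_pct": np.round(bio["hba1c_pct"], 1),
        "tg_decile": tg_decile,
        "hdl_decile": hdl_decile,
        "weight": weights,
        "stratum": [f"S{h}" for h in stratum],
        "psu": [f"S{h}-U{u}" for h, u in zip(stratum, psu_within)],
    })

    if cfg.outcome_mode != "components":
        # degenerate testing modes carry the outcome explicitly
        data["mets_override"] = _mets_from_quantiles(cfg, bio, r_outcome)

    if cfg.missingness_rate > 0:
        for col in ("sex", "race", "age", "smoking_days", "height_cm",
                    "waist_cm", "sbp", "dbp", "hba1c_pct",
                    "tg_decile", "hdl_decile"):
            mask = r_miss.random(n) < cfg.missingness_rate
            if data[col].dtype == object:
                data.loc[mask, col] = None
            else:
                data.loc[mask, col] = np.nan

    truth = compute_ground_truth(cfg, n_mc=truth_n_mc) if compute_truth else None
    return Cohort(data), truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Plain-text ``key: value`` sidecar."""
    with open(path, "w") as fh:
        for k, v in vars(truth).items():
            fh.write(f"{k}: {v}\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    kv: dict = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                k, v = line.split(":", 1)
                kv[k.strip()] = v.strip()
    return GroundTruth(
        true_optimal_cutoff=float(kv["true_optimal_cutoff"]),
        true_prevalence=float(kv["true_prevalence"]),
        true_auc=float(kv["true_auc"]),
        true_youden_j=float(kv["true_youden_j"]),
        degenerate=kv.get("degenerate", "False") == "True",
        grid_resolution=float(kv.get("grid_resolution", 0.001)),
        n_mc=int(kv.get("n_mc", 1_000_000)),
    )
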