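"""Synthetic health-checkup cohorts with sex- and status-conditional structure.

The study population this generator emulates — an asymptomatic Korean
health-checkup cohort — is published only as group-level summaries: for
each (sex x ultrasound-steatosis status) cell, means +/- SD for roughly
normal variables (age, BMI, waist circumference, blood pressure, AST,
ALT), mean +/- SD for the right-skewed GGT, and median (Q1, Q3) for
triglycerides and CAP. No subject-level data are available.

The generator therefore draws each subject's stratum (sex by a male
fraction, steatosis status by a per-sex prevalence) and then samples the
continuous variables from stratum-conditional marginals joined by a
Gaussian copula over (BMI, WC, TG, GGT, CAP). The ultrasound label IS
the latent stratum assignment; the CAP-defined label arises implicitly
from the simulated CAP via the 248 dB/m rule, which keeps the two
reference standards imperfectly concordant, as observed.

Marginal families:

* normal, truncated at a physiologic floor by inverse-CDF mapping
  (BMI >= 12, WC >= 40, others > 0) — age, BMI, WC, SBP, DBP, AST, ALT;
* log-normal fitted from median and quartiles — TG, CAP;
* log-normal moment-matched from mean and SD — GGT.

Inter-variable correlation is not published; the copula correlation is
an explicit knob (default 0.3 among the four FLI inputs, 0.2 between
CAP and each of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .cohort import COLUMNS

#: Order of the copula-joined variables.
COPULA_VARS = ("bmi", "wc", "tg", "ggt", "cap")

_Z75 = norm.ppf(0.75)  # standard-normal upper-quartile deviate

#: Physiologic floors for truncated-normal marginals.
FLOORS = {"age": 18.0, "bmi": 12.0, "wc": 40.0, "sbp": 0.0, "dbp": 0.0,
          "ast": 0.0, "alt": 0.0, "creatinine": 0.2}


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple:
    """(mu, sigma) of the log-normal with the given median and quartiles.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 * z_0.75). The implied
    distribution reproduces all three quantiles when the quartiles are
    log-symmetric about the median, and interpolates them otherwise.
    """
    if not 0 < q1 < median < q3:
        raise ValueError("need 0 < q1 < median < q3")
    return float(np.log(median)), float((np.log(q3) - np.log(q1)) / (2 * _Z75))


def lognormal_from_mean_sd(mean: float, sd: float) -> tuple:
    """(mu, sigma) of the log-normal moment-matched to a mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2); mu = ln(mean) - sigma^2/2. The implied
    first two moments reproduce the inputs exactly.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass
class GroupParams:
    """Marginal parameters for one (sex x steatosis-status) stratum.

    ``normal`` maps variable name -> (mean, sd); ``lognormal_q`` maps
    name -> (median, q1, q3); ``lognormal_m`` maps name -> (mean, sd)
    for moment-matched log-normals. ``p_diabetes``/``p_hypertension``
    are treated-comorbidity probabilities.
    """

    sex: str
    status: str  # "nafld" or "no_nafld"
    normal: dict = field(default_factory=dict)
    lognormal_q: dict = field(default_factory=dict)
    lognormal_m: dict = field(default_factory=dict)
    p_diabetes: float = 0.0
    p_hypertension: float = 0.0

    def __post_init__(self) -> None:
        for name, (mean, sd) in {**self.normal, **self.lognormal_m}.items():
            if sd <= 0:
                raise ValueError(f"{name}: sd must be positive")
        for name, (med, q1, q3) in self.lognormal_q.items():
            if not 0 < q1 < med < q3:
                raise ValueError(f"{name}: need q1 < median < q3")
        for p in (self.p_diabetes, self.p_hypertension):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def mu_sigma(self, var: str) -> tuple:
        """Log-normal (mu, sigma) for a skewed variable of this stratum."""
        if var in self.lognormal_q:
            return lognormal_from_median_iqr(*self.lognormal_q[var])
        return lognormal_from_mean_sd(*self.lognormal_m[var])


def default_copula_correlation(rho_fli: float = 0.3,
                               rho_cap: float = 0.2) -> np.ndarray:
    """Exchangeable correlation among the FLI inputs, rho_cap with CAP."""
    r = np.full((5, 5), rho_fli)
    r[4, :4] = r[:4, 4] = rho_cap
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SyntheticConfig:
    """Full generator configuration; defaults reproduce the emulated checkup cohort."""

    n_total: int = 4009
    male_fraction: float = 0.835
    prevalence: dict = field(default_factory=lambda: {
        "male": 2162 / 3349, "female": 301 / 661,
    })
    copula_correlation: np.ndarray = field(
        default_factory=default_copula_correlation)
    seed: int = 0
    params: dict = field(default_factory=dict)  # (sex, status) -> GroupParams

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        for p in self.prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalence must be in [0, 1]")
        r = np.asarray(self.copula_correlation, dtype=float)
        if r.shape != (5, 5) or not np.allclose(r, r.T):
            raise ValueError("copula correlation must be symmetric 5x5")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("copula correlation must be positive definite")
        self.copula_correlation = r


def default_params() -> dict:
    """The four stratum parameter sets of the emulated checkup cohort.

    Values are the published ultrasound-stratified group summaries:
    mean +/- SD for age, blood pressure, BMI, WC, AST, ALT and GGT;
    median (Q1, Q3) for triglycerides and CAP; treated-comorbidity
    proportions for diabetes and hypertension.
    """
    def gp(sex, status, age, sbp, dbp, bmi, wc, ast, alt, ggt, tg, cap,
           p_dm, p_htn):
        return GroupParams(
            sex=sex, status=status,
            normal={"age": age, "sbp": sbp, "dbp": dbp, "bmi": bmi,
                    "wc": wc, "ast": ast, "alt": alt},
            lognormal_m={"ggt": ggt},
            lognormal_q={"tg": tg, "cap": cap},
            p_diabetes=p_dm, p_hypertension=p_htn,
        )

    return {
        ("male", "no_nafld"): gp(
            "male", "no_nafld", age=(55.5, 11.6), sbp=(120.9, 14.0),
            dbp=(79.2, 10.2), bmi=(23.3, 2.5), wc=(85.8, 7.3),
            ast=(26.2, 11.5), alt=(27.7, 20.0), ggt=(30.0, 27.5),
            tg=(83, 62, 114), cap=(224, 200, 248), p_dm=0.094, p_htn=0.208),
        ("male", "nafld"): gp(
            "male", "nafld", age=(54.4, 9.7), sbp=(120.5, 13.8),
            dbp=(79.8, 10.4), bmi=(25.9, 3.0), wc=(92.8, 7.8),
            ast=(28.6, 13.7), alt=(33.3, 23.3), ggt=(41.4, 33.1),
            tg=(128, 92, 177), cap=(278, 247, 309), p_dm=0.178, p_htn=0.207),
        ("female", "no_nafld"): gp(
            "female", "no_nafld", age=(53.8, 10.6), sbp=(120.1, 14.4),
            dbp=(80.0, 9.5), bmi=(22.3, 2.7), wc=(79.1, 7.6),
            ast=(24.5, 11.2), alt=(27.5, 23.3), ggt=(19.3, 12.0),
            tg=(67, 49, 88.5), cap=(213, 189, 240), p_dm=0.033, p_htn=0.217),
        ("female", "nafld"): gp(
            "female", "nafld", age=(57.6, 9.1), sbp=(121.6, 14.7),
            dbp=(81.0, 10.2), bmi=(24.9, 3.4), wc=(88.1, 8.4),
            ast=(26.7, 13.6), alt=(29.3, 18.0), ggt=(30.5, 36.4),
            tg=(112, 78, 152), cap=(283, 256, 319), p_dm=0.189, p_htn=0.239),
    }


def default_config(n_total: int = 4009, seed: int = 0, **kwargs) -> SyntheticConfig:
    """A ready-to-run configuration parameterized to the emulated checkup cohort."""
    return SyntheticConfig(n_total=n_total, seed=seed,
                           params=default_params(), **kwargs)


# creatinine marginals are not published; values are typical adult
# reference ranges so the descriptive GFR column is realistic.
_CREATININE = {"male": (0.95, 0.14), "female": (0.72, 0.12)}

_ALCOHOL_LIMIT = {"male": 20.0, "female": 10.0}


def _truncnorm_ppf(u, mean, sd, floor):
    a = (floor - mean) / sd
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _sample_stratum(gp: GroupParams, n: int, corr_chol: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw n subjects from one stratum's conditional distribution."""
    z = rng.standard_normal((n, 5)) @ corr_chol.T
    u = norm.cdf(z)
    cols = {}
    for k, var in enumerate(COPULA_VARS):
        if var in gp.normal:
            mean, sd = gp.normal[var]
            cols[var] = _truncnorm_ppf(u[:, k], mean, sd, FLOORS.get(var, 0.0))
        else:
            mu, sigma = gp.mu_sigma(var)
            cols[var] = np.exp(mu + sigma * z[:, k])
    for var, (mean, sd) in gp.normal.items():
        if var in cols:
            continue
        cols[var] = _truncnorm_ppf(rng.random(n), mean, sd,
                                   FLOORS.get(var, 0.0))
    cr_mean, cr_sd = _CREATININE[gp.sex]
    cols["creatinine"] = _truncnorm_ppf(rng.random(n), cr_mean, cr_sd,
                                        FLOORS["creatinine"])

    diabetes = rng.random(n) < gp.p_diabetes
    # fasting glucose consistent with the diabetes flag: treated subjects
    # sit at or above the 126 mg/dL diagnostic threshold, others below it
    glucose = np.where(
        diabetes,
        126.0 + np.abs(rng.normal(14.0, 20.0, n)),
        _truncnorm_ppf(rng.random(n), 95.0, 10.0, 50.0),
    )
    glucose = np.where(~diabetes & (glucose >= 126.0), 125.0, glucose)
    cols["fasting_glucose"] = glucose
    cols["on_glucose_lowering"] = diabetes
    cols["on_antihypertensives"] = rng.random(n) < gp.p_hypertension

    # exposures set so every synthetic subject survives the exclusion cascade
    cols["alcohol"] = rng.random(n) * _ALCOHOL_LIMIT[gp.sex]
    cols["hbv_positive"] = np.zeros(n, dtype=bool)
    cols["hcv_positive"] = np.zeros(n, dtype=bool)

    cols["lsm_median"] = np.exp(rng.normal(np.log(4.5), 0.25, n))
    cols["lsm_iqr_over_median"] = np.abs(rng.normal(0.13, 0.06, n))
    cols["lsm_n_valid"] = np.full(n, 10.0)

    df = pd.DataFrame(cols)
    df["sex"] = gp.sex
    df["us_steatosis"] = gp.status == "nafld"
    return df


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a synthetic cohort in the canonical column schema.

    A single integer seed drives everything; the stream is split into
    one child per stratum (plus one for the stratum assignment), so the
    same seed yields identical draws per stratum even if other strata
    change size. Identical config => identical cohort.
    """
    ss = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    stratum_seeds = ss.spawn(4)

    n = config.n_total
    male = assign_rng.random(n) < config.male_fraction
    sexes = np.where(male, "male", "female")
    prev = np.where(male, config.prevalence["male"], config.prevalence["female"])
    nafld = assign_rng.random(n) < prev

    chol = np.linalg.cholesky(config.copula_correlation)
    frames = []
    order = np.arange(n)
    keys = [("male", "no_nafld"), ("male", "nafld"),
            ("female", "no_nafld"), ("female", "nafld")]
    for key, child in zip(keys, stratum_seeds):
        sex, status = key
        mask = (sexes == sex) & (nafld == (status == "nafld"))
        k = int(mask.sum())
        if k == 0:
            continue
        rng = np.random.default_rng(child)
        block = _sample_stratum(config.params[key], k, chol, rng)
        block.index = order[mask]
        frames.append(block)
    if not frames:
        return pd.DataFrame(columns=list(COLUMNS))
    df = pd.concat(frames).sort_index()
    df["subject_id"] = [f"S{i + 1:05d}" for i in range(len(df))]
    for col in ("hbv_positive", "hcv_positive", "on_antihypertensives",
                "on_glucose_lowering", "us_steatosis"):
        df[col] = df[col].astype("boolean")
    return df[list(COLUMNS)].reset_index(drop=True)


def config_from_yaml(path) -> SyntheticConfig:
    """Load a generator configuration, filling unset fields with defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config()
    simple = {k: raw[k] for k in ("n_total", "male_fraction", "seed")
              if k in raw}
    if "prevalence" in raw:
        simple["prevalence"] = dict(raw["prevalence"])
    if "copula_correlation" in raw:
        simple["copula_correlation"] = np.asarray(raw["copula_correlation"],
                                                  dtype=float)
    elif "rho_fli" in raw or "rho_cap" in raw:
        simple["copula_correlation"] = default_copula_correlation(
            raw.get("rho_fli", 0.3), raw.get("rho_cap", 0.2))
    return replace(cfg, **simple)
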