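"""Synthetic birth cohorts: demographics, risk factors, frailty, mortality.

Generates the cohort the screening engine operates on.  Each individual
carries sex, risk-factor covariates (BMI, smoking, alcohol), a positive
multiplicative *frailty* on the adenoma onset rate, and an other-cause death
age pre-scheduled by inverse transform from the per-sex life table.  Frailty
is linked to the QCancer-like risk score through a Gaussian copula so the
score is informative but imperfect for true underlying risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelParams

__all__ = ["Individual", "Cohort", "generate_cohort", "qcancer_like_score", "risk_linear_predictor"]

SMOKING_LEVELS = ("never", "former", "current")

# Named substreams: all randomness is derived from (seed, stream-tag) so each
# stage of the pipeline is independently reproducible.
_STREAM_COHORT = 11
_STREAM_NATHIST = 22
_STREAM_SCREEN = 33


def substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), int(tag)])))


@dataclass(frozen=True)
class Individual:
    """One simulated person (a row view into a :class:`Cohort`)."""

    id: int
    sex: str                     # 'male' / 'female'
    bmi: float                   # kg/m^2
    smoking: str                 # never / former / current
    alcohol: int                 # ordinal 0..3
    frailty: float               # multiplicative factor on adenoma onset, >= 0
    other_cause_death_age: float


@dataclass
class Cohort:
    """Column-oriented cohort; ids are dense 0..n-1."""

    sex_male: np.ndarray           # bool
    bmi: np.ndarray                # float
    smoking: np.ndarray            # int codes into SMOKING_LEVELS
    alcohol: np.ndarray            # int 0..3
    frailty: np.ndarray            # float >= 0
    other_cause_death_age: np.ndarray
    seed: int
    params_fingerprint: str

    @property
    def n(self) -> int:
        return self.sex_male.size

    def individual(self, i: int) -> Individual:
        return Individual(
            id=int(i),
            sex="male" if self.sex_male[i] else "female",
            bmi=float(self.bmi[i]),
            smoking=SMOKING_LEVELS[int(self.smoking[i])],
            alcohol=int(self.alcohol[i]),
            frailty=float(self.frailty[i]),
            other_cause_death_age=float(self.other_cause_death_age[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "sex": np.where(self.sex_male, "male", "female"),
                "bmi": self.bmi,
                "smoking": np.asarray(SMOKING_LEVELS)[self.smoking],
                "alcohol": self.alcohol,
                "frailty": self.frailty,
                "other_cause_death_age": self.other_cause_death_age,
            }
        )


def _death_ages_from_life_table(qx: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-transform continuous death ages from yearly probabilities.

    The death year is found on the discrete survival curve; the death moment
    is uniform within that year.  ``qx[-1]`` is 1, so ages never exceed the
    terminal age.
    """
    surv = np.cumprod(1.0 - qx)                  # S(x+1), x = 0..terminal
    cdf = 1.0 - surv                             # P(death age < x+1)
    year = np.searchsorted(cdf, u, side="right")
    year = np.minimum(year, qx.size - 1)
    s_lo = np.concatenate([[0.0], cdf])[year]
    s_hi = cdf[year]
    frac = np.where(s_hi > s_lo, (u - s_lo) / np.maximum(s_hi - s_lo, 1e-300), 0.5)
    # the terminal year is absorbing: death ages never exceed the terminal age
    return np.minimum(year + np.clip(frac, 0.0, 1.0), float(qx.size - 1))


def risk_linear_predictor(
    age, sex_male, bmi, smoking_code, alcohol, params: ModelParams
) -> np.ndarray:
    """Log-odds linear predictor of the QCancer-like 15-year CRC risk."""
    rs = params.population["risk_score"]
    smoke_beta = np.array([rs["smoking"][k] for k in SMOKING_LEVELS], dtype=float)
    lp = (
        rs["intercept"]
        + rs["age_per_year"] * (np.asarray(age, dtype=float) - rs["age_reference"])
        + rs["male"] * np.asarray(sex_male, dtype=float)
        + rs["bmi_per_unit"] * (np.asarray(bmi, dtype=float) - rs["bmi_reference"])
        + smoke_beta[np.asarray(smoking_code, dtype=int)]
        + rs["alcohol_per_level"] * np.asarray(alcohol, dtype=float)
    )
    return lp


def qcancer_like_score(ind, age: float, params: ModelParams | None = None):
    """15-year CRC risk in (0, 1) for one individual (or cohort arrays) at ``age``.

    Individuals are assumed to report no ulcerative colitis and no previously
    detected polyps (those predictors sit at their reference level), matching
    routine-screening eligibility.  Strictly increasing in age for fixed
    covariates by construction (positive age coefficient, logistic link).
    """
    if params is None:
        raise TypeError("params is required")
    if isinstance(ind, Individual):
        lp = risk_linear_predictor(
            age, ind.sex == "male", ind.bmi, SMOKING_LEVELS.index(ind.smoking), ind.alcohol, params
        )
        return float(1.0 / (1.0 + np.exp(-lp)))
    # cohort-array form
    lp = risk_linear_predictor(age, ind.sex_male, ind.bmi, ind.smoking, ind.alcohol, params)
    return 1.0 / (1.0 + np.exp(-lp))


def cohort_scores(cohort: Cohort, age, params: ModelParams) -> np.ndarray:
    """Vectorized risk score for every cohort member at ``age`` (scalar or array)."""
    lp = risk_linear_predictor(age, cohort.sex_male, cohort.bmi, cohort.smoking, cohort.alcohol, params)
    return 1.0 / (1.0 + np.exp(-lp))


def generate_cohort(n: int, params: ModelParams, seed: int) -> Cohort:
    """Draw a cohort of ``n`` individuals; fully reproducible from (n, params, seed).

    Frailty is gamma with mean 1 and configured variance (optionally with a
    point mass of never-developers at 0), drawn through a Gaussian copula with
    configured latent correlation to the risk-score linear predictor at age 50.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = substream(seed, _STREAM_COHORT)
    pop = params.population

    sex_male = rng.random(n) < float(pop.get("sex_male_fraction", 0.5))

    cov = pop["covariates"]
    bmi = np.empty(n)
    smoking = np.empty(n, dtype=np.int64)
    alcohol = np.empty(n, dtype=np.int64)
    for is_male, key in ((True, "male"), (False, "female")):
        m = sex_male == is_male
        k = int(m.sum())
        b = cov["bmi"][key]
        bmi[m] = rng.lognormal(b["mu_log"], b["sigma_log"], size=k)
        smoking[m] = rng.choice(3, size=k, p=np.asarray(cov["smoking"][key], dtype=float))
        alcohol[m] = rng.choice(4, size=k, p=np.asarray(cov["alcohol"][key], dtype=float))

    # frailty via Gaussian copula with the linear predictor at age 50
    fr = pop["frailty"]
    var = float(fr["variance"])
    p0 = float(fr.get("zero_fraction", 0.0))
    rho = float(fr.get("score_correlation", 0.0))
    lp50 = risk_linear_predictor(50.0, sex_male, bmi, smoking, alcohol, params)
    # normal scores of the covariate-driven predictor (ranks -> normal quantiles)
    ranks = stats.rankdata(lp50, method="average")
    z_lp = stats.norm.ppf(ranks / (n + 1.0))
    z_eps = rng.standard_normal(n)
    z_f = rho * z_lp + np.sqrt(max(0.0, 1.0 - rho**2)) * z_eps
    u_f = stats.norm.cdf(z_f)
    frailty = np.zeros(n)
    dev = u_f >= p0
    if var > 0:
        shape = 1.0 / var
        mean_dev = 1.0 / max(1.0 - p0, 1e-12)  # developers rescaled so E[frailty] = 1
        u_resc = np.clip((u_f[dev] - p0) / max(1.0 - p0, 1e-12), 1e-12, 1 - 1e-12)
        frailty[dev] = stats.gamma.ppf(u_resc, a=shape, scale=mean_dev / shape)
    else:
        frailty[dev] = 1.0 / max(1.0 - p0, 1e-12)

    u_death = rng.random(n)
    death = np.empty(n)
    qx_m = params.life_table_qx("male")
    qx_f = params.life_table_qx("female")
    death[sex_male] = _death_ages_from_life_table(qx_m, u_death[sex_male])
    death[~sex_male] = _death_ages_from_life_table(qx_f, u_death[~sex_male])

    return Cohort(
        sex_male=sex_male,
        bmi=bmi,
        smoking=smoking,
        alcohol=alcohol,
        frailty=frailty,
        other_cause_death_age=death,
        seed=int(seed),
        params_fingerprint=params.fingerprint(),
    )
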