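"""Screening test models: quantitative FIT and colonoscopy.

FIT is modeled as a latent fecal hemoglobin concentration: per lesion state a
lognormal with a common shape whose scale is calibrated so the upper-tail
mass at the positivity cut-off (15 ug/g) equals the configured sensitivity
(1 - specificity for the lesion-free state).  The continuous concentration is
what defines the sub-cut-off "elevated but negative" bands (5-15 or 10-15
ug/g) that FIT-based switching strategies act on.

Colonoscopy detects each lesion independently with stage-specific
sensitivity; detected adenomas are removed (polypectomy), detected
preclinical cancers become screen-detected diagnoses, and each procedure
carries a small complication risk with its own case fatality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ModelParams
from .natural_history import STAGE_PC1

__all__ = [
    "FitResult",
    "ColonoscopyResult",
    "FitDistributions",
    "calibrate_fit_distributions",
    "draw_fit",
    "classify_band",
    "band_probabilities",
    "perform_colonoscopy",
    "stage_class",
]

FIT_STATES = ("none", "adenoma_small", "adenoma_medium", "adenoma_large", "preclinical_crc")


@dataclass(frozen=True)
class FitResult:
    hemoglobin: float            # ug Hb / g feces
    band: str                    # negative / elevated_negative / positive
    thresholds_used: tuple       # (elevated lower bound, positivity cut-off)


@dataclass
class ColonoscopyResult:
    lesions_detected: list       # indices of detected lesions
    findings_category: str       # no_adenoma / nonadvanced / advanced / crc
    complication: bool
    complication_fatal: bool


def stage_class(stage_code: np.ndarray) -> np.ndarray:
    """Collapse stage codes to the 5 test-characteristic classes (0..4).

    0 none, 1..3 adenoma size classes, 4 preclinical CRC (any stage).
    """
    s = np.asarray(stage_code, dtype=np.int8)
    return np.clip(s, 0, 4).astype(np.int8)


@dataclass(frozen=True)
class FitDistributions:
    """Per-state lognormal hemoglobin distributions (common shape)."""

    mu_log: np.ndarray        # scale (log-median) per state, indexed 0..4
    sigma_log: float
    cutoff: float

    def positive_probability(self, state_idx) -> np.ndarray:
        z = (np.log(self.cutoff) - self.mu_log[np.asarray(state_idx, dtype=int)]) / self.sigma_log
        return stats.norm.sf(z)


def calibrate_fit_distributions(params: ModelParams) -> FitDistributions:
    """Solve per-state lognormal scales hitting the configured tail mass.

    With a common shape ``sigma``, requiring P(Hb >= cutoff | state) = p gives
    the closed form ``mu = ln(cutoff) - sigma * Phi^{-1}(1 - p)``; a target
    tail mass of 0.5 therefore puts the lognormal median exactly at the
    cut-off.  Targets of 0 or 1 are unattainable for a lognormal and are
    rejected.
    """
    fit = params.fit_characteristics
    sigma = float(fit["sigma_log"])
    cutoff = float(fit["cutoff"])
    mu = np.empty(len(FIT_STATES))
    for i, state in enumerate(FIT_STATES):
        p = float(fit["positive_probability"][state])
        if not 0.0 < p < 1.0:
            raise ValueError(f"unattainable tail-mass target {p} for state {state}")
        mu[i] = np.log(cutoff) - sigma * stats.norm.ppf(1.0 - p)
    dists = FitDistributions(mu_log=mu, sigma_log=sigma, cutoff=cutoff)
    resid = np.abs(dists.positive_probability(np.arange(len(FIT_STATES)))
                   - np.array([fit["positive_probability"][s] for s in FIT_STATES]))
    assert resid.max() < 1e-9
    return dists


def classify_band(hemoglobin, elevated_lower: float, cutoff: float):
    """Band from a hemoglobin value: positive iff >= cutoff, elevated_negative
    iff elevated_lower <= value < cutoff, else negative."""
    hb = np.asarray(hemoglobin, dtype=float)
    band = np.where(hb >= cutoff, "positive",
                    np.where(hb >= elevated_lower, "elevated_negative", "negative"))
    return band if band.ndim else str(band)


def band_probabilities(dists: FitDistributions, state_idx: int, elevated_lower: float) -> dict:
    """Closed-form band probabilities for one state (quadrature-free oracle)."""
    mu, s = dists.mu_log[state_idx], dists.sigma_log
    p_pos = stats.norm.sf((np.log(dists.cutoff) - mu) / s)
    p_ge_lower = stats.norm.sf((np.log(elevated_lower) - mu) / s)
    return {
        "positive": float(p_pos),
        "elevated_negative": float(p_ge_lower - p_pos),
        "negative": float(1.0 - p_ge_lower),
    }


def hemoglobin_from_uniform(u: np.ndarray, state_class: np.ndarray, dists: FitDistributions) -> np.ndarray:
    """Inverse-transform hemoglobin draw; shared uniforms give common random
    numbers across strategies (same person, same test index, same quantile)."""
    z = stats.norm.ppf(np.clip(u, 1e-15, 1 - 1e-15))
    return np.exp(dists.mu_log[np.asarray(state_class, dtype=int)] + dists.sigma_log * z)


def draw_fit(state: str | int, params: ModelParams, rng: np.random.Generator,
             elevated_lower: float | None = None, dists: FitDistributions | None = None) -> FitResult:
    """Draw one FIT result given the most advanced lesion state.

    ``state`` is a stage-class index (0..4) or one of the names in
    ``FIT_STATES``; ``elevated_lower`` defaults to the lowest configured band
    bound.
    """
    if dists is None:
        dists = calibrate_fit_distributions(params)
    idx = FIT_STATES.index(state) if isinstance(state, str) else int(state)
    if elevated_lower is None:
        elevated_lower = float(min(params.fit_characteristics["elevated_lower_bounds"]))
    hb = float(hemoglobin_from_uniform(rng.random(), idx, dists))
    return FitResult(
        hemoglobin=hb,
        band=classify_band(hb, elevated_lower, dists.cutoff),
        thresholds_used=(float(elevated_lower), dists.cutoff),
    )


def perform_colonoscopy(stage_codes: np.ndarray, params: ModelParams,
                        rng: np.random.Generator) -> ColonoscopyResult:
    """One colonoscopy over the lesions present (stage codes per lesion).

    Each lesion is detected independently with its stage-class sensitivity;
    the findings category follows the most advanced detected lesion (advanced
    = any large adenoma or at least ``advanced_min_count`` adenomas).  This
    standalone form serves tests and small studies; the strategy engine uses
    the same parameters through its vectorized path.
    """
    sens_cfg = params.colonoscopy_characteristics["sensitivity"]
    sens = np.array([0.0, sens_cfg["adenoma_small"], sens_cfg["adenoma_medium"],
                     sens_cfg["adenoma_large"], sens_cfg["preclinical_crc"]])
    cls = stage_class(stage_codes)
    detected = rng.random(cls.size) < sens[cls]
    det_idx = list(np.flatnonzero(detected))
    det_cls = cls[detected]
    if (det_cls == 4).any():
        cat = "crc"
    elif (det_cls == 3).any() or det_cls.size >= int(
        params.colonoscopy_characteristics.get("advanced_min_count",
            params.surveillance_policy.get("advanced_min_count", 3))
    ):
        cat = "advanced"
    elif det_cls.size > 0:
        cat = "nonadvanced"
    else:
        cat = "no_adenoma"
    u = rng.random()
    p_comp = float(params.colonoscopy_characteristics["complication_probability"])
    fat = float(params.colonoscopy_characteristics["complication_case_fatality"])
    complication = u < p_comp
    fatal = u < p_comp * fat
    return ColonoscopyResult(
        lesions_detected=det_idx,
        findings_category=cat,
        complication=bool(complication),
        complication_fatal=bool(fatal),
    )
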