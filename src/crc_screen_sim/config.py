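"""Model parameter definitions, validation, loading and persistence.

The full parameter set of the simulation lives in a single YAML document.
A packaged default calibration (``data/default_params.yaml``) ships with the
package; it is an explicitly *synthetic* "Swiss-like" calibration whose
behaviour is pinned by the target bands under ``calibration_targets`` rather
than by any registry fit.  Every quantity the screening engine consumes —
life table, adenoma onset rates, dwell times, FIT and colonoscopy operating
characteristics, disutilities, surveillance policy — is a named key here so
that alternative calibrations can be swapped in without touching code.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "load_params",
    "save_params",
    "validate_params",
    "default_params_path",
    "ConfigError",
]

STAGES = ("I", "II", "III", "IV")
LESION_STATES = ("adenoma_small", "adenoma_medium", "adenoma_large", "preclinical_crc")


class ConfigError(ValueError):
    """Raised when a config file violates the schema or an invariant."""


def default_params_path() -> Path:
    """Path of the packaged default (synthetic) calibration."""
    return Path(str(resources.files("crc_screen_sim").joinpath("data/default_params.yaml")))


@dataclass(frozen=True)
class ModelParams:
    """Immutable container for the complete model parameterization.

    Attributes mirror the top-level YAML sections.  Nested values are plain
    dicts / lists exactly as parsed, so a save/load round trip reproduces the
    object bit-for-bit.  Hot paths in the simulation read arrays out of these
    dicts once, at setup time.
    """

    meta: dict = field(default_factory=dict)
    life_table: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    adenoma_onset: dict = field(default_factory=dict)
    lesion_progression: dict = field(default_factory=dict)
    sojourn: dict = field(default_factory=dict)
    crc_survival: dict = field(default_factory=dict)
    fit_characteristics: dict = field(default_factory=dict)
    colonoscopy_characteristics: dict = field(default_factory=dict)
    disutilities: dict = field(default_factory=dict)
    surveillance_policy: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    discount_rate: float = 0.0
    qaly_reference_age: float = 50.0
    calibration_targets: dict = field(default_factory=dict)
    risk_score_schedules: list = field(default_factory=list)

    # -- convenience accessors -------------------------------------------------

    @property
    def fit_cutoff(self) -> float:
        return float(self.fit_characteristics["cutoff"])

    @property
    def terminal_age(self) -> int:
        return int(self.life_table["terminal_age"])

    def life_table_qx(self, sex: str) -> np.ndarray:
        """Per-year probability of other-cause death for ``sex`` ('male'/'female')."""
        return np.asarray(self.life_table[sex], dtype=float)

    def to_dict(self) -> dict:
        d = {
            "meta": self.meta,
            "life_table": self.life_table,
            "population": self.population,
            "adenoma_onset": self.adenoma_onset,
            "lesion_progression": self.lesion_progression,
            "sojourn": self.sojourn,
            "crc_survival": self.crc_survival,
            "fit_characteristics": self.fit_characteristics,
            "colonoscopy_characteristics": self.colonoscopy_characteristics,
            "disutilities": self.disutilities,
            "surveillance_policy": self.surveillance_policy,
            "screening": self.screening,
            "discount_rate": self.discount_rate,
            "qaly_reference_age": self.qaly_reference_age,
            "calibration_targets": self.calibration_targets,
            "risk_score_schedules": self.risk_score_schedules,
        }
        return copy.deepcopy(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**copy.deepcopy(d))

    def fingerprint(self) -> str:
        """Stable hash of the parameter set, used to tag cohorts and runs."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **sections) -> "ModelParams":
        """Return a copy with whole top-level sections replaced."""
        d = self.to_dict()
        d.update(copy.deepcopy(sections))
        return ModelParams.from_dict(d)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a config file, fill missing keys from the packaged defaults,
    validate, and return :class:`ModelParams`.

    Raises :class:`ConfigError` naming the offending key/invariant on failure.
    """
    with open(default_params_path()) as fh:
        base = yaml.safe_load(fh)
    if path is None:
        merged = base
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ConfigError(f"config root must be a mapping, got {type(override).__name__}")
        merged = _deep_merge(base, override)
    params = ModelParams.from_dict(merged)
    violations = validate_params(params)
    if violations:
        raise ConfigError("invalid parameters: " + "; ".join(violations))
    return params


def save_params(params: ModelParams, path: str | Path) -> Path:
    """Persist a parameter set as YAML. ``load_params(save_params(p))`` is exact."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
    return path


# -- validation ------------------------------------------------------------------


def _prob(x) -> bool:
    try:
        return 0.0 <= float(x) <= 1.0
    except (TypeError, ValueError):
        return False


def validate_params(p: ModelParams) -> list[str]:
    """Check every config invariant; return a list of human-readable violations.

    Violations are returned, never raised, so callers can report all problems
    at once (the CLI ``validate-config`` command prints them).
    """
    v: list[str] = []

    # life table
    term = p.life_table.get("terminal_age")
    for sex in ("male", "female"):
        qx = p.life_table.get(sex)
        if qx is None:
            v.append(f"life_table.{sex}: missing")
            continue
        if term is not None and len(qx) != int(term) + 1:
            v.append(f"life_table.{sex}: expected {int(term) + 1} entries (ages 0..{term})")
        if any(not _prob(q) for q in qx):
            v.append(f"life_table.{sex}: death probabilities must lie in [0, 1]")
        elif qx and float(qx[-1]) != 1.0:
            v.append(f"life_table.{sex}: death probability at terminal age must be 1")

    # adenoma onset
    rates = p.adenoma_onset.get("rates", [])
    if any(float(r) < 0 for r in rates):
        v.append("adenoma_onset.rates: rates must be >= 0")
    breaks = p.adenoma_onset.get("age_breaks", [])
    if len(breaks) != len(rates) + 1:
        v.append("adenoma_onset: age_breaks must have exactly one more entry than rates")
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        v.append("adenoma_onset.age_breaks: must be strictly increasing")
    fr = p.population.get("frailty", {})
    if float(fr.get("variance", 0.0)) < 0:
        v.append("population.frailty.variance: must be >= 0")
    if not _prob(fr.get("zero_fraction", 0.0)):
        v.append("population.frailty.zero_fraction: must lie in [0, 1]")

    # progression / sojourn
    for key, d in (("lesion_progression.mean_years", p.lesion_progression.get("mean_years", {})),
                   ("sojourn.progression_mean_years", p.sojourn.get("progression_mean_years", {})),
                   ("sojourn.clinical_mean_years", p.sojourn.get("clinical_mean_years", {}))):
        for k, val in d.items():
            if float(val) <= 0:
                v.append(f"{key}.{k}: dwell-time means must be > 0")

    # survival
    for stage in STAGES:
        cure = p.crc_survival.get("cure_probability", {}).get(stage)
        if cure is None or not _prob(cure):
            v.append(f"crc_survival.cure_probability.{stage}: must lie in [0, 1]")
        mean = p.crc_survival.get("mean_survival_years", {}).get(stage)
        if mean is None or float(mean) <= 0:
            v.append(f"crc_survival.mean_survival_years.{stage}: must be > 0")

    # FIT
    fit = p.fit_characteristics
    cutoff = float(fit.get("cutoff", 0.0))
    if cutoff <= 0:
        v.append("fit_characteristics.cutoff: must be > 0")
    for lb in fit.get("elevated_lower_bounds", []):
        if not float(lb) < cutoff:
            v.append(
                f"fit_characteristics.elevated_lower_bounds: bound {lb} must be strictly "
                f"below the positivity cut-off {cutoff}"
            )
    if float(fit.get("sigma_log", 1.0)) <= 0:
        v.append("fit_characteristics.sigma_log: must be > 0")
    for state, prob in fit.get("positive_probability", {}).items():
        if not _prob(prob) or float(prob) in (0.0, 1.0):
            v.append(f"fit_characteristics.positive_probability.{state}: must lie strictly in (0, 1)")

    # colonoscopy
    col = p.colonoscopy_characteristics
    for state, s in col.get("sensitivity", {}).items():
        if not _prob(s):
            v.append(f"colonoscopy_characteristics.sensitivity.{state}: must lie in [0, 1]")
    for k in ("complication_probability", "complication_case_fatality"):
        if not _prob(col.get(k, 0.0)):
            v.append(f"colonoscopy_characteristics.{k}: must lie in [0, 1]")

    # disutilities
    dis = p.disutilities
    for k in ("fit", "colonoscopy", "complication"):
        if float(dis.get(k, 0.0)) < 0:
            v.append(f"disutilities.{k}: must be >= 0")
    for phase in ("initial", "continuing"):
        for stage, val in dis.get("crc_care", {}).get(phase, {}).items():
            if not _prob(val):
                v.append(f"disutilities.crc_care.{phase}.{stage}: must lie in [0, 1]")

    # surveillance / screening age structure
    surv_term = float(p.surveillance_policy.get("terminal_age", 0))
    stop_age = float(p.screening.get("stop_age", 0))
    max_stop = max([stop_age] + [float(a) for a in p.screening.get("allowed_stop_ages", [stop_age])])
    if not surv_term > max_stop:
        v.append(
            f"surveillance_policy.terminal_age: must exceed any allowed screening stop age "
            f"({surv_term} <= {max_stop})"
        )
    if float(p.screening.get("start_age", 50)) >= stop_age:
        v.append("screening.start_age: must be below screening.stop_age")

    if float(p.discount_rate) < 0:
        v.append("discount_rate: must be >= 0")

    return v
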