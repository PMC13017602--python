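"""Adenoma-carcinoma natural history in the absence of screening.

Semi-Markov individual-level model: adenomas arise from a nonhomogeneous
Poisson process (piecewise-constant baseline age rate x individual frailty),
grow through three size classes with independent exponential dwell times,
may transform to preclinical cancer, progress through preclinical stages
I-IV in competition with clinical surfacing, and - once clinical - draw a
stage/age/location-specific survival time from an exponential-mixture cure
model.  Other-cause death is pre-scheduled at the start of each life.

Internally the whole cohort's lesions live in flat numpy arrays (CSR-indexed
by person) so that screening strategies can be replayed over identical
histories cheaply; :class:`LifeHistory` offers the per-individual view.

Stage codes used throughout the package::

    0 none | 1 small adenoma | 2 medium | 3 large | 4..7 preclinical I..IV
    8 clinically surfaced cancer
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelParams
from .population import Cohort, Individual, substream

__all__ = [
    "Lesion",
    "LifeHistory",
    "NaturalHistories",
    "simulate_cohort_histories",
    "simulate_life_history",
    "state_at",
    "calibration_summary",
]

_STREAM_NATHIST = 22

STAGE_NONE = 0
STAGE_SMALL = 1
STAGE_MEDIUM = 2
STAGE_LARGE = 3
STAGE_PC1 = 4
STAGE_PC4 = 7
STAGE_CLINICAL = 8

STAGE_NAMES = {
    0: "none", 1: "adenoma_small", 2: "adenoma_medium", 3: "adenoma_large",
    4: "preclinical_crc_stage_I", 5: "preclinical_crc_stage_II",
    6: "preclinical_crc_stage_III", 7: "preclinical_crc_stage_IV",
    8: "clinical_crc",
}


@dataclass
class Lesion:
    """One lesion's full (untruncated) stage path."""

    onset_age: float
    stage_path: list  # [(stage_name, transition_age), ...] in increasing age
    location: str     # 'proximal' / 'distal'
    transformed: bool


@dataclass
class LifeHistory:
    """Event timeline of one individual with no screening applied."""

    individual_id: int
    lesions: list
    clinical_diagnosis: tuple | None   # (age, stage 1-4, location) or None
    crc_death_age: float | None
    death_age: float
    death_cause: str                   # 'other' / 'crc'


@dataclass
class NaturalHistories:
    """Cohort-level natural histories (flat lesion arrays, CSR by person)."""

    n: int
    # per-lesion (sorted by person)
    person: np.ndarray        # int32
    onset: np.ndarray         # onset age of the small adenoma
    enter: np.ndarray         # (m, 6): ages entering medium, large, pcI..pcIV (inf if never)
    clin_age: np.ndarray      # age of clinical surfacing (inf if never)
    clin_stage: np.ndarray    # int8 1..4 stage at surfacing (0 if never)
    proximal: np.ndarray      # bool
    indptr: np.ndarray        # (n+1,) CSR pointers into the lesion arrays
    # per-person
    other_cause_death_age: np.ndarray
    u_cure: np.ndarray        # survival-draw uniforms, shared across strategies
    u_surv: np.ndarray
    # no-screening outcome (derived once)
    ns_dx_age: np.ndarray     # inf if never clinically diagnosed
    ns_dx_stage: np.ndarray   # int8, 0 if none
    ns_dx_proximal: np.ndarray
    ns_crc_death_age: np.ndarray  # inf if none
    ns_death_age: np.ndarray
    seed: int = 0

    @property
    def m(self) -> int:
        return self.person.size

    def lesion_stage_at(self, lesion_idx: np.ndarray, age: float) -> np.ndarray:
        """Stage code of each indexed lesion at scalar ``age`` (no removal applied)."""
        a = float(age)
        started = self.onset[lesion_idx] <= a
        adv = (self.enter[lesion_idx] <= a).sum(axis=1).astype(np.int8)
        stage = np.where(started, 1 + adv, 0).astype(np.int8)
        stage = np.where((self.clin_age[lesion_idx] <= a) & started, STAGE_CLINICAL, stage)
        return stage

    def life_history(self, i: int) -> LifeHistory:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        lesions = []
        for j in range(lo, hi):
            path = [("adenoma_small", float(self.onset[j]))]
            names = ["adenoma_medium", "adenoma_large", "preclinical_crc_stage_I",
                     "preclinical_crc_stage_II", "preclinical_crc_stage_III",
                     "preclinical_crc_stage_IV"]
            for k, nm in enumerate(names):
                if np.isfinite(self.enter[j, k]):
                    path.append((nm, float(self.enter[j, k])))
            if np.isfinite(self.clin_age[j]):
                path.append(("clinical_crc", float(self.clin_age[j])))
            lesions.append(
                Lesion(
                    onset_age=float(self.onset[j]),
                    stage_path=path,
                    location="proximal" if self.proximal[j] else "distal",
                    transformed=bool(np.isfinite(self.enter[j, 2])),
                )
            )
        dx = None
        if np.isfinite(self.ns_dx_age[i]) and self.ns_dx_age[i] <= self.ns_death_age[i]:
            dx = (
                float(self.ns_dx_age[i]),
                int(self.ns_dx_stage[i]),
                "proximal" if self.ns_dx_proximal[i] else "distal",
            )
        crc_death = float(self.ns_crc_death_age[i]) if np.isfinite(self.ns_crc_death_age[i]) else None
        death = float(self.ns_death_age[i])
        cause = "crc" if (crc_death is not None and crc_death <= self.other_cause_death_age[i]) else "other"
        return LifeHistory(
            individual_id=int(i),
            lesions=lesions,
            clinical_diagnosis=dx if (dx and dx[0] < death + 1e-12) else dx,
            crc_death_age=crc_death,
            death_age=death,
            death_cause=cause,
        )


# -- survival ------------------------------------------------------------------


def crc_survival_time(
    dx_age: np.ndarray,
    stage: np.ndarray,
    proximal: np.ndarray,
    u_cure: np.ndarray,
    u_surv: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Years from diagnosis to CRC death; inf for cured patients.

    Exponential-mixture cure model: cure probability depends on stage, age
    group at diagnosis and location; non-cured survival is exponential with a
    stage-specific mean.  Uniforms come from per-person substreams so the same
    person gets coherent draws across strategies (screen detection at an
    earlier stage can only improve the outcome).
    """
    cs = params.crc_survival
    stages = np.asarray(stage, dtype=int)
    cure = np.array([0.0] + [cs["cure_probability"][s] for s in ("I", "II", "III", "IV")])[stages]
    mean = np.array([1.0] + [cs["mean_survival_years"][s] for s in ("I", "II", "III", "IV")])[stages]
    breaks = np.asarray(cs["age_breaks"], dtype=float)
    fac = np.asarray(cs["age_cure_factor"], dtype=float)
    grp = np.clip(np.searchsorted(breaks, np.asarray(dx_age, dtype=float), side="right") - 1, 0, fac.size - 1)
    cure = cure * fac[grp]
    cure = np.where(np.asarray(proximal, dtype=bool), cure * float(cs["proximal_cure_factor"]), cure)
    cured = np.asarray(u_cure) < cure
    t = -mean * np.log1p(-np.asarray(u_surv))
    return np.where(cured, np.inf, t)


# -- simulation ----------------------------------------------------------------


def simulate_cohort_histories(cohort: Cohort, params: ModelParams, seed: int) -> NaturalHistories:
    """Simulate every individual's unscreened life history (vectorized).

    Lesion paths are generated in full (ignoring death) and truncated at the
    point of use; this is what lets every screening strategy replay the exact
    same biology.
    """
    rng = substream(seed, _STREAM_NATHIST)
    n = cohort.n

    breaks = np.asarray(params.adenoma_onset["age_breaks"], dtype=float)
    rates = np.asarray(params.adenoma_onset["rates"], dtype=float)
    widths = np.diff(breaks)
    cum = np.concatenate([[0.0], np.cumsum(rates * widths)])  # cumulative baseline hazard
    total = cum[-1]

    lam = cohort.frailty * total
    counts = rng.poisson(lam)
    m = int(counts.sum())
    person = np.repeat(np.arange(n, dtype=np.int32), counts)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    # onset ages by inverting the piecewise-linear cumulative baseline hazard
    u = rng.random(m) * total
    band = np.searchsorted(cum, u, side="right") - 1
    band = np.clip(band, 0, rates.size - 1)
    onset = breaks[band] + (u - cum[band]) / np.maximum(rates[band], 1e-300)
    # sort lesions within person by onset for readable per-person views
    order = np.lexsort((onset, person))
    person, onset = person[order], onset[order]

    mp = params.lesion_progression["mean_years"]
    d1 = rng.exponential(float(mp["small_to_medium"]), m)
    d2 = rng.exponential(float(mp["medium_to_large"]), m)
    d3 = rng.exponential(float(mp["large_to_preclinical"]), m)
    a_med = onset + d1
    a_lar = a_med + d2
    a_pc1 = a_lar + d3

    prog = params.sojourn["progression_mean_years"]
    clin = params.sojourn["clinical_mean_years"]
    enter = np.full((m, 6), np.inf)
    enter[:, 0], enter[:, 1], enter[:, 2] = a_med, a_lar, a_pc1
    clin_age = np.full(m, np.inf)
    clin_stage = np.zeros(m, dtype=np.int8)
    t_cur = a_pc1.copy()
    active = np.ones(m, dtype=bool)
    for k, s in enumerate(("I", "II", "III")):
        rp, rc = 1.0 / float(prog[s]), 1.0 / float(clin[s])
        stay = rng.exponential(1.0 / (rp + rc), m)
        to_clinic = rng.random(m) < rc / (rp + rc)
        exit_t = t_cur + stay
        surf = active & to_clinic
        clin_age[surf] = exit_t[surf]
        clin_stage[surf] = k + 1
        progress = active & ~to_clinic
        enter[progress, 3 + k] = exit_t[progress]
        t_cur = exit_t
        active = progress
    stay4 = rng.exponential(float(clin["IV"]), m)
    clin_age[active] = t_cur[active] + stay4[active]
    clin_stage[active] = 4

    proximal = rng.random(m) < float(params.lesion_progression["proximal_fraction"])

    u_cure = rng.random(n)
    u_surv = rng.random(n)

    # no-screening outcome: first clinical surfacing before other-cause death
    ocd = cohort.other_cause_death_age
    cand = clin_age.copy()
    cand[cand >= ocd[person]] = np.inf
    ns_dx_age = np.full(n, np.inf)
    np.minimum.at(ns_dx_age, person, cand)
    has_dx = np.isfinite(ns_dx_age)
    ns_dx_stage = np.zeros(n, dtype=np.int8)
    ns_dx_prox = np.zeros(n, dtype=bool)
    hit = cand == ns_dx_age[person]
    hit &= np.isfinite(cand)
    ns_dx_stage[person[hit]] = clin_stage[hit]
    ns_dx_prox[person[hit]] = proximal[hit]

    ns_crc_death = np.full(n, np.inf)
    if has_dx.any():
        t = crc_survival_time(
            ns_dx_age[has_dx], ns_dx_stage[has_dx], ns_dx_prox[has_dx],
            u_cure[has_dx], u_surv[has_dx], params,
        )
        ns_crc_death[has_dx] = ns_dx_age[has_dx] + t
    ns_death = np.minimum(ocd, ns_crc_death)

    return NaturalHistories(
        n=n, person=person, onset=onset, enter=enter, clin_age=clin_age,
        clin_stage=clin_stage, proximal=proximal, indptr=indptr,
        other_cause_death_age=np.asarray(ocd, dtype=float),
        u_cure=u_cure, u_surv=u_surv,
        ns_dx_age=ns_dx_age, ns_dx_stage=ns_dx_stage, ns_dx_proximal=ns_dx_prox,
        ns_crc_death_age=ns_crc_death, ns_death_age=ns_death, seed=int(seed),
    )


def _single_cohort(ind: Individual) -> Cohort:
    return Cohort(
        sex_male=np.array([ind.sex == "male"]),
        bmi=np.array([ind.bmi]),
        smoking=np.array([("never", "former", "current").index(ind.smoking)]),
        alcohol=np.array([ind.alcohol]),
        frailty=np.array([ind.frailty]),
        other_cause_death_age=np.array([ind.other_cause_death_age]),
        seed=0,
        params_fingerprint="",
    )


def simulate_life_history(ind: Individual, params: ModelParams, seed: int) -> LifeHistory:
    """Simulate one individual's unscreened life history from its own substream."""
    mini = _single_cohort(ind)
    nh = simulate_cohort_histories(mini, params, seed=(int(seed) * 1_000_003 + ind.id) % (2**31))
    lh = nh.life_history(0)
    lh.individual_id = ind.id
    return lh


def state_at(lh: LifeHistory, age: float, removed_onsets: set | None = None) -> str:
    """Most advanced lesion state present and undetected at ``age``.

    Ordering: none < adenoma_small < adenoma_medium < adenoma_large <
    preclinical_crc.  Lesions removed by an earlier polypectomy (identified by
    onset age in ``removed_onsets``) are excluded.
    """
    if age > lh.death_age:
        raise ValueError(f"age {age} is after death at {lh.death_age}")
    order = ["none", "adenoma_small", "adenoma_medium", "adenoma_large", "preclinical_crc"]
    best = 0
    for les in lh.lesions:
        if removed_onsets and les.onset_age in removed_onsets:
            continue
        if les.onset_age > age:
            continue
        stage = "adenoma_small"
        for name, t in les.stage_path:
            if t <= age:
                stage = name
        if stage == "clinical_crc":
            continue  # surfaced cancers are diagnosed, not silent
        key = "preclinical_crc" if stage.startswith("preclinical") else stage
        best = max(best, order.index(key))
    return order[best]


# -- calibration ----------------------------------------------------------------


def calibration_summary(nh: NaturalHistories, params: ModelParams, to_age: float = 90.0) -> pd.DataFrame:
    """Summarize the unscreened cohort against the configured target bands.

    Reports lifetime (to ``to_age``) adenoma prevalence, CRC incidence and
    mortality, mean preclinical sojourn of surfaced cancers, and per-decade
    incidence; flags any summary outside its ``calibration_targets`` band.
    """
    if nh.n == 0:
        raise ValueError("empty cohort")
    horizon = np.minimum(nh.ns_death_age, to_age)
    has_adenoma = np.zeros(nh.n, dtype=bool)
    seen = nh.onset < horizon[nh.person]
    has_adenoma[nh.person[seen]] = True
    prevalence = has_adenoma.mean()

    dx = np.isfinite(nh.ns_dx_age) & (nh.ns_dx_age <= to_age)
    incidence = dx.mean()
    crc_death = np.isfinite(nh.ns_crc_death_age) & (nh.ns_crc_death_age <= np.minimum(nh.other_cause_death_age, to_age))
    mortality = crc_death.mean()

    # sojourn of the diagnosed lesion: clinical age minus preclinical onset
    hit = (nh.clin_age == nh.ns_dx_age[nh.person]) & np.isfinite(nh.clin_age)
    sojourn = nh.clin_age[hit] - nh.enter[hit, 2]
    mean_sojourn = float(sojourn.mean()) if sojourn.size else np.nan

    targets = params.calibration_targets
    rows = [
        ("adenoma_prevalence", prevalence, targets.get("adenoma_prevalence")),
        ("lifetime_crc_incidence", incidence, targets.get("lifetime_crc_incidence")),
        ("lifetime_crc_mortality", mortality, targets.get("lifetime_crc_mortality")),
        ("mean_sojourn_years", mean_sojourn, targets.get("mean_sojourn_years")),
    ]
    for lo_age in range(50, 90, 10):
        mask = np.isfinite(nh.ns_dx_age) & (nh.ns_dx_age >= lo_age) & (nh.ns_dx_age < lo_age + 10)
        at_risk = nh.ns_death_age > lo_age
        rate = mask.sum() / max(at_risk.sum(), 1)
        rows.append((f"incidence_{lo_age}_{lo_age + 10}", rate, None))

    df = pd.DataFrame(rows, columns=["quantity", "value", "target_band"])
    df["in_band"] = [
        bool(b[0] <= v <= b[1]) if isinstance(b, (list, tuple)) else None
        for v, b in zip(df["value"], df["target_band"])
    ]
    return df
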