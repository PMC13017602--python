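"""Screening strategy definitions and the cohort execution engine.

A :class:`StrategySpec` declaratively describes one strategy from one of four
families:

* ``age_based`` — biennial FIT from the start age, switching everyone to
  10-yearly colonoscopy at a fixed *transition age*;
* ``risk_score_based`` — FIT by default, with QCancer-like risk assessments
  at fixed ages; the top configured proportion of pooled assessed scores
  switches to colonoscopy;
* ``fit_based`` — FIT by default; an "elevated but negative" result (above a
  5 or 10 ug/g band bound but under the 15 ug/g cut-off) triggers a switch to
  colonoscopy at the next due screen two years later, optionally backstopped
  by a fixed transition age;
* ``reference`` — FIT only, colonoscopy only, a 50/50 free-choice split, and
  the no-screening baseline.

Universal rules: a positive FIT (>= 15 ug/g) sends the person to an immediate
diagnostic colonoscopy; after any colonoscopy the person never returns to FIT;
adenoma findings trigger surveillance at findings-dependent intervals until
age 86; detected CRC ends screening and redraws survival at the detected
stage.

The engine executes a whole cohort at once over an integer-age event loop
using flat numpy state arrays.  All screening randomness is pre-drawn as
per-person / per-event-index uniform tables from the run seed, so two
strategies executed with the same seed share every random draw up to the
first event at which they diverge (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ModelParams
from .natural_history import NaturalHistories, crc_survival_time
from .population import Cohort, cohort_scores, substream
from .screen_tests import FitDistributions, calibrate_fit_distributions, hemoglobin_from_uniform

__all__ = [
    "StrategySpec",
    "StrategyRun",
    "enumerate_strategies",
    "scheduled_colonoscopy_ages",
    "compute_risk_threshold",
    "run_strategy",
    "apply_adherence_scenario",
    "resolve_stop_age",
    "no_screening_spec",
]

# mode codes
FIT, COLO, SURV, NONE = 0, 1, 2, 3
# adherence codes
COMPLIANT, ALWAYS_FIT, ALWAYS_COL, NEVER = 0, 1, 2, 3

_STREAM_SCREEN = 33
_STREAM_ADHERENCE = 44
_STREAM_STOPAGE = 55

AGE_SENTINEL = 127  # "no event scheduled"


@dataclass(frozen=True)
class StrategySpec:
    """Declarative description of one screening strategy."""

    family: str                                  # age_based / risk_score_based / fit_based / reference
    transition_age: int | None = None
    assessment_ages: tuple = ()
    top_proportion: float | None = None
    elevated_band_lower: float | None = None     # ug/g, 5 or 10
    reference_kind: str | None = None            # fit_only / col_only / fifty_fifty / no_screening
    start_age: int = 50
    stop_age_policy: dict = field(default_factory=lambda: {"kind": "fixed", "age": 74})
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "assessment_ages", tuple(self.assessment_ages))
        self._check()
        if not self.label:
            object.__setattr__(self, "label", self._canonical_label())

    def _canonical_label(self) -> str:
        if self.family == "age_based":
            return f"age_{self.transition_age}"
        if self.family == "risk_score_based":
            ages = ":".join(str(a) for a in self.assessment_ages)
            return f"{int(round(self.top_proportion * 100))}%_{ages}"
        if self.family == "fit_based":
            band = f"FIT{int(self.elevated_band_lower)}"
            return f"{band}_{self.transition_age}" if self.transition_age else f"{band}_x"
        if self.family == "reference":
            return {"fit_only": "FIT_only", "col_only": "COL_only",
                    "fifty_fifty": "50/50", "no_screening": "no_screening"}[self.reference_kind]
        raise ValueError(f"unknown family {self.family!r}")

    def _check(self):
        fam = self.family
        if fam == "age_based":
            if self.transition_age is None:
                raise ValueError("age_based strategy requires transition_age")
        elif fam == "risk_score_based":
            if not self.assessment_ages or self.top_proportion is None:
                raise ValueError("risk_score_based requires assessment_ages and top_proportion")
            if any(b >= a for b, a in zip(self.assessment_ages, self.assessment_ages[1:])):
                raise ValueError("assessment_ages must be strictly increasing")
            if not 0.0 < self.top_proportion <= 1.0:
                raise ValueError("top_proportion must lie in (0, 1]")
        elif fam == "fit_based":
            if self.elevated_band_lower is None:
                raise ValueError("fit_based requires elevated_band_lower")
        elif fam == "reference":
            if self.reference_kind not in ("fit_only", "col_only", "fifty_fifty", "no_screening"):
                raise ValueError(f"unknown reference_kind {self.reference_kind!r}")
        else:
            raise ValueError(f"unknown family {fam!r}")


def no_screening_spec(start_age: int = 50, stop_age_policy: dict | None = None) -> StrategySpec:
    return StrategySpec(
        family="reference", reference_kind="no_screening", start_age=start_age,
        stop_age_policy=stop_age_policy or {"kind": "fixed", "age": 74},
    )


def enumerate_strategies(family: str, params: ModelParams,
                         start_age: int = 50, stop_age_policy: dict | None = None) -> list[StrategySpec]:
    """Enumerate the strategy space of one family with canonical labels."""
    pol = stop_age_policy or {"kind": "fixed", "age": int(params.screening["stop_age"])}
    common = dict(start_age=start_age, stop_age_policy=pol)
    if family == "age_based":
        return [StrategySpec(family="age_based", transition_age=t, **common)
                for t in range(52, 76, 2)]
    if family == "fit_based":
        specs = []
        for band in params.fit_characteristics["elevated_lower_bounds"]:
            specs.append(StrategySpec(family="fit_based", elevated_band_lower=float(band), **common))
            specs.extend(
                StrategySpec(family="fit_based", elevated_band_lower=float(band), transition_age=t, **common)
                for t in range(54, 76, 2)
            )
        return specs
    if family == "risk_score_based":
        schedules = [tuple(s) for s in params.risk_score_schedules]
        return [
            StrategySpec(family="risk_score_based", assessment_ages=s, top_proportion=p / 100.0, **common)
            for p in range(10, 100, 10) for s in schedules
        ]
    if family == "reference":
        return [StrategySpec(family="reference", reference_kind=k, **common)
                for k in ("fit_only", "col_only", "fifty_fifty")]
    raise ValueError(f"unknown family {family!r}")


def scheduled_colonoscopy_ages(transition_age: int, stop_age: int, interval: int = 10) -> list[int]:
    """Colonoscopy ages implied by switching at ``transition_age``:
    {transition, transition+interval, ...} up to and including ``stop_age``."""
    if transition_age > stop_age:
        raise ValueError(f"transition age {transition_age} exceeds stop age {stop_age}")
    return list(range(int(transition_age), int(stop_age) + 1, int(interval)))


def resolve_stop_age(policy: dict, n: int, seed: int, default_start: int = 50) -> tuple[int, np.ndarray]:
    """Resolve a stop-age policy to (start_age, per-person stop ages).

    ``fixed`` returns its age for everyone; ``distribution`` draws each
    person's stop age independently of CRC risk; ``uspstf`` is start 45 /
    stop 75.
    """
    kind = policy["kind"]
    if kind == "fixed":
        return default_start, np.full(n, int(policy["age"]), dtype=np.int16)
    if kind == "distribution":
        rng = substream(seed, _STREAM_STOPAGE)
        ages = np.asarray(policy["ages"], dtype=np.int16)
        w = np.asarray(policy["weights"], dtype=float)
        w = w / w.sum()
        return default_start, ages[rng.choice(ages.size, size=n, p=w)]
    if kind == "uspstf":
        return 45, np.full(n, 75, dtype=np.int16)
    raise ValueError(f"unknown stop-age policy kind {kind!r}")


def apply_adherence_scenario(n: int, mix: dict | None, seed: int) -> np.ndarray:
    """Assign adherence types independently of risk.

    ``mix`` maps {'always_fit', 'always_col', 'never', 'compliant'} to
    fractions summing to 1; ``None`` means full adherence (all compliant).
    """
    if mix is None:
        return np.full(n, COMPLIANT, dtype=np.int8)
    fracs = np.array([mix.get("compliant", 0.0), mix.get("always_fit", 0.0),
                      mix.get("always_col", 0.0), mix.get("never", 0.0)])
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError(f"adherence fractions must sum to 1, got {fracs.sum()}")
    rng = substream(seed, _STREAM_ADHERENCE)
    return rng.choice(4, size=n, p=fracs).astype(np.int8)


# -- execution ------------------------------------------------------------------


@dataclass
class StrategyRun:
    """Per-person results of one strategy executed on one cohort."""

    spec: StrategySpec
    seed: int
    start_age: int
    stop_age: np.ndarray
    death_age: np.ndarray
    dx_age: np.ndarray          # inf if never diagnosed
    dx_stage: np.ndarray        # 0 if none, else 1..4
    dx_screen: np.ndarray       # True if screen-detected
    crc_death_age: np.ndarray   # inf if none
    n_fit: np.ndarray
    n_colo_screen: np.ndarray
    n_colo_dx: np.ndarray       # diagnostic (positive-FIT workup + clinical workup)
    n_colo_surv: np.ndarray
    n_complications: np.ndarray
    dw_fit: np.ndarray          # discount-weight sums of per-event disutilities
    dw_colo: np.ndarray
    dw_compl: np.ndarray
    events: pd.DataFrame | None = None
    risk_threshold: float | None = None

    @property
    def n_colonoscopies(self) -> np.ndarray:
        return self.n_colo_screen + self.n_colo_dx + self.n_colo_surv


def _lesions_of(persons: np.ndarray, indptr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat lesion indices of ``persons`` plus the position of each owner in
    ``persons`` (CSR gather without Python loops)."""
    counts = (indptr[persons + 1] - indptr[persons]).astype(np.int64)
    tot = int(counts.sum())
    if tot == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    owner_pos = np.repeat(np.arange(persons.size), counts)
    cum = np.concatenate([[0], np.cumsum(counts)])
    offset = np.arange(tot) - cum[owner_pos]
    lesion_idx = indptr[persons][owner_pos] + offset
    return lesion_idx, owner_pos


def compute_risk_threshold(spec: StrategySpec, cohort: Cohort, nh: NaturalHistories,
                           params: ModelParams, seed: int,
                           adherence: np.ndarray | None = None) -> float:
    """Two-pass risk-score threshold: pass 1 replays the strategy with nobody
    switching and pools the scores of every assessment performed on
    individuals alive, CRC-free, and still FIT-screening; the threshold is the
    (1 - top_proportion) quantile of that pool."""
    if spec.family != "risk_score_based":
        raise ValueError("risk threshold is defined only for risk_score_based strategies")
    if adherence is None:
        adherence = apply_adherence_scenario(cohort.n, None, seed)
    run = _execute(spec, cohort, nh, params, seed, adherence=adherence,
                   threshold=np.inf, collect_scores=True)
    pooled = run["pooled_scores"]
    if pooled.size == 0:
        raise ValueError("no assessment events occurred; cannot compute a threshold")
    return float(np.quantile(pooled, 1.0 - spec.top_proportion))


def run_strategy(spec: StrategySpec, cohort: Cohort, nh: NaturalHistories,
                 params: ModelParams, seed: int,
                 adherence_mix: dict | None = None,
                 threshold: float | None = None,
                 collect_events: bool = False) -> StrategyRun:
    """Execute one strategy over the cohort's natural histories.

    ``seed`` controls all screening randomness; running two specs with the
    same seed compares them under common random numbers.  For
    risk_score_based specs the pooled-score threshold is computed with the
    two-pass procedure unless supplied.
    """
    adherence = apply_adherence_scenario(cohort.n, adherence_mix, seed)
    if spec.family == "risk_score_based" and threshold is None:
        threshold = compute_risk_threshold(spec, cohort, nh, params, seed, adherence=adherence)
    out = _execute(spec, cohort, nh, params, seed, adherence=adherence,
                   threshold=threshold, collect_events=collect_events)
    events = None
    if collect_events:
        events = pd.DataFrame(out["events"], columns=["id", "age", "event", "detail"])
        events = events.sort_values(["age", "id"], kind="stable").reset_index(drop=True)
    return StrategyRun(
        spec=spec, seed=int(seed), start_age=out["start_age"], stop_age=out["stop_age"],
        death_age=out["death_age"], dx_age=out["dx_age"], dx_stage=out["dx_stage"],
        dx_screen=out["dx_screen"], crc_death_age=out["crc_death_age"],
        n_fit=out["n_fit"], n_colo_screen=out["n_colo_screen"], n_colo_dx=out["n_colo_dx"],
        n_colo_surv=out["n_colo_surv"], n_complications=out["n_compl"],
        dw_fit=out["dw_fit"], dw_colo=out["dw_colo"], dw_compl=out["dw_compl"],
        events=events, risk_threshold=(None if threshold is None or not np.isfinite(threshold)
                                       else float(threshold)),
    )


def _execute(spec: StrategySpec, cohort: Cohort, nh: NaturalHistories, params: ModelParams,
             seed: int, adherence: np.ndarray, threshold: float | None = None,
             collect_scores: bool = False, collect_events: bool = False) -> dict:
    n = cohort.n
    rng = substream(seed, _STREAM_SCREEN)

    start_age, stop_age = resolve_stop_age(spec.stop_age_policy, n, seed,
                                           default_start=spec.start_age)
    surv_term = int(params.surveillance_policy["terminal_age"])
    fit_int = int(params.screening["fit_interval_years"])
    col_int = int(params.screening["colonoscopy_interval_years"])
    adv_int = int(params.surveillance_policy["advanced_interval_years"])
    nonadv_int = int(params.surveillance_policy["nonadvanced_interval_years"])
    adv_min = int(params.surveillance_policy["advanced_min_count"])

    dists: FitDistributions = calibrate_fit_distributions(params)
    cutoff = dists.cutoff
    band_lower = spec.elevated_band_lower
    sens_cfg = params.colonoscopy_characteristics["sensitivity"]
    sens = np.array([0.0, sens_cfg["adenoma_small"], sens_cfg["adenoma_medium"],
                     sens_cfg["adenoma_large"], sens_cfg["preclinical_crc"]])
    p_comp = float(params.colonoscopy_characteristics["complication_probability"])
    p_fatal = p_comp * float(params.colonoscopy_characteristics["complication_case_fatality"])

    rate = float(params.discount_rate)
    ref_age = float(params.qaly_reference_age)

    def df_at(age: float) -> float:
        # discounting starts at the reference age; earlier events weigh 1
        return 1.0 if rate == 0.0 or age <= ref_age else (1.0 + rate) ** (-(age - ref_age))

    # pre-drawn uniform tables: identical across strategies for a given seed
    MAXF, MAXC, MAXE = 20, 24, 24
    u_fit = rng.random((n, MAXF))
    u_det = rng.random((nh.m, MAXE))
    u_compl = rng.random((n, MAXC))
    u_5050 = rng.random(n)
    eff_sd = float(params.fit_characteristics.get("individual_effect_sd", 0.0))
    log_effect = eff_sd * rng.standard_normal(n) if eff_sd > 0 else None

    # mutable per-person state
    mode = np.full(n, FIT, dtype=np.int8)
    next_fit = np.full(n, start_age, dtype=np.int16)
    next_colo = np.full(n, AGE_SENTINEL, dtype=np.int16)
    next_surv = np.full(n, AGE_SENTINEL, dtype=np.int16)
    death_cur = nh.other_cause_death_age.copy()
    dx = np.zeros(n, dtype=bool)
    dx_age = np.full(n, np.inf)
    dx_stage = np.zeros(n, dtype=np.int8)
    dx_screen = np.zeros(n, dtype=bool)
    crc_death_age = np.full(n, np.inf)
    removed = np.zeros(nh.m, dtype=bool)
    next_clin = nh.clin_age.copy()
    next_clin[~np.isfinite(next_clin)] = np.inf
    person_next_clin = np.full(n, np.inf)
    np.minimum.at(person_next_clin, nh.person, next_clin)

    # decennial-grid anchor: age of the most recent screening/diagnostic
    # colonoscopy; a clear surveillance exam returns people to this grid so
    # the scheduled exam ages (e.g. 50/60/70 for colonoscopy-only) persist
    anchor = np.full(n, AGE_SENTINEL, dtype=np.int16)
    fit_idx = np.zeros(n, dtype=np.int16)
    colo_idx = np.zeros(n, dtype=np.int16)
    exp_idx = np.zeros(nh.m, dtype=np.int16)

    n_fit = np.zeros(n, dtype=np.int32)
    n_colo_screen = np.zeros(n, dtype=np.int32)
    n_colo_dx = np.zeros(n, dtype=np.int32)
    n_colo_surv = np.zeros(n, dtype=np.int32)
    n_compl = np.zeros(n, dtype=np.int32)
    dw_fit = np.zeros(n)
    dw_colo = np.zeros(n)
    dw_compl = np.zeros(n)

    events: list = []
    pooled_scores: list = []

    # initial mode by family / adherence
    if spec.family == "reference" and spec.reference_kind == "no_screening":
        mode[:] = NONE
    else:
        mode[adherence == NEVER] = NONE
        col_start = adherence == ALWAYS_COL
        if spec.family == "reference":
            if spec.reference_kind == "col_only":
                col_start |= adherence == COMPLIANT
            elif spec.reference_kind == "fifty_fifty":
                col_start |= (adherence == COMPLIANT) & (u_5050 < 0.5)
        mode[col_start] = COLO
        next_colo[col_start] = start_age
        next_fit[mode != FIT] = AGE_SENTINEL

    switch_rules = (adherence == COMPLIANT) & (mode != NONE)

    def log(ids, age, event, detail):
        if collect_events:
            ages = np.broadcast_to(np.asarray(age, dtype=float), np.shape(ids))
            events.extend((int(i), float(t), event, d) for i, t, d in zip(ids, ages, detail))

    def recompute_next_clin(persons: np.ndarray):
        if persons.size == 0:
            return
        person_next_clin[persons] = np.inf
        li, owner = _lesions_of(persons, nh.indptr)
        if li.size:
            cand = np.where(removed[li], np.inf, next_clin[li])
            np.minimum.at(person_next_clin, nh.person[li], cand)

    def diagnose(persons: np.ndarray, ages, stages, prox, screen: bool):
        dx[persons] = True
        dx_age[persons] = ages
        dx_stage[persons] = stages
        dx_screen[persons] = screen
        t = crc_survival_time(ages, stages, prox, nh.u_cure[persons], nh.u_surv[persons], params)
        crc_death_age[persons] = np.asarray(ages) + t
        death_cur[persons] = np.minimum(death_cur[persons], crc_death_age[persons])
        mode[persons] = NONE
        # diagnostic workup colonoscopy for clinical presentations is counted
        # by the caller; screen detections already count their exam.

    def exam(persons: np.ndarray, a: int, kind: str):
        """One colonoscopy for each of ``persons`` at integer age ``a``.
        Returns (found_crc, found_advanced, found_any) aligned with persons."""
        k = persons.size
        counter = {"screen": n_colo_screen, "dx": n_colo_dx, "surv": n_colo_surv}[kind]
        counter[persons] += 1
        if kind != "surv":
            anchor[persons] = a
        dw_colo[persons] += df_at(a)
        log(persons, a, f"colonoscopy_{kind}", [""] * k)
        u = u_compl[persons, np.minimum(colo_idx[persons], MAXC - 1)]
        colo_idx[persons] += 1
        comp = u < p_comp
        n_compl[persons] += comp
        dw_compl[persons[comp]] += df_at(a)
        if comp.any():
            log(persons[comp], a, "complication", [""] * int(comp.sum()))
        fatal = u < p_fatal
        if fatal.any():
            death_cur[persons[fatal]] = np.minimum(death_cur[persons[fatal]], float(a))
            mode[persons[fatal]] = NONE

        li, owner = _lesions_of(persons, nh.indptr)
        found_crc = np.zeros(k, dtype=bool)
        found_adv = np.zeros(k, dtype=bool)
        found_any = np.zeros(k, dtype=bool)
        crc_key = np.full(k, -1, dtype=np.int64)
        if li.size:
            active = (~removed[li]) & (nh.onset[li] <= a) & (nh.clin_age[li] > a)
            li, owner = li[active], owner[active]
            stage = np.where(nh.onset[li] <= a, 1 + (nh.enter[li] <= a).sum(axis=1), 0).astype(np.int8)
            cls = np.clip(stage, 0, 4)
            det = u_det[li, np.minimum(exp_idx[li], MAXE - 1)] < sens[cls]
            exp_idx[li] += 1
            dli, downer, dstage = li[det], owner[det], stage[det]
            # adenomas: polypectomy
            aden = dstage <= 3
            removed[dli[aden]] = True
            cnt = np.zeros(k, dtype=np.int32)
            np.add.at(cnt, downer[aden], 1)
            large = np.zeros(k, dtype=bool)
            large[downer[aden & (dstage == 3)]] = True
            found_any = cnt > 0
            found_adv = large | (cnt >= adv_min)
            # preclinical CRC: screen-detected diagnosis at the most advanced stage
            pc = dstage >= 4
            if pc.any():
                key = (dstage[pc].astype(np.int64) << 1) | nh.proximal[dli[pc]]
                np.maximum.at(crc_key, downer[pc], key)
                found_crc = crc_key >= 0
            if aden.any():
                touched = persons[np.unique(downer[aden])]
                recompute_next_clin(touched[~dx[touched]])

        if found_crc.any():
            pdx = persons[found_crc]
            stages = ((crc_key[found_crc] >> 1) - 3).astype(np.int8)
            prox = (crc_key[found_crc] & 1).astype(bool)
            still = death_cur[pdx] > a  # fatal complication in same exam wins
            pdx, stages, prox = pdx[still], stages[still], prox[still]
            if pdx.size:
                diagnose(pdx, float(a), stages, prox, screen=True)
                log(pdx, a, "diagnosis", [f"screen_stage_{s}" for s in stages])
        return found_crc, found_adv, found_any

    def settle_clinical(before_age: float):
        """Diagnose clinical surfacings occurring strictly before ``before_age``."""
        while True:
            due = (~dx) & (person_next_clin < before_age) & (person_next_clin < death_cur)
            if not due.any():
                return
            persons = np.flatnonzero(due)
            ages = person_next_clin[persons]
            li, owner = _lesions_of(persons, nh.indptr)
            pick = (~removed[li]) & (next_clin[li] == ages[owner])
            stages = np.zeros(persons.size, dtype=np.int8)
            prox = np.zeros(persons.size, dtype=bool)
            stages[owner[pick]] = nh.clin_stage[li[pick]]
            prox[owner[pick]] = nh.proximal[li[pick]]
            diagnose(persons, ages, stages, prox, screen=False)
            n_colo_dx[persons] += 1  # clinical diagnostic workup
            dw_colo[persons] += (
                (1.0 + rate) ** (-np.maximum(ages - ref_age, 0.0)) if rate else 1.0
            )
            log(persons, ages, "diagnosis", [f"clinical_stage_{s}" for s in stages])

    ages_iter = range(int(start_age), surv_term + 1)
    for a in ages_iter:
        settle_clinical(float(a))
        alive = death_cur > a

        # -- scheduled switches (compliant only)
        if spec.family in ("age_based", "fit_based") and spec.transition_age == a:
            sw = switch_rules & (mode == FIT) & alive & ~dx & (a <= stop_age)
            mode[sw] = COLO
            next_colo[sw] = a
            next_fit[sw] = AGE_SENTINEL
            log(np.flatnonzero(sw), a, "switch", ["transition_age"] * int(sw.sum()))

        if spec.family == "risk_score_based" and a in spec.assessment_ages:
            elig = switch_rules & (mode == FIT) & alive & ~dx & (a <= stop_age) & (a >= start_age)
            if elig.any():
                idx = np.flatnonzero(elig)
                scores = cohort_scores_subset(cohort, idx, float(a), params)
                if collect_scores:
                    pooled_scores.append(scores)
                if threshold is not None and np.isfinite(threshold):
                    hi = scores >= threshold
                    sw = idx[hi]
                    mode[sw] = COLO
                    next_colo[sw] = a
                    next_fit[sw] = AGE_SENTINEL
                    log(sw, a, "switch", ["risk_score"] * sw.size)

        # -- FIT screening
        f = (mode == FIT) & alive & ~dx & (next_fit == a) & (a <= stop_age) & (a >= start_age)
        if f.any():
            idx = np.flatnonzero(f)
            state = np.zeros(idx.size, dtype=np.int8)
            li, owner = _lesions_of(idx, nh.indptr)
            if li.size:
                active = (~removed[li]) & (nh.onset[li] <= a) & (nh.clin_age[li] > a)
                stage = np.where(active, 1 + (nh.enter[li] <= a).sum(axis=1), 0).astype(np.int8)
                cls = np.clip(stage, 0, 4).astype(np.int8)
                np.maximum.at(state, owner, cls)
            u = u_fit[idx, np.minimum(fit_idx[idx], MAXF - 1)]
            fit_idx[idx] += 1
            hb = hemoglobin_from_uniform(u, state, dists)
            if log_effect is not None:
                hb = hb * np.exp(log_effect[idx])
            n_fit[idx] += 1
            dw_fit[idx] += df_at(a)
            log(idx, a, "fit", [f"{h:.3f}" for h in hb])

            pos = hb >= cutoff
            if pos.any():
                ppos = idx[pos]
                found_crc, found_adv, found_any = exam(ppos, a, "dx")
                _post_exam_schedule(
                    ppos, a, found_crc, found_adv, found_any, mode, next_colo, next_surv,
                    next_fit, dx, death_cur, stop_age, col_int, adv_int, nonadv_int, surv_term,
                )
            if spec.family == "fit_based" and band_lower is not None:
                elev = (~pos) & (hb >= band_lower) & switch_rules[idx]
                sw = idx[elev]
                if sw.size:
                    mode[sw] = COLO
                    next_colo[sw] = a + fit_int
                    next_fit[sw] = AGE_SENTINEL
                    log(sw, a, "switch", ["elevated_fit"] * sw.size)
            rest = (~pos) & (mode[idx] == FIT)
            nf = idx[rest]
            next_fit[nf] = a + fit_int

        # -- screening colonoscopy
        c = (mode == COLO) & alive & ~dx & (next_colo == a) & (a <= stop_age) & (a >= start_age)
        if c.any():
            idx = np.flatnonzero(c)
            found_crc, found_adv, found_any = exam(idx, a, "screen")
            _post_exam_schedule(
                idx, a, found_crc, found_adv, found_any, mode, next_colo, next_surv,
                next_fit, dx, death_cur, stop_age, col_int, adv_int, nonadv_int, surv_term,
            )

        # -- surveillance colonoscopy (runs past the stop age, up to 86)
        s = (mode == SURV) & alive & ~dx & (next_surv == a)
        if s.any():
            idx = np.flatnonzero(s)
            found_crc, found_adv, found_any = exam(idx, a, "surv")
            ok = ~dx[idx] & (death_cur[idx] > a)
            adv = ok & found_adv
            nonadv = ok & found_any & ~found_adv
            clear = ok & ~found_any
            tgt = idx[adv]
            next_surv[tgt] = a + adv_int
            tgt = idx[nonadv]
            next_surv[tgt] = a + nonadv_int
            over = idx[(adv | nonadv)]
            stopn = over[next_surv[over] > surv_term]
            mode[stopn] = NONE
            back = idx[clear]
            # return to the anchored decennial grid, not 10y from this exam
            nxt = anchor[back] + col_int * ((a - anchor[back]) // col_int + 1)
            keep = nxt <= stop_age[back]
            mode[back] = NONE
            ret = back[keep]
            mode[ret] = COLO
            next_colo[ret] = nxt[keep]

    settle_clinical(np.inf)

    return {
        "start_age": int(start_age), "stop_age": stop_age,
        "death_age": death_cur, "dx_age": dx_age, "dx_stage": dx_stage,
        "dx_screen": dx_screen, "crc_death_age": crc_death_age,
        "n_fit": n_fit, "n_colo_screen": n_colo_screen, "n_colo_dx": n_colo_dx,
        "n_colo_surv": n_colo_surv, "n_compl": n_compl,
        "dw_fit": dw_fit, "dw_colo": dw_colo, "dw_compl": dw_compl,
        "events": events,
        "pooled_scores": (np.concatenate(pooled_scores) if pooled_scores else np.empty(0)),
    }


def _post_exam_schedule(persons, a, found_crc, found_adv, found_any, mode, next_colo,
                        next_surv, next_fit, dx, death_cur, stop_age, col_int,
                        adv_int, nonadv_int, surv_term):
    """Schedule what follows a diagnostic or screening colonoscopy: adenoma
    findings start surveillance, a clear exam continues 10-yearly colonoscopy
    within screening ages; nobody returns to FIT."""
    ok = ~dx[persons] & (death_cur[persons] > a)
    next_fit[persons] = AGE_SENTINEL
    findings = ok & found_any
    tgt = persons[findings]
    mode[tgt] = SURV
    next_surv[tgt] = np.where(found_adv[findings], a + adv_int, a + nonadv_int)
    drop = tgt[next_surv[tgt] > surv_term]
    mode[drop] = NONE
    clear = persons[ok & ~found_any]
    cont = clear[(a + col_int) <= stop_age[clear]]
    mode[clear] = NONE
    next_colo[clear] = AGE_SENTINEL
    mode[cont] = COLO
    next_colo[cont] = a + col_int


def cohort_scores_subset(cohort: Cohort, idx: np.ndarray, age: float, params: ModelParams) -> np.ndarray:
    from .population import risk_linear_predictor

    lp = risk_linear_predictor(age, cohort.sex_male[idx], cohort.bmi[idx],
                               cohort.smoking[idx], cohort.alcohol[idx], params)
    return 1.0 / (1.0 + np.exp(-lp))
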