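"""Outcome accounting: QALYs and colonoscopy demand per 1000 50-year-olds.

Utility is 1 per life-year before a CRC diagnosis.  After diagnosis, years
accrue 1 minus a stage- and phase-specific care disutility (initial year /
continuing / terminal year before CRC death); a config switch restores the
literal zero-utility-after-diagnosis reading.  Per-event disutilities are
subtracted for each FIT, colonoscopy and complication at the event's age.
With a positive discount rate every utility increment at age ``a`` is scaled
by ``(1 + r)^-(a - reference_age)`` (reference age 50), integrated exactly
between event ages.

Strategies are compared against a no-screening run of the *same* cohort and
natural-history randomness; aggregation is restricted to individuals alive
and CRC-free at the aggregation start age in the no-screening scenario, and
reported per 1000 such individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelParams
from .strategies import StrategyRun

__all__ = ["CohortOutcome", "individual_qalys", "qalys_from_run", "aggregate", "percent_change"]


@dataclass(frozen=True)
class CohortOutcome:
    strategy_label: str
    n_eligible: int
    colonoscopies_per_1000: float
    qalys_gained_per_1000: float
    crc_cases_per_1000: float
    crc_deaths_per_1000: float
    discount_rate_used: float


def _dint(t0, t1, rate: float, ref: float):
    """Integral of the discount weight over [t0, t1].

    The weight is (1+r)^-(a-ref) for ages past the reference age and 1 before
    it — discounting starts at the reference age; earlier life-years are
    neither discounted nor inflated.
    """
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    span = np.maximum(t1 - t0, 0.0)
    if rate == 0.0:
        return span
    lo = np.minimum(t0, t1)
    hi = lo + span
    pre = np.clip(np.minimum(hi, ref) - lo, 0.0, None)
    a = np.maximum(lo, ref)
    b = np.maximum(hi, ref)
    ln = np.log1p(rate)
    post = ((1.0 + rate) ** (-(a - ref)) - (1.0 + rate) ** (-(b - ref))) / ln
    return pre + post


def individual_qalys(
    death_age,
    dx_age,
    dx_stage,
    crc_death,
    dw_fit,
    dw_colo,
    dw_compl,
    params: ModelParams,
    discount_rate: float | None = None,
    reference_age: float | None = None,
):
    """Quality-adjusted life years for one individual (or arrays of them).

    ``dx_age`` is inf for the never-diagnosed; ``dw_*`` are the discounted
    event-weight sums accumulated by the engine (plain counts when the rate
    is 0).  Total = discounted life years - care-phase losses - event
    disutilities; additive by construction.
    """
    rate = float(params.discount_rate if discount_rate is None else discount_rate)
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    ref = float(params.qaly_reference_age if reference_age is None else reference_age)
    dis = params.disutilities

    death_age = np.asarray(death_age, dtype=float)
    dx_age = np.asarray(dx_age, dtype=float)
    stage = np.asarray(dx_stage, dtype=int)
    crc_death = np.asarray(crc_death, dtype=bool)

    total = _dint(0.0, death_age, rate, ref)

    diagnosed = np.isfinite(dx_age) & (dx_age <= death_age)
    if np.any(diagnosed):
        if bool(dis.get("literal_zero_after_diagnosis", False)):
            total = total - np.where(diagnosed, _dint(dx_age, death_age, rate, ref), 0.0)
        else:
            care = dis["crc_care"]
            names = ("I", "II", "III", "IV")
            d_init = np.array([0.0] + [care["initial"][s] for s in names])[np.clip(stage, 0, 4)]
            d_cont = np.array([0.0] + [care["continuing"][s] for s in names])[np.clip(stage, 0, 4)]
            d_term = float(care["terminal"])
            end1 = np.minimum(dx_age + 1.0, death_age)
            loss = d_init * _dint(dx_age, end1, rate, ref) + d_cont * _dint(end1, death_age, rate, ref)
            # terminal year before a CRC death overrides the phase rate
            t0 = np.maximum(dx_age, death_age - 1.0)
            o1 = _dint(np.maximum(t0, dx_age), np.minimum(end1, death_age), rate, ref)
            o2 = _dint(np.maximum(t0, end1), death_age, rate, ref)
            term_extra = np.where(crc_death, (d_term - d_init) * o1 + (d_term - d_cont) * o2, 0.0)
            loss = loss + np.maximum(term_extra, -loss)
            total = total - np.where(diagnosed, loss, 0.0)

    total = total - (
        float(dis["fit"]) * np.asarray(dw_fit, dtype=float)
        + float(dis["colonoscopy"]) * np.asarray(dw_colo, dtype=float)
        + float(dis["complication"]) * np.asarray(dw_compl, dtype=float)
    )
    return total


def qalys_from_run(run: StrategyRun, params: ModelParams,
                   discount_rate: float | None = None) -> np.ndarray:
    crc_death = np.isfinite(run.crc_death_age) & (run.crc_death_age <= run.death_age + 1e-12)
    return individual_qalys(
        run.death_age, run.dx_age, run.dx_stage, crc_death,
        run.dw_fit, run.dw_colo, run.dw_compl, params, discount_rate=discount_rate,
    )


def eligibility_mask(baseline: StrategyRun, aggregation_age: float) -> np.ndarray:
    """Alive and without detected CRC at the aggregation start age, judged in
    the no-screening scenario (identical across strategies)."""
    no_prior_dx = ~(np.isfinite(baseline.dx_age) & (baseline.dx_age < aggregation_age))
    return (baseline.death_age > aggregation_age) & no_prior_dx


def aggregate(run: StrategyRun, baseline: StrategyRun, params: ModelParams,
              aggregation_age: float | None = None) -> CohortOutcome:
    """Per-1000 cohort outcome of ``run`` versus the no-screening ``baseline``.

    Both runs must come from the same cohort and natural-history randomness;
    colonoscopies include screening, surveillance and diagnostic exams.
    """
    if run.death_age.size != baseline.death_age.size:
        raise ValueError("strategy and baseline runs cover different cohorts")
    agg_age = float(run.start_age if aggregation_age is None else aggregation_age)
    elig = eligibility_mask(baseline, agg_age)
    n_elig = int(elig.sum())
    if n_elig == 0:
        raise ValueError("no eligible individuals at the aggregation age")
    scale = 1000.0 / n_elig

    q_run = qalys_from_run(run, params)
    q_base = qalys_from_run(baseline, params)
    crc_death = np.isfinite(run.crc_death_age) & (run.crc_death_age <= run.death_age + 1e-12)

    return CohortOutcome(
        strategy_label=run.spec.label,
        n_eligible=n_elig,
        colonoscopies_per_1000=float(run.n_colonoscopies[elig].sum() * scale),
        qalys_gained_per_1000=float((q_run[elig] - q_base[elig]).sum() * scale),
        crc_cases_per_1000=float((np.isfinite(run.dx_age) & elig).sum() * scale),
        crc_deaths_per_1000=float((crc_death & elig).sum() * scale),
        discount_rate_used=float(params.discount_rate),
    )


def percent_change(a: float, b: float) -> float:
    """100 x (a - b) / b, reported to one decimal."""
    if b == 0:
        raise ZeroDivisionError("reference value is zero")
    return round(100.0 * (a - b) / b, 1)
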