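"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: generate a cohort, simulate
natural histories once, execute the no-screening baseline and every requested
strategy under common random numbers, aggregate per-1000 outcomes, and run
the frontier analysis.  Scenarios map onto parameter/engine overrides:

* ``base_case`` — full adherence, undiscounted, screening ages 50-74;
* ``adherence_present`` — trial-based adherence mix (14% always-FIT, 14%
  always-colonoscopy, 50% never screen, 22% compliant);
* ``discounted`` — 3% annual QALY discounting from age 50;
* ``stop_age_variant:<fixed_70|fixed_72|fixed_76|delayed|early_delayed>``;
* ``uspstf`` — screening ages 45-75, outcomes aggregated from age 45.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import ModelParams, load_params
from .frontier import NEAR_EFFICIENCY_TOLERANCE, FrontierResult, find_frontier
from .natural_history import simulate_cohort_histories
from .outcomes import aggregate
from .population import generate_cohort
from .strategies import StrategySpec, enumerate_strategies, no_screening_spec, run_strategy

__all__ = ["ExperimentPlan", "run_experiment", "resolve_scenario", "build_strategy_set"]

PRESENT_ADHERENCE_MIX = {"always_fit": 0.14, "always_col": 0.14, "never": 0.50, "compliant": 0.22}

DESK_COHORT_SIZE = 200_000   # full-scale runs use millions; per-1000 outcomes are scale-invariant


@dataclass
class ExperimentPlan:
    cohort_size: int = DESK_COHORT_SIZE
    seed: int = 0
    strategy_set: tuple = ("reference",)     # families, labels, or StrategySpec objects
    scenario: str = "base_case"
    output_dir: str | None = None
    frontier_tolerance: float = NEAR_EFFICIENCY_TOLERANCE


def resolve_scenario(scenario: str, params: ModelParams) -> dict:
    """Map a scenario name to engine overrides."""
    stop = int(params.screening["stop_age"])
    base = {"adherence_mix": None, "discount_rate": None, "start_age": 50,
            "stop_age_policy": {"kind": "fixed", "age": stop}, "aggregation_age": None}
    if scenario == "base_case":
        return base
    if scenario == "adherence_present":
        return {**base, "adherence_mix": dict(PRESENT_ADHERENCE_MIX)}
    if scenario == "discounted":
        return {**base, "discount_rate": 0.03}
    if scenario.startswith("stop_age_variant:"):
        name = scenario.split(":", 1)[1]
        if name.startswith("fixed_"):
            return {**base, "stop_age_policy": {"kind": "fixed", "age": int(name.split("_")[1])}}
        if name == "delayed":
            return {**base, "stop_age_policy": {
                "kind": "distribution", "ages": [74, 76, 78], "weights": [1 / 3] * 3}}
        if name == "early_delayed":
            return {**base, "stop_age_policy": {
                "kind": "distribution", "ages": [70, 72, 74, 76, 78], "weights": [0.2] * 5}}
        raise ValueError(f"unknown stop-age variant {name!r}")
    if scenario == "uspstf":
        return {**base, "start_age": 45,
                "stop_age_policy": {"kind": "uspstf"}, "aggregation_age": 45.0}
    raise ValueError(f"unknown scenario {scenario!r}")


def build_strategy_set(strategy_set, params: ModelParams, start_age: int,
                       stop_age_policy: dict) -> list[StrategySpec]:
    """Expand a mix of family names, labels and StrategySpec objects."""
    families = ("age_based", "risk_score_based", "fit_based", "reference")
    by_label: dict[str, StrategySpec] = {}
    all_specs = None

    def ensure_all():
        nonlocal all_specs
        if all_specs is None:
            all_specs = {
                s.label: s
                for fam in families
                for s in enumerate_strategies(fam, params, start_age=start_age,
                                              stop_age_policy=stop_age_policy)
            }
        return all_specs

    for item in strategy_set:
        if isinstance(item, StrategySpec):
            by_label[item.label] = item
        elif item in families:
            for s in enumerate_strategies(item, params, start_age=start_age,
                                          stop_age_policy=stop_age_policy):
                by_label[s.label] = s
        else:
            pool = ensure_all()
            if item not in pool:
                raise KeyError(f"unknown strategy label or family {item!r}")
            by_label[item] = pool[item]
    return list(by_label.values())


def run_experiment(plan: ExperimentPlan, params: ModelParams | None = None
                   ) -> tuple[pd.DataFrame, FrontierResult]:
    """Run every strategy of the plan on one shared cohort; return the
    outcome table and frontier result (and write them when an output
    directory is set).  Fully reproducible from (plan, params)."""
    params = params if params is not None else load_params()
    ov = resolve_scenario(plan.scenario, params)
    if ov["discount_rate"] is not None:
        params = params.replace(discount_rate=float(ov["discount_rate"]))

    t0 = time.time()
    cohort = generate_cohort(plan.cohort_size, params, seed=plan.seed)
    nh = simulate_cohort_histories(cohort, params, seed=plan.seed)

    baseline_spec = no_screening_spec(start_age=ov["start_age"], stop_age_policy=ov["stop_age_policy"])
    baseline = run_strategy(baseline_spec, cohort, nh, params, seed=plan.seed,
                            adherence_mix=ov["adherence_mix"])

    specs = build_strategy_set(plan.strategy_set, params, ov["start_age"], ov["stop_age_policy"])
    rows, runtimes = [], {}
    for spec in specs:
        t = time.time()
        try:
            run = run_strategy(spec, cohort, nh, params, seed=plan.seed,
                               adherence_mix=ov["adherence_mix"])
            out = aggregate(run, baseline, params, aggregation_age=ov["aggregation_age"])
        except Exception as exc:  # annotate failures with the strategy label
            raise RuntimeError(f"strategy {spec.label!r} failed: {exc}") from exc
        runtimes[spec.label] = round(time.time() - t, 3)
        rows.append({
            "label": out.strategy_label,
            "family": spec.family,
            "n_eligible": out.n_eligible,
            "colonoscopies_per_1000": out.colonoscopies_per_1000,
            "qalys_gained_per_1000": out.qalys_gained_per_1000,
            "crc_cases_per_1000": out.crc_cases_per_1000,
            "crc_deaths_per_1000": out.crc_deaths_per_1000,
            "discount_rate_used": out.discount_rate_used,
        })
    outcomes = pd.DataFrame(rows)
    fr = find_frontier(outcomes["colonoscopies_per_1000"].to_numpy(),
                       outcomes["qalys_gained_per_1000"].to_numpy(),
                       tolerance=plan.frontier_tolerance)
    if plan.output_dir:
        outdir = Path(plan.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        outcomes.to_csv(outdir / "outcomes.csv", index=False)
        fr.to_frame(labels=outcomes["label"]).to_csv(outdir / "frontier.csv", index=False)
        manifest = {
            "seed": plan.seed,
            "cohort_size": plan.cohort_size,
            "scenario": plan.scenario,
            "params_fingerprint": params.fingerprint(),
            "n_strategies": len(specs),
            "strategy_runtimes_s": runtimes,
            "total_runtime_s": round(time.time() - t0, 3),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outcomes, fr
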