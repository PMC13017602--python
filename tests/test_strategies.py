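"""Strategy enumeration, schedules, switching semantics and engine invariants."""

import numpy as np
import pytest

import crc_screen_sim as cs
from crc_screen_sim.strategies import StrategySpec, scheduled_colonoscopy_ages


# -- enumeration and schedules ---------------------------------------------------


def test_family_counts(params):
    assert len(cs.enumerate_strategies("age_based", params)) == 12
    assert len(cs.enumerate_strategies("fit_based", params)) == 24
    refs = cs.enumerate_strategies("reference", params)
    assert sorted(s.reference_kind for s in refs) == ["col_only", "fifty_fifty", "fit_only"]
    risk = cs.enumerate_strategies("risk_score_based", params)
    assert len(risk) == 9 * len(params.risk_score_schedules)
    labels = [s.label for fam in ("age_based", "fit_based", "risk_score_based", "reference")
              for s in cs.enumerate_strategies(fam, params)]
    assert len(labels) == len(set(labels)), "labels must be unique"


@pytest.mark.parametrize(
    "transition, stop, expected",
    [(56, 74, [56, 66]), (54, 74, [54, 64, 74]), (66, 74, [66]), (74, 74, [74])],
)
def test_scheduled_colonoscopy_ages(transition, stop, expected):
    assert scheduled_colonoscopy_ages(transition, stop) == expected


def test_schedule_rejects_transition_after_stop():
    with pytest.raises(ValueError):
        scheduled_colonoscopy_ages(76, 74)


def test_spec_validation():
    with pytest.raises(ValueError):
        StrategySpec(family="age_based")  # missing transition age
    with pytest.raises(ValueError):
        StrategySpec(family="risk_score_based", assessment_ages=(64, 54), top_proportion=0.2)
    with pytest.raises(ValueError):
        StrategySpec(family="reference", reference_kind="bogus")
    assert StrategySpec(family="risk_score_based", assessment_ages=(54, 64, 74),
                        top_proportion=0.2).label == "20%_54:64:74"


# -- stop ages and adherence -----------------------------------------------------


def test_resolve_stop_age_policies():
    start, stops = cs.resolve_stop_age({"kind": "fixed", "age": 74}, 100, seed=1)
    assert start == 50 and (stops == 74).all()
    start, stops = cs.resolve_stop_age({"kind": "uspstf"}, 10, seed=1)
    assert (start, int(stops[0])) == (45, 75) and (stops == 75).all()
    n = 60_000
    _, stops = cs.resolve_stop_age(
        {"kind": "distribution", "ages": [74, 76, 78], "weights": [1 / 3] * 3}, n, seed=1)
    for age in (74, 76, 78):
        frac = (stops == age).mean()
        assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)


def test_adherence_assignment_fractions():
    n = 100_000
    mix = {"always_fit": 0.14, "always_col": 0.14, "never": 0.50, "compliant": 0.22}
    codes = cs.apply_adherence_scenario(n, mix, seed=1)
    fracs = np.bincount(codes, minlength=4) / n
    for code, key in ((0, "compliant"), (1, "always_fit"), (2, "always_col"), (3, "never")):
        assert abs(fracs[code] - mix[key]) < 0.01
    with pytest.raises(ValueError):
        cs.apply_adherence_scenario(10, {"compliant": 0.5}, seed=1)
    assert (cs.apply_adherence_scenario(10, None, seed=1) == 0).all()


# -- risk threshold ---------------------------------------------------------------


def test_risk_threshold_quantile_definition(params, small_world):
    """With pooled scores {s_1..s_n} and top proportion p, exactly ~p of the
    pooled scores lie at or above the threshold."""
    spec = StrategySpec(family="risk_score_based", assessment_ages=(54, 64, 74),
                        top_proportion=0.2)
    thr = cs.compute_risk_threshold(spec, small_world["cohort"], small_world["nh"],
                                    params, seed=small_world["seed"])
    run = cs.run_strategy(spec, small_world["cohort"], small_world["nh"], params,
                          seed=small_world["seed"])
    assert run.risk_threshold == pytest.approx(thr)
    assert 0.0 < thr < 1.0
    # an explicit numeric check of the quantile rule
    pooled = np.arange(1, 11, dtype=float)
    t = np.quantile(pooled, 1 - 0.2)
    assert (pooled >= t).mean() == pytest.approx(0.2)


def test_high_risk_switchers_are_predominantly_old(params, small_world):
    """Because the score rises steeply with age, switchers under a pooled
    threshold come mostly from the oldest assessment age."""
    spec = StrategySpec(family="risk_score_based", assessment_ages=(54, 64, 74),
                        top_proportion=0.2)
    run = cs.run_strategy(spec, small_world["cohort"], small_world["nh"], params,
                          seed=small_world["seed"], collect_events=True)
    switches = run.events.query("event == 'switch'")
    assert len(switches) > 0
    assert (switches["age"] == 74).mean() > 0.5


# -- engine semantics -------------------------------------------------------------


@pytest.fixture(scope="module")
def age56_run(params, small_world):
    return cs.run_strategy(StrategySpec(family="age_based", transition_age=56),
                           small_world["cohort"], small_world["nh"], params,
                           seed=small_world["seed"], collect_events=True)


def test_age_based_56_schedule(age56_run):
    """Transition at 56 means FIT at 50/52/54 and colonoscopy at 56/66 for
    anyone who stays event-free."""
    ev = age56_run.events
    fit_ages = set(ev.query("event == 'fit'")["age"].unique())
    assert fit_ages == {50.0, 52.0, 54.0}
    # the scheduled 56/66 exams apply to anyone without an earlier diagnostic
    # colonoscopy (a positive FIT moves its person to a decennial grid of
    # their own, anchored at the diagnostic exam)
    dx_people = set(ev.query("event == 'colonoscopy_dx'")["id"])
    screen = ev.query("event == 'colonoscopy_screen'")
    screen_ages = set(screen[~screen["id"].isin(dx_people)]["age"].unique())
    assert screen_ages == {56.0, 66.0}
    # at least one individual follows the full uninterrupted schedule
    tests_only = ev[ev["event"].isin(["fit", "colonoscopy_screen", "colonoscopy_dx",
                                      "colonoscopy_surv"])]
    per_person = tests_only.groupby("id").agg(events=("event", list), ages=("age", list))
    full = [
        (e, a) for e, a in zip(per_person["events"], per_person["ages"])
        if e == ["fit", "fit", "fit", "colonoscopy_screen", "colonoscopy_screen"]
        and a == [50.0, 52.0, 54.0, 56.0, 66.0]
    ]
    assert full, "expected someone with the canonical FIT 50/52/54 + colonoscopy 56/66 path"


def test_col_only_examines_at_50_60_70(params, small_world):
    run = cs.run_strategy(StrategySpec(family="reference", reference_kind="col_only"),
                          small_world["cohort"], small_world["nh"], params,
                          seed=small_world["seed"], collect_events=True)
    screen_ages = set(run.events.query("event == 'colonoscopy_screen'")["age"].unique())
    assert screen_ages == {50.0, 60.0, 70.0}
    assert run.events.query("event == 'fit'").empty


def test_fit10_66_switch_semantics(params, small_world):
    """FIT10 with transition 66: an elevated-but-negative FIT at age x < 66
    leads to colonoscopy at x+2 (e.g. 58 -> 60); those never elevated before
    66 start colonoscopy at 66."""
    spec = StrategySpec(family="fit_based", elevated_band_lower=10.0, transition_age=66)
    run = cs.run_strategy(spec, small_world["cohort"], small_world["nh"], params,
                          seed=small_world["seed"], collect_events=True)
    ev = run.events
    hb = ev.query("event == 'fit'").copy()
    hb["value"] = hb["detail"].astype(float)
    first_elev, first_pos = {}, {}
    for pid, g in hb.groupby("id"):
        g = g.sort_values("age")
        e = g[(g["value"] >= 10.0) & (g["value"] < 15.0)]
        p = g[g["value"] >= 15.0]
        if len(e):
            first_elev[pid] = float(e["age"].iloc[0])
        if len(p):
            first_pos[pid] = float(p["age"].iloc[0])
    colo = ev[ev["event"].str.startswith("colonoscopy")]
    first_colo = colo.groupby("id")["age"].min()

    checked_58 = 0
    for pid, a_elev in first_elev.items():
        a_pos = first_pos.get(pid, np.inf)
        if a_pos < a_elev:
            continue  # a positive FIT intervened first
        if pid in first_colo.index:
            assert first_colo[pid] == a_elev + 2.0, pid
            if a_elev == 58.0:
                checked_58 += 1
    assert checked_58 > 0, "no one with first elevated FIT at 58 reached colonoscopy at 60"

    never_flagged = [
        pid for pid in first_colo.index
        if pid not in first_elev and pid not in first_pos
    ]
    assert never_flagged and all(first_colo[p] == 66.0 for p in never_flagged)


def test_event_log_invariants(params, small_world, age56_run):
    """No screening event after death, diagnosis or the stop age (except
    surveillance up to 86); no FIT ever after a colonoscopy."""
    run = age56_run
    ev = run.events
    death = run.death_age
    for _, row in ev.iterrows():
        pid, age, event = int(row["id"]), row["age"], row["event"]
        if event in ("fit", "colonoscopy_screen", "colonoscopy_dx", "colonoscopy_surv", "switch"):
            assert age <= death[pid] + 1e-9
        if event in ("fit", "colonoscopy_screen"):
            assert age <= run.stop_age[pid]
            assert age >= run.start_age
        if event == "colonoscopy_surv":
            assert age <= params.surveillance_policy["terminal_age"]
    first_colo = (ev[ev["event"].str.startswith("colonoscopy")]
                  .groupby("id")["age"].min())
    for pid, g in ev.query("event == 'fit'").groupby("id"):
        if pid in first_colo.index:
            assert (g["age"] <= first_colo[pid]).all(), "FIT after a colonoscopy"


# -- equivalences under common random numbers ------------------------------------


def _outcome_fields(run):
    return (run.n_colonoscopies, run.n_fit, run.death_age, run.dx_age, run.dx_stage)


def test_age_based_equals_col_only_at_start_age(params, small_world):
    a = cs.run_strategy(StrategySpec(family="age_based", transition_age=50),
                        small_world["cohort"], small_world["nh"], params, seed=3)
    b = cs.run_strategy(StrategySpec(family="reference", reference_kind="col_only"),
                        small_world["cohort"], small_world["nh"], params, seed=3)
    for x, y in zip(_outcome_fields(a), _outcome_fields(b)):
        assert np.array_equal(x, y, equal_nan=True)


def test_age_based_beyond_stop_equals_fit_only(params, small_world):
    a = cs.run_strategy(StrategySpec(family="age_based", transition_age=74,
                                     stop_age_policy={"kind": "fixed", "age": 72}),
                        small_world["cohort"], small_world["nh"], params, seed=3)
    b = cs.run_strategy(StrategySpec(family="reference", reference_kind="fit_only",
                                     stop_age_policy={"kind": "fixed", "age": 72}),
                        small_world["cohort"], small_world["nh"], params, seed=3)
    for x, y in zip(_outcome_fields(a), _outcome_fields(b)):
        assert np.array_equal(x, y, equal_nan=True)


def test_risk_based_full_proportion_equals_age_based(params, small_world):
    a = cs.run_strategy(StrategySpec(family="risk_score_based", assessment_ages=(64,),
                                     top_proportion=1.0),
                        small_world["cohort"], small_world["nh"], params, seed=3)
    b = cs.run_strategy(StrategySpec(family="age_based", transition_age=64),
                        small_world["cohort"], small_world["nh"], params, seed=3)
    for x, y in zip(_outcome_fields(a), _outcome_fields(b)):
        assert np.array_equal(x, y, equal_nan=True)


def test_colonoscopies_nondecreasing_in_top_proportion(params, small_world):
    totals = []
    for p100 in (20, 50, 80):
        run = cs.run_strategy(
            StrategySpec(family="risk_score_based", assessment_ages=(54, 64, 74),
                         top_proportion=p100 / 100),
            small_world["cohort"], small_world["nh"], params, seed=3)
        totals.append(int(run.n_colonoscopies.sum()))
    assert totals[0] <= totals[1] <= totals[2]


def test_never_adherent_population_equals_no_screening(params, small_world):
    run = cs.run_strategy(StrategySpec(family="reference", reference_kind="col_only"),
                          small_world["cohort"], small_world["nh"], params, seed=3,
                          adherence_mix={"never": 1.0})
    base = small_world["baseline"]
    assert np.array_equal(run.death_age, base.death_age, equal_nan=True)
    assert np.array_equal(run.dx_age, base.dx_age, equal_nan=True)
    assert int(run.n_colo_screen.sum()) == 0 and int(run.n_fit.sum()) == 0
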