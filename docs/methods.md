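# Methods

This note documents the model, its parameters, the synthetic calibration,
and the design choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Natural history

Each individual is simulated from birth to death.

**Other-cause mortality.** Death from causes other than CRC is scheduled at
the start of the simulation by inverse transform from a per-sex life table
(yearly probabilities, ages 0–100; the terminal year is absorbing). The
packaged table is Gompertz–Makeham-shaped with life expectancy ≈ 78 y
(male) / 84 y (female).

**Adenoma onset.** Lesions arise from a nonhomogeneous Poisson process with
rate `baseline(age) × frailty`. The baseline is piecewise constant
(default: 0 below 40, then 0.004 / 0.009 / 0.014 / 0.028 lesions per
person-year on 40–50 / 50–60 / 60–70 / 70+). Frailty is gamma with mean 1
and variance 1.2 (a configurable point mass at zero — never-developers — is
available and defaults to 0), linked to the risk-score linear predictor at
age 50 through a Gaussian copula with latent correlation 0.4. The measured
Spearman correlation between score and frailty is slightly below the latent
value (≈ 0.385 for 0.4), a standard property of the copula construction;
the test tolerance (±0.05) covers it.

**Growth and progression.** Each lesion advances
small → medium → large adenoma with independent exponential dwell times
(defaults 22 / 9 / 7 years), then enters preclinical CRC stage I. Each
preclinical stage competes exponentially between progressing to the next
stage (means 2.5 / 2.5 / 2.0 y for I–III) and surfacing clinically (means
12 / 6 / 3 / 1.5 y for I–IV). The sojourn time — preclinical onset to
clinical surfacing — averages ≈ 4 years. Most adenomas never progress
within a lifetime; multiple lesions per person are independent given
frailty, and the earliest clinically surfacing lesion defines the
diagnosis (other lesions are censored at diagnosis).

**Survival after diagnosis.** An exponential-mixture cure model: cure
probability by stage (0.90 / 0.75 / 0.50 / 0.08 for I–IV) multiplied by an
age-group factor (1.0 / 0.95 / 0.85 for <60 / 60–75 / 75+) and a proximal
location factor (0.95); non-cured survival is exponential with
stage-specific mean (7 / 5 / 3 / 1.3 y). Screen-detected cancers draw
survival at the stage at detection with the same per-person uniforms, so
earlier detection can only improve the draw.

### Calibration

The default calibration is **synthetic**: no registry or survey data enter
the package. Its behaviour is pinned by target bands checked by
`calibration_summary` on an unscreened cohort (lifetime to age 90):
adenoma prevalence 30–45%, CRC incidence 3–6%, CRC mortality 1–3%, mean
sojourn 3–7 years. Within those bands the onset and dwell defaults were
chosen so the model also expresses the mechanism that drives the policy
comparison: onset concentrated at older ages and moderately fast
progression mean that ending colonoscopy coverage years before the
screening stop age forfeits real protection — the property that makes the
timing of the *final* colonoscopy the decisive feature of a strategy. A
slow-dwell calibration can satisfy the same bands while erasing that
gradient (post-exam onsets never surface within a lifetime), which would
make all transition ages equivalent up to noise.

## Screening tests

**Quantitative FIT.** Hemoglobin is lognormal per lesion state (none /
small / medium / large adenoma / preclinical CRC) with a common shape
(σ_log = 1.2) and state scales solved in closed form so that
P(Hb ≥ 15 µg/g | state) equals the configured operating characteristic
(defaults 0.035 / 0.05 / 0.09 / 0.28 / 0.75; the first is 1 − specificity).
A continuous concentration is required because the FIT-based strategies act
on sub-cut-off bands (5–15, 10–15 µg/g) that sensitivity/specificity pairs
alone do not define. Successive FITs are conditionally independent given
state; an optional per-person multiplicative random effect
(`individual_effect_sd`) introduces within-person tracking and defaults to
off.

**Colonoscopy.** Each lesion present is detected independently with
stage-class sensitivity (0.65 / 0.85 / 0.95 for adenoma sizes, 0.95 for
preclinical CRC). Detected adenomas are removed (their future progression
is cancelled; other lesions are untouched). Detected preclinical CRC
becomes a screen-detected diagnosis at the exam age. Each procedure draws a
complication (probability 0.002, disutility 0.05 QALY, case fatality 0.02
given complication; a fatal complication ends life at the exam age).
Misses are independent across exams.

## Strategy engine

All strategies share: biennial FIT for the low-risk, immediate diagnostic
colonoscopy after a positive FIT (≥ 15 µg/g), 10-yearly colonoscopy for the
high-risk, screening from age 50 to 74 in the base case, and **no return to
FIT after any colonoscopy**. Adenoma findings trigger surveillance
(advanced findings — any large adenoma or ≥ 3 adenomas — at 3-year
intervals, non-advanced at 5-year) continuing past the stop age until 86; a
clear surveillance exam returns the person to their decennial screening
grid *anchored at their last screening/diagnostic colonoscopy* while within
screening ages (so a findings-free colonoscopy-only participant is examined
at exactly 50/60/70). Detected CRC ends screening.

Risk-score strategies use a two-pass threshold: pass 1 replays the strategy
with nobody switching and pools the scores of every assessment performed on
individuals alive, CRC-free, not under surveillance and still
FIT-screening; the threshold is the (1 − p) quantile of the pool; pass 2
switches at the first assessment at or above it. With a single assessment
and p = 1 this reproduces the age-based strategy exactly.

**Common random numbers.** Natural histories are drawn once per cohort and
shared by every strategy. Screening randomness is pre-drawn as per-person /
per-event-index uniform tables (FIT quantile by FIT count, lesion detection
by exposure count, complications by colonoscopy count), so two strategies
agree on every random outcome up to their first divergent event. Outcome
differences between strategies are therefore structural, not sampling
noise, and the equivalences above hold bit-for-bit.

**Adherence.** The trial-based sensitivity scenario assigns, independently
of risk: 14% always choose FIT (strategy switch rules ignored), 14% always
choose colonoscopy, 50% never screen (diagnostic care retained), 22%
comply. Always-FIT participants who test positive still receive the
diagnostic colonoscopy and, per the universal rule, do not return to FIT.

**Stop ages.** Fixed (70 / 72 / 74 / 76), delayed (thirds at 74/76/78),
early-and-delayed (fifths at 70–78), or ages 45–75 with aggregation from
45; per-person stop ages are drawn independently of risk.

## Outcomes

Utility is 1 per life-year without a CRC diagnosis. After diagnosis, years
accrue 1 minus a stage-specific care disutility by phase: initial year
(0.12–0.40), continuing (0.03–0.30), and the terminal year before a CRC
death (0.55). A config switch (`literal_zero_after_diagnosis`) zeroes
post-diagnosis utility instead; it is off by default because it would
penalize early detection through lead time alone. Per-event disutilities:
FIT 0.001, colonoscopy 0.005, complication 0.05. All disutility values are
synthetic placeholders in plausible ranges.

Discounting (off in the base case, 3% in the sensitivity scenario) weights
a utility increment at age *a* by (1 + r)^−(a − 50); years and events
before the reference age are neither discounted nor inflated. Utility is
integrated exactly between event ages (no cycle discretization).

Aggregation: individuals alive and without detected CRC at age 50 (45 for
the 45–75 variant) *in the no-screening scenario* form the denominator —
identical across strategies, so rankings are unaffected by the choice.
Colonoscopies count screening, surveillance, diagnostic (positive-FIT
workup) and clinical-diagnosis workup exams. QALYs gained are per-person
differences against no screening on the same histories, summed over the
eligible and scaled per 1000.

## Frontier

The efficiency frontier is the upper-left concave hull of the strategy
points, computed by a monotone chain that retains collinear vertices.
Dominance: another point with ≤ colonoscopies and ≥ QALYs, one strict; at
equal colonoscopy demand only the higher-QALY point can be a hull
candidate. Near-efficiency: vertical distance to the interpolated hull
≤ 0.125 QALYs per 1000 (1.5 quality-adjusted months), constant beyond the
last vertex. The efficiency *labels* use the strict hull; the tolerance
only widens the reported near-efficient band — on the packaged published
table the strict hull reproduces the printed efficiency column exactly,
including a borderline point ~0.008 QALYs below the hull chord.

## Problem sizes and numerical choices

Engine-level property checks run on cohorts of 200 000 individuals (the
package's desk scale; per-1000 outcomes are scale-invariant in
expectation, and the vectorized engine executes a strategy on 200 000
people in under a second). Statistical oracles use 100 000 draws with 3
binomial-SE tolerances; FIT band masses are verified against quadrature at
1e-6. Event ages are integers by construction (biennial/decennial/
surveillance intervals on integer start ages), so schedule comparisons are
exact; clinical events occur in continuous time and are settled before
each integer age. Ties at measure-zero ages (an exam exactly at a clinical
surfacing age) resolve in favour of the clinical event at the next settle.

## Known limitations

* Test characteristics, disutilities, complication and adherence rates do
  not depend on age or calendar time.
* No serrated pathway; lesion location enters only as a proximal/distal
  survival shift; no bowel-preparation quality or correlated per-person
  colonoscopy misses.
* No health-care costs — outputs are demand/benefit pairs, not
  cost-effectiveness ratios.
* The synthetic calibration reproduces band-level epidemiology and the
  structural mechanisms above, not any specific population's registry
  values; absolute QALY and colonoscopy levels should be read
  comparatively, not as forecasts.
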