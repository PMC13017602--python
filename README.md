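# crc-screen-sim

Microsimulation of **risk-based guidance between fecal immunochemical
testing (FIT) and colonoscopy** in colorectal cancer (CRC) screening.

Screening programs in Switzerland, Germany and the United States let
participants choose between biennial quantitative FIT and 10-yearly
colonoscopy. Because colonoscopy capacity is scarce, a natural policy
question is *who* should be guided toward colonoscopy, and *when*. This
package simulates individual adenoma–carcinoma natural histories and
executes three families of switching strategies on identical simulated
populations:

* **age-based** — everyone starts biennial FIT at 50 and switches to
  10-yearly colonoscopy at a fixed transition age (52, 54, …, 74);
* **risk-score-based** — a QCancer-like 15-year CRC risk score (age, sex,
  BMI, smoking, alcohol) is assessed at fixed ages; the top *p*% of pooled
  assessed scores switch to colonoscopy (`20%_54:64:74` means assessments at
  54/64/74 with the top 20% switching);
* **FIT-based** — an "elevated but negative" quantitative FIT result
  (hemoglobin in [5,15) or [10,15) µg/g, below the 15 µg/g positivity
  cut-off) triggers the switch at the next due screen two years later,
  optionally backstopped by a fixed transition age.

Reference strategies are FIT-only, colonoscopy-only (exams at 50/60/70), a
50/50 free-choice split, and no screening. For every strategy the package
accounts **QALYs gained and colonoscopies required per 1000 individuals
alive and CRC-free at age 50** versus no screening on the same simulated
histories (common random numbers), then identifies **efficient strategies**
— the upper-left convex hull in (colonoscopy demand, QALYs gained) space —
and near-efficient ones within 1.5 quality-adjusted months (0.125 QALYs per
1000) of the interpolated hull.

The natural-history engine is a semi-Markov individual-level model:
adenomas arise from a nonhomogeneous Poisson process (age-dependent
baseline × gamma frailty correlated with the risk score), grow through
three size classes with exponential dwell times, progress through
preclinical stages I–IV in competition with clinical surfacing, and draw
stage/age/location-specific survival from an exponential-mixture cure
model. Quantitative FIT is a per-state lognormal hemoglobin concentration
calibrated to configured operating characteristics at the 15 µg/g cut-off;
colonoscopy detects lesions with stage-specific sensitivity, removes
adenomas, and carries a small complication risk. The packaged default
calibration is **synthetic** (documented target bands; no registry fit) —
absolute outcome levels are therefore illustrative, while the structural
comparisons between strategies are the object of study.

## Worked example

```python
import crc_screen_sim as cs
from crc_screen_sim.pipeline import ExperimentPlan, run_experiment

plan = ExperimentPlan(cohort_size=50_000, seed=1,
                      strategy_set=("reference", "age_54", "age_64", "age_74"))
outcomes, frontier = run_experiment(plan, cs.load_params())
print(outcomes[["label", "colonoscopies_per_1000", "qalys_gained_per_1000"]]
      .round(1).to_string(index=False))
```

prints (seed 1, 50 000 individuals, default synthetic calibration):

```
   label  colonoscopies_per_1000  qalys_gained_per_1000
FIT_only                   798.4                  198.7
COL_only                  2958.1                  255.2
   50/50                  1876.6                  230.9
  age_54                  2863.6                  273.6
  age_64                  1982.0                  254.2
  age_74                  1296.8                  232.1
```

Reading: FIT-only needs by far the fewest colonoscopies but gains the
fewest QALYs. Colonoscopy-only is *not* efficient — its last exam falls at
age 70, four years before screening cessation, while the age-based
strategies place the final colonoscopy at 74. Switching at 64 gains
essentially the same QALYs as colonoscopy-only with a third fewer
colonoscopies; `frontier.near_efficient` flags FIT-only and the three
age-based strategies, but neither reference hybrid. Scenario variants
(`adherence_present`, `discounted`, `stop_age_variant:*`, `uspstf`) apply
the corresponding sensitivity analyses.

A CLI mirrors the library:

```bash
crc-screen-sim validate-config src/crc_screen_sim/data/default_params.yaml
crc-screen-sim enumerate --family fit_based
crc-screen-sim simulate --strategies reference --n 20000 --seed 1 --out out/
crc-screen-sim frontier --outcomes out/outcomes.csv --out out/frontier.csv
```

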