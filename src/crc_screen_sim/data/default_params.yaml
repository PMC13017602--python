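# Default SYNTHETIC "Swiss-like" calibration for crc-screen-sim.
#
# Nothing in this file is fitted to registry data: every value is a synthetic
# stand-in chosen so that the unscreened natural-history model lands inside
# the calibration target bands below (checked by
# natural_history.calibration_summary):
#   lifetime (to age 90, no screening) adenoma prevalence   30-45%
#   lifetime CRC incidence                                   3-6%
#   mean preclinical sojourn time                            3-7 years
#   lifetime CRC mortality                                   1-3%
# Test characteristics, disutilities and complication rates are likewise
# synthetic placeholders in plausible literature ranges, not published values.

meta:
  name: synthetic-swiss-like
  synthetic: true
  version: 1

life_table:
  terminal_age: 100
  # per-year probability of other-cause death, ages 0..100 (Gompertz-Makeham
  # shaped; synthetic, life expectancy ~78 y male / ~84 y female)
  male: [
    0.004, 0.000644, 0.000648, 0.000653, 0.000658, 0.000663, 0.000669, 0.000676,
    0.000684, 0.000692, 0.0007, 0.00071, 0.000721, 0.000732, 0.000745, 0.000759,
    0.000774, 0.000791, 0.00081, 0.00083, 0.000852, 0.000876, 0.000903, 0.000932,
    0.000964, 0.000999, 0.001037, 0.00108, 0.001126, 0.001176, 0.001232, 0.001293,
    0.00136, 0.001433, 0.001513, 0.001601, 0.001698, 0.001803, 0.001919, 0.002046,
    0.002186, 0.002339, 0.002506, 0.00269, 0.002891, 0.003112, 0.003354, 0.00362,
    0.003911, 0.00423, 0.004579, 0.004963, 0.005383, 0.005844, 0.00635, 0.006904,
    0.007511, 0.008177, 0.008907, 0.009708, 0.010585, 0.011548, 0.012603, 0.013759,
    0.015027, 0.016418, 0.017942, 0.019613, 0.021445, 0.023454, 0.025656, 0.028071,
    0.030718, 0.03362, 0.036802, 0.040291, 0.044116, 0.048309, 0.052907, 0.057947,
    0.063473, 0.069532, 0.076175, 0.083458, 0.091442, 0.100196, 0.109794, 0.120316,
    0.131853, 0.144501, 0.158368, 0.173571, 0.190239, 0.208514, 0.22855, 0.250516,
    0.274599, 0.301003, 0.329951, 0.361689, 1.0
  ]
  female: [
    0.0035, 0.000424, 0.000427, 0.000429, 0.000432, 0.000435, 0.000439, 0.000442,
    0.000447, 0.000451, 0.000456, 0.000462, 0.000468, 0.000475, 0.000482, 0.00049,
    0.000499, 0.000509, 0.000519, 0.000531, 0.000544, 0.000558, 0.000574, 0.000591,
    0.00061, 0.000631, 0.000653, 0.000678, 0.000706, 0.000736, 0.000769, 0.000805,
    0.000845, 0.000889, 0.000938, 0.000991, 0.001049, 0.001113, 0.001183, 0.00126,
    0.001345, 0.001438, 0.00154, 0.001653, 0.001776, 0.001912, 0.002061, 0.002224,
    0.002404, 0.002602, 0.002819, 0.003057, 0.003319, 0.003607, 0.003923, 0.00427,
    0.004652, 0.005071, 0.005531, 0.006037, 0.006592, 0.007202, 0.007873, 0.008609,
    0.009419, 0.010307, 0.011284, 0.012357, 0.013535, 0.01483, 0.016252, 0.017814,
    0.019531, 0.021416, 0.023487, 0.025763, 0.028263, 0.031009, 0.034026, 0.03734,
    0.04098, 0.04498, 0.049374, 0.054201, 0.059503, 0.065329, 0.071728, 0.078758,
    0.086481, 0.094965, 0.104285, 0.114524, 0.125772, 0.138129, 0.151703, 0.166616,
    0.182998, 0.200995, 0.220765, 0.242485, 1.0
  ]

population:
  sex_male_fraction: 0.5
  covariates:
    bmi:
      # lognormal body-mass index (kg/m^2) per sex
      male: {mu_log: 3.23, sigma_log: 0.13}
      female: {mu_log: 3.18, sigma_log: 0.16}
    smoking:
      # probabilities for (never, former, current)
      male: [0.45, 0.30, 0.25]
      female: [0.55, 0.25, 0.20]
    alcohol:
      # ordinal consumption categories 0..3 (none/light/moderate/heavy)
      male: [0.25, 0.35, 0.30, 0.10]
      female: [0.40, 0.35, 0.20, 0.05]
  risk_score:
    # QCancer-like 15-year CRC risk: logistic in a log-linear predictor.
    # Coefficients are synthetic but sign-correct (risk rises with age, BMI,
    # smoking, alcohol and is higher in males).
    horizon_years: 15
    intercept: -4.0
    age_reference: 60.0
    age_per_year: 0.09
    male: 0.35
    bmi_reference: 25.0
    bmi_per_unit: 0.02
    smoking: {never: 0.0, former: 0.15, current: 0.35}
    alcohol_per_level: 0.10
  frailty:
    # gamma multiplicative factor on adenoma onset, mean 1
    variance: 1.2
    zero_fraction: 0.0       # optional point mass of never-developers
    score_correlation: 0.4   # latent Gaussian-copula correlation with the risk score

adenoma_onset:
  # piecewise-constant baseline onset rate (lesions per person-year) on
  # [age_breaks[i], age_breaks[i+1])
  age_breaks: [0, 40, 50, 60, 70, 100]
  rates: [0.0, 0.004, 0.009, 0.014, 0.028]

lesion_progression:
  # exponential dwell-time means (years) between adenoma stages
  mean_years:
    small_to_medium: 22.0
    medium_to_large: 9.0
    large_to_preclinical: 7.0
  proximal_fraction: 0.4

sojourn:
  # preclinical CRC: competing exponential progression vs clinical surfacing
  progression_mean_years: {I: 2.5, II: 2.5, III: 2.0}
  clinical_mean_years: {I: 12.0, II: 6.0, III: 3.0, IV: 1.5}

crc_survival:
  # exponential-mixture cure model by stage; age and location shift the mixture
  cure_probability: {I: 0.90, II: 0.75, III: 0.50, IV: 0.08}
  mean_survival_years: {I: 7.0, II: 5.0, III: 3.0, IV: 1.3}
  age_breaks: [0, 60, 75, 120]        # age groups at diagnosis
  age_cure_factor: [1.0, 0.95, 0.85]  # multiplies cure probability per age group
  proximal_cure_factor: 0.95

fit_characteristics:
  cutoff: 15.0                   # ug Hb / g feces, positivity threshold
  elevated_lower_bounds: [5.0, 10.0]
  sigma_log: 1.2                 # common lognormal shape for all states
  # P(hemoglobin >= cutoff | state); 'none' is 1 - specificity. Synthetic
  # values in literature ranges.
  positive_probability:
    none: 0.035
    adenoma_small: 0.05
    adenoma_medium: 0.09
    adenoma_large: 0.28
    preclinical_crc: 0.75
  individual_effect_sd: 0.0      # optional within-person random effect (log scale)

colonoscopy_characteristics:
  sensitivity:
    adenoma_small: 0.65
    adenoma_medium: 0.85
    adenoma_large: 0.95
    preclinical_crc: 0.95
  complication_probability: 0.002
  complication_case_fatality: 0.02

disutilities:
  # QALY decrements; per-event for tests, per-year rates for CRC care phases.
  # Synthetic placeholders.
  fit: 0.001
  colonoscopy: 0.005
  complication: 0.05
  crc_care:
    initial: {I: 0.12, II: 0.18, III: 0.24, IV: 0.40}     # first year after diagnosis
    continuing: {I: 0.03, II: 0.05, III: 0.08, IV: 0.30}  # later years
    terminal: 0.55                                          # last year before CRC death
  literal_zero_after_diagnosis: false

surveillance_policy:
  advanced_interval_years: 3
  nonadvanced_interval_years: 5
  advanced_min_count: 3          # >= this many adenomas counts as advanced findings
  terminal_age: 86

screening:
  start_age: 50
  stop_age: 74
  allowed_stop_ages: [70, 72, 74, 76, 78]
  fit_interval_years: 2
  colonoscopy_interval_years: 10

discount_rate: 0.0
qaly_reference_age: 50.0

calibration_targets:
  adenoma_prevalence: [0.30, 0.45]
  lifetime_crc_incidence: [0.03, 0.06]
  mean_sojourn_years: [3.0, 7.0]
  lifetime_crc_mortality: [0.01, 0.03]

risk_score_schedules:
  # default assessment-age schedules: 10-year-spaced schedules on 52..74
  # plus the short late-life schedules 70:72:74 and 72:74
  - [52]
  - [54]
  - [56]
  - [58]
  - [60]
  - [62]
  - [64]
  - [66]
  - [68]
  - [70]
  - [72]
  - [74]
  - [52, 62]
  - [54, 64]
  - [56, 66]
  - [58, 68]
  - [60, 70]
  - [62, 72]
  - [64, 74]
  - [52, 62, 72]
  - [54, 64, 74]
  - [70, 72, 74]
  - [72, 74]
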