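# Default study configuration: adult occupational inhalation exposure
# factors, phthalate toxicity values, and the per-compound concentration
# summary targets (industrial n = 16, administrative n = 6) that the
# synthetic-data generator reproduces.
exposure_factors:
  male:
    ir: 19.02          # inhalation rate, m3/day
    bw: 62.7           # body weight, kg
    ef: 261            # exposure frequency, days/year
    ed: 24             # exposure duration, years
    at_noncancer: 8760 # 24 y x 365 d
    at_cancer: 25550   # 70 y x 365 d
    cf: 1.0e-3         # ug -> mg
  female:
    ir: 14.7
    bw: 54.4
    ef: 261
    ed: 24
    at_noncancer: 8760
    at_cancer: 25550
    cf: 1.0e-3

toxicity:
  DMP:
    rfc_air: 0.05      # inhalation reference concentration, mg/m3
    carcinogenic: false
  DEP:
    rfc_air: 2.8
    carcinogenic: false
  DBP:
    rfc_air: 0.02
    carcinogenic: false
  DEHP:
    rfc_air: 0.07
    carcinogenic: true
    slope_factor: 0.014  # (mg/kg-day)^-1

# Per-compound concentration summary targets (ug/m3).
concentration_targets:
  industrial:
    n_samples: 16
    compounds:
      DMP:  {mean: 485.79,  median: 278.05, sd: 496.07,  min: 28.0, max: 1583.0}
      DEP:  {mean: 807.38,  median: 627.65, sd: 738.43,  min: 25.0, max: 2153.0}
      DBP:  {mean: 849.62,  median: 476.40, sd: 936.76,  min: 18.0, max: 2514.0}
      DEHP: {mean: 1268.08, median: 708.25, sd: 1343.53, min: 37.0, max: 3544.0}
  administrative:
    n_samples: 6
    compounds:
      DMP:  {mean: 49.83, median: 51.50, sd: 17.85, min: 28.0, max: 73.0}
      DEP:  {mean: 30.17, median: 28.00, sd: 9.85,  min: 18.0, max: 45.0}
      DBP:  {mean: 37.50, median: 36.50, sd: 9.65,  min: 25.0, max: 52.0}
      DEHP: {mean: 45.50, median: 47.50, sd: 6.98,  min: 37.0, max: 53.0}

# Target Spearman rank correlations between compounds (industrial section).
# DEP pairs are not reported by the source monitoring campaign; the 0.3
# defaults are an invented, weakly-positive stand-in.
rank_correlations:
  - [DMP, DBP, 0.762]
  - [DMP, DEHP, 0.606]
  - [DBP, DEHP, 0.471]
  - [DMP, DEP, 0.3]
  - [DEP, DBP, 0.3]
  - [DEP, DEHP, 0.3]

monte_carlo:
  n_trials: 100000
  seed: 20240725
  baseline: 1.0e-6
  percentiles: [15, 25, 50, 75, 90]
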