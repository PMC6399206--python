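"""Frozen recovery thresholds, fixed by pre-build Monte-Carlo oracle runs.

Each constant was set from independent oracle simulations run before the
test suite was frozen, with a safety margin below the observed minimum over
oracle seeds; they are not tuned to any single test realization.

Oracle observations (default generator settings unless noted):

* PC1 vs multi-subject matrix edge correlation: 0.9998-0.9999 (seeds 7-11).
* Best age-component coefficient-age |r|: 0.906-0.942 (seeds 7-11).
* Best age-component matrix vs planted age pattern |r|: 0.804-0.851.
* Planted trajectory-class recovery at q=0.05: 0.986-1.000.
* Planted-slope 2-SE coverage: 0.934-1.000.
* Mean corr(empirical z, target z) at n=200, p=50, 400 volumes: 0.531-0.546
  over 20 seeds.
* Best-model pooled 10-fold internal r: 0.962-0.968; internal MAE 5.3-5.5 y;
  external r of the best combo 0.943-0.950 (seeds 7-9), always below the
  internal r.
"""

# component / recovery (acceptance criterion on the seed-7 cohort)
PC1_MULTISUBJECT_R_MIN = 0.95        # spec-stated qualitative analogue of 0.98
AGE_COEFF_R_MIN = 0.85
AGE_PATTERN_R_MIN = 0.75
CLASS_RECOVERY_MIN = 0.80            # spec-stated
SLOPE_COVERAGE_MIN = 0.90            # spec-stated invariant
EMPIRICAL_TARGET_CORR_MIN = 0.50     # 20-seed oracle min 0.531

# end-to-end prediction (paired default cohorts, seed 7)
BEST_INTERNAL_R_MIN = 0.93
BEST_INTERNAL_MAE_MAX = 8.0
EXTERNAL_R_FLOOR = 0.85
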