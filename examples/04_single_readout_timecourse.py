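"""Per-day bootstrapped medians of one raw readout.

Follows body weight through a cholestasis-like (bile duct ligation) cohort:
per-day median estimates with 95% CIs per treatment arm, and the
time-dependent test on animals with complete day blocks.
"""

from relsev import default_profiles, run_single_readout, simulate_model_cohort

cohort, _ = simulate_model_cohort(default_profiles()["BDL"], n=14, seed=5)
report = run_single_readout(cohort, "body_weight", B=5_000, seed=3)

for _, row in report.estimates[report.estimates.subgroup == "vehicle"].iterrows():
    print(f"day {int(row.day):+3d}: y^ = {row.median_hat:6.1f}%  "
          f"CI95% [{row.ci_low:6.1f}; {row.ci_high:6.1f}]  n = {int(row.n)}")

for t in report.time_tests:
    print(f"{t.groups[0]}: {t.test_name} chi2/F = {t.statistic:.1f}, p = {t.p_raw:.2g} {t.stars}"
          " (body weight changes over time)")
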