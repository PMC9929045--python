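"""Robustness of the severity ranking to the choice of reference set.

Scores the same four disease cohorts against two independent reference
yardsticks: a 3-variable one (body weight, burrowing, distress score —
laboratory-A style) and a 2-variable one (body weight, burrowing —
laboratory-B style).  A robust procedure keeps the ordering unchanged.
"""

from relsev import (
    build_reference,
    default_profiles,
    run_between_models,
    simulate_model_cohort,
    simulate_reference_cohort,
)

cohorts = {
    name: simulate_model_cohort(profile, n=15, seed=200 + i)[0]
    for i, (name, profile) in enumerate(default_profiles().items())
}

for label, variables, seed in [
    ("laboratory A (3 variables)", ("body_weight", "burrowing", "distress_score"), 31),
    ("laboratory B (2 variables)", ("body_weight", "burrowing"), 32),
]:
    ref_cohort, _ = simulate_reference_cohort(10, variables=variables, seed=seed, provenance=label)
    report = run_between_models(cohorts, build_reference(ref_cohort), B=5_000, seed=4)
    print(f"{label}: {report.ordering_label}")
    print("   ", {m: round(report.estimates[m].median_hat, 2) for m in report.ordering})
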