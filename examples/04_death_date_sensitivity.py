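"""Sensitivity of life expectancy to the placement of unrecorded deaths.

When a death is ascertained at a wave without a date, the date is imputed
at the midpoint of the censoring interval.  This script re-runs the whole
LE pipeline with the imputed dates pushed to the earliest and latest
plausible days of the interval.  Because the wave-cycle multinomial models
see a death through the interval it falls in, the LE tables barely move —
the within-interval placement matters to the intensity fit, not to the
cycle-based life table.
"""

from healthspan import (Gender, GeneratorConfig, SimConfig,
                        baseline_state_mix, build_panels, fit_discrete_model,
                        generate, life_expectancy, simulate_cohort)

ds = generate(GeneratorConfig(n_subjects=2000, seed=1))
for mode in ("early", "midpoint", "late"):
    panels = build_panels(ds.frame, death_date_mode=mode)
    model = fit_discrete_model(panels)
    mix = baseline_state_mix(panels)
    cfg = SimConfig(n_individuals=100_000, gender=Gender.WOMAN,
                    start_state_distribution=mix[Gender.WOMAN], seed=1)
    le = life_expectancy(simulate_cohort(model, cfg), cfg).iloc[0]
    print(f"{mode:9s} women le_total = {le.le_total:6.3f} y  "
          f"(robust {le.le_robust:.3f}, iadl {le.le_iadl:.3f}, "
          f"badl {le.le_badl:.3f})")
# All three rows should agree to well under 0.1 years.
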