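"""Simulate a synthetic ICM cohort and inspect its follow-up structure.

Generates daily device diagnostics (AF burden, longest continuous episode,
activity, ventricular rates, HRV) for a mixed paroxysmal/persistent cohort
with trend-state-linked CVH hazards, then applies the cohort preprocessing.
"""

from aftrends import SimulationConfig, apply_inclusion, follow_up_summary
from aftrends.synth import simulate_cohort

config = SimulationConfig(n_patients=300, seed=7)
cohort, truth = simulate_cohort(config)
retained, exclusions = apply_inclusion(cohort)

summary = follow_up_summary(retained)
n_persistent = sum(1 for v in truth.phenotype.values() if v == "persistent")

print(f"simulated patients:        {len(cohort)}")
print(f"persistent phenotype:      {n_persistent} ({n_persistent / len(cohort):.1%})")
print(f"retained after inclusion:  {summary['n_patients']}")
print(f"excluded:                  {len(exclusions)}")
print(f"total patient-days:        {summary['total_patient_days']}")
print(f"patients with CVH:         {summary['n_events']}")
print(f"mean follow-up (event):    {summary['mean_follow_up_event']:.0f} days")
print(f"mean follow-up (censored): {summary['mean_follow_up_censored']:.0f} days")

# Patients with an event stop contributing records the day before the CVH, so
# their mean follow-up is much shorter than for censored patients; the
# exclusion log lists the single rule each dropped patient violated.
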