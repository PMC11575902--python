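"""Classify one patient's days into AF-burden trend states A-D.

Builds a stylized two-year course: sinus rhythm, burden onset, a spike, then
a quiet period, and shows how the 21-day moving average crossing its
historical (cumulative) average switches the day-level risk state.
"""

import numpy as np

from aftrends import TrendConfig
from aftrends.timeline import make_timeline
from aftrends.trends import flag_days

# 30 quiet days, 20 days of sustained AF (300 min/day), then 60 quiet days
burden = np.concatenate([np.zeros(30), np.full(20, 300.0), np.zeros(60)])
n = len(burden)
tl = make_timeline(
    "EX1", np.arange(1, n + 1),
    {
        "af_burden_min": burden,
        "max_continuous_af_min": burden * 0.8,
        "activity_min": np.full(n, 120.0) - 0.4 * np.arange(n),  # declining
        "vrate_day_bpm": np.full(n, 78.0),
        "vrate_night_bpm": np.full(n, 66.0),
        "hrv_sd_ms": np.full(n, 100.0),
    },
    censor_day=n)

flags = flag_days(tl, TrendConfig())
transitions = flags[flags["trend_state"].ne(flags["trend_state"].shift())]
print("state transitions (crossover days):")
for _, row in transitions.iterrows():
    print(f"  day {row['day_offset']:>3}: -> {row['trend_state']}")
print()
counts = flags["trend_state"].value_counts().sort_index()
print("days per state:", counts.to_dict())
print("duration-threshold days (continuous AF >= 1 h):", int(flags["duration_met"].sum()))
print("quantity-threshold days (total AT/AF >= 72 min):", int(flags["quantity_met"].sum()))

# A = sinus rhythm (burden history < 1% of the day); the onset pushes the
# 21-day average above the from-implant average (state C, then D once the
# activity average drops below 87 min/day); when AF quiets down the 21-day
# average crosses back below the baseline (state B).
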