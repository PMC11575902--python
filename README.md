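# aftrends

Dynamic risk analytics for daily atrial-fibrillation (AF) burden telemetry
from insertable cardiac monitors (ICMs).

Continuously monitored patients produce one diagnostic summary per day: total
AT/AF burden (minutes), the longest continuous AF episode, patient activity
minutes, day/night ventricular rate and heart-rate variability. A change in a
patient's AF burden relative to their own baseline — not just its absolute
level — carries information about near-term risk of cardiovascular
hospitalization (CVH). `aftrends` implements a change-from-baseline pipeline
for researchers studying this question: a synthetic cohort generator with
known ground truth, a moving-average trend engine, decision-rule mining, and
day-level validation statistics.

## The model

For a daily parameter $d_i$ recorded from the day after implant, the engine
computes the cumulative moving average and the simple moving average over
clinical windows $p \in \{1,2,3,5,8,13,21\}$:

$$\mathrm{CMA}(t) = \frac{1}{t}\sum_{i=1}^{t} d_i, \qquad
\mathrm{SMA}_p(t) = \frac{1}{p}\sum_{i=t-p+1}^{t} d_i .$$

Each follow-up day (from the index day, implant + 21 days) is assigned one
AF-burden trend state:

| state | definition | reading |
|---|---|---|
| A | burden CMA < 1% of the day (14.4 min) | sinus rhythm |
| B | SMA₂₁ < CMA | below-average burden |
| C | SMA₂₁ ≥ CMA | above-average burden |
| D | C, and burden CMA > 8.5 min, activity CMA < 87 min | above-average burden with low activity |

Two prespecified clinical comparators are flagged per day: the **duration**
threshold (a continuous AF episode ≥ 1 hour) and the **quantity** threshold
(total AT/AF ≥ 72 min, 5% of the day). Risk is quantified per day: the
incidence-rate ratio of CVH on state-days versus A-days (log-Wald 95% CIs),
the day-level AUROC of a criteria-count score for classifying the 5 days
preceding a CVH (Hanley–McNeil CIs), and the Venn event yield of each
criterion's pre-event flags.

Rule discovery reproduces how the trend-D definition arises: every parameter
is expanded into its CMA, its SMAs, and all 28 pairwise trend indicators
(shorter-window average at/above longer); CART trees on bootstrap 70%/30%
patient partitions classify pre-event days; root-to-leaf rules are scored by
incidence rate and patient percentage and matched against the clinical
comparators' floors.

## Worked example

```bash
python examples/04_validate_holdout.py
```

simulates 500 patients whose per-day CVH hazard is multiplied by the
generating state rate ratios (B 4.49, C 8.41, D 11.15), evaluates the frozen
thresholds on the 30% holdout, and prints:

```
holdout patients: 150, events: 126

trend-state rate ratios vs A (generating truth 4.49 / 8.41 / 11.15):
  B:  3.96  [2.15, 7.29]
  C: 14.54  [7.71, 27.42]
  D:  9.22  [6.05, 14.04]

AUROC duration+quantity score:      0.552
AUROC with the trend criterion:     0.623  (+13% relative)

events captured by any criterion:   43
trend-exclusive events:             21  (+95% over clinical criteria)
```

The estimated rate ratios bracket the generating multipliers (the CIs are
wide at 150 patients; parameter recovery is exercised at 2000 patients in the
test suite), and adding the trend criterion to the day score raises the
AUROC — the trend flags days before hospitalizations that the duration and
quantity thresholds miss.

The other examples cover cohort simulation (`01`), per-patient trend-state
crossovers (`02`) and rule mining with comparator matching (`03`). The same
stages are scriptable via the thin CLI:

```bash
aftrends run --seed 7 --out-dir out/
aftrends report out/report.json
```

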