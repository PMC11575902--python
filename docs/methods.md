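# Methods

## Scope and data model

`aftrends` analyses daily ICM diagnostics at the patient-day level. A
timeline holds one record per day since implant (day 1 = the day after
implant): AF burden minutes, longest continuous AF minutes, activity
minutes, day/night ventricular rate, HRV-SD, and an observed flag. The index
day is day 22 — the day after a 21-day window that initializes the
moving-average history. The package takes follow-up eligibility to start the
day after day 21; the CMA accumulates from day 1, so at the index day every
window up to 21 days is complete and trend classification never encounters
an undefined long-window SMA.

Preprocessing follows the cohort protocol in a fixed order: (1) events after
day 730 are converted to censoring at day 730 (the 2-year limit; whether a
later event should instead count at truncation is not decidable from the
protocol, so the conservative reading — censoring — is used and flagged);
(2) records are truncated to the day before any CVH; (3) patients with no
AT/AF burden > 0 on or after the index day, or with a follow-up gap of ≥ 30
days, are excluded — the gap rule is evaluated on the raw observation
pattern, before imputation, where a gap is a maximal run of unobserved days;
(4) remaining gaps are forward-filled with the last known value, keeping
`observed=False` on imputed days. A patient failing both exclusion rules is
logged once, under the no-AF rule. Only the first CVH per patient is used.

## Trend states and thresholds

States are assigned per day from three quantities: burden CMA, burden
SMA₂₁, and activity CMA. A if burden CMA < 14.4 min/day (1% of a 1440-minute
day — the percentage is configurable because only the "1%" is specified);
otherwise B if SMA₂₁ < CMA (strict) and C if SMA₂₁ ≥ CMA (the tie reads as
"at or above"); C is upgraded to D when burden CMA > 8.5 min/day and
activity CMA < 87 min/day. Under the 14.4-min A threshold the 8.5-min D
bound can never bind (D-days already have CMA ≥ 14.4); both thresholds are
kept explicit and configurable rather than simplified, since either may be
changed independently. The duration (≥ 60 min continuous) and quantity
(≥ 72 min total) comparators read single record fields; a multi-day episode
is represented by consecutive saturated days, so each affected day meets the
duration threshold regardless of when the episode started.

## Synthetic cohort generator

Linked claims/device telemetry of this kind cannot be shared, so the
generator is a first-class component that emulates its structure with known
ground truth.

**AF burden.** Paroxysmal AF is a per-day Bernoulli episode process. The
daily episode probability is `episode_rate` modulated by a mean-one
multiplicative AR(1) propensity (ρ = 0.97, stationary log-sd 0.35), which
gives burden slow trends so SMA/CMA crossovers are informative. Episode
durations are log-normal around a patient-level characteristic scale:
between-patient log-sd 1.2, within-patient log-sd 0.12. This separation is
deliberate: the cohort's burden distribution is extremely skewed (a minority
of patients carries most of the burden), and clinically meaningful
"ever met a threshold" patient percentages are only reproducible when most
patients' episodes essentially never reach one hour while a minority's
routinely do. A day may contain 1 + Poisson(0.1) episodes; daily totals cap
at 1440 min, the longest episode is the per-day maximum, and every nonzero
burden respects the 2-minute device detection floor. Persistent patients
(6% of the cohort) overlay runs of ≥ 7 consecutive saturated days
(≥ 1410 min); the first run is anchored at the index day and kept observed
even if a follow-up gap is drawn, so the device-based phenotype classifier
identifies every persistent patient with ≥ 7 post-index days. A patient
whose event lands inside that first week can still be phenotyped paroxysmal
from the truncated record — a structural consequence of events ending
follow-up.

**Activity.** Daily activity is normal around a patient mean (population
70 ± 30 min/day between patients, 20 min/day within), clipped to [0, 1440];
half the patients decline linearly at 0.35 min/day². The low population mean
reflects an elderly monitored AF cohort in which sub-87-min average activity
— the trend-D refinement — is common.

**Events.** Each follow-up day d from the index day onward carries hazard
`baseline_hazard × multiplier[state(d)]`, where the state is computed from
the generated series itself (self-consistent, no latent state). The
Bernoulli trial of day d produces an event on day d + 1 and diagnostic
records end on day d. This timing makes the estimator exact in expectation:
every observed state-day is an i.i.d. trial given its state, events are
attributed to the state of the last record day, and the day-level rate MLE
is unbiased for the generating multipliers. Defaults: baseline hazard
2×10⁻³/day with multipliers {A:1, B:4.49, C:8.41, D:11.15} — the validated
state rate ratios used as generating truth — giving an overall event rate
near 0.0035/day (the reference cohort's is 1998/605363 ≈ 0.0033/day).

**Gaps.** A follow-up gap starts on any day after the first with probability
2.5×10⁻⁴ and lasts Geometric(1/7.4) days; unobserved days carry no values.
This yields roughly 8–9% of patients with a gap at mean ≈ 7 days.

**What the generator does not emulate.** Calendar effects, enrollment-window
censoring (all censored patients reach 730 days, so cumulative event
percentages run higher than a claims cohort's), comorbidity structure,
device-algorithm false detections, and competing risks. Mean daily burden
lands near 20 min rather than the reference cohort's 65 min because saturated
persistent patients are event-truncated early under the C/D multipliers;
the per-day event rate and the threshold patient-percentage ordering
(duration < quantity < trend-D) — the features the analysis depends on —
are preserved. Passing tests therefore demonstrate estimator correctness
and procedure recovery under this generative structure, not performance on
real claims-linked telemetry.

## Rule discovery

Features per patient-day and parameter: CMA, the seven SMAs, and all
C(8,2) = 28 binary indicators "shorter-window average ≥ longer-window/CMA"
(5 parameters × 36 = 180 columns). Labels mark the 5 days preceding a CVH.
Trees are CART (scikit-learn) with depth ≤ 4 and ≥ 50 days per leaf —
unspecified in the source protocol, chosen small so rules stay
human-readable — trained one per bootstrap replicate on a random 70%
patient partition. Positive days are weighted inversely to prevalence
(≈ 0.3–1% positive days), switchable. Every root-to-leaf path to a
positive-majority leaf becomes a conjunction; per-column bounds are
canonicalized and numerically adjacent split thresholds (within 1% relative
tolerance) are snapped to a common representative so rule frequencies are
comparable across replicates. Rules are scored on the training days: log
incidence-rate ratio versus trend-A days (events attributed via the 5-day
pre-event window) and the percentage of patients ever satisfying the rule;
the day-level share is computed alongside because the matching statistic's
denominator (days versus patients) is ambiguous in the source description.
Matching selects the highest-frequency rule whose log RR and patient
percentage strictly exceed the floors of the comparator with the widest
patient coverage (the quantity threshold), mirroring how the trend-D
definition was fixed before validation; the matched rule can be frozen into
a `TrendConfig` for holdout evaluation.

## Validation statistics

Rate ratios use day-level person-time with log-Wald 95% CIs
(`exp(log rr ± 1.96·√(1/a + 1/c))`); the CI method is a package choice, as
none is named in the source. Trend-state RRs attribute each event to the
state of the last record day (see the hazard-timing argument above);
criterion-level RRs attribute an event to a criterion when any of the 5
pre-event days meets it — the only attribution consistent with the
discovery target. AUROC is the Mann–Whitney rank statistic (ties ½) with
the Hanley–McNeil variance, chosen over bootstrap for determinism; the day
score is the number of criteria met (0–2 clinical, 0–3 with the trend).
Equal-proportion tests are pooled two-sided z (χ²-equivalent). The Poisson
rate comparison fits a saturated log-linear model with one indicator per
criterion and a log person-days offset by IRLS (statsmodels GLM) and
reports pairwise Wald tests. The Venn event yield assigns each event to the
subset of criteria met in its pre-event window; regions partition captured
events, and the percent increase is trend-exclusive events over events
captured by at least one clinical criterion.

## Numerical and degenerate-input conventions

Moving averages are cumulative-sum based and agree with naive means to
1e-9 (property-tested). SMA_p is undefined (NaN) for t < p and
classification refuses undefined long-window days. Zero exposed events
yield RR 0 with a one-sided Poisson upper bound and a degenerate flag; zero
reference events raise. Single-class AUROC and empty criteria raise typed
errors rather than returning silent NaNs. All randomness flows through
`numpy.random.Generator`; the pipeline derives per-stage seeds from the
global seed and the stage name (CRC32 into a `SeedSequence`), so stages are
independently re-runnable and end-to-end runs are byte-identical under a
fixed seed.

## Problem sizes in the test suite

Parameter recovery runs 50 replicate cohorts of 2000 patients × ≤ 730 days
(CI coverage of the generating B/C/D multipliers ≥ 90%); planted-signal
discovery runs 50 replicates of 200 patients × 365 days with 6 trees each,
checking that the matched rule contains the burden SMA₂₁-vs-CMA condition
in ≥ 80%; the holdout matched-rule-versus-quantity comparison uses 8
replicates of 400 patients and the AUROC-gain property 10 replicates of 150
patients; smoke pipelines use 100–120 patients. These sizes were chosen as
the smallest at which the estimators' sampling noise is comfortably inside
the tested margins.

## Known limitations

The matching floors depend on the synthetic world's comparator statistics,
which differ numerically from the reference cohort's (see the generator
section);
recovery claims are about the procedure, not the published coefficients.
Persistent-phenotype misclassification under very early events is possible
(documented above). The AUROC day score treats criteria as exchangeable
votes; no calibration of probability outputs is attempted. Deaths and
competing risks are out of scope, as are ECG-waveform features.
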