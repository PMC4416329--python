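# Methods

This note records how `glyvar` defines each quantity, the conventions chosen
where the literature is silent, and what the synthetic fixtures do and do
not establish about real sensor data.

## Data model

A recording enters as timestamped glucose readings in mg/dL or mmol/L
(converted internally at 18.0182 mg/dL per mmol/L, the molar mass of glucose
divided by ten; all metrics are computed and reported in mg/dL). Readings
are snapped to a fixed grid of `interval` minutes (default 5, the sampling
scheme of the target sensors), anchored at the first timestamp rounded down
to a whole interval — deterministic, and consistent with devices sampling on
a fixed epoch. Each sample maps to its nearest slot (always within half an
interval); two samples in one slot indicate ambiguous sampling and are an
error rather than silently averaged. A window selection (e.g. a 48 h
analysis period) is half-open: 48 h at 5-minute sampling is 576 slots, 288
per day.

## Gap filling

Interior runs of missing slots of length ≤ `max_gap` (default 21 slots,
105 min) are filled linearly between the bounding measurements and flagged
as interpolated; longer runs, and runs touching the window edges, are left
missing — extrapolation would invent data. Interpolation is idempotent and
every filled value lies between its bounds, which means filling can only
*reduce* apparent variability; reports therefore carry the interpolated
count alongside the total so readers can judge how much of the curve is
reconstructed. Interpolation is applied after window selection, so a window
never borrows information from data outside it.

Metrics treat interpolated slots as observed. Remaining missing slots are
excluded slot-wise (AUC, time in range, SD) or pair-wise (CONGA, MODD: a
difference is used only when both endpoints are observed). For MAGE, a
missing run splits the window into independent segments whose retained
excursions are pooled into one amplitude list.

## Closed-form metrics

* **Avg. AUC-H / AUC-L** — rectangle rule: each observed slot contributes
  its exceedance `(G − TR_H)⁺` (resp. `(TR_L − G)⁺`) for one interval,
  divided by the *total* observed duration. Under this convention a series
  constantly 10 mg/dL above TR_H scores exactly 10 mg/dL, i.e. the value
  reads "mean exceedance over the whole window".
* **PATR / PBTR** — slot-count percentages with strict comparisons
  (`G > TR_H`, `G < TR_L`); a value exactly on a threshold counts as in
  range, consistent with the strict inequalities in the AUC definitions.
* **CONGA(n)** — sample SD (k − 1 denominator) of lag differences at
  n × 60 min, n = 1 by default.
* **MODD** — mean |difference| at lag 1440 min; undefined unless the
  recording spans more than 24 h and at least one pair matches.
* **SD** — sample standard deviation (N − 1), matching CONGA's k − 1
  convention; the N vs N − 1 choice is unstated in the source material.

Undefined metrics are `None`/JSON `null`, never zero.

## MAGE

The meaningful-excursion threshold ν defaults to a fixed 45 mg/dL rather
than the classical one-SD rule, and is user-adjustable. The procedure, per
fully observed segment:

1. **Turning points.** Plateaus (runs of equal values) collapse to their
   first slot; all strict local extrema plus the two endpoints are kept, and
   the list alternates peak/nadir. Windows shorter than 3 slots, or
   constant, yield no points.
2. **Both-sided pruning.** An interior point whose adjacent excursions are
   both ≤ ν is deleted and its two like-kind neighbours merge, keeping the
   more extreme (ties keep the earlier) — *unless* the point is a W/M
   centre: a peak strictly lower than both neighbouring peaks, or a nadir
   strictly higher than both neighbouring nadirs. W/M centres are retained
   throughout, and a merge is skipped rather than allowed to delete one.
3. **One-sided pruning.** A remaining sub-ν excursion is removed by merging
   each of its two points with its like-kind neighbour across the excursion,
   again keeping the more extreme. The merge formulation (rather than blind
   deletion of the pair) guarantees global extrema survive pruning. A point
   with no like-kind neighbour on the far side stays; consequently a
   recording's outermost extremes are never discarded, and a curve whose
   total range is below ν retains only its two endpoints.
4. **Start point.** If, with the first sample as reference, neither
   `max(G) − G(t₁) > ν` nor `G(t₁) − min(G) > ν`, yet the pruned curve does
   contain a meaningful excursion, the scan start moves to the global
   extremum — maximum or minimum, whichever occurs first (the choice when
   the minimum precedes the maximum is this package's reading; sources show
   only the maximum case). Data before the new start are not part of the
   MAGE curve.
5. **Backtrack re-check.** After the first meaningful excursion is known,
   the stretch between the start point and the first slot already covered by
   the excursion list is re-scanned and any missed meaningful excursion is
   prepended in temporal order. When the caller supplies the complete
   pruned curve this is a no-op by construction; re-scanning a stretch the
   curve already covers would double-count and could collapse deliberately
   retained W/M patterns.

MAGE+ (MAGE−) is the mean amplitude of retained upward (downward)
excursions exceeding ν; MAGE avg. is the mean of whichever of the two is
defined (equal to the defined one when only one side exists — the one-sided
case is ambiguous in the literature). Excursion frequency counts only
excursions exceeding ν, in both directions; retained sub-ν excursions (W/M
interiors, or end remnants) do not count but set the visual-analysis alert,
whose message text is emitted verbatim by the CLI. Pruning runs to a fixed
point, applying at each step the leftmost applicable rule; every step
removes at least one point, so termination is immediate.

On noisy data with plateau-like stretches (e.g. a sinusoid's flat tops with
sensor noise), W/M micro-patterns are retained in numbers and the alert
fires readily; this is the algorithm's designed behaviour, and the alert is
precisely the instruction to look at the curve.

## Synthetic fixtures

The generator emits 5-minute-grid series over a half-open window (default
48 h / 576 slots, baseline 140 mg/dL): constant, ramp (rise `amplitude` per
`period` minutes), sinusoid, triangle "sawtooth" (swing `amplitude` per half
`period`), square wave (± `amplitude`), and a seeded Gaussian random walk
reflected into 40–400 mg/dL, with optional Gaussian sensor noise and
injected missing runs. Gaussian noise is the simplest stationary stand-in
for sensor error; dropout runs emulate late-calibration data loss (clinical
recordings in this setting average ~2 missing samples per day).

For noise-free analytic specs, `known_answer` returns closed forms (ramp →
CONGA 0 and MODD = rise per day; 24 h-divisible periods → MODD 0; square
wave → AUC by rectangle area; sawtooth with on-grid extremes → MAGE =
amplitude), and the test suite requires the pipeline to hit them to 1e-9.
Random-walk fixtures are checked against independent naive-loop
re-implementations of every metric and, for MAGE, against a naive
transcription plus an exhaustive enumeration of all rule-application orders
on short series (the implementation's retained curve must be among the
reachable fixed points).

What this does **not** show: fidelity to any particular sensor's error
profile (noise here is white, real sensor error is autocorrelated and
calibration steps cause jumps), behaviour under calibration artifacts
(no correction is attempted, matching the scope of the original program),
or agreement with vendor software on clinical recordings. Linear
interpolation biases variability downward on real gaps; the interpolated
count in every report is the caveat's handle.

## Problem sizes

Tests and the acceptance script use 48 h / 576-slot fixtures for the metric
panel (the standard analysis window for this application), 50 seeded
random-walk fixtures for metric-oracle equivalence, and 100 short (≤ 40
slot) fixtures for MAGE-oracle equivalence — short because the exhaustive
rule-order enumeration grows exponentially in turning points.
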