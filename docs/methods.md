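# Methods

`cgmagree` implements the agreement analysis used to assess whether a
continuous glucose monitor (CGM) can substitute for laboratory serum glucose
in a post-surgical ICU population held under tight glycemic control — for
example children recovering from total pancreatectomy with islet
autotransplantation (TPIAT), where euglycemia (70–140 mg/dL) is maintained to
protect engrafting islets. Because patient-level data of this kind are not
publicly depositable, the package ships a synthetic cohort generator whose
defaults reproduce the study conditions, so the entire pipeline runs and is
testable end to end with no external data.

## Pairing

Serum draws are the reference; each draw is matched to the closest CGM
reading within ±300 s (the five minutes before or after the draw). Three
conventions the literature leaves open are fixed here:

* **One-to-one matching.** Serum draws are processed in time order and a CGM
  reading already consumed by an earlier draw is skipped (the next-nearest
  free reading is used). This prevents a single sensor reading from serving
  as evidence twice; with hourly draws against a 5-minute sensor grid the
  rule is almost never binding.
* **Ties.** At equal |Δt| before and after the draw, the earlier reading
  wins — deterministic, and the earlier reading cannot have been influenced
  by the draw event.
* **Window boundary.** |Δt| = 300 s is inclusive.

Point-of-care fingerstick values are carried in the data model (they drive
insulin titration in practice) but are never paired.

## Post-operative day index and exclusions

Post-op day *k* is the half-open 24-hour block [(k−1)·24 h, k·24 h) measured
from sensor activation. Sensor age — not calendar date — is what drives the
day-1 "warm-up" inaccuracy, which is why sensor start is the default anchor;
the end of surgery is available as an alternative (`day_anchor config
option`), and in the synthetic cohorts the two coincide because the sensor is
placed on ICU arrival.

Three exclusion-window types reproduce the analysis filters of this study
design:

* **Warm-up** — the whole of day 1, excluded from the primary analysis set
  (day-1 statistics are still reported separately).
* **Drug interference** — an open-ended window from the first dose of an
  interfering drug (hydroxyurea distorts this sensor class electrochemically
  for hours after dosing); start-inclusive, covering everything after
  initiation.
* **Whole-patient** — e.g. dialysis at the time of surgery.

A pair is removed iff its serum time falls in any window for its patient;
kept + removed partitions the input exactly, and the run manifest checks the
conservation.

## Agreement statistics

With difference defined as CGM − serum (positive = sensor over-reads):

* MAD = mean |CGM − serum| (mg/dL), with sample SD (n−1);
* MARD = 100 · mean(|CGM − serum| / serum) (%);
* signed difference mean ± SD and median (IQR), quantiles by linear
  interpolation between order statistics;
* within ±10/15/20 mg/dL bands, boundaries inclusive;
* %20/20 (and %15/15): within 20% of the reference when the reference
  exceeds 100 mg/dL, within 20 mg/dL otherwise — boundaries inclusive, and
  the relative branch applies strictly above the 100 mg/dL cutover;
* goal-range classification: 70–140 mg/dL inclusive, applied separately to
  the serum and CGM channels.

Percentages are reported to the nearest integer (halves away from zero) and
MARD to one decimal, matching how such tables are printed; unrounded values
are retained in the JSON report. The sign convention for the mean difference
is not universal in the literature; CGM − serum is used throughout and
stated in the output.

## Clarke Error Grid

Zones A–E follow the canonical piecewise formulation of the original 1987
grid, evaluated in a fixed precedence order (A, E, C, D, else B) so that
boundary points classify deterministically:

1. **A** iff (ref < 70 and dev < 70) or |dev − ref| ≤ 0.2·ref;
2. **E** iff (ref ≥ 180 and dev ≤ 70) or (ref ≤ 70 and dev ≥ 180);
3. **C** iff (70 ≤ ref ≤ 290 and dev ≥ ref + 110) or
   (130 ≤ ref ≤ 180 and dev ≤ 1.4·ref − 182);
4. **D** iff (ref ≥ 240 and 70 ≤ dev ≤ 180) or (ref ≤ 175/3 and
   70 ≤ dev ≤ 180) or (175/3 ≤ ref ≤ 70 and dev ≥ 1.2·ref);
5. else **B**.

The test suite verifies the classifier is total on a 1 mg/dL grid over
(0, 400]² and agrees with an independent polygon-membership oracle
(explicit shapely polygons for each zone) on 10⁵ random off-boundary points.
Published Clarke analyses occasionally differ in how exact boundary points
are assigned; with real data this can shift per-zone counts by single pairs.

One tempting invariant is deliberately *not* asserted: a %15/15-qualifying
pair with reference ≥ 70 mg/dL is *not* always zone A. For references in
70–75 mg/dL the absolute 15 mg/dL band is wider than the 20% A band
(e.g. reference 70, device 85 qualifies %15/15 but is zone D). The relative
branch (reference > 100) does always land in zone A, and that is what the
tests check.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the physiology producing it:

* **True glucose** — a mean-reverting (Ornstein–Uhlenbeck-style) process on
  a 1-minute grid, `G(t+Δ) = G(t) + rate·(setpoint − G(t))·Δ + σ_p √Δ z`,
  clipped to [40, 400] mg/dL. Defaults: setpoint 110 mg/dL, start
  140 mg/dL (post-operative arrival), reversion rate 0.5 h⁻¹, process SD
  12 mg/dL·h^(−1/2) → stationary SD 12 mg/dL, which keeps ≈99% of minutes in
  the 70–140 mg/dL goal band — the tight control an hourly titration
  protocol achieves. Mean reversion is the simplest process with the
  observed tight range; no meal or insulin pharmacokinetics are modelled.
* **Serum draws** — hourly; true value + N(0, 5 mg/dL) assay noise, rounded
  to 1 mg/dL, floored at 40.
* **CGM readings** — every 5 minutes:
  `true·(1 + ε_prop) + ε_add + bias_day + drug_term`, rounded and clipped to
  the sensor range [40, 400]. The proportional (SD 0.13) and additive
  (SD 7 mg/dL) error streams are stationary AR(1) series with lag-1
  correlation 0.5 at the 5-minute cadence; `bias_day` is a per-sensor-day
  constant bias (SD 7 mg/dL) standing in for calibration error. All three
  sensor-noise SDs are multiplied by 1.5 during sensor day 1 (warm-up).
  These defaults put the days-2+ pipeline MARD near 13% — a convenience
  calibration to the regime such ICU studies report, not a claim of sensor
  fidelity.
* **Drug interference** — a constant +30 mg/dL CGM bias for 7.5 h after each
  dose (the midpoint of the 6–9 h discrepancy window reported for
  hydroxyurea), doses daily from the patient's first-dose day. No
  quantitative interference magnitude is published, so the 30 mg/dL default
  was chosen once as a clearly clinically visible positive bias (~25% at the
  setpoint) and is a free parameter. In the default 25-patient cohort,
  12 patients start dosing (2 on day 4, 2 on day 5, 5 on day 6, 3 on
  day 7), matching the dosing pattern of the studied cohort.
* **Seeding** — each (patient, stream) pair draws from a child seed of
  (cohort seed, patient index, stream), so cohorts are byte-reproducible and
  adding patients never perturbs existing patients' data.

What the generator does **not** emulate: interstitial-fluid lag,
calibration drift, sensor dropout and compression artifacts, meal/insulin
excursions, hypo/hyperglycemic extremes (trajectories rarely leave
70–140 mg/dL), and the sparsity of real serum draws — in the studied design
most hourly titration values are fingersticks, so real cohorts yield a few
hundred serum–CGM pairs where the synthetic default yields ~3,600. Passing
tests therefore demonstrate correctness of the statistics and filters and
qualitative reproduction of the day-1/interference effects, not quantitative
sensor accuracy on real patients.

## Numerical and design choices

* The OU and AR(1) recursions are evaluated exactly as IIR filters
  (`scipy.signal.lfilter`), keeping 100-replicate property tests cheap.
* Statistics raise `UndefinedStatisticError` on empty input rather than
  returning NaN; the pipeline exits non-zero when no analyzable pairs
  remain.
* A pair caught by several exclusion windows is tallied once, under the most
  severe reason (whole-patient > warm-up > drug).
* Timestamps are timezone-naive at second resolution; epoch arithmetic uses
  naive-datetime subtraction, independent of the process timezone.
* Problem sizes in the test suite (replicate counts, pair counts per
  Monte-Carlo check) are chosen so the statistical tolerances — 3 standard
  errors for closed-form recovery, ≥95/100 replicates for stochastic
  orderings — are comfortably resolvable.

## Limitations

The day-boundary convention (sensor-anchored 24 h blocks) and the CGM−serum
sign convention are documented choices, not universal standards; both are
configurable or stated in output. Clarke zone counts at exact zone
boundaries depend on the precedence order above. The generator's MARD-level
calibration is a regime match only; none of the published cohort's patient
data enters the package.
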