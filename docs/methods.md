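# Methods

## Problem and model

Offline high-pH reversed-phase (RP) fractionation splits a peptide
sample across a first-dimension gradient into timed fractions, pools
("concatenates") non-adjacent fractions into a few wells, and submits
each pooled well to a second, low-pH RP separation. Concatenation keeps
each pooled well sampling the whole first gradient, which preserves
orthogonality between the two dimensions. At nano-flow rates
(~500 nL/min, a few µL per fraction) the eluate cannot be dripped; it is
captured by *dip collection* — holding the column outlet ~1 mm below the
surface of ~50 µL of buffer preloaded in each well. The collector
itself is a converted consumer 3D printer (an Ender 5 S1-class gantry),
which is why the device layer speaks a Marlin-style G-code subset.

`nanofrac` models this workflow end to end without hardware:

1. **Scheduling** (`plate_schedule`): map fraction *k* of *n* to a well.
   Round-robin (`(k−1) mod n_wells` from the start well) is the
   concatenation scheme; the canonical defaults are 40 fractions at
   1 min intervals into 8 wells (8 × 5). `blocked` pools contiguous
   runs and `identity` gives one well per fraction, because the
   collection pattern is configurable on the instrument; `custom`
   accepts an explicit map. When `n_fractions` is not divisible by
   `n_wells`, earlier wells receive the extra events so per-well counts
   never differ by more than one (this also governs the `blocked` block
   sizes). Fraction windows are half-open `[t_start, t_end)` so no
   instant belongs to two fractions. The drawn pooling order of the
   original instrument is not documented; round-robin is the standard
   concatenation reading and is the assumption made here, as are the
   A1 start well and row-major traversal.
2. **Motion planning** (`motion_gcode`): every well change is
   raise-to-safe-Z → XY transit → descend; collection windows are
   device-timed dwells at `liquid_surface_z − dip_depth` (default
   1 mm). The dwell preceding each transition is shortened by that
   transition's exact transit time, so event boundaries land on
   schedule and total plan duration equals the schedule span plus the
   bounded approach/park moves. A transition whose transit time exceeds
   `transition_budget_s` is a planning error naming the transition.
3. **Device simulation** (`device_sim`): a virtual printer executes the
   emitted subset (G21/G90/G28/G0/G1/G4/M400) with a distance/feed time
   model, zero acceleration, hard axis limits (220 × 220 × 280 mm) and
   moves-rejected-before-homing semantics. The line protocol is
   newline-terminated commands with one acknowledgment each,
   block-until-ack; runs abort to the safe-travel height on any error.
4. **Metrics** (`metrics`): peak capacity, fraction overlap, signal
   recovery, retention-time orthogonality (below).
5. **Synthetic fixtures** (`synth`): generators with known ground truth
   so every metric is validated by parameter recovery.

## Metric definitions

**Peak capacity.** For gradient time *t*_g and Gaussian peaks of
baseline width *w*_b (= 4σ), the single-dimension capacity is
*Pc* = 1 + *t*_g / *w*_b. Widths quoted as FWHM are converted via
*w*_b = (4/2.355) · FWHM ≈ 1.699 · FWHM. A 2D system with *n* fractions
is upper-bounded by *n* · *Pc* under full orthogonality; this is a bound,
not an estimate, and the defaults-derived first-dimension value
(1 + 2640/47 ≈ 57.2; × 8 ≈ 457) makes no claim about the second
dimension's own width, which must be measured to get the full 2D number.

**Fraction overlap.** Histogram of |fractions| per peptide, and the
percentage detected in exactly one fraction (sharpness proxy).

**Signal recovery.** Over peptide ids common to a fractionated/
recombined table and an unfractionated reference:
`total_ratio = Σ test / Σ reference` (the headline statistic) and the
median per-peptide ratio (robust companion). Peptides with zero
reference intensity cannot form a ratio and are excluded with a logged
count. Both forms are always reported since "average recovery" is
ambiguous between them.

**RT orthogonality.** Pearson and Spearman correlation on raw retention
times, plus the occupied-cell fraction of an `n_bins × n_bins` grid over
rank-normalized times (how the joint distribution fills the separation
space, independent of marginal gradient shapes). Constant vectors leave
the correlations NaN with a warning.

## Synthetic-data generators

Defaults encode the canonical run conditions: a 44 min (2640 s)
first-dimension gradient in forty 1-min fractions, Gaussian elution
peaks of 47 s baseline width (σ = 11.75 s), true recovery 0.74 with
lognormal intensity noise of CV 0.2, and a loose RT correlation
ρ = 0.3.

* **RT pairs** come from a Gaussian copula mapped to uniform gradient
  windows. The latent correlation uses the sin correction
  ρ_latent = 2·sin(πρ/6), so the Pearson correlation of the *emitted*
  (uniform-margin) times converges to the requested ρ rather than the
  slightly attenuated value a naive copula would give.
* **Detection sets** place each peptide's apex uniformly over the run
  and mark it detected in every fraction window intersecting
  apex ± 2σ. The singleton probability then has a closed form:
  interior windows contribute (L − 4σ)/L and the two edge windows
  (where the span clips to the run) (L − 2σ)/L, giving
  ((n−2)(L−4σ) + 2(L−2σ))/(nL) for 4σ ≤ L.
* **Recovery pairs** are lognormal reference intensities with
  test = reference · loss · noise, mean-one lognormal noise of the
  requested CV, so the expected summed ratio is exactly the loss factor.

What the generators deliberately do not model: intensity-dependent
detection thresholds, ionization competition, missing values, and
identification stochasticity. Consequently the geometric-overlap
singleton share at the default peak width (~24 % over raw 1-min
fractions) is far below what identification-filtered real data shows
for pooled fractions (~70 %): real detection censors the low-intensity
peak tails, while the ±2σ rule counts them. Passing parameter-recovery
tests therefore validates the metric implementations, not instrument
performance. Note also that under round-robin pooling a narrow peak
spanning two *adjacent* fractions still lands in two different wells,
so pooling leaves the geometric singleton share essentially unchanged —
which is exactly the orthogonality-preserving point of concatenation.

## Numerical and design choices

* Geometry defaults: 96-well plate, 9 mm pitch, A1 at (50, 50) mm;
  liquid surface Z = 30 mm, well rim 40 mm, safe travel 50 mm; 200 µL
  wells with 50 µL preload. The ≤ 3 µL added per well is negligible
  against the preload, so the liquid surface is a configured constant
  (no level tracking or evaporation model).
* Motion defaults: 3000 mm/min travel, 300 mm/min dip feed engaging
  2 mm above the surface (`approach_clearance_mm`), 1 mm dip depth,
  5 s transition budget. The slow feed only near the liquid keeps a
  full-plate diagonal transition (~3.7 s) inside the budget while still
  entering the buffer gently. Feed rates and budgets are assumptions —
  the original controller's values are undocumented — and are exposed
  as parameters.
* Z is raised fully to safe-travel for every transition, even between
  adjacent wells: simplicity and rim-collision safety over a few
  hundred ms of transit. Effluent emitted during transit is
  unrecovered; the schedule grants each event `interval − transit` at
  depth and the run log records the gaps.
* Dwells are device-timed (`G4`) with an `M400` sync after every
  motion command, rather than host-side sleeping: deterministic and
  simulator-testable; LC-trigger wiring is out of scope, so run start
  is manual or a configured delay.
* G-code output is byte-deterministic: coordinates at 3 decimals, feeds
  as integer mm/min, dwells as integer milliseconds. Only the
  `marlin` dialect is implemented.
* Well rows are single letters (A–Z, up to 26 rows), covering 96- and
  384-well geometry; multi-plate runs are out of scope.
* All generators take an explicit integer seed and are reproducible to
  the byte; statistical tests fix seeds and use ≥ 4-sigma Monte-Carlo
  tolerances.

## Problem sizes

The validation suite and the reproduction script run the package at the
canonical 40-event run for planning/simulation; 1000 randomized
schedules for safety properties; n = 1000 peptides for recovery,
n = 10⁴ for correlation recovery, and n = 2 × 10⁴ for the
singleton-share oracle — sizes at which Monte-Carlo error is well below
the asserted tolerances.

## Known limitations

Zero-acceleration kinematics (transit times are mild underestimates);
no liquid-level, evaporation, or droplet modeling; no acquisition or
identification simulation; the virtual printer implements only the
emitted command subset; serial operation requires the optional
`pyserial` dependency and is untested against real firmware variants.
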