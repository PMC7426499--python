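# Methods

## The measurement model

### Tracking

A frame's fly position is the intensity-weighted mean of the coordinates
of all pixels **strictly** brighter than the detection threshold (default
60 on the 8-bit scale); "brighter than" is read as a strict inequality, so
a frame whose maximum is exactly 60 yields a missing detection.  Intensity
weighting was chosen over a binary-mask centroid because it is sub-pixel
accurate on a smooth blob (a `weighting="binary"` flag provides the
alternative).  Missing detections are flagged, never interpolated —
interpolation would invent motion that the activity metrics would then
count.  Pixel centers sit at integer coordinates (0-based); millimetre
output is arena-centered with +y pointing up (image rows negated).

Calibration maps pixels to millimetres via the chamber geometry: the
bright arena disk is the largest connected super-threshold region (Otsu by
default), and its diameter in pixels is the mean of the region's row and
column extents measured between extreme pixel centers — exact for a clean
rasterized disk, and within a pixel for arbitrary sub-pixel disk centers
(0.25 % at 400 px).  `mm_per_pixel = 20 mm / diameter_px` for the standard
chamber; a manual `Calibration` can always be supplied instead.

### Quantization and the five SLA parameters

The record is divided into 1-s quanta.  Each displacement between
successive detected samples is attributed to the quantum containing its
*earlier* sample, and the quantum's mean speed is the attributed path
length divided by the quantum duration.  This convention partitions the
path exactly across quanta — at *f* frames per second a full quantum
carries *f* steps, so a fly moving steadily at *v* mm/s scores *v* mm/s.
The popular alternative (counting only steps with both endpoints inside
the quantum) loses one step per quantum and under-measures every speed by
(f−1)/f; we use the partition rule because the speed estimates then need
no frame-rate-dependent correction.  Path length rather than net
displacement is used because "mean speed" is a speed, not a velocity
magnitude, and path length is robust to direction changes within the
second.

Quanta with fewer than two detected samples are flagged invalid and
excluded from every parameter; invalid quanta also break run bouts.
A quantum is *rest* when its mean speed is lower than 1 mm/s and *run*
otherwise — the boundary value 1.00 mm/s classifies as run, since only
"lower than" defines rest.  The five parameters over the valid quanta:

* index of activity = run quanta / valid quanta (a fraction in [0, 1];
  a percentage property is provided, since the conventional-unit scale is
  not formally defined);
* run frequency = 100 × bout count / valid record seconds (normalizing by
  valid time keeps records of unequal length comparable);
* running speed = mean quantum speed over run quanta (absent if none);
* total speed = mean quantum speed over all valid quanta;
* run bout time = mean duration of maximal blocks of consecutive run
  quanta.  Bouts truncated by the record edges are counted: excluding
  them would bias bout time downward for active flies.

These definitions force `run_frequency × run_bout_time =
100 × index_of_activity` exactly whenever bouts exist, and
`total_speed ≤ running_speed` whenever a run quantum exists; both are
asserted on every synthetic run.

The centrophobia index is the fraction of detected samples whose distance
from the arena center exceeds 0.7 of the arena radius.  The 0.7 cutoff is
a convention (exposed in `AnalysisConfig`); under uniform-over-area
exploration the expected index is 1 − 0.7² = 0.51, so wall-followers score
well above 0.51.

### Group statistics

The two-tailed Mann–Whitney U test is implemented in the package so that
every *p* value is auditable: U from rank sums with midranks for ties;
exact two-tailed *p* by full enumeration of the null distribution of U
(standard counting recurrence) when n₁ + n₂ ≤ 20 and there are no ties;
otherwise a normal approximation with tie correction and, by default,
continuity correction (whether the original analyses used continuity
correction is unknowable, hence the flag).  The two-tailed *p* is twice
the smaller one-tailed *p*, capped at 1.  Significance tiers use strict
inequalities: 1 for *p* < 0.05, 2 for < 0.01, 3 for < 0.001.  Comparison
tables run all between-strain tests at matched ages and each strain
against its own baseline age, with **no** multiple-testing correction by
default (matching common practice for these cross-sectional panels); Holm
or Bonferroni adjustment is available.  Group summaries are mean ± SEM
(sample SD with n−1 denominator over √n; SEM absent for n = 1).

### Densitometry

Spot OD is the mean intensity of a local background annulus (default
radii: spot radius + 2 to + 6 px) minus the mean of the spot disk, floored
at zero.  The local annulus, rather than a global background estimate,
makes OD invariant to illumination offsets and gentle gradients.  Spot
positions are user-supplied circles; dot blots are gridded by hand and no
automatic spot finder is attempted.  The standard curve is an ordinary
least-squares line OD = slope × concentration + intercept with R²
reported; inversion warns outside the calibrated concentration range.
Exact-ratio and exact-slope behavior on noiseless phantoms requires
integer-valued rendered intensities (8-bit images), which the default
phantom settings satisfy.

### Pedunculus ratio

R = x/y with x the mean of a square ROI on the pedunculus and y the mean
of the equal-size ROI shifted toward the image top.  The default shift is
exactly one side length (adjacent, non-overlapping squares); it is
configurable because on a phantom whose dimmed region is a disk the
adjacent square necessarily clips the disk, and exactness checks use a
larger offset that clears it.  Slice selection takes the k = 3 slices with
the lowest pedunculus-ROI mean, ties broken toward lower slice index;
averaging over slices happens **before** the ratio (a
ratio-per-slice-then-average variant exists behind a flag, since the
verbal definition is ambiguous between the two).  R is exactly invariant
to global intensity gain.  Group comparisons of per-brain R default to
Welch's two-sided t-test (variances are not assumed equal); Mann–Whitney
is available.

### Unit conversion

μg analyte per g fresh tissue × tissue density (g/mL) ÷ molar mass
(g/mol) is exactly mmol/L; with density 1 g/mL, 396 μg/g of
3-hydroxykynurenine (224.21 g/mol) gives 1.766 mM.

## The synthetic generators

### Walker

Real recordings come from live flies; the generator is the minimal model
the metrics can be validated against: since the analysis itself
dichotomizes behavior into rest/run at 1 mm/s, the walker is a two-state
continuous-time Markov chain (rates k₁ rest→run, k₂ run→rest), simulated
as its exact discrete skeleton at the frame grid (per-frame switch
probability 1 − e^(−k·dt)); the initial state is drawn from the
stationary law k₁/(k₁+k₂).  Running speed is drawn once per bout from a
normal law truncated below at 1 mm/s (so every run bout is a run by the
classification rule; negligible truncated mass at the defaults), giving
"running speed" a recoverable ground truth; heading increments during
runs are von Mises with concentration κ; rest is isotropic jitter with
Rayleigh step lengths scaled to the requested mean speed.  At the wall
the position is projected back onto the boundary, the heading is
specularly reflected across the local tangent, and then rotated toward
the nearer tangent direction with weight `wall_bias` — 0 gives a pure
bounce (near-uniform exploration), 1 gives wall-riding and hence the
centrophobic, annular tracks real flies show.

Defaults (changeable per run): k₁ = k₂ = 0.1/s (10-s sojourns), run speed
4 ± 1 mm/s, rest jitter 0.2 mm/s, κ = 4, wall bias 0.7, arena radius
10 mm, 10 frames/s (the recording hardware's rate is a convention here,
not a measured fact), duration 3600 s.  These are ordinary magnitudes for
walking flies in small arenas.  Identical seeds reproduce byte-identical
output.

What the generator does **not** emulate: body shape and orientation (the
tracker needs only a centroid, so the rendered fly is a radially
symmetric Gaussian blob), grooming and micro-movements, flight, speed
modulation within bouts, and any interaction between position and state
switching.  Passing recovery tests on this walker therefore validates the
computational chain, not the biological realism of any particular
recording.

### Renderer, membrane and brain phantoms

Frames are Gaussian background noise plus the fly blob, quantized to
8 bits, with the invariant `fly_peak > 60 > background_mean + 3·sd` so the
fly is detectable and the background essentially never is.  Membrane
phantoms render non-overlapping spot disks whose darkness is
`darkness_per_unit × concentration` (clipped at fully dark) on a noisy
light background — a linear stand-in for a serial dilution.  Brain
phantoms are uniform stacks with a darkened pedunculus disk
(`contrast × surround`) in chosen slices.  All three are deterministic
given their seed.

## Known estimator biases (by design, quantified by the test suite)

The 1-s quantum dichotomization is a *consistent* description of behavior
but a *biased* estimator of the underlying bout model.  Two effects,
both reproduced and measured on the walker at the default regime:

* **Bout-edge mixing.**  A quantum straddling a state switch contains both
  run and rest frames; it classifies as run whenever its blended speed
  reaches 1 mm/s, i.e. at a run fraction of roughly (1 mm/s)/v — about
  0.25 at v = 4 mm/s, well below a majority rule.  This inflates the
  activity index (measured: +0.022 at k₁ = k₂ = 0.1/s over 20 one-hour
  records, against a stationary probability of 0.5) and dilutes the mean
  speed of run-classified quanta (−0.19 mm/s at the defaults).
* **Wall-contact shortening.**  Projected wall contacts shorten realized
  steps relative to the drawn bout speed for wall-following walkers
  (−0.11 mm/s at the defaults).

Consequently the recovered running speed sits a few percent below the
generative per-bout mean, and the recovered activity index a couple of
percent above the stationary run probability, with Monte-Carlo error far
smaller than either offset at the 20-seed × 1-h scale.  The corresponding
recovery test asserts unbiasedness within 3 standard errors and documents
this as a known failure; comparisons *between* groups analyzed with the
same quantization are unaffected, which is why the group-level tests
(constructed effects detected, type-I error at nominal level) pass.

## Numerical and scale choices

* Exact Mann–Whitney enumeration is limited to n₁ + n₂ ≤ 20 (the
  distribution table is cached); beyond that the corrected normal
  approximation differs from exact by < 0.02 already at n₁ = n₂ = 8.
* The empirical-size (type-I error) experiment uses 1000 replicate pairs
  of 20 flies each with 60-s records — short records keep the experiment
  to tens of seconds while still exercising simulate → quantize →
  profile → test end to end; the tested parameter (total speed) is
  continuous, so ties are no concern.
* Tracker-validation renders use 3-s clips at 256² px, 0.1 mm/px: RMSE is
  a per-frame quantity, so clip length only controls the sample count.
* Confinement is enforced with a 1 − 10⁻¹² radial margin so the invariant
  `x² + y² ≤ R²` survives floating-point rounding.
* Degenerate inputs fail loudly: empty groups, all-tied exact tests,
  zero-OD references, flat standard curves, stacks shallower than k, ROIs
  (or their derived reference ROI) outside the image, trajectories
  shorter than one quantum.

## Limitations

Single-animal, single-arena only; no identity maintenance, no
body-orientation or sleep/grooming scoring; no automatic spot or
pedunculus detection (ROIs are hand-placed, as in practice); densitometry
assumes a light membrane with darker spots; the walker omits the
biomechanics noted above.  Biological cohort values from live flies are
outside what synthetic validation can certify.
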