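# Methods

This note documents the models, conventions and design choices behind
`pursuit3d`: what is computed, under which assumptions, and what the
synthetic benchmarks do and do not show.

## Coordinate conventions

Positions live in an HMD-anchored right-handed frame (origin at the headset
centre, `+z` forward, `+y` up, `+x` right) and are reduced to spherical
coordinates `(r, θ, φ)` with `θ = asin(y/r)` (pitch, `[-90°, 90°]`) and
`φ = atan2(x, z)` (yaw, `(-180°, 180°]`).  The convention itself is a free
choice; it is validated by an exact round-trip property (better than
1 nm over the workspace).  The degenerate origin maps to `θ = φ = 0`.

Before any windowed statistic, every yaw series is unwrapped (no ±360°
jumps), so trajectories crossing the seam behind the observer do not corrupt
correlations or movement vectors.  Unwrapping whole series versus per-window
differs only by a constant offset inside any window, which both detectors
are invariant to.

## 3D point of regard

The binocular gaze point is the midpoint of the shortest segment between the
two eyes' gaze lines, computed in closed form.  Ray pairs whose direction
cross product has norm below `1e-9` are near-parallel (no usable vergence);
the frame is flagged invalid and dropped before windowing, exactly like a
tracking-loss sample.  The closed form is checked against a brute-force
two-parameter grid search to within `1e-4` m.

## Target geometry

Selectable objects spawn on a 0.2 m sphere centred on the viewing axis at
0.4 m (near, single-target setting), 0.8 m (near, multi-object setting) or
1.4 m (far).  The 26 spawn points are radial projections of the cube
landmarks (8 corners, 12 edge midpoints, 6 face centres); labels concatenate
the face letters in the order x (`l`/`r`), z (`n`/`f`), y (`t`/`b`).

Circular trajectories rotate a spawn point at 45°/s about a principal axis
through the sphere centre.  The original experiment drew seven trajectory
arcs but gave no equations; the default reconstruction assigns each point to
a circle about the x, y or z axis such that seven arcs of 2–6 points result
and the equatorial arc carries exactly the lateral target group of the
published velocity table.  The assignment is a configuration artifact
(serialisable with the layout) and can be replaced.  Linear trajectories
move an object from the sphere centre through a spawn point at 0.15 m/s.
In the multi-object setting all linear objects share that start point; the
small de-overlap offsets of the original rendering are not modelled because
they are visual, not kinematic.

The observer-relative velocity table derives from these constants alone:
tangential speed (`ω·radius-about-axis` for circular motion at spawn, the
full 0.15 m/s for linear motion, 0 for pure-depth motion) divided by the
axial z distance of the target group, converted to degrees and rounded half
up to one decimal.  This is the only rule that reproduces all ten published
entries simultaneously, which is why the axial distance — not the slant
range — is used.

## Detectors

Both detectors operate on a 40-sample moving window of time-aligned gaze and
object spherical coordinates (~0.67 s at the 60 Hz analysis rate) and emit
no decision before the window fills; a trial's decision is the first frame
at which any object crosses the threshold, and the duration until selection
is that sample count divided by the frame rate.

**Correlation.**  Per object, per dimension, the Pearson product-moment
correlation between gaze and object series; the three coefficients are
averaged and the argmax compared against the threshold.  When either series
is constant in a dimension, Pearson is undefined; that dimension contributes
0 to the average.  This keeps the score scale identical across objects but
deliberately caps the score at 2/3 whenever a trajectory leaves one
spherical dimension constant.  Every principal-axis circle does exactly that
(rotation about z fixes `r`; about x fixes `φ`; about y fixes `θ`), as do
face- and edge-direction linear paths — only the eight corner directions
excite all three dimensions.  Consequently the perfect-pursuit benchmark
(100 % detection at threshold .75) is run on corner-direction linear trials;
for degenerate-symmetry trajectories the cap is an honest property of the
averaging rule, not a bug.  Constancy is judged with a relative tolerance
(`1e-12`) so floating-point jitter on an analytically constant coordinate is
not mistaken for signal.

**Difference.**  Movement vectors are half-window mean differences (the
older half takes the extra sample at odd lengths).  The per-dimension
coefficient is the reconstruction `c = |Δg − Δo| / (2|Δg + Δo|)`, which has
every documented property of the original: 0 iff the deltas are equal
(including both zero), 0.5 at a stationary gaze and in the fast-gaze limit,
> 0.5 for opposite motion, symmetric in `log10(Δg/Δo)`, and undefined
(division by zero) at `Δg = −Δo ≠ 0` — such dimension-frames are skipped
and the average renormalised.  The formula is isolated behind
`difference_coefficient` so an alternative algebra can be swapped in without
touching callers.  Per-dimension coefficients are additionally averaged over
their recomputations at the frames spanned by the window (smoothing that
suppresses single-frame outliers; disable with `smooth=False`), then
combined across dimensions by mean (default) or sum — the mean is
commensurate with the .20–.01 threshold grid.

A known consequence of the scale-free coefficient: in a dimension where the
object does not move, the coefficient compares gaze noise against zero and
hovers around 0.5 regardless of how small the noise is.  Circular
trajectories therefore score ≈ 0.17 at best under realistic noise and are
not selectable at the .07 operating point, while linear corner trajectories
behave well.  The recorded-data behaviour of the original coefficient in
such dimensions cannot be recovered from its published description; the
reconstruction makes the behaviour explicit rather than hiding it.

Ties at the argmax/argmin are broken towards the lexicographically smallest
object id and flagged on the decision, keeping every pipeline deterministic.

## Synthetic gaze

The simulator produces the idealised, highly standardised smooth pursuit the
detectors assume: the pursued point follows the target's spherical position
through a latency shift (default 0.12 s) and a first-order per-frame gain
(default 0.95); there are no catch-up saccades.  Gain and latency defaults
are literature-typical values for healthy observers, not measurements from
the original study, and are exposed in `OculomotorParams`.

The pursued point is converted to two eye rays from `±IPD/2` on the x axis
(IPD default 0.065 m, configurable — the original setup never states it).
Each ray direction receives independent Gaussian noise of 0.2° per
perpendicular axis, the typical error quoted for the tracker; with two
independent eyes this yields ≈ 0.2° RMS directional error of the
reconstructed point of regard (verified by Monte Carlo, asserted within
[0.15°, 0.3°]).  Because the point of regard is re-triangulated from the
noisy rays, depth errors grow with distance exactly as vergence geometry
dictates (≈ 0.01 m radial SD at 0.4 m vs ≈ 0.13 m at 1.4 m in the
benchmark), reproducing the qualitative near-vs-far degradation.  Frames
are flagged invalid with probability 0.01 per frame and dropped before
windowing.

Frame rate is fixed at the 60 Hz analysis assumption; the tracker's native
250 Hz is not modelled.  What the simulator does *not* emulate: saccades and
blinks, head motion, calibration drift, vergence–accommodation coupling,
and any human variability in pursuit quality.  Green tests on synthetic
blocks therefore validate the algorithms and the pipeline, not human-level
detection rates; empirical optima such as the .75/.07 operating points are
properties of recorded human data and are used here as fixed reference
thresholds, not re-derived.

Blocks mirror the two experimental designs: 3 rounds × 26 targets = 78
single-visible-target trials (1 s rest + 4 s movement), and 17 object
configurations × 3 repeats = 51 multi-object trials (2 s rest + 4 s
movement).  All randomness flows from one master seed through spawned
substreams (trial order, per-trial noise), making every artefact bit-stable.

## Evaluation

`DR + FPR + NDR = 1` on every summary by construction; efficiency is
`TP/(TP+FP)` and reported as 1 with a `no_selections` flag when nothing was
selected.  Threshold sweeps cache per-frame score traces and re-threshold
them, which is exactly equivalent to re-running the detectors.

The composite criteria are reconstructions specified by their documented
properties (their original algebra is not published in machine-readable
form):

* `efficiency_1 = e·(1 − e·NDR)` with effectiveness `e = DR/(DR+FPR)`;
  property-tested to prefer, at equal DR, operating points whose residual
  mass is non-detections rather than false positives.
* `efficiency_2` is the signed adjacent-threshold change of
  `e + NDR`; flat curves score 0, an abrupt non-detection step scores
  maximally at the step, and reversing the grid negates the slopes.

The recommendation rule codifies the hybrid procedure deterministically:
candidate = argmax of `efficiency_2` (correlation) or `efficiency_1`
(difference), adjusted to the nearest grid point with DR ≥ 95 % of the curve
maximum, preferring points with NDR ≥ FPR when attainable; the full
rationale is attached to the curve.  The 95 % floor replaces the "visual
inspection of the DR development" of the manual procedure.

The paired sign test drops trials with equal correctness, assigns `+` to the
algorithm that was correct, and evaluates an exact binomial at p = 0.5,
two-sided by doubling the smaller tail (capped at 1) — cross-checked against
an independent implementation.

## Problem sizes

The shipped benchmarks use blocks of 16–78 trials of 5 s at 60 Hz and up to
26 candidate objects, and 200 seeded trials for the noise-degradation
property (52 per noise level at 0, 0.2, 1.0 and 3.0°, compared with a
one-sided 95 % confidence margin).  These sizes give stable statistics for
every asserted property while keeping the full suite fast; all of them
scale up by changing a single argument.

## Known limitations

* The trajectory-arc reconstruction, the difference coefficient and both
  efficiency formulas are property-faithful reconstructions, not verbatim
  transcriptions (the originals are unavailable in symbolic form).
* The correlation zero-variance rule caps scores for degenerate-symmetry
  trajectories (see above); a threshold-lowering variant for such windows is
  deliberately not enabled.
* Human-level detection rates, the empirical optimality of .75/.07 and the
  human-subject statistics (ANOVAs, preferences, reaction times) depend on
  recorded gaze and are out of scope.
* The stereo error margins quoted for the tracker (0.02 m near / 0.22 m far)
  presume an unstated interocular distance; the simulator reproduces the
  qualitative growth, and no operation claims those two numbers.
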