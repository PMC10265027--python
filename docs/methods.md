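# Methods

## The model

A hawk chasing a towed lure over flat ground is modelled as a planar
pursuer whose *heading* is commanded by a guidance law while its *speed* is
constrained to the measured flight speed (speed matching). With the
line-of-sight vector **r** from pursuer to target, the candidate laws
command the inertial turn rate γ̇ from delayed feedback of two angular
signals:

* the deviation angle δ = atan2(r × v_P, r · v_P), the signed angle
  between the pursuer's velocity and the line of sight (egocentric — no
  external reference needed);
* the inertial line-of-sight rate Iλ̇ = r × (v_T − v_P)/|r|², the angular
  rate of the line of sight in a fixed frame (requires an inertial
  reference, e.g. visual–vestibular fusion);
* the background line-of-sight rate Bλ̇ = r × v_T/|r|², the target's
  angular motion relative to a background feature immediately behind it
  (purely visual). The identity Iλ̇ − Bλ̇ = −(r × v_P)/|r|² says the two
  rates differ exactly by the pursuer's self-motion across the line of
  sight, which is why background-PN alone cannot correct heading error but
  the mixed background law can, via its δ term.

The five laws are PP (γ̇ = −K δ), inertial-PN (γ̇ = N·Iλ̇), background-PN
(γ̇ = N·Bλ̇), and the mixed forms inertial-PNP and background-PNP
(γ̇ = N·λ̇ − K δ). N is a dimensionless navigation gain, K a pursuit gain
(1/s) and τ a fixed sensorimotor delay (s). All angular quantities are
counterclockwise-positive scalars (the z-components of the corresponding
vertical vectors); the commanded acceleration is the turn rate times the
+90°-rotated velocity, hence always centripetal.

## Simulation

The discrete-time recursion is forward Euler at step dt (default 5·10⁻⁵ s,
i.e. 20 kHz):

    r[n+1] = r[n] + dt·v[n]
    v[n+1] = s[n] · (v[n] + dt·a[n]) / |v[n] + dt·a[n]|

where s[n] is the measured speed at step n (the normalisation uses the
speed indexed at n, exactly as the recursion is written; the simulated
|v[n+1]| therefore equals s[n]). Delays are realised as round(τ/dt) steps
read from the simulated history; before the simulation start the measured
pursuer states feed the delayed terms. Simulations for fitting start at
t = τ_max = 0.15 s so that measured data exist for every admissible delay,
with the initial state taken from the measured track, and run to the
intercept time. Degenerate states (coincident pursuer/target, vanishing
speed) abort a simulation; during grid search such a parameter point scores
+∞.

The per-step arithmetic lives in one numba kernel shared by the
single-trajectory and batched grid paths, so a trajectory generated by the
simulator is reproduced bit-for-bit when refitted at the generating
parameters; a plain-Python re-implementation of the recursion serves as an
independent cross-check in the tests.

## Fitting

The fit criterion is the RMS Euclidean distance ϵ between simulated and
measured pursuer positions, evaluated at the 200 Hz measurement frames on
[τ_max, intercept] (frames with missing data are skipped; evaluating at the
measurement frames makes ϵ independent of the integration rate).

*Per flight*: for each delay on the τ grid (0–0.15 s in 0.005 s steps, 31
values), the continuous gain(s) are minimised by Nelder–Mead, unconstrained
in sign, multi-started from a fixed set of gain values plus the best cell
of a coarse gain grid at that delay (long flights that end circling a
stopped lure have needle-shaped error surfaces; the grid-seeded start keeps
the search in the global basin). The best (τ̂, N̂, K̂, ϵ̂) wins.

*Globally*: ϵ is evaluated exhaustively on the grid N ∈ [0, 1.5] step 0.1,
K ∈ [0, 5] s⁻¹ step 0.2, τ ∈ [0, 0.15] s step 0.005, for every flight; the
global optimum (N̆, K̆, τ̆) minimises the cell-wise median ϵ̃ across
flights. PP and the pure PN laws are the N = 0 / K = 0 slices of the mixed
grid, so the mixed optimum can never be worse (tested). Ties at the minimum
break deterministically to the smallest (τ, N, K). Grids are cached
(`ErrorGrid.save`) so bootstrap and cross-validation never re-simulate.

## Validation statistics

Confidence intervals use the bias-corrected and accelerated (BCa)
percentile bootstrap: flights resampled with replacement (10⁶ iterations
for per-flight medians, 10³ for globally fitted parameters, both seeded and
chunked deterministically), bias correction from the fraction of replicates
below the point estimate, acceleration from the jackknife skewness.
Degenerate inputs (identical values) give a zero-width interval. Paired
model comparisons use the exact two-tailed binomial sign test on per-flight
error differences, with zero differences dropped (the classical conditional
sign test; a tie-splitting variant is available). k-fold cross-validation
partitions flights uniformly at random (seeded) into k near-equal folds,
refits the global model on k−1 folds from the cached grid and scores the
median error of the held-out fold at the training-optimal parameters,
reporting the mean of the k validation medians.

## The synthetic-data generator

The generator emulates the indoor lure-pursuit protocol: a 20.2 × 6.1 m
arena; a zigzag lure course between two lateral bands with circular fillets
(default radius 0.2 m) standing in for the pulley corners, towed at a
constant speed drawn from 6–8 m/s, starting at t = 0 and dwelling at the
course end; a hawk launched from one of three perch positions aimed at the
lure, steered by a chosen guidance law at known (N, K, τ); 200 Hz sampling
with isotropic Gaussian position noise (default σ = 1 mm, the scale at
which the 0.03 m flight-track spline tolerance is the noise-consistent
residual budget σ√n for a few-second flight); and raw marker clouds
carrying rigid backpack (4 asymmetric markers), tail-mount (3 symmetric)
and lure (3 per long face) templates oriented by the velocity heading, with
independent per-marker dropout and injected spike points. All generators
are pure functions of (spec, seed).

The hawk's speed profile is prescribed, not modelled: a ramp from 2 m/s to
a 10 m/s cruise, and a braking flare once the lure has stopped and the
range is closing (speed tracks 3·range per second, rate-limited at
12 m/s², floored at 0.1 m/s). The cruise sits above the lure band so
capture is kinematically attainable, and the flare emulates the
deceleration of a landing grab: a constant-speed pursuer has a turn-radius
floor proportional to its speed and would otherwise orbit the stopped lure
outside the 30 mm capture radius. Crucially the steering law is applied
unchanged throughout — only the speed profile, which the fitter treats as
measured, is shaped — so refitting a noise-free synthetic flight
reproduces it exactly and the generating grid point is recovered exactly.

Capture is declared at the first 200 Hz frame within 30 mm of the lure, and
the recording keeps a 0.15 s "grab window" past first contact (the
intercept time, and the fitting window, end at first contact). Background-
PN is the one law that cannot steer an intercept under speed matching — it
carries no feedback on self-motion-induced heading error, the very reason
it fits real pursuit data poorly — so cohorts generated under it use the
closest-approach cropping mode (`require_intercept=False`).

What the generator does *not* emulate: vertical manoeuvres (constant flight
height), aerodynamics and wind, body roll/pitch in the marker geometry,
correlated or heteroscedastic mocap noise, marker-identity swaps, and the
post-grab dynamics of a real capture. Passing tests therefore demonstrate
the correctness and identifiability of the estimation machinery under the
stated noise model, not the behavioural conclusions one would draw from
real recordings.

## Preprocessing

Marker labelling: points confined to the same 10 mm box in ≥ 60 % of the
recorded frames are stationary apparatus (the fraction is counted over all
frames, since per-marker visibility is undefined for unlabelled clouds);
of the rest, points within 150 mm of the floor plane are lure markers, and
the remaining bird markers are matched to the rigid templates by within-
frame pairwise distances at 5 mm tolerance (full template first, then
3-subsets against the template's sub-triangles for one-marker occlusion;
multiple distinct matches mark the frame missing, conservatively).

Position estimation: by default the bird (backpack + tail-mount, treated as
one rigid body) and the lure are localised by planar rigid-body
registration — a backtracking search assigns measured points to template
offsets purely through distance consistency, then a 2-D Kabsch fit yields
the body origin. This keeps the reference point stable under partial
occlusion, whereas the plain centroid of identified markers (available via
`compute_centroids` without templates) shifts by tens of millimetres when a
template is incomplete. The template offsets are defined so the combined
body origin is the tracked reference point.

Cleaning: two passes of centered sliding-window (0.05 s, 11 frames) mean
elimination remove points more than 500 mm (extreme) and then 75 mm
(moderate) from the window mean; removed points become missing. Only frames
with a complete centered window are tested — the one-sided mean at a track
boundary lags a 10 m/s flight by more than the moderate threshold by
construction. The filter is idempotent on its own output.

Smoothing: interior gaps are filled by cubic interpolation; a degree-5
smoothing spline is then fitted per axis with the smoothing parameter set
so the root-sum-of-squares residual over frames does not exceed the
tolerance (0.03 m for the bird, 0.01 m for the lure, split evenly across
axes) — scipy's smoothing condition performs the smoothest-within-tolerance
search directly. Positions, velocities and accelerations are evaluated
analytically on a 20 kHz grid (configurable).

QC: flights are rejected unless the back template is reconstructed in more
than 50 % of frames and the bird comes within 30 mm of the lure at some
mutually visible frame; accepted flights are cropped to the first mutually
visible frame and truncated at the intercept, with time zeroed at the crop.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study pipeline at a dense
step of 1 ms (every τ-grid value remains an integer number of steps; the
simulator's default remains 20 kHz and the δ-conservation check runs at
20 kHz), with cohorts of 20 flights per law, a 228-flight cohort for the
12-fold cross-validation bookkeeping, and bootstrap sizes of 10²–10³ in
tests (production defaults 10⁶/10³). Euler integration is first order
(halving dt halves the endpoint error; verified). The delay is rounded to
the nearest integer step (error ≤ dt/2). Quantile interpolation in the
bootstrap uses numpy's default linear scheme. Random streams derive from
numpy's PCG64 via explicit seeds everywhere; identical seeds reproduce
courses, flights, resamples and folds bit-for-bit.

## Known limitations

* The simulator is planar; climbing or diving flight is outside scope.
* Identifiability of (N, K, τ) degrades on long stalled-lure endgames,
  where the error surface is nearly chaotic in the gains; the grid-seeded
  multi-start mitigates but slow per-flight fits on such flights remain the
  costliest operation.
* The rigid-registration correspondence search is exponential in the worst
  case; it is fast for the ≤ 8-marker bodies used here but not intended for
  dense marker sets.
* The background line-of-sight rate assumes the background feature lies at
  the target's distance; no distance-dependent parallax scaling is
  modelled.
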