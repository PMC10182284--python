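# Methods

## The measurement being modelled

A single F1-ATPase is fixed to a surface and a probe (a 40-nm gold
nanoparticle in the experiments this package targets) is attached to the
rotating γ shaft. A fast camera (250–10,000 frames per second) records
the probe centroid; its polar angle about the rotation centre, unwrapped
to a continuous degree scale, is the raw signal. The motor waits at
discrete angles (pauses) and jumps between them much faster than the
frame period, so the ideal trace is piecewise constant with additive
angular noise. Three pause classes matter here: ATP-binding waits,
catalytic waits, and short sub-pauses (including the temperature-sensitive
dwell of the thermophilic enzyme). A motor is a 3-, 6- or 9-stepper
according to how many distinguishable pauses it makes per 360° turn.

Angles are handled in degrees throughout (every threshold in the analysis
— 3° bins, 40° progressivity, 120° repeats — is conventionally quoted in
degrees). Counterclockwise is positive; mirrored movies must be flipped
upstream. The rotation centre for centroid data is the arithmetic mean of
all points; no ellipticity correction is attempted, since bulk statistics
used downstream (medians of long pauses) are insensitive to modest
eccentricity.

## Synthetic traces

`simulate.simulate_trace` draws dwell durations independently from
Exponential(mean_dwell) for each pause of the scheme, visits pauses in
cyclic order (repeat k at offset + 120k degrees), switches
instantaneously, and observes each frame as the current pause angle plus
white Gaussian noise. Defaults reflect the recording conditions the
analysis is designed for: 10,000 fps and 8° angular noise. The 8° figure
is a calibration choice for a 40-nm probe (no published value exists for
this setup); it is exposed on every scheme. Scheme presets encode the
three genuine motors: TF1 (catalytic dwell ~10 ms at 80° per repeat, a
~0.6 ms temperature-sensitive dwell at the binding angle), bMF1
(catalytic dwell with a ~1 ms short dwell midway between catalytic
angles at saturating ATPγS) and PdF1 (binding and catalytic waits at one
angle — a three-stepper).

What the generator deliberately does *not* model: probe relaxation after
a step (steps are instantaneous and noise is white, so there is no
autocorrelation), torque or viscous load, backsteps, ATP-concentration
dependence beyond the chosen mean dwells, and drift of the rotation
centre. Passing tests therefore demonstrate that the analysis chain
recovers the truth under its own stated assumptions — piecewise-constant
signal, exchangeable noise within a pause — not that it is robust to
correlated noise or drifting baselines in real recordings. Dwells shorter
than one frame may leave zero samples, so detectors must tolerate skipped
pauses, mimicking why very short dwells are practically unobservable at
low frame rates.

## Change-point detection

For a segment x₁…xₙ with mean x̄, CUSUM(t) = Σ_{t'≤t}(x_{t'} − x̄) and the
test statistic is its range D = max − min. Under the null (no change
point) the samples are exchangeable, so D is calibrated by uniform random
permutations of the segment; the add-one estimator
p = (1 + #{D_perm ≥ D_obs}) / (1 + n_perm) keeps p > 0. If p < α, the
change point is placed at the split k minimising the total squared error
about the left and right means (ties to the smallest k), and both halves
are examined recursively; recursion stops when the test fails or a
segment is shorter than 2·min_seg.

Defaults: n_perm = 1000, α = 0.01, min_seg = 5 frames. These are not
dictated by the method; they were chosen so that the downstream 7-point
interval filter is meaningful and a ~6-frame temperature-sensitive dwell
at 10 kfps remains detectable, while keeping the familywise spurious-CP
rate low on pure noise. All three are exposed in the config.

Two implementation notes:

* Permutations are drawn in vectorised batches from one seeded generator
  per trace, consumed in deterministic traversal order, so detection is
  bit-reproducible end-to-end.
* Inside the segmentation loop the permutation test stops early once the
  exceedance count already guarantees p ≥ α — the remaining permutations
  cannot change the accept/reject decision, only sharpen a p-value that
  is not used. The standalone `permutation_test` always completes all
  n_perm permutations and returns the exact estimator.

Power limit worth knowing: a short excursion (≲6 points) of 40° at the
edge of a long segment produces a D comparable to the null CUSUM-range
fluctuation of the segment, so its boundary can escape detection at
α = 0.01. In TF1-preset simulations, transitions flanked by ≥7 usable
frames on both sides are recovered within ±3 frames ≥95% of the time;
at 5-frame flanks recovery drops to ~92–95%. This mirrors the
experimental fact that very short dwells are borderline observable.

## Cleanup and the merge factor A

After detection, interval i is summarised by its median x̃ᵢ and median
absolute deviation MADᵢ (robust to outliers). The change point between
intervals i and i+1 is removed when |x̃ᵢ − x̃ᵢ₊₁| < A·(MADᵢ + MADᵢ₊₁);
the sweep runs left to right, merged statistics are recomputed from the
pooled samples, and passes repeat until stable. Whether the original
procedure recomputed MADs after each merge is not documented; we
recompute, which makes the merged summary self-consistent.

Choosing A: sweeping A upward and plotting the squared error between the
raw trace and the interval-median (denoised) trace shows a flat region —
spurious change points merging at negligible cost — followed by a sharp
rise when genuine steps start to merge; the right A sits just before the
rise. Two automatic rules are provided:

* `changepoint.select_A` works on the (A, error) curve alone and flags
  the first increment exceeding `rel_jump` (default 2%) of the *baseline*
  error. The increment is judged against the baseline rather than the
  curve's total range because the merge criterion cascades at large A
  (pooled MADs grow after each merge) until the whole trace collapses to
  one interval; the resulting astronomical final error would swamp any
  range-relative threshold and hide the onset of the rise.
* The pipeline's `_auto_select_A` additionally knows how many change
  points each grid step removed, and stops just before the first step
  whose error increment *per removed change point* exceeds k_sigma
  (default 50) times the per-frame noise variance, estimated as
  baseline error / trace length. Removing a spurious CP inside a pause
  costs O(σ²) per affected frame; merging a genuine step of size δ over
  m frames costs ~mδ² — two regimes separated by orders of magnitude
  regardless of trace length, which makes this rule scale-free. The
  factor 50 sits between the worst spurious merge (~10² deg²·frames for
  8° noise) and the cheapest genuine merge (a 7-frame, 40° sub-pause,
  ~10⁴ deg²·frames).

The default sweep grid is 0–5 in steps of 0.25. A manual override is
available in the config.

## Pause counting and the angular distance ratio

Each surviving interval contributes one count at its median angle mod
360° (so brief pauses register equally). Before counting, intervals
shorter than 7 frames are dropped, and an interior interval that sits
within 40° of its nearer temporal neighbour while the three consecutive
medians fail to increase strictly monotonically is removed as a backstep
or residual fluctuation; a genuine forward step of ≥40° on both sides,
or any progressive triple, is always kept, and the first/last intervals
are never removed (a backstep cannot be judged from one neighbour).

Significant peaks are found on the 3°-binned circular histogram: bins
below 5% of the tallest bin are treated as empty, and the occupied bins
are clustered by single linkage with a 20° circular gap; clusters with at
least max(2, 1% of intervals) member intervals are peaks. The occupancy
floor exists because a handful of leftover transition intervals (medians
midway between genuine pauses) would otherwise chain two peaks separated
by only 40° into one — single-linkage clustering on raw medians has zero
tolerance for stragglers, whereas the eye reading the histogram ignores
1-count bins next to 200-count peaks. All parameters (bin width, floor,
gap, member floor) are config-exposed. Per-turn analyses fold mod 360°,
preserving the per-turn presentation; mod-120° pooling of the threefold
symmetry is a trivial config change upstream if desired.

With six peaks per turn, the three alternating peaks carrying the larger
total occupancy (summed frame counts; ties broken by longer median
interval) are labelled main, the others sub. For each temporal
main→sub→main run of pause occurrences, a is the unwrapped distance from
the main's median to the sub's, b from the sub's to the next main's, and
the per-step ratio a/b uses per-occurrence medians so its spread reflects
trace variability. The mean ratio is reported after Tukey fencing
(outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]); the outlier rule is not specified
in the original analysis, and Tukey fences are the conventional default.
TF1 geometry (sub 40° after main) gives a/b ≈ 0.5; a midway sub gives
≈ 1.0. Mean ratios of different motors are compared by agglomerative
clustering with average linkage on |Δ mean ratio| — also a conventional
choice where none is documented.

Stepper classification is a pure rule: 3 pauses at the Km condition ⇒
3-stepper; ≥6 at Km with 6 at saturation ⇒ 9-stepper *candidate*; ≥6 at
Km with 3 at saturation ⇒ 6-stepper candidate. The saturating count is
evidence only — an extra sub-pause such as the temperature-sensitive
dwell lets a genuine 6-stepper show 6 pauses at saturation — so the final
call rests on the angular distance ratio.

## Kinetics

Michaelis–Menten fits are unweighted nonlinear least squares of
v = V_max·S/(K_m + S) (no weighting scheme is documented for the original
fits), initialised at V_max⁰ = max rate and K_m⁰ = the concentration
nearest half-max, with asymptotic standard errors. Catalytic efficiency
is k_on = 3·V_max/K_m: three ATP per turn converts rps to s⁻¹.

The quadratic composition model fits V_max/V̄ on the nine regressors
(V_α, V_β, V_γ, their three pairwise products and three squares) with no
intercept, where each variable is the genuine V_max of that subunit's
origin divided by V̄. V̄ is the *exact* mean (189 + 338 + 786)/3 =
437.666… rps, not the rounded 438 quoted alongside the model; using 438
instead shifts coefficients only in the third decimal (the encoding and
the response rescale by the same factor, so predictions in rps move by
≪1 rps), but the exact mean keeps the fit self-consistent. Fitting the
dimensionless response is required for the published coefficient scale:
evaluating the published coefficients at the all-bovine corner gives
≈1.80·V̄ ≈ 786 rps, confirming the normalisation. Standard errors use
σ̂² = RSS/(n − 9), i.e. 2 residual degrees of freedom for the 11-variant
table; the original SE convention is undocumented, so SEs are reported
but nothing downstream depends on them.

Lattice predictions cover all 27 origin triplets; a point is flagged
"interpolated" only when its encoded coordinates lie in the convex hull
of the observed compositions (Delaunay membership), since a quadratic
extrapolates poorly — this operationalises "surrounded by observed
values". The minimality check refits the model nine times with one term
dropped (reporting each RSS ratio against the full model) and once with
an intercept added (reporting the fitted constant, which should be ~0
relative to the dimensionless response scale ~1).

## Problem sizes and determinism

Simulation-based checks use 2–5 s traces at 10,000 fps (20k–50k frames,
hundreds of dwells) for test-suite runs and 20–30 s traces (200k–300k
frames) for the acceptance script's headline numbers; at these sizes a
trace holds enough pause occurrences (≥400) that counting and ratio
estimates are limited by method, not sampling. Every stochastic stage
consumes a sub-seed spawned deterministically from one master seed
(`numpy.random.SeedSequence`), so identical configs reproduce identical
artifacts byte for byte.

## Known limitations

* White-noise assumption: real probe noise is autocorrelated on the
  probe-relaxation timescale; the permutation null then overstates
  exchangeability and the detector will over-segment. An A-sweep cleanup
  absorbs mild violations but has not been validated against correlated
  noise.
* Pause counting assumes pause angles are stable within a molecule;
  slow drift of the rotation centre would smear histogram peaks.
* The 6-vs-9 stepper call is evidential, not decisive, by design.
* Sub-pauses shorter than ~7 frames are systematically under-detected
  (see the power limit above); at 10 kfps this corresponds to ~0.7 ms.
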