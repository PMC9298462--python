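# Methods

`reeftrack` reconstructs the spatial behavior of a reef fish from underwater
acoustic telemetry, end to end: a synthetic data generator stands in for the
field campaign, and the analysis chain — receiver clock synchronization,
difference-of-time-of-arrival (DToA) localization, trajectory quality
control and interpolation, home-range and occupancy estimation, trajectory
segmentation, and behavioral classification — is the package's subject.
This note records the models, the tunable parameters, the numerical
choices, and what the synthetic data do and do not establish.

## Movement and detection simulator

**Movement model.** A fish is a discrete-time (1-min) correlated random
walk switching among four behavioral modes — *scanning*, *dwelling*, *fast
ranging*, *slow ranging* — by a per-minute Markov chain (default
self-transition 0.995/min, i.e. mean bout ≈ 3.3 h, so most 30-min analysis
segments lie within one bout; off-diagonal mass is structured so the fish
settles into rest only from the adjacent foraging modes, never straight off
a patrol). Each step draws speed from a mode-specific AR(1) process
(stationary mean/SD per mode; the AR coefficient models cruising inertia)
and a turning angle from a von Mises distribution with mode-specific
concentration κ.

Behaviors are place-bound, as in real reef fish: each confined mode is
anchored to a habitual territory (a disc of mode-specific radius around a
fixed site). Entering the mode the fish commutes toward its territory at
25 m/min; inside, boundary crossings reflect specularly (position *and*
heading — a persistent walker must bounce, not stick). Fast ranging is an
*orbiting* mode: it patrols an elliptical circuit matched to the home
range's aspect ratio, with a tangential heading plus a radial correction
toward 0.85 of the patrol radius; with default values one patrol lap takes
roughly one 30-min segment. The whole walk is reflected into the
rectangular home extent (default 200 m × 50 m). At night the fish sits at
its fixed sleeping site plus ≤ 5 m Gaussian jitter; the daytime rest
(dwelling) territory coincides with the sleeping grounds, so dawn and dusk
involve no long commute. Depth is a
bounded random walk in 0–15 m.

No quantitative per-mode kinematics exist for wild *Siganus*-type reef
fish, so the default mode parameters are fixed plausible values chosen so
that each mode has a distinct multi-feature signature (speed, territory
size, tortuosity, speed persistence, place): the generator's purpose is
ground-truth recovery testing, which requires the four modes to be
distinguishable in principle from 30-min segments. Defaults (speed
mean±SD m/min, κ, territory radius m, AR coefficient): scanning 7±1.2,
0.3, 12, 0.3; dwelling 0.2±0.1, 0, 2, 0; slow ranging 11±1.5, 2, 30, 0.6;
fast ranging 15±2, 20, 90 (orbit), 0.9.

**Detection model.** Tags transmit every 10 s (optional uniform jitter).
Each moored receiver within the 70 m detection range logs a transmission
with probability 1 inside half the range, falling linearly to 0 at the
range, multiplied by 0.5 at night (acoustic clutter while fish rest on the
bottom). Arrival time = emission + distance / c + station clock error +
Gaussian timing noise (default SD 1 ms); c defaults to 1500 m/s and is
configurable everywhere. Station clocks carry an initial offset (SD 20 ms)
and a linear drift (SD 2·10⁻⁶ s/s). Receivers form an equilateral-triangle
lattice (default 60 m spacing) covering the home range plus a margin; sync
beacons are co-located with every third station and topped up until every
station hears a beacon *and* the co-detection graph is connected (otherwise
some clocks could never be chained to the reference).

**What the generator does not emulate.** No multipath or thermocline
propagation, no tag code collisions, no currents, no bathymetry. Real
behavioral repertoires are continua; the generator produces four discrete,
place-anchored modes by construction. Passing the recovery tests therefore
shows the analysis chain is correct and sensitive under conditions where
the answer is knowable — not that four classes exist in any real fish.

## Clock synchronization

Within fitting windows (default 900 s), travel-time-corrected beacon
arrivals give one linear equation per co-detection (offset difference
between two stations); the per-window least-squares system is solved with
the reference station (nearest the array centroid) pinned to zero, each
pair weighted by √(number of co-detections). Stations not chained to the
reference in a window are left unsolved and interpolated across windows;
stations never hearing any beacon are flagged and excluded downstream.
Offsets interpolate linearly between window midpoints and extrapolate
linearly at the edges — that is what tracks drift. Beacons transmit every 30 s in the
pipeline defaults; their transmissions are grouped with a 10 s time gap, deliberately large because relative
clock offsets grow to seconds over weeks of drift.

## DToA localization

Detections are clock-corrected and grouped into transmissions by
single-linkage time clustering (gap = array span / c + 6 timing SDs).
Groups heard by ≥ 3 non-collinear receivers are localized by minimizing

e(x) = Σ over receiver pairs (i,j) of |(tᵢ − tⱼ) − (|x − rᵢ| − |x − rⱼ|)/c|

on a horizontal grid (default 1 m spacing over the station bounding box
inflated by 50 m) at the tag-reported depth; the sum of absolute pairwise
residuals was chosen over squares for robustness (squares differ only in
weighting; the argmin is compared against a brute-force oracle in tests).
With three receivers only two independent DToAs exist and both
hyperbola-branch intersections fit the arrivals; the physical constraint
that every *detecting* receiver actually heard the tag (distance ≤ range +
10 m slack) enters as a quadratic penalty and removes the mirror solution.
The search runs coarse (5× spacing) to fine, restricted to cells within
range of all detecting receivers, then refines sub-grid by a 1-D quadratic
fit per axis (an exhaustive single-pass mode is kept for validation).
Exactly collinear stations are rejected rather than returning a
mirror-ambiguous fix. Under the default conditions the median horizontal
error is ≈ 1.6 m with ≈ 0.5% of fixes beyond 10 m.

## Trajectory preparation

Sunrise/sunset come from the standard NOAA solar-position equations
(−0.833° altitude) or an explicit override (the simulator uses a fixed
06:00–18:00 window). A day passes quality control iff every clock hour
fully inside the daytime window holds ≥ 30 fixes; accepted days are kept
as contiguous runs (trajectory analyses require runs ≥ 2 days; single days
remain usable for home-range summaries). The 30/hour rule counts daytime
hours only — night data are degraded by design — with an all-hours option.
Fixes are aggregated to one robust (median) position per 60 s bin, which
suppresses timing noise and the occasional badly localized fix at the cost
of a small bias at sharp turns, then x and y are linearly interpolated onto
the 1-min grid from sunrise to sunset; points outside the observed span
hold the nearest endpoint and are flagged `extrapolated`.

## Home range and occupancy

The home-range boundary is an alpha shape: Delaunay triangles with
circumradius above an alpha radius are discarded and the rest unioned. The
shrink factor maps onto the alpha radius on a log scale between the largest
circumradius (shrink 0: the convex hull) and the smallest radius that keeps
a single connected region containing every point (shrink 1); 0.5 is the
default. This intrinsic parameterization replaces the internals of the
originating implementation, which are not public; it preserves the
endpoints and monotonicity. A kernel (utilization-distribution) range is
provided for comparison: a Gaussian KDE on a grid, polygonizing the contour
that encloses the requested probability mass (default 95%; bandwidth is the
caller's, conventionally a few meters here).

Occupancy maps deposit one minute per 5 m × 5 m bin, smoothed with a
truncated Gaussian (σ = 2.5 m, 6σ support on a padded grid, renormalized so
total dwell time is conserved exactly); the display layer is
log₁₀(smoothed + 10⁻³). Range stability is the intersection-over-union of
the boundary polygons of the first and last k tracked days (default 3).
The sleeping site is summarized as the geometric median of nighttime fixes
(Weiszfeld iteration) with the 95th-percentile radius.

## Segmentation and features

Daily trajectories are cut into 30-min windows starting every 15 min from
sunrise (50% overlap; a trailing partial window is dropped). Each segment
yields 13 features: net displacement D, path length L, straightness
S = D/L, convex-hull area A, median per-minute speed MS, distance ρ of the
segment centroid from the fish's global center (the coordinate-wise median
of all its positions, computed per fish), directional autocorrelations
DAC5/DAC10 (mean cosine of heading change at 5- and 10-min lags; steps
shorter than 0.5 m — below the localization error scale — carry no defined
heading and are skipped, with 0 imputed when fewer than 5 valid pairs
remain), speed autocorrelations SAC5/SAC10 (Pearson autocorrelation of the
per-minute speed series; 0 when variance vanishes), day phase DP (segment
midpoint, normalized sunrise→sunset), bearing cosine θ of the centroid from
the global center (east = 0), and focus F = 1 − 4A/(πL²). Motionless
segments take S = 0, F = 1, MS = 0 (maximally non-ranging, maximally
focused); degenerate hulls take A = 0. Features are made unit-free by
dividing each column by its sample SD (zero-variance columns are zeroed
and flagged); centering happens inside PCA.

## Classification

Per fish (each fish is clustered separately; pooling is available), the
scaled features are reduced to the first 4 principal components of the
centered covariance (sign fixed so each component's largest-magnitude
loading is positive — the pipeline is fully deterministic), then clustered
by Ward agglomeration on Euclidean distances (single/average/complete
selectable). The tree is cut with a merger-score rule: merge-height
increments are normalized by the total merging cost (the sum of all merge
heights) and the cut is placed at the first increment, scanning bottom-up,
exceeding the threshold (default 1.5%). This operationalization was chosen
because, among the threshold rules consistent with the verbal description,
it is the one that recovers the true cluster count on reference data
(well-separated Gaussian blobs at every threshold in 1–3%; a single blob
stays at 1–3 classes). Every cut carries a sensitivity report over
{1%, 1.5%, 2%, 3%}. On the default synthetic conditions the 1% and 1.5%
thresholds recover the four modes; the stricter 2–3% thresholds can
collapse to two classes, because sampling noise in 30-point feature
estimates bounds the attainable cluster separation (see limitations).

A four-class partition is auto-named by kinematics — dwelling: lowest
median speed; fast ranging: highest; of the remaining two, the larger net
displacement is slow ranging, the other scanning — and an optional,
explicit list of class merges (the reviewable analogue of manual
over-split correction) can coarsen the partition; naming never changes the
partition. Class occupancy weights every daytime minute equally across the
(up to two) overlapping segments covering it, so per-fish-day fractions sum
to one despite the 50% overlap; stability is the standard error of
per-class fractions across consecutive 4-day groups.

## Problem sizes and determinism

The default study conditions are 3 fish × 14 days (≈ 121 000 transmissions
and ≈ 650 daytime segments per fish); all randomness flows from one seed
through `numpy` SeedSequence spawning, and rerunning a configuration
reproduces byte-identical outputs. The full pipeline takes a few minutes
on one core; the acceptance script additionally runs a 500-transmission
localization benchmark and the clock-recovery benchmark.

## Known limitations

- With three receivers the mirror ambiguity is broken only by the
  detection-range constraint; fixes just outside the array can still be
  displaced along the constraint boundary (≈ 0.5% of fixes beyond 10 m
  under default noise).
- The robust 60-s median aggregation biases interpolated positions by a
  few meters at sharp turnarounds of fast travel.
- The 13 features are 30-point sample statistics; their sampling noise
  (notably the lag-5/10 autocorrelations and the day phase, which carries
  no class signal under a time-homogeneous switching policy) sets a floor
  on within-class scatter. That floor is what limits the merger-score
  cut's stability at thresholds well above the default 1.5%.
- Alpha-shape areas depend on the fix density at the range margin;
  kernel/alpha agreement is asserted only as an overlap bound (IoU ≥ 0.5),
  not area equality.
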