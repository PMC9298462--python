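# reeftrack

Analysis pipeline for underwater acoustic telemetry of reef fish: from raw
receiver detection logs to home ranges, occupancy maps, and behavioral
classes. It is aimed at movement ecologists (and field neuroscientists
choosing a tracking-friendly model animal) who track individual fish with
implanted acoustic tags — transmitting every 10 s, audible to ~70 m — on a
fixed array of moored receivers, and who want the entire analysis chain
reproducible and testable without field data: a built-in simulator
generates ground-truth fish movement and the detection logs an array would
record.

## What it computes

1. **Clock synchronization.** Stationary sync beacons at known positions
   let per-receiver clock offsets (including drift) be estimated by
   windowed least squares and removed.
2. **DToA localization.** A transmission heard by ≥ 3 receivers is located
   by minimizing the summed pairwise difference-of-time-of-arrival error
   e(x) = Σ₍ᵢⱼ₎ |(tᵢ − tⱼ) − (|x − rᵢ| − |x − rⱼ|)/c| on a grid at the
   tag-reported depth, with the detection range as a physical constraint
   against mirror solutions.
3. **Trajectory preparation.** Days pass quality control when every full
   daytime hour holds ≥ 30 fixes; accepted days are interpolated to a
   regular 1-min sunrise-to-sunset track (NOAA solar windows or explicit
   times).
4. **Home range.** Alpha-shape boundary around the fixes (shrink factor
   0.5; shrink 0 = convex hull), kernel utilization-distribution range for
   comparison, 5 m × 5 m dwell-time occupancy grid smoothed with a
   σ = 2.5 m Gaussian (log₁₀ display), first-vs-last-days boundary overlap
   (stability), and a nighttime sleeping-site summary.
5. **Behavioral classes.** Daily tracks are cut into 30-min segments with
   50% overlap; each segment yields 13 geometric/temporal features
   (D, L, S = D/L, A, MS, ρ, DAC5, DAC10, SAC5, SAC10, DP, θ,
   F = 1 − 4A/(πL²)); features are SD-scaled, reduced to 4 principal
   components, Ward-clustered, cut with a 1.5% merger-score rule (with a
   threshold sensitivity report), and the classes named by their
   kinematics: *scanning*, *dwelling*, *fast ranging*, *slow ranging*.

The models, parameter defaults, and numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered drivers under `analysis/` chain through `results/`:

```sh
python analysis/01_simulate.py --seed 1      # fish + array + detections
python analysis/02_localize.py               # clock sync + DToA fixes
python analysis/03_prep.py                   # QC + 1-min interpolation
python analysis/04_homerange.py              # boundaries, occupancy, sleep
python analysis/05_features.py               # 30-min segment features
python analysis/06_cluster.py                # PCA + clustering + classes
```

With the default conditions (3 fish × 14 days in a 200 m × 50 m home
range) this prints, per stage (abridged):

```
simulated 3 fish x 14 d: 778783 tag detections at 24 stations, 11 sync beacons
148753 fixes from 778783 detections (0 stations unsynchronizable); median residual 0.21 ms
F1: 14/14 days pass QC, runs [[0, 1, ..., 13]]
F1: range 186 x 64 m, boundary 10627 m2 (kernel 12146 m2, IoU 0.83);
    first/last-days IoU 0.93; sleeping site (-80.0, -15.0) r95 4.3 m
F1: 658 segments over 14 days; median speed quartiles [ 0.7  4.2 11.7] m/min
F1: 4 classes at 1.5% (sensitivity {0.01: 4, 0.015: 4, 0.02: 2, 0.03: 1});
    73% variance in 4 PCs; time shares {'dwelling': 0.47, 'fast_ranging': 0.26,
    'scanning': 0.15, 'slow_ranging': 0.12}
```

Reading the numbers: the array localizes ~150 k transmissions with
millisecond residuals; every day passes the 30-fixes/hour rule; the
reconstructed home range matches the simulated 200 m × 50 m extent, its
boundary is stable over time (first-vs-last-days overlap 0.93) and agrees
with the kernel estimate (IoU 0.83); the fish sleeps within ~4 m of one
site every night; and the segment classifier recovers exactly the four
movement modes the simulator generated, with each fish showing its own
division of the day among them.

The same computations are importable from the `reeftrack` package
(`reeftrack.simulate`, `.localize`, `.prep`, `.homerange`, `.features`,
`.cluster`), and `reeftrack.run_pipeline(PipelineConfig(seed=1))` runs the
whole chain in memory with one seed controlling all randomness.

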