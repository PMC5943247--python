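# Methods

This note documents the models and algorithms implemented in `qsmlm`,
the defaults chosen where the design was open, and what the synthetic
benchmarks do and do not establish.

## Localization tables

All coordinates are stored internally in nanometres as floating point;
frame indices are 1-based and time zero is the start of frame 1, so a
detection in frame f occurred at t = (f − 1) × frame_time. The default
frame time is 60 ms, the camera exposure used in the acquisitions this
toolkit targets. Unit conversion happens once at the file boundary:
pixel-unit dialects (QuickPALM-style tables) require the camera pixel
size in nm and are converted on read.

Dialect auto-detection is by exact header match only. An ambiguous or
unknown header is an error, never a guess — silent misparsing of a
localization table corrupts every downstream statistic. An explicit
`column_map` always overrides detection.

Rectangle ROIs are half-open, `[min, max)` on both axes, so a tiling of
rectangles partitions a point set exactly. The native CSV writer
quantizes values to 1e-4 nm (0.1 pm, far below any localization
precision), which makes write → read an exact identity and repeated
round trips idempotent.

## Rendering

Each localization contributes a unit-mass isotropic Gaussian whose σ is
its localization uncertainty, or a fixed σ (default 20 nm, a typical
PALM localization precision) when uncertainties are absent. Kernels are
integrated analytically over each rendered pixel (difference of error
functions per axis) rather than point-sampled, and truncated at 4σ; the
rendered grid pads the point-cloud bounding box by the full truncation
radius. Consequently the image integral equals the number of rendered
localizations to within the truncation loss of 0.013%, independent of
σ and pixel size. The default rendered pixel is 20 nm. Unit mass per
localization (rather than per photon) is deliberate: the time-correlated
analysis treats every localization equally, and rendering is kept
consistent with it.

Note that the per-pixel *integrated* value differs from the Gaussian
density times pixel area by a curvature term of order
2 (p/σ)²/24 at the peak; tests that compare against the closed-form
density therefore use σ ≥ 4 rendered pixels.

## Spatial clustering

**DBSCAN.** A point is a core point when at least `min_pts` points
(counting itself) lie within `eps`. Clusters are the connected
components of core points linked within `eps`; a non-core point within
`eps` of a core point is a border point and joins the cluster of its
lowest-index core neighbour; everything else is noise. The border rule
is the one ambiguity in the textbook definition, and pinning it to the
lowest-index core neighbour makes the partition deterministic and
independent of input order. Neighbour queries use a k-d tree (expected
O(n log n)). Defaults eps = 100 nm, min_pts = 10 suit clusters a few
tens of nm across against sparse background; both are surfaced
everywhere.

**Centroid-linkage sequential recombination.** Jet-style
agglomeration: repeatedly merge the pair of clusters whose centroids
(unweighted means of member localizations) are nearest, until the
minimum inter-centroid distance exceeds the cutoff R; clusters with
fewer than `min_count` members (default 3, below which a hull area is
degenerate) are then discarded as noise. Ties are broken by the
lexicographically smallest cluster-id pair. The implementation keeps a
slot-reuse distance matrix with incremental row updates (O(n²) memory,
O(n² · merges) worst-case scan), which is exact and fast for the
10²–10³-point regions this analysis targets; it is not intended for
millions of points.

**Summaries.** Cluster area is the convex-hull area. The choice is
deliberate: the hull is deterministic and parameter-free, whereas
alpha-shapes would introduce a free parameter into a quantity reported
per cluster. Clusters with fewer than 3 non-collinear members report
area 0. Cluster size for survival curves is the localization count, not
the area.

**Pair correlation.** g(r_k) = W_k / (λ n a_k) on half-open radial bins,
with W_k the ordered pair count, λ = n/|window| and a_k the annulus
area. Edge correction is by translation on the rectangular window
(minimum-image/toroidal distances), which is exactly unbiased under
complete spatial randomness; an uncorrected mode is available and is
biased low at large r. r_max is limited to half the shorter window side,
the validity limit of the minimum-image convention.

## tcPALM

A region's time trace is its per-frame detection count over the full
acquisition (an empty region gives an all-zero trace of full length,
not an error). Optional boxcar smoothing is display-only and rescaled
to conserve the total count.

**Burst detection.** The centred moving-average rate (window default 50
frames = 3 s) is thresholded and maximal above-threshold runs become
bursts; runs separated by less than `min_gap` (1 s) merge, and runs
carrying fewer than `min_burst` (10) localizations are dropped. The
threshold has two regimes:

- *sparse* — the trace is quiet most of the time: background is the
  median windowed rate (robust to the burst itself), floored at one
  detection per window, and a burst frame must exceed it by
  `rate_threshold_factor` (3) standard errors of the windowed mean,
  i.e. threshold = b + 3·√(b/w). For a Poisson background this is a
  z-test per frame.
- *dense* — the median itself exceeds the detectability floor
  (3/window): the trace is active for most of the acquisition, the
  median measures activity rather than background (on merged 0/1
  traces it can sit near saturation, where no frame can stand out
  against a multiple of it), and bursts are the runs above the absolute
  floor. A uniformly active trace is then a single burst from t = 0.

**Classification.** A burst is *transient* iff its onset exceeds
`onset_delay_threshold` (5 s) **and** its lifetime is below
`plateau_fraction` (0.5) of the acquisition; otherwise *stable*. The
two conditions encode the two signatures: a stable cluster produces
detections from t = 0 (it pre-existed) with a gradual plateau driven by
fluorophore-pool depletion on the photoactivation timescale, while a
transient cluster shows near-zero counts, a delayed abrupt rise, and an
abrupt stop. When a spatial cluster's trace contains several bursts,
the *earliest* detected burst decides the class: the distinction is
about presence at acquisition start, and the decaying stream of a
stable cluster can fragment into several late runs whose largest
fragment is uninformative.

Per-cluster regions are derived automatically from a spatial
clustering (bounding box padded by 100 nm) or supplied manually.
Lifetime histograms and transient fractions are computed over
classified bursts; a single-burst lifetime sample reports SEM 0 with a
degeneracy flag.

Converting burst sizes (localization counts) into molecule numbers is
explicitly out of scope: single-molecule photophysics makes that
mapping non-trivial, and no such conversion is attempted anywhere.

## Photophysics model

States {1 pre-converted, 2 fluorescent, 3 dark, 4 bleached}; the
discrete-time transition matrix is given in the README. Default rates
(1/s): k_on = 1/43, k_dark = 9.61, k_rec = 2.33, k_bleach = 3.0;
Δt = 6 ms; camera bins of 60 ms (10 steps). All molecules start
pre-converted; state 4 is absorbing. Validation rejects any Δt that
would make a matrix entry negative, naming the offending rate.

The chain is simulated exactly as the discrete matrix (one uniform per
molecule per step, partitioned per the matrix row) rather than as the
continuous-time process; fidelity to the published discrete scheme was
preferred over Gillespie sampling, and at these rates the Δt = 6 ms
discretization error is far below the statistical noise of any
realistic ensemble. Per camera bin, a molecule is *detected* if it was
fluorescent at any step of the bin. With the single-spot merge rule
(default for clusters), simultaneously detected molecules contribute
one localization; the non-merged per-bin molecule count serves
diagnostics and spatially extended regions — in particular whole-field
traces, where spots do not overlap and a merged 0/1 trace would
saturate and destroy rate information. Transient clusters are emulated
by zeroing detections outside a temporal window, leaving the
photophysics untouched.

**Activation-rate fit.** Nonlinear least squares of the cumulative
trace against N(t) = N₀(1 − e^(−k_on t)) + B t, initialized with
N₀ = max N, B = terminal slope, k_on from the half-maximum time;
relative tolerance 1e-8. B ≥ 0 is enforced by default: the linear term
models a nonnegative background rate, and leaving it unconstrained
opens a flat ridge where a negative slope compensates a slower
exponential, inflating 1/k_on by up to ~18% on background-free traces.
An unconstrained mode is available and warns when B < 0. On simulated
5000-molecule, 300 s whole-field acquisitions the constrained fit
recovers 1/k_on within ~8% (43–46.5 s across seeds); the small upward
tendency comes from each molecule's detections trailing its activation
by the ~2 s blinking epoch, which the fit model does not represent.

## Synthetic scenes

A scene is a rectangular field (default 5 × 5 µm) imaged for 5000
frames of 60 ms (300 s). Background localizations are completely
random in space with a Poisson count per frame (default 0.2/frame —
sparse, as in nuclear regions away from clusters). Each planted cluster
scatters immobile molecules around its centre (Gaussian σ = 50 nm),
runs the photophysics chain per molecule, applies the single-spot merge
per frame (the emitting molecule is drawn uniformly among those
fluorescent), and adds fresh localization noise (σ = 20 nm) per
detection. Stable clusters use 50 molecules; transient clusters use 200
within windows starting uniformly in [10, 60] s with exponential
lifetimes of mean 8.7 s (floored at 3 s) — the larger molecule pool
reflects what a transient cluster is: a sudden recruitment of many
molecules to one locus, producing bursts of tens of localizations in
seconds, not a handful.

The generator is byte-deterministic given the spec (including its
seed). Ground truth records each localization's source and each
cluster's class and window, and `scene_report` scores an analysis
point-wise by majority-label matching (precision/recall), per-cluster
classification accuracy, and onset/lifetime errors.

What the scenes do **not** emulate: molecular diffusion and cluster
drift, stage drift, detector noise and localization-precision
heterogeneity, variable activation laser power, multiple emitters
mis-localized as midpoints, and 3-D structure. Passing the benchmarks
therefore demonstrates correctness of the analysis chain under the
stated generative model, not robustness to every artifact of real
acquisitions.

## Numerical and degenerate-input conventions

- Empty tables cluster to empty labelings; an empty ROI yields a zero
  trace; a localization-free trace yields no bursts. Errors are
  reserved for genuinely undefined requests (survival curve of zero
  clusters, g(r) of fewer than two points, lifetime histogram with no
  transient bursts).
- Coincident points merge at distance 0 first in the linkage; collinear
  clusters have hull area 0.
- All stochastic operations take an explicit seed; identical seed and
  parameters give identical output.
- Histogram and rendering bins are half-open; a value on an edge
  belongs to the upper bin.

## Benchmark problem sizes

The test suite runs the clusterer-versus-brute-force comparisons on 200
random scenes of up to 300 points (DBSCAN) and 100 scenes of up to 100
points (linkage); the pipeline benchmark uses 20 scenes of 10 clusters
each at the full 300 s acquisition; the ensemble-occupancy checks use
10,000 trajectories. These sizes give the oracle comparisons full
coverage of the combinatorics (ties, border points, noise-only scenes)
and the stochastic checks 3σ resolution well below the asserted
tolerances, while keeping the whole suite around three minutes on one
core.
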