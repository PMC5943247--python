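# qsmlm

Quantitative analysis of single-molecule localization microscopy
(PALM/STORM) data from living cells, with an emphasis on the *temporal*
structure of protein clusters.

A live-cell super-resolution acquisition yields a pointillist table of
localizations — one row per detected fluorophore, with position (nm) and
camera frame. Spatial statistics alone cannot tell a long-lived protein
assembly from one that formed and dissolved during the movie. This
package provides both halves of the analysis:

- **Spatial**: super-resolution image reconstruction (Gaussian kernel
  rendering), density-based clustering (DBSCAN), jet-style
  centroid-linkage sequential recombination clustering, per-cluster
  summaries (counts, convex-hull areas, radii of gyration), cluster-size
  survival curves, and the pair-correlation function g(r) with toroidal
  edge correction.
- **Temporal (tcPALM)**: per-ROI detection time traces, burst detection
  against a Poisson background model, and classification of each
  cluster as **stable** (localization stream from acquisition start that
  gradually plateaus as the photoconvertible-fluorophore pool depletes)
  or **transient** (a delayed, abrupt burst that ceases abruptly —
  assembly and disassembly in real time).
- **Photophysics simulation**: a 4-state discrete-time Markov model of a
  green-to-red photoconvertible fluorophore (pre-converted →
  fluorescent ⇄ dark, fluorescent → bleached), used to generate
  synthetic tcPALM acquisitions and to verify that observed transient
  signatures cannot be produced by single-molecule blinking alone.
- **Ground-truth scenes**: a generator that plants stable and transient
  clusters with known positions, windows and photophysics over a
  completely-spatially-random background, so every analysis step can be
  scored against truth.

## The models

**Photophysics.** Each fluorophore moves through states
{1 pre-converted, 2 fluorescent, 3 dark, 4 bleached} with per-step
(Δt = 6 ms) transition matrix

```
T = | 1-k_on Δt   k_on Δt                0          0         |
    | 0           1-(k_dark+k_bleach)Δt  k_dark Δt  k_bleach Δt|
    | 0           k_rec Δt               1-k_rec Δt 0         |
    | 0           0                      0          1         |
```

with defaults k_on = 1/43 s⁻¹, k_dark = 9.61 s⁻¹, k_rec = 2.33 s⁻¹,
k_bleach = 3.0 s⁻¹. Simulated detections are binned into 60 ms camera
exposures; within one diffraction-limited cluster, simultaneously
fluorescent molecules merge into a single localization per bin.

**Activation-rate estimation.** The cumulative localization count of a
whole-field trace is fitted with

    N(t) = N₀ (1 − exp(−k_on t)) + B·t,   B ≥ 0

giving the photoactivation rate k_on (the B·t term absorbs a constant
background).

**Burst detection.** The windowed localization rate is compared with the
trace's median rate plus a multiple of its Poisson standard error; runs
of elevated rate are merged across short gaps and filtered by a minimum
burst size. A burst is *transient* when its onset is delayed
(> 5 s by default) **and** its lifetime is shorter than half the
acquisition; otherwise the cluster is *stable*.

## Worked example

```python
import qsmlm as q

# simulate a whole-nucleus acquisition and recover the activation rate
trace = q.simulate_cluster_trace(q.DENDRA2, n_molecules=5000,
                                 acquisition_s=300.0, merge=False, seed=1)
fit = q.fit_activation_rate(trace)
print(f"recovered 1/k_on = {fit.tau:.1f} s  (N0 = {fit.N0:.0f}, B = {fit.B:.3f}/s)")

# generate a ground-truth scene and run the full pipeline
table, truth = q.generate_scene(q.reference_scene(seed=42))
labels = q.DBSCANClusterer(eps=100, min_pts=10).fit(table).labels_
dyn = q.cluster_dynamics(table, labels)
frac_t, frac_s, n = q.transient_fraction(
    [d["burst"] for d in dyn if d["burst"] is not None])
print(f"{n} clusters: {frac_t:.0%} transient, {frac_s:.0%} stable")
rep = q.scene_report(truth, labels, [d["classification"] for d in dyn],
                     [d["burst"].onset if d["burst"] else None for d in dyn])
print(f"classification accuracy vs ground truth: {rep.classification_accuracy:.2f}")
```

prints

```
recovered 1/k_on = 43.1 s  (N0 = 46103, B = 0.000/s)
10 clusters: 70% transient, 30% stable
classification accuracy vs ground truth: 1.00
```

The recovered time constant matches the 43 s used to generate the
simulation; the scene planted 7 transient and 3 stable clusters, and
the pipeline recovered both the spatial clusters and their temporal
classes.

## Command line

Every analysis is also a `qsmlm` subcommand operating on CSV files
(ThunderSTORM, QuickPALM-style pixel tables, or the native
`x_nm,y_nm,frame,sigma_nm,intensity` format):

```sh
qsmlm synth --seed 42 --out scene.csv --truth truth.json
qsmlm cluster scene.csv out --method dbscan --eps 100 --min-pts 10
qsmlm tcpalm scene.csv tc --roi 2000 3000 2000 3000
qsmlm render scene.csv scene.png --colormap redhot
qsmlm paircorr scene.csv g.csv --bin 25 --rmax 500
qsmlm simulate trace.csv --n-molecules 50 --duration 300 --seed 7
```

Each run writes a `.provenance.json` beside its output recording the
package version, parameters, seed and input checksums.

## Scope

The package consumes localization tables; raw-movie spot detection and
localization, drift correction, 3-D localization, and conversion of
detection counts into absolute molecule numbers are out of scope.

See `docs/methods.md` for the full description of the models, defaults
and limitations.
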