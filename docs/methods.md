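# Methods

## The in silico community procedure

Each axenic culture is measured separately by FCM, so its events carry an
implicit taxon label. The pipeline is:

1. **Gating.** Events are denoised by a fixed simple polygon in the
   arcsinh(FL1-H) × arcsinh(FL3-H) plane (cofactor 1, i.e. plain
   `arcsinh(x)`). The same gate instance is applied to every replicate of a
   culture, and gating happens *before* replicates are pooled. Events
   exactly on the polygon boundary count as inside — cytometry tools
   conventionally include boundaries, and a fixed convention is required for
   determinism. Real per-culture gate vertices are configuration inputs; the
   built-in default is the rectangle `[1, 20]²` in transformed coordinates,
   which separates stained cells from the low-fluorescence debris corner.
2. **Community construction.** An even community subsamples
   `N_ax = 5,000` events per taxon uniformly **without replacement** from
   each pooled sample (`N_tot = S × N_ax`). Gradients hold 10,000 cells per
   level at the 13 default levels 1, 5, 10, 20, …, 90, 95, 99%; the
   first-taxon count is round-half-even(`p₁·n_total`) with the remainder
   assigned to the second taxon, so totals are exact.
3. **Split.** 70% train / 30% test, **stratified by taxon** (per taxon,
   `round(0.70 · n_i)` to train). Stratification prevents composition drift
   in small communities; plain random splitting would add noise without any
   benefit to the comparison.
4. **Classification.** LDA (shared-covariance Gaussian classes) and a
   random forest (200 unpruned gini trees on bootstrap samples,
   `floor(sqrt(K)) = 3` of the K = 12 channels per split). Features enter
   **raw** — no standardization or transform — because tree splits are
   monotone-invariant and LDA is affine-equivariant, and because that is how
   acquisition software exports the data; an arcsinh feature option exists in
   the preprocessing layer for users who want it. LDA uses the eigen solver
   with shrinkage `1e-6` (a ridge of 1e-6 × mean eigenvalue) purely for
   numerical stability on near-degenerate channels.
5. **Composition and diversity.** The plug-in estimator converts predicted
   labels to proportions. The Hill number `D1 = exp(−Σ pᵢ ln pᵢ)`
   summarizes evenness; instrument error is propagated as below.

## Error propagation into D1

A relative abundance is a ratio of two independently measured cell counts,
each with relative instrumental error `ε_I` (default 0.05, the conventional
upper bound for FCM counting), giving `σ²_p = 2 ε_I² p²`. First-order
propagation through D1 yields

```
σ²_D1 = D1² Σᵢ (ln pᵢ + 1)² σ²_pᵢ
```

with the conventions `0·ln 0 := 0` and the `pᵢ = 0` term skipped (its limit
is 0). A term also vanishes at `pᵢ = 1/e`. For S = 2 this reduces exactly to

```
σ²_D1 = 2 ε_I² D1² [p₁²(ln p₁ + 1)² + (1−p₁)²(ln(1−p₁) + 1)²].
```

Confidence intervals assume approximate normality of D1: z = 1.0 for the
68% band and z = 1.96 for 95%. Monte-Carlo simulation under the assumed
error model (each pᵢ perturbed by independent numerator and denominator
count errors of 5%, D1 recomputed on the unnormalised vector) gives 95%-CI
coverage of 0.948–0.949 at p₁ = 0.3 with 10,000 draws. The linearization
degrades as any pᵢ → 0 or 1, where D1 is pinned at a boundary; near-boundary
CIs should be read as indicative only. Note the factor 2 presumes the
numerator and denominator counts are measured independently; if the total is
the *sum* of the population counts, the errors correlate and the true
variance at moderate p is roughly half, making these intervals conservative.

## The synthetic-data generator

The generator emulates SYBR-Green-stained bacterial populations on a
12-parameter panel. Design choices:

* **Event model.** 1–3 Gaussian components per population in arcsinh space,
  where real stained clouds are roughly elliptic. Height channels get the
  cloud location (defaults: FL1 6.5, FL2 5.5, FL3 5.2, FL4 4.6, FSC 7.5,
  SSC 7.0 arcsinh units; SD 0.45); area channels are their height channel
  plus an offset of 0.5 (raw A/H ratio ≈ 1.65) plus independent noise
  (SD 0.15), encoding the strong A–H correlation of real data. Draws are
  back-transformed through `sinh` and clipped at zero. The optional second
  mixture component (weight 0.25, +0.3 shift in scatter) stands in for
  cell-size/cell-cycle substructure.
* **Replicate drift.** One additive shift (SD 0.05) and one multiplicative
  scale (SD 0.02) draw per replicate in arcsinh space, shared by all events
  of the replicate. Within a panel the draw is shared by **all taxa of the
  same replicate index**: drift models the instrument/staining state of a
  measurement run, which samples acquired together experience jointly. A
  separate `drift_seed` re-measures the same panel under fresh conditions
  (the `--fresh-batch` CLI flag), emulating cultures re-grown and re-measured
  on another day.
* **Debris noise.** A diffuse component centered at 0.3 arcsinh units in the
  fluorescence channels (≈ 99% of its mass below the default gate threshold
  of 1), mixed in as a Binomial(n, fraction) share of each file (default
  fraction 0.05). Debris flags live in the returned masks and the manifest;
  the event files themselves look unlabeled, as acquired data would.
* **Separability presets.** Pairs shifted symmetrically on FL1/FL3 by
  0.40 / 0.85 / 1.80 arcsinh units ("low" / "medium" / "high"), calibrated
  once against the reference RF configuration on an even 10,000-cell
  community (calibration seed 20170125) to land at held-out accuracies of
  ≈ 0.72, ≈ 0.90 and ≈ 0.995, and then frozen. `identical_pair()` provides
  the no-signal limit (two taxa from one distribution).

What the generator does **not** model: staining chemistry, optical
saturation, doublets/aggregates, non-Gaussian tails, or the true
distributions of any particular organism. Green tests therefore demonstrate
that the statistical machinery (gating, subsampling, training, estimation,
propagation) is correct and well-calibrated on data with known structure —
not that any particular accuracy will be reached on a given real panel.

## Numerical and design notes

* **Seeds.** Every stochastic operation takes an explicit seed; experiment
  runners derive per-task seeds by SHA-256 hashing of (root seed, task
  tokens), truncated below 2³¹. Result tables are byte-identical across
  reruns with the same root seed.
* **Combination enumeration.** All `C(n, S)` combinations are returned when
  they fit the cap (default 150 per richness increment); otherwise a uniform
  distinct sample. Tuples are internally sorted; sampling is seeded.
* **Gradient vs training draws.** The gradient is the test set, so the
  classifier trains on the *full* even community (no held-out split).
  Training draws and gradient draws come from disjoint pool events whenever
  the pool is large enough (training events are drawn first, gradient levels
  from the remainder); with `--fresh-batch` the gradient instead comes from a
  re-measured panel.
* **Tie-breaking.** Score ties resolve to the first class in lexicographic
  taxon order (argmax convention), keeping predictions deterministic.
* **Multiclass accuracy.** The headline metric is the fraction correct; the
  macro tp/tn form is implemented as a cross-check only, since for S > 2 it
  counts true negatives and systematically exceeds the fraction correct. AUC
  is computed for S = 2 only. The "68% band" of the richness scan is the
  mean ± 1 SD of per-community accuracies — an empirical spread band, not a
  standard error of the mean.
* **Problem sizes.** Full-protocol sizes (5,000 cells/taxon, 10,000-cell
  gradient levels, 200 trees) are used wherever a quantity is quoted; the
  richness-scan demonstrations use 10 taxa with 1,500 cells/taxon and 4
  communities per S, and quick orchestration tests use a few hundred cells —
  sizes chosen so the full suite exercises every code path at comfortable
  desk scale while the headline computations keep the reference protocol.

## Known limitations

* FCS support covers list-mode float/double data, versions 3.0/3.1, single
  dataset per file; no compensation/spillover handling, integer data types
  or escaped TEXT delimiters.
* Gate inference is out of scope: gates are inputs (per-taxon config or the
  default rectangle), only their application is automated.
* The delta-method CI is symmetric and can cross the theoretical bounds
  [1, S] of D1 near boundary compositions.
* Classifier scope is deliberately LDA + RF; no hyperparameter search
  (near-optimal defaults are part of the protocol).
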