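# flowident

Identify the composition of synthetic (defined-mixture) bacterial
communities from flow cytometry data, using **in silico communities** and
supervised single-cell classification.

## The problem

Synthetic microbial ecology assembles communities from known axenic
(single-taxon) cultures and needs to track the relative abundance of each
member. Plate counts and qPCR are slow and biased; flow cytometry (FCM)
measures tens of thousands of single cells per second, each described by 12
parameters (FL1–FL4 fluorescence and FSC/SSC scatter, area and height), but
a mixed sample carries no label saying which taxon a cell came from.

The trick: measure each culture **separately** first. Aggregating events
subsampled from those measurements gives an *in silico community* in which
every cell's population of origin is known — a labeled training set. A
classifier trained on it can then assign every cell of a real mixed sample
to a taxon, and the community composition follows from the plug-in count
estimator

```
p̂_i = (# cells assigned to taxon i) / (total cells).
```

## What the package does

* **fcs_io** — read/write FCS 3.0/3.1 list-mode files (and a CSV fallback)
  as channel-named event matrices.
* **preprocessing** — reproducible polygon gating in arcsinh-transformed
  FL1/FL3 space to strip (in)organic debris and instrument noise; replicate
  pooling (one fixed gate per culture, applied before pooling).
* **community** — seeded, without-replacement construction of even
  communities (`N_ax = 5,000` cells/taxon), stratified 70/30 train/test
  splits, two-taxon abundance gradients (1%…99%, 10,000 cells per level) and
  richness-S combination enumeration.
* **classify** — LDA and random forest (200 unpruned gini trees,
  `floor(sqrt(K))` features per split) single-cell classifiers plus the
  plug-in composition estimator.
* **evaluation** — accuracy, Mann–Whitney AUC, row-normalized confusion
  matrices, and RMSE between target and predicted abundance gradients:
  `RMSE = sqrt(Σ_i (p_i − p̂_i)² / n)`.
* **diversity** — Hill number `D1 = exp(−Σ p_i ln p_i)` with instrument
  error propagated through the delta method:
  `σ²_p = 2 ε_I² p²` and `σ²_D1 = D1² Σ (ln p_i + 1)² σ²_p_i`
  (ε_I = 5% by default), yielding 68%/95% confidence intervals.
* **synthetic** — a ground-truth generator of 12-channel event clouds
  (Gaussian mixtures in arcsinh space) with controllable inter-population
  overlap, per-batch replicate drift and debris noise, including calibrated
  low/medium/high-separability preset pairs.
* **experiments / CLI** — three end-to-end experiments (pairwise scan,
  richness scan, gradient recovery) emitting tidy CSV tables, reproducible
  bit-for-bit from a root seed.

## Worked example

Recover an abundance gradient for the high-separability synthetic pair:

```python
from flowident import (
    ExperimentConfig, preset_pairs, simulate_panel, run_gradient_recovery, d1_with_ci,
)

# simulate the "high"-separability pair: 2 replicates x 9,000 events per taxon
models = preset_pairs(n_events=9000)["high"]
panel = simulate_panel(list(models), replicates=2, seed=42)
sample_a, sample_b = panel.samples()      # gated + pooled per taxon

config = ExperimentConfig(seed=42)        # N_ax=5000, 13 levels, 10,000 cells/level
levels, rmse = run_gradient_recovery(sample_a, sample_b, config)

print(rmse[["classifier", "rmse"]].to_string(index=False))
```

```
classifier     rmse
       LDA 0.042291
        RF 0.002163
```

The random forest recovers the 13-level gradient with an RMSE of 0.002 —
its predicted abundances differ from the designed mixing ratios by a few
cells in ten thousand — while LDA shows a small systematic bias (0.04).
The per-level table carries the diversity view of the same result:

```python
sub = levels[levels.classifier == "RF"].head(4)
print(sub[["level", "p_hat1", "d1_target", "d1_target_ci95_lo", "d1_target_ci95_hi"]]
      .to_string(index=False))
```

```
 level  p_hat1  d1_target  d1_target_ci95_lo  d1_target_ci95_hi
  0.01  0.0126   1.057599           0.913851           1.201348
  0.05  0.0522   1.219591           1.066321           1.372860
  0.10  0.1017   1.384145           1.227678           1.540613
  0.20  0.2018   1.649385           1.504611           1.794159
```

`d1_target` is the Hill diversity of the designed composition and the CI
columns bound where a measured community's diversity should fall given a 5%
instrumental count error, e.g. at a 30/70 mixture:

```python
est = d1_with_ci([0.3, 0.7], epsilon_i=0.05)
print(f"D1 = {est.d1:.4f}  95% CI = ({est.ci95[0]:.4f}, {est.ci95[1]:.4f})")
# D1 = 1.8420  95% CI = (1.7260, 1.9580)
```

The same analyses run from the shell on folders of FCS/CSV files:

```bash
flowident simulate --config panel.yaml --seed 1 --out data/
flowident pairwise --config run.yaml  --seed 1 --out results/
flowident gradient --config run.yaml  --seed 1 --out results/ --fresh-batch
```

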