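# motilikit

Single-cell motility profiling: harmonize time-lapse trajectory datasets
acquired at different frame intervals, extract anisotropic-persistent-
random-walk (APRW) motility parameters per cell, discover and classify
motility states, and quantify spatial and temporal heterogeneity with
Shannon entropies.

## Who this is for

Labs that track individual cells in time-lapse microscopy (2D substrates or
2D projections of 3D scaffolds) and want population-resolved answers:
which motility phenotypes exist in a dataset, how a perturbation
redistributes cells among them, how stable each phenotype is over time, and
how heterogeneous each condition is — instead of a single averaged speed
per condition.

## The model

Each cell is modeled as two independent persistent random walks along its
primary and non-primary migration axes, with per-axis speed *S* and
persistence time *P*:

    MSD_p(τ) = S_p² P_p [τ − P_p (1 − e^(−τ/P_p))] + 2σ_p²

Eight parameters summarize a cell — MSD₁₀, MSD₁₀₀ (empirical MSD at 10 and
100 min), the diffusivities D_p = S_p²P_p/4, D_np, D_tot = D_p + D_np, the
persistence times P_p, P_np, and the anisotropy index φ = D_p/D_np ≥ 1.
Cells are grouped by k-means on correlation distance over the log/z-scored
parameters (17 clusters for 2.5-h tracks, 25 for 8-h tracks by default),
clusters merge into four behavior classes (low/high speed × low/high
persistence) by hierarchical clustering of the centroids, and a linear SVM
classifies new cells into the learned states. Heterogeneity per condition
is measured by four entropies: spatial (cluster abundances), state
(class frequencies per 2.5-h segment), transition (joint class pairs
between consecutive segments), and conditional-transition.

Datasets recorded at other frame intervals are first harmonized onto a
common 5-min grid: linear interpolation plus a calibrated chord-scaled
perturbation (pseudo-Monte-Carlo, factor 2.01), which preserves the
distribution of all eight motility parameters where plain linear
interpolation distorts the short-timescale ones.

See `docs/methods.md` for assumptions, estimation details and limitations.

## Worked example

Simulate a small cohort of two motility phenotypes, fit the APRW
parameters, cluster, and classify:

```python
import motilikit as mk

crawler = mk.SimulationSpec(Sp=0.3, Snp=0.1, Pp=40, Pnp=10, n_cells=100,
                            n_steps=96, rng_seed=0,
                            condition_id="slow_persistent")
dasher = mk.SimulationSpec(Sp=1.5, Snp=1.3, Pp=3, Pnp=2.5, n_cells=100,
                           n_steps=96, rng_seed=1,
                           condition_id="fast_tortuous")
ts = mk.TrajectorySet(mk.simulate_cohort(crawler).trajectories
                      + mk.simulate_cohort(dasher).trajectories, {})

table = mk.fit_dataset(ts)              # one row per cell, 8 parameters
fm = mk.normalize_features(table)       # log + z-score
model = mk.kmeans_correlation(fm, k=2, replicates=10, seed=0)
model = mk.derive_behavior_classes(model, n_classes=2)
bundle = mk.train_cluster_classifier(fm, model.assignments.to_numpy(),
                                     seed=0)

print(table[["Dtot", "Pp", "phi"]].groupby(
    table.condition_id).median().round(3))
print(mk.abundance_profiles(model)[0].round(2))
print(f"SVM train/test accuracy: {bundle.train_accuracy:.3f} "
      f"/ {bundle.test_accuracy:.3f}")
```

prints

```
                  Dtot      Pp     phi
condition_id
fast_tortuous    2.580   3.407   1.736
slow_persistent  0.808  34.163  30.424
                  S1   S2
condition_id
fast_tortuous    0.0  1.0
slow_persistent  1.0  0.0
SVM train/test accuracy: 1.000 / 1.000
```

The two phenotypes differ in persistence time (3 vs 34 min median),
anisotropy (φ 1.7 vs 30) and diffusivity; the two discovered clusters
recover the planted populations exactly, and the SVM separates them
perfectly. Note that correlation-distance clustering groups cells by the
*shape* of their parameter profile: phenotypes that differ only by a
uniform magnitude shift across all eight parameters fall into the same
cluster by design, which is why the example phenotypes differ in
persistence and anisotropy rather than speed alone.

The same workflow is available from the shell:

```bash
motilikit simulate --spec cohort.yaml --out traj.csv
motilikit harmonize --in traj.csv --interval 5 --seed 1 --out harmonized.csv
motilikit fit --in harmonized.csv --out params.csv
motilikit cluster --params params.csv --k 17 --out model.json
motilikit train-svm --params params.csv --model model.json --out svm.json
motilikit classify --model model.json --bundle svm.json \
    --params new_params.csv --out assignments.csv
```

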