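# Methods

## Scope and model

`motilikit` profiles single-cell migration from time-lapse trajectory
tables. The core statistical model is the anisotropic persistent random walk
(APRW): each cell migrates as two independent persistent random walks along
a primary and an orthogonal non-primary axis, with per-axis speed `S`
(µm/min) and persistence time `P` (min). The per-axis time-averaged mean
squared displacement is

    MSD_p(τ)  = Sp²·Pp·[τ − Pp·(1 − e^(−τ/Pp))] + 2σp²
    MSD_np(τ) = Snp²·Pnp·[τ − Pnp·(1 − e^(−τ/Pnp))] + 2σnp²

where `2σ²` is the localization-noise floor. Eight parameters summarize a
cell: the empirical MSD at lags 10 and 100 min (`MSD10`, `MSD100`), the
per-axis diffusivities `Dp = Sp²Pp/4` and `Dnp = Snp²Pnp/4`, their sum
`Dtot`, the persistence times `Pp`, `Pnp`, and the anisotropy index
`φ = Dp/Dnp` (≥ 1 by axis ordering). The identities `Dtot = Dp + Dnp` and
`φ = Dp/Dnp` hold exactly by construction for every emitted parameter
vector.

## Harmonization

Acquisition interval reshapes perceived trajectories: coarser sampling
straightens paths and deflates short-lag displacement statistics. The
package quantifies the distortion as geometric concordance — for every
skipped sample, the triangle area between that intermediate point and the
two bracketing points of the coarser sampling; both the summed and the mean
area are reported because either convention appears in practice, and both
vanish exactly for identical sampling or collinear intermediate points.

Resampling onto a common grid (default 5 min) uses either plain linear
interpolation or the pseudo-Monte-Carlo (pMC) scheme: the linear estimate
plus a perturbation `δ = (chord displacement) · u / pMCF`, where the chord
connects the bracketing observed samples, `u = 1` by default (random
variants `u ~ Uniform(0, 1)` and `u ~ Uniform(−1, 1)` are selectable), and
the perturbation acts only in the dimension with the larger absolute chord
displacement (both dimensions on exact ties). The perturbation law is a
genuinely open design point — published descriptions of such schemes call
the perturbation random while the update rule itself carries no random
variable — so the calibration acceptance below is the arbiter: on
simulated heterogeneous cohorts (2-min tracks degraded to 10 min and
reconstructed) the deterministic and unsigned-uniform laws leave all eight
parameter distributions statistically unchanged at factor 2.01, while the
wider signed-uniform law distorts the non-primary persistence time; the
deterministic rule is therefore the default. Observed
samples are fixed points of both interpolators. Conditions whose interval
divides the target are degraded by subsampling; everything else (coarser or
incommensurate, e.g. 2 → 5 min) is pMC-resampled between bracketing
observed samples.

The pMC factor defaults to 2.01 and can be recalibrated on any
fine-resolution cohort: candidates (default 2.00–2.03) are scored by
degrading, reconstructing, refitting the eight parameters, and comparing
each parameter's distribution against the original with Kruskal–Wallis
followed by Dunn's rank test (Bonferroni-adjusted, α = 0.05; Dunn's test is
implemented in-package with the standard tie correction). The smallest
candidate with no significant difference wins; if none passes, the least
bad candidate is flagged.

## Fitting

Per cell, the migration axes are the eigenvectors of the step-displacement
covariance (primary = leading eigenvector, sign fixed toward +x, ties
toward +y). MSDs are time-averaged over all ordered same-lag pairs, with
lags up to 75 % of the track duration; the per-axis model is fitted by
nonlinear least squares on log-MSD with an analytic Jacobian, positivity
bounds, a multi-start persistence grid (1, 5, 20, 60 min; the three
best-scoring starts are refined), and a restricted second pass — a single
refinement from the first-pass optimum over lags ≤ max(5·P̂, 10·Δt). The
second pass exists because the curvature that identifies `P` lives at lags
of order `P`; when the fit window contains many linear-regime lags the
single-pass estimate of `P` is biased low (≈ −20 % at P = 10 min, Δt = 5
min in our checks; the two-pass median is unbiased within a few percent).
Fits are restricted to lags ≤ one third of the duration by default, since
long-lag time-averaged MSDs average few displacement pairs. Noiseless
closed-form MSD inputs are inverted to better than 1e−4 relative error.

`MSD10`/`MSD100` are read from the empirical profile at the nearest grid
lag (not the fitted curve); a track too short to reach a 100-min lag gets a
missing `MSD100` and is excluded from clustering. Failed fits return NaN
parameters and are excluded and counted downstream.

Known estimation limits, measured on simulated cohorts: a single 97-frame
track constrains `P` only to within roughly a factor of two (interquartile
range ≈ 3–16 min for a true 10 min); per-axis diffusivities carry ~40–60 %
sampling error; and when the persistence time exceeds ~10 % of the track
duration the median single-track estimate of `P` is biased low by ~20 %
(the time-averaged MSD fluctuates strongly at lags of order `P`, and
widening the fit window only adds noisier lags — it worsens the bias).
Localization noise comparable to the per-frame non-primary displacement
additionally lets the fitted `S` and `σ²` trade off, inflating the speed
of slow, weakly anisotropic cells. Consequently, for a truly isotropic walk the *ordered*
ratio φ = Dp/Dnp has a median of ~2–3 rather than 1 — the eigen-ordering of
sample axes plus the ordered ratio of two noisy estimates inflates it —
even though ensemble-level fits recover `S` and `P` to under 1 %. φ should
therefore be read as a relative anisotropy score across cells profiled at
the same track length, not as an absolute test of isotropy; cohort-level
isotropy is better judged from `Dtot` or from ensemble fits.

## Simulation

The simulator advances per-axis velocity as an exact integrated
Ornstein–Uhlenbeck process: displacement and velocity are jointly Gaussian
over a step, with

    var(Δx)    = s²P²(2Δt/P − 3 + 4a − a²),   a = e^(−Δt/P)
    cov(Δx, v) = s²P(1 − a)²,   var(v|v₀) = s²(1 − a²),   s² = S²/2

so sampled positions follow the continuous-time law exactly at any Δt (no
Euler bias), and the ensemble per-axis MSD equals the closed form above
with `2σ² = 2·sigma_loc²`. Localization noise is added i.i.d. per
coordinate per frame; each cell's anisotropy axes sit at a uniformly random
orientation. Cohort heterogeneity multiplies per-cell parameters by
independent log-normal factors (parameters act multiplicatively, matching
the log-normalization used downstream). When Δt exceeds ~5 persistence
times the simulator warns: the sampled walk is then effectively diffusive
and `P` is unrecoverable from the output.

## Clustering and classification

Parameters are natural-log transformed and z-scored per column (the log
base only rescales z-scores). k-means runs on correlation distance
(1 − Pearson correlation between a cell's 8-vector and a centroid), i.e.
spherical k-means on row-centered unit vectors, with k-means++ seeding, 50
seeded restarts by default (correlation k-means is restart-sensitive),
empty-cluster reseeding from the worst-fit point, and a monotone objective.
Cluster indices are canonically ordered by ascending centroid `MSD100` so
numbering is reproducible across runs. Defaults follow the two study
scales: k = 17 clusters for 2.5-h tracks, k = 25 for 8-h tracks; inertia
(elbow by maximum second difference) and mean silhouette diagnostics are
emitted, with the final k a user decision. Behavior classes come from
average-linkage hierarchical clustering of the centroids on correlation
distance, cut into four groups and labeled SG1–SG4 (short) or CG1–CG4
(long) in ascending mean `MSD100` — class 1 least motile, class 4 most.

New cells are classified by a multi-class linear hinge-loss SVM
(Crammer–Singer formulation, C = 100) over the stored normalization. The
joint multiclass formulation is deliberate: correlation-distance cluster
assignment reduces to an argmax of linear score functions of the z-scored
features, which the joint hinge can represent directly, whereas independent
one-vs-rest hinges underfit exactly this geometry (by ~30 accuracy points
at k = 17 in our checks). C = 100 places the SVM in the near-interpolating
regime appropriate for a linearly representable labeling; C = 1000 already
over-fits the held-out split. A nearest-centroid rule (Euclidean in z-score
space, ties toward the lowest cluster index) serves as an independent
cross-check. Simulated cohorts are ground-truthed by augmented
reclustering — conceptually re-clustering the training set plus the one new
cell — implemented as assignment under the frozen k-means objective;
one-at-a-time warm-started exact reclustering is available and agrees with
the frozen-objective assignment on ≥ 99 % of probes at desk scale.

## Temporal dynamics and entropies

8-h tracks at 5-min interval (97 samples) are cut into three 2.5-h
segments covering the first 90 intervals; consecutive segments share their
boundary sample, and the trailing 30-min remainder is kept for the 8-h fit
but not segmented (8 h is not divisible by 2.5 h; this treatment is a
package choice and configurable). Each segment is classified into the
short-duration clusters/classes, the full track into the long-duration
ones; joint 4×4 class-pair tables for the steps T1→T2, T2→T3 and T3→C,
per-class stability fractions, and Sankey node/flow listings follow by
direct counting.

Four plug-in Shannon entropies (natural log, nats; 0·ln 0 ≡ 0) quantify
heterogeneity per condition: spatial (over cluster abundances; ≤ ln k),
state (over the four class frequencies per stage; ≤ ln 4), transition (over
the 16 joint class pairs per step; ≤ ln 16, treated as a joint rather than
conditional distribution so a uniform table gives ln 16 — the conditional
variant is exactly the conditional-transition entropy), and
conditional-transition (over the remaining two stages' class pairs given a
class at one stage). No bias correction is applied; a warning is issued
when any probability rests on fewer than five cells, because plug-in
entropies of sparse tables are biased. 2D-versus-3D prediction trains a
linear SVM per entropy family and on all entropies combined, over repeated
(default 25) stratified 90:10 splits of the conditions, reporting mean
accuracy and an ROC/AUC from decision scores pooled across iterations (the
pooling scheme is a package choice).

## Synthetic reference studies

Because the curated experimental dataset is an optional external input, the
package validates itself on seeded synthetic studies
(`motilikit.studies`): a reference cohort of four archetypes (slow/fast ×
persistent/tortuous; speeds 0.25/1.2 µm/min, persistence 6–30 min,
localization noise 0.2 µm) under wide log-normal heterogeneity (σ_log
0.45–0.5), which turns the archetypes into a heterogeneous continuum of
phenotypes as in pooled experiments. Study sizes used by the test suite and
the acceptance script — 2,000 cells per duration for cluster/SVM studies,
1,000 simulated cells for validation, 500 cells per point of the
parameter-recovery grid, 2,000 cells for the ensemble-MSD check, 200
two-minute cells for harmonization calibration, and a 60-condition matched
2D/3D panel with 25 cells per condition — were chosen as the smallest
cohorts at which the corresponding statistics are stable.

The matched 2D/3D panel plants the direction observed empirically (3D
conditions more heterogeneous): each pair shares a dominant archetype, the
2D member concentrates on it (90 % of cells, half-width parameter spread)
while the 3D member mixes all archetypes at full spread. What a passing
prediction shows is that the entropy features separate conditions whose
heterogeneity differs in this planted way — not that real 2D/3D data are
separable, which requires the experimental dataset.

What the synthetic studies do not emulate: tracking errors other than
i.i.d. Gaussian localization noise (no missed frames, no identity swaps),
cell division or death, drift/flow artifacts, condition-specific
correlations between parameters beyond the archetype structure, and any
time-inhomogeneity within a cell (except where a switch is planted
deliberately). Desk-scale accuracies of the cluster SVM depend on training
size; with 2,000 training cells the held-out accuracy is a few points below
what a 74k-cell training set supports.

## Numerical conventions and edge cases

- Time is always minutes internally; coordinates µm (pixel inputs are
  calibrated on read via the per-condition pixel size, which acts linearly).
- Uniform spacing is enforced to 1e−9 min; segment windows must be integer
  multiples of the interval; trailing remainders shorter than one window
  are discarded.
- Zero-displacement trajectories have undefined axes and are flagged
  degenerate; zero-length steps are skipped in angular profiles.
- The angular-velocity circularity score is the minor/major radius ratio of
  the second-moment ellipse of the polar direction density (mass-weighted
  unit directions): 1 for an isotropic profile, → 0 for strictly 1D motion,
  bounded away from 0 only by the finite bin width. The exact formula
  behind published circularity scores is not standardized; this ellipse
  definition is the package's stated choice.
- Cluster models and SVM bundles serialize to human-readable JSON
  (centroids, directions, normalization stats, class map, coefficient
  matrix, split record), so classification is reproducible from text
  artifacts alone.
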