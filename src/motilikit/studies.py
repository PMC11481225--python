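"""Reference synthetic studies: end-to-end validation constructions.

These builders assemble the simulated studies used to validate the whole
pipeline (and to generate the worked examples): a heterogeneous reference
cohort of four motility archetypes, the fitted/clustered/classified study
objects, and a matched 2D-versus-3D condition panel in which 3D conditions
mix archetypes more broadly than 2D ones — emulating the empirical
observation that cells in 3D microenvironments show wider motility
heterogeneity than matched 2D cultures.  All inputs here are synthetic and
seeded; nothing is read from disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from motilikit.aprw import fit_dataset
from motilikit.classification import (
    ClassifierBundle,
    train_cluster_classifier,
)
from motilikit.clustering import (
    ClusterModel,
    FeatureMatrix,
    derive_behavior_classes,
    kmeans_correlation,
    normalize_features,
)
from motilikit.entropy_analysis import entropy_report
from motilikit.simulator import SimulationSpec, simulate_cohort
from motilikit.temporal_dynamics import build_transition_records
from motilikit.trajectory_io import TrajectorySet

#: four motility archetypes: slow/fast crossed with persistent/tortuous
REFERENCE_ARCHETYPES = [
    dict(Sp=0.25, Snp=0.12, Pp=25.0, Pnp=8.0),
    dict(Sp=0.25, Snp=0.20, Pp=6.0, Pnp=4.0),
    dict(Sp=1.2, Snp=0.35, Pp=30.0, Pnp=10.0),
    dict(Sp=1.2, Snp=0.90, Pp=7.0, Pnp=5.0),
]
#: log-normal spread (sigma of the log) emulating population heterogeneity
REFERENCE_HETEROGENEITY = {"Sp": 0.45, "Snp": 0.45, "Pp": 0.5, "Pnp": 0.5}


def build_reference_cohort(
    n_per_archetype: int,
    n_steps: int,
    seed0: int,
    condition_prefix: str = "ref",
) -> TrajectorySet:
    """Simulate the four-archetype reference cohort, one condition each.

    The wide log-normal heterogeneity turns the four archetypes into a
    heterogeneous continuum of phenotypes, as in pooled experimental
    datasets; short-persistence draws below the frame interval are part of
    that continuum (their persistence is simply unresolvable).
    """
    trajectories, metadata = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a, arch in enumerate(REFERENCE_ARCHETYPES):
            spec = SimulationSpec(
                n_cells=n_per_archetype,
                n_steps=n_steps,
                rng_seed=seed0 + a,
                condition_id=f"{condition_prefix}{a}",
                heterogeneity=dict(REFERENCE_HETEROGENEITY),
                sigma_loc=0.2,
                **arch,
            )
            ts = simulate_cohort(spec)
            trajectories += ts.trajectories
            metadata.update(ts.metadata)
    return TrajectorySet(trajectories, metadata)


@dataclass
class MotilityStudy:
    """A fitted end-to-end study: cohort, parameters, clusters, classifier."""

    cohort: TrajectorySet
    table: pd.DataFrame
    fm: FeatureMatrix
    model: ClusterModel
    bundle: ClassifierBundle


def build_motility_study(
    n_per_archetype: int,
    n_steps: int,
    k: int,
    seed0: int,
    prefix: str,
    class_prefix: str,
    condition_prefix: str,
) -> MotilityStudy:
    """Simulate, fit, cluster, derive behavior classes and train the SVM."""
    cohort = build_reference_cohort(
        n_per_archetype, n_steps, seed0, condition_prefix
    )
    table = fit_dataset(cohort)
    fm = normalize_features(table)
    model = kmeans_correlation(fm, k=k, replicates=20, seed=0, prefix=prefix)
    model = derive_behavior_classes(model, class_prefix=class_prefix)
    bundle = train_cluster_classifier(fm, model.assignments.to_numpy(), seed=0)
    return MotilityStudy(cohort, table, fm, model, bundle)


def build_short_study(n_per_archetype: int = 500, seed0: int = 100):
    """2.5-h study (31 frames at 5 min), 17 motility clusters, SG classes."""
    return build_motility_study(
        n_per_archetype, n_steps=30, k=17, seed0=seed0,
        prefix="S", class_prefix="SG", condition_prefix="short",
    )


def build_long_study(n_per_archetype: int = 500, seed0: int = 200):
    """8-h study (97 frames at 5 min), 25 motility clusters, CG classes."""
    return build_motility_study(
        n_per_archetype, n_steps=96, k=25, seed0=seed0,
        prefix="C", class_prefix="CG", condition_prefix="long",
    )


def _condition_cohort(
    weights: np.ndarray,
    n_cells: int,
    n_steps: int,
    condition_id: str,
    rng: np.random.Generator,
    het_scale: float = 1.0,
) -> TrajectorySet:
    """One condition: cells drawn from an archetype mixture.

    ``het_scale`` scales the log-normal parameter spread, controlling how
    broad the condition's phenotype distribution is.
    """
    from motilikit.simulator import _draw_cell_params, simulate_cell

    draws = rng.choice(len(REFERENCE_ARCHETYPES), size=n_cells, p=weights)
    heterogeneity = {
        k: het_scale * v for k, v in REFERENCE_HETEROGENEITY.items()
    }
    trajectories = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, a in enumerate(draws):
            spec = SimulationSpec(
                n_steps=n_steps,
                rng_seed=0,
                condition_id=condition_id,
                sigma_loc=0.2,
                heterogeneity=dict(heterogeneity),
                **REFERENCE_ARCHETYPES[a],
            )
            trajectories.append(
                simulate_cell(
                    _draw_cell_params(spec, rng),
                    cell_id=f"{condition_id}_c{i:03d}",
                    rng=rng,
                )
            )
    return TrajectorySet(trajectories, {})


def build_dimensionality_study(
    short: MotilityStudy,
    long: MotilityStudy,
    n_pairs: int = 30,
    cells_per_condition: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Matched 2D/3D condition panel with entropy features per condition.

    Each pair shares a dominant archetype; the 2D member concentrates on it
    (90% of cells, narrowed parameter spread) while the 3D member mixes all
    archetypes with the full spread, giving 3D conditions systematically
    higher spatial and temporal heterogeneity — the direction observed
    empirically for cells in 3D scaffolds versus matched 2D substrates.
    All cells are 8-h trajectories; per condition the transition records
    and long-cluster abundances feed :func:`entropy_report`.  Returns the
    per-condition entropy feature table and the 2D/3D label series.
    """
    rng = np.random.default_rng(seed)
    n_arch = len(REFERENCE_ARCHETYPES)
    all_records, abundance_rows, labels = [], {}, {}
    for p in range(n_pairs):
        dominant = p % n_arch
        w2d = np.full(n_arch, 0.10 / (n_arch - 1))
        w2d[dominant] = 0.90
        w3d = np.full(n_arch, 1.0 / n_arch)
        for dim, weights, het_scale in (
            ("2D", w2d, 0.5), ("3D", w3d, 1.0)
        ):
            cond = f"pair{p:02d}_{dim}"
            cohort = _condition_cohort(
                weights, cells_per_condition, 96, cond, rng,
                het_scale=het_scale,
            )
            records, _ = build_transition_records(
                cohort, short.model, long.model, short.bundle, long.bundle
            )
            all_records.append(records)
            # long-duration cluster abundance for the spatial entropy,
            # read off the records' long-cluster labels
            idx = records["cluster_C"].str.lstrip("C").astype(int) - 1
            counts = idx.value_counts().reindex(
                range(long.model.k), fill_value=0
            )
            abundance_rows[cond] = (counts / counts.sum()).to_numpy()
            labels[cond] = dim
    records = pd.concat(all_records, ignore_index=True)
    abundance = pd.DataFrame.from_dict(abundance_rows, orient="index")
    abundance.index.name = "condition_id"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-count entropy estimates
        features = entropy_report(records, abundance)
    return features, pd.Series(labels)
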