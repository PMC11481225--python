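"""Shared fixtures: reference simulated cohorts and fitted studies.

The expensive end-to-end studies (simulate -> fit -> cluster -> classify)
are built once per session and shared across test modules.  The reference
cohort emulates a pooled motility dataset: four behavioral archetypes
(slow/fast crossed with persistent/tortuous) with wide log-normal parameter
spread, so the fitted parameter cloud is a heterogeneous continuum rather
than four clean blobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import motilikit as mk
from motilikit.aprw import PARAMETER_NAMES
from motilikit.studies import (
    build_reference_cohort,
    build_long_study,
    build_short_study,
)

__all__ = ["build_reference_cohort"]


def _as_dict(study) -> dict:
    return {
        "cohort": study.cohort,
        "table": study.table,
        "fm": study.fm,
        "model": study.model,
        "bundle": study.bundle,
        "study": study,
    }


@pytest.fixture(scope="session")
def short_study() -> dict:
    """2.5-h study: 2,000 cells at 5-min interval, 17 motility clusters."""
    return _as_dict(build_short_study())


@pytest.fixture(scope="session")
def long_study() -> dict:
    """8-h study: 2,000 cells at 5-min interval, 25 motility clusters."""
    return _as_dict(build_long_study())


def planted_parameter_table(
    n_per: int = 500, sd: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted 4-archetype cohort directly in parameter space.

    Archetype mean log-profiles are a common base plus mutually orthogonal
    zero-sum patterns, so the centered profile shapes (what correlation
    distance sees) are maximally distinct, and the archetypes are separated
    by > 2 within-archetype sd in every parameter.  The table is a
    clustering-geometry construct, not an APRW-consistent parameter set.
    Returns the raw parameter table and the ground-truth archetype labels.
    """
    base = np.array([2.0, 3.0, -1.0, -1.5, -2.5, 2.0, 1.0, 1.0])
    patterns = {
        "a": [+1, +1, +1, +1, -1, -1, -1, -1],
        "b": [+1, +1, -1, -1, +1, +1, -1, -1],
        "c": [+1, -1, +1, -1, +1, -1, +1, -1],
        "d": [+1, +1, -1, -1, -1, -1, +1, +1],
    }
    amplitude = 0.8
    means = {k: base + amplitude * np.asarray(v, float)
             for k, v in patterns.items()}
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for name, mu in means.items():
        draws = rng.normal(mu, sd, size=(n_per, 8))
        for i, logp in enumerate(draws):
            rows.append(
                {
                    "condition_id": name,
                    "cell_id": f"{name}{i:04d}",
                    **dict(zip(PARAMETER_NAMES, np.exp(logp))),
                }
            )
            truth.append(name)
    return pd.DataFrame(rows), np.asarray(truth)


@pytest.fixture(scope="session")
def planted_params() -> tuple[pd.DataFrame, np.ndarray]:
    return planted_parameter_table()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_trajectory(
    rng: np.random.Generator, n: int, dt: float = 5.0, cell_id: str = "r0"
) -> mk.Trajectory:
    """A random-walk trajectory of n samples (no model structure implied)."""
    steps = rng.normal(0.0, 2.0, size=(n - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return mk.Trajectory(
        cell_id=cell_id, condition_id="rand", t=dt * np.arange(n),
        x=pos[:, 0], y=pos[:, 1], interval=dt,
    )
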