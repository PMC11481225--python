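"""Synthetic anisotropic-persistent-random-walk trajectory generation.

Each migration axis carries an independent Ornstein-Uhlenbeck velocity
process with persistence time P and stationary speed scale S/sqrt(2), so the
ensemble per-axis MSD equals the closed-form APRW expression

    MSD(tau) = S^2 P [tau - P (1 - exp(-tau/P))] + 2 sigma_loc^2 .

Positions and velocities are advanced with the exact joint Gaussian update
of the integrated OU process (not an Euler scheme), so the sampled positions
follow the continuous-time law exactly at any time step.  Independent
Gaussian localization noise of standard deviation ``sigma_loc`` is added per
coordinate per frame, and each cell's anisotropy axes sit at a random
orientation, as in pooled experimental datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from motilikit.trajectory_io import (
    ConditionMetadata,
    Trajectory,
    TrajectorySet,
)


@dataclass
class SimulationSpec:
    """Cohort-level simulation settings.

    Sp, Snp : per-axis speeds, um/min.
    Pp, Pnp : per-axis persistence times, min.
    sigma_loc : per-coordinate localization noise, um.
    dt, n_steps : sampling interval (min) and number of steps
        (``n_steps + 1`` samples per trajectory).
    heterogeneity : optional log-normal spread (sigma of log) per parameter,
        keyed by {'Sp','Snp','Pp','Pnp'}; multiplies each cell's parameter by
        exp(N(0, sigma^2)).
    """

    Sp: float = 0.5
    Snp: float = 0.25
    Pp: float = 30.0
    Pnp: float = 10.0
    sigma_loc: float = 0.2
    dt: float = 5.0
    n_steps: int = 30
    n_cells: int = 100
    rng_seed: int = 0
    condition_id: str = "simulated"
    dimensionality: str = "2D"
    heterogeneity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("Sp", "Snp", "Pp", "Pnp", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


def _integrated_ou_axis(
    rng: np.random.Generator, S: float, P: float, dt: float, n_steps: int
) -> np.ndarray:
    """Positions of one axis's integrated OU velocity process.

    Exact joint update of (displacement, velocity) over each step: with
    a = exp(-dt/P) and stationary velocity variance s2 = S^2/2,

        var(dx)    = s2 P^2 (2 dt/P - 3 + 4a - a^2)
        cov(dx, v) = s2 P (1 - a)^2
        var(v)     = s2 (1 - a^2)

    conditioned on the current velocity; the initial velocity is stationary.
    """
    a = np.exp(-dt / P)
    s2 = S**2 / 2.0
    # for P >> dt the bracket suffers catastrophic cancellation; clamp at 0
    var_x = max(s2 * P**2 * (2.0 * dt / P - 3.0 + 4.0 * a - a**2), 0.0)
    cov_xv = s2 * P * (1.0 - a) ** 2
    var_v = s2 * (1.0 - a**2)

    # Cholesky factor of the 2x2 conditional covariance [[var_x, cov],[cov, var_v]]
    l11 = np.sqrt(var_x)
    l21 = cov_xv / l11 if l11 > 0 else 0.0
    l22 = np.sqrt(max(var_v - l21**2, 0.0))

    v = rng.normal(0.0, np.sqrt(s2))
    pos = np.empty(n_steps + 1)
    pos[0] = 0.0
    z = rng.standard_normal((n_steps, 2))
    for k in range(n_steps):
        dx = P * (1.0 - a) * v + l11 * z[k, 0]
        v = a * v + l21 * z[k, 0] + l22 * z[k, 1]
        pos[k + 1] = pos[k] + dx
    return pos


def simulate_cell(
    spec: SimulationSpec, cell_id: str = "sim_0", rng=None
) -> Trajectory:
    """Simulate one APRW trajectory; deterministic given the spec's seed.

    Warns when dt greatly exceeds the persistence times: the velocity then
    decorrelates within a single frame and the sampled walk is effectively
    diffusive, so the persistence times are unrecoverable from the output.
    """
    if spec.dt >= 5.0 * min(spec.Pp, spec.Pnp):
        warnings.warn(
            f"dt={spec.dt} min is >= 5x the shortest persistence time; "
            "sampled trajectory is effectively diffusive",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    p_axis = _integrated_ou_axis(rng, spec.Sp, spec.Pp, spec.dt, spec.n_steps)
    np_axis = _integrated_ou_axis(
        rng, spec.Snp, spec.Pnp, spec.dt, spec.n_steps
    )
    angle = rng.uniform(0.0, np.pi)
    c, s = np.cos(angle), np.sin(angle)
    x = c * p_axis - s * np_axis
    y = s * p_axis + c * np_axis
    if spec.sigma_loc > 0:
        x = x + rng.normal(0.0, spec.sigma_loc, size=x.shape)
        y = y + rng.normal(0.0, spec.sigma_loc, size=y.shape)
    t = spec.dt * np.arange(spec.n_steps + 1)
    return Trajectory(
        cell_id=cell_id,
        condition_id=spec.condition_id,
        t=t,
        x=x,
        y=y,
        interval=spec.dt,
    )


def _draw_cell_params(
    spec: SimulationSpec, rng: np.random.Generator
) -> SimulationSpec:
    if not spec.heterogeneity:
        return spec
    updates = {}
    for name in ("Sp", "Snp", "Pp", "Pnp"):
        sigma = spec.heterogeneity.get(name, 0.0)
        factor = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
        updates[name] = getattr(spec, name) * factor
    from dataclasses import replace

    return replace(spec, heterogeneity={}, **updates)


def simulate_cohort(spec: SimulationSpec) -> TrajectorySet:
    """Simulate ``spec.n_cells`` independent trajectories as one condition.

    With heterogeneity, each cell's (Sp, Snp, Pp, Pnp) are multiplied by
    independent log-normal factors, emulating the multiplicative spread of
    motility parameters across a real cell population.
    """
    rng = np.random.default_rng(spec.rng_seed)
    width = len(str(spec.n_cells))
    trajectories = [
        simulate_cell(
            _draw_cell_params(spec, rng),
            cell_id=f"sim_{i:0{width}d}",
            rng=rng,
        )
        for i in range(spec.n_cells)
    ]
    metadata = {
        spec.condition_id: ConditionMetadata(
            condition_id=spec.condition_id,
            total_duration=spec.dt * spec.n_steps,
            acquisition_interval=spec.dt,
            pixel_size=1.0,
            dimensionality=spec.dimensionality,
            description="APRW simulation",
        )
    }
    return TrajectorySet(trajectories, metadata)


def simulate_from_parameter_table(
    table: pd.DataFrame,
    n_cells: int,
    dt: float = 5.0,
    n_steps: int = 30,
    sigma_loc: float = 0.2,
    rng_seed: int = 0,
    condition_id: str = "simulated",
) -> TrajectorySet:
    """Simulate cells whose APRW parameters are resampled (with replacement)
    from a fitted-parameter table with columns Sp, Pp, Snp, Pnp.

    This reproduces the distribution of motility phenotypes present in a
    profiled dataset, the natural input for classifier validation.
    """
    rng = np.random.default_rng(rng_seed)
    rows = table[["Sp", "Pp", "Snp", "Pnp"]].dropna()
    picks = rng.integers(0, len(rows), size=n_cells)
    width = len(str(n_cells))
    trajectories = []
    for i, ridx in enumerate(picks):
        r = rows.iloc[int(ridx)]
        spec = SimulationSpec(
            Sp=float(r.Sp), Snp=float(r.Snp), Pp=float(r.Pp),
            Pnp=float(r.Pnp), sigma_loc=sigma_loc, dt=dt, n_steps=n_steps,
            n_cells=1, condition_id=condition_id,
        )
        trajectories.append(
            simulate_cell(spec, cell_id=f"val_{i:0{width}d}", rng=rng)
        )
    metadata = {
        condition_id: ConditionMetadata(
            condition_id=condition_id,
            total_duration=dt * n_steps,
            acquisition_interval=dt,
            pixel_size=1.0,
            dimensionality="2D",
            description="APRW simulation resampled from fitted parameters",
        )
    }
    return TrajectorySet(trajectories, metadata)
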