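"""Anisotropic persistent random walk (APRW) profiling of trajectories.

The APRW model describes cell migration as two independent persistent random
walks along a primary and an orthogonal non-primary axis, each with its own
speed S and persistence time P.  The per-axis mean squared displacement is

    MSD_p(tau)  = Sp^2  Pp  [tau - Pp (1 - exp(-tau/Pp))]  + 2 sigma_p^2
    MSD_np(tau) = Snp^2 Pnp [tau - Pnp(1 - exp(-tau/Pnp))] + 2 sigma_np^2

where 2 sigma^2 is the localization-noise floor.  Eight motility parameters
summarize each cell: the empirical MSD at lags 10 and 100 min (MSD10,
MSD100), the per-axis diffusivities Dp = Sp^2 Pp / 4 and Dnp = Snp^2 Pnp / 4,
their sum Dtot, the per-axis persistence times Pp and Pnp, and the
anisotropy index phi = Dp / Dnp (>= 1 after axis ordering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from motilikit.trajectory_io import Trajectory, TrajectorySet

#: the eight motility parameters, in canonical column order
PARAMETER_NAMES = ["MSD10", "MSD100", "Dtot", "Dp", "Dnp", "Pp", "Pnp", "phi"]

#: multi-start grid of persistence times for the nonlinear fit, minutes
_P_STARTS = (1.0, 5.0, 20.0, 60.0)


@dataclass
class AxisDecomposition:
    """Step displacements rotated into the (primary, non-primary) frame."""

    displacements: np.ndarray  # (n_steps, 2): columns primary, non-primary
    axes: np.ndarray  # (2, 2): rows are the primary / non-primary unit axes
    eigenvalues: np.ndarray  # descending variances along the axes
    degenerate: bool = False

    @property
    def angle(self) -> float:
        """Orientation of the primary axis, radians in (-pi/2, pi/2]."""
        return math.atan2(self.axes[0, 1], self.axes[0, 0])


@dataclass
class MSDProfile:
    """Time-averaged MSD versus lag, total and per migration axis."""

    lags: np.ndarray  # minutes, strictly increasing
    msd_total: np.ndarray  # um^2
    msd_p: np.ndarray  # um^2, primary axis
    msd_np: np.ndarray  # um^2, non-primary axis
    n_pairs: np.ndarray  # displacement pairs averaged per lag
    dt: float  # sampling interval, minutes


@dataclass
class APRWFit:
    """Per-axis model parameters from the nonlinear least-squares fit."""

    Sp: float  # um/min
    Pp: float  # min
    sigma2_p: float  # um^2
    Snp: float
    Pnp: float
    sigma2_np: float
    residual_p: float = np.nan  # RMS log-residual, primary axis
    residual_np: float = np.nan
    converged: bool = True


@dataclass
class MotilityParameters:
    """The eight per-cell motility parameters.

    Invariants: Dtot = Dp + Dnp and phi = Dp/Dnp hold exactly; axis ordering
    guarantees Dp >= Dnp hence phi >= 1.
    """

    MSD10: float
    MSD100: float
    Dtot: float
    Dp: float
    Dnp: float
    Pp: float
    Pnp: float
    phi: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAMETER_NAMES])


def decompose_axes(traj: Trajectory) -> AxisDecomposition:
    """Rotate step displacements into the primary/non-primary frame.

    The primary axis is the leading eigenvector of the displacement
    covariance; its sign is fixed to a non-negative x-component (ties toward
    +y) so the decomposition is deterministic.  A zero-displacement
    trajectory has undefined axes and is flagged degenerate.
    """
    disp = traj.displacements()
    if np.allclose(disp, 0.0):
        return AxisDecomposition(
            displacements=disp.copy(),
            axes=np.eye(2),
            eigenvalues=np.zeros(2),
            degenerate=True,
        )
    cov = np.cov(disp, rowvar=False, bias=True)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    primary = eigvecs[:, 0]
    if primary[0] < 0 or (primary[0] == 0 and primary[1] < 0):
        primary = -primary
    secondary = np.array([-primary[1], primary[0]])
    axes = np.vstack([primary, secondary])
    return AxisDecomposition(
        displacements=disp @ axes.T,
        axes=axes,
        eigenvalues=np.maximum(eigvals, 0.0),
    )


def _msd_1d(coord: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one coordinate over all ordered same-lag pairs."""
    return np.array(
        [np.mean((coord[n:] - coord[:-n]) ** 2) for n in range(1, max_lag + 1)]
    )


def compute_msd(
    traj: Trajectory, max_lag_fraction: float = 0.75
) -> MSDProfile:
    """Time-averaged MSD profile, total and decomposed per migration axis.

    Lags run from dt up to ``max_lag_fraction`` of the elapsed duration
    (every lag averages at least two pairs by construction of the bound).
    The per-axis MSDs are computed on the coordinates projected onto the
    primary/non-primary axes, so ``msd_p + msd_np == msd_total`` by
    orthonormality of the rotation.
    """
    if len(traj) < 3:
        raise ValueError(f"cell {traj.cell_id}: need at least 3 samples")
    if not traj.is_uniform:
        raise ValueError(f"cell {traj.cell_id}: not uniformly sampled")
    n_samples = len(traj)
    dt = traj.interval
    max_lag = min(
        n_samples - 2,
        int(np.floor(max_lag_fraction * traj.duration / dt)),
    )
    max_lag = max(max_lag, 1)

    decomp = decompose_axes(traj)
    pos = np.column_stack([traj.x - traj.x[0], traj.y - traj.y[0]])
    rotated = pos @ decomp.axes.T

    msd_p = _msd_1d(rotated[:, 0], max_lag)
    msd_np = _msd_1d(rotated[:, 1], max_lag)
    lags = dt * np.arange(1, max_lag + 1)
    return MSDProfile(
        lags=lags,
        msd_total=msd_p + msd_np,
        msd_p=msd_p,
        msd_np=msd_np,
        n_pairs=n_samples - np.arange(1, max_lag + 1),
        dt=dt,
    )


def aprw_msd_model(
    tau: np.ndarray, S: float, P: float, sigma2: float
) -> np.ndarray:
    """Closed-form per-axis APRW MSD with localization-noise floor."""
    tau = np.asarray(tau, dtype=float)
    return S**2 * P * (tau - P * (1.0 - np.exp(-tau / P))) + 2.0 * sigma2


def _fit_axis(
    lags: np.ndarray,
    msd: np.ndarray,
    x0: np.ndarray | None = None,
) -> tuple[float, float, float, float, bool]:
    """Fit (S, P, sigma2) to one axis's MSD by least squares in log space.

    With ``x0`` given, a single refinement from that start is run instead of
    the multi-start search.
    """
    keep = msd > 0
    lags, msd = lags[keep], msd[keep]
    if len(lags) < 5:
        return np.nan, np.nan, np.nan, np.nan, False

    log_msd = np.log(msd)
    floor = 1e-12 * max(msd.max(), 1.0)

    def residuals(theta):
        model = aprw_msd_model(lags, *theta)
        return np.log(np.maximum(model, floor)) - log_msd

    def jacobian(theta):
        S, P, sigma2 = theta
        E = np.exp(-lags / P)
        core = S**2 * P * (lags - P * (1.0 - E))
        m = np.maximum(core + 2.0 * sigma2, floor)
        dS = 2.0 * core / S
        dP = S**2 * lags * (1.0 + E) - 2.0 * S**2 * P * (1.0 - E)
        return np.column_stack([dS, dP, np.full_like(lags, 2.0)]) / m[:, None]

    if x0 is not None:
        candidates = [list(x0)]
        order = np.array([0])
    else:
        # candidate starts: ballistic small-lag guess MSD ~ S^2 tau^2 / 2
        # for tau << P, and a diffusive-consistent guess per persistence
        # start
        s0 = math.sqrt(2.0 * msd[0]) / lags[0]
        candidates = []
        for p0 in _P_STARTS:
            s_alt = math.sqrt(max(msd[-1] / (p0 * lags[-1]), 1e-12))
            for s_init in (s0, s_alt):
                candidates.append([max(s_init, 1e-4), p0, msd[0] * 1e-3])
        # refine only the most promising starts, cheapest initial cost first
        costs = [0.5 * np.sum(residuals(c) ** 2) for c in candidates]
        order = np.argsort(costs)[:3]

    best = None
    target = 1e-10 * len(lags)  # early exit on an essentially exact fit
    for idx in order:
        try:
            sol = least_squares(
                residuals,
                x0=candidates[idx],
                jac=jacobian,
                bounds=([1e-8, 1e-4, 0.0], [np.inf, np.inf, np.inf]),
                max_nfev=200,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < target:
            break
    if best is None:
        return np.nan, np.nan, np.nan, np.nan, False
    S, P, sigma2 = best.x
    rms = float(np.sqrt(2.0 * best.cost / len(lags)))
    return float(S), float(P), float(sigma2), rms, bool(best.success)


def _fit_axis_twopass(
    lags: np.ndarray, msd: np.ndarray, dt: float
) -> tuple[float, float, float, float, bool]:
    """Fit one axis, then refit restricted to lags near the persistence time.

    The persistence information lives in the MSD curvature at lags of order
    P; when the first-pass P is small compared to the fit range, the many
    linear-regime lags swamp the few curved ones and bias P downward.  The
    second pass refits over lags <= max(5 P, 10 dt), which removes that bias
    while leaving long-persistence fits untouched.
    """
    S, P, s2, res, ok = _fit_axis(lags, msd)
    if ok and np.isfinite(P):
        cut = max(5.0 * P, 10.0 * dt)
        sel = lags <= cut
        if 5 <= sel.sum() < len(lags):
            S2, P2, s22, res2, ok2 = _fit_axis(
                lags[sel], msd[sel], x0=np.array([S, P, s2])
            )
            if ok2:
                return S2, P2, s22, res2, ok2
    return S, P, s2, res, ok


def fit_aprw(
    profile: MSDProfile, fit_lag_max: float | None = None
) -> APRWFit:
    """Fit the per-axis APRW model to an MSD profile.

    The fit runs in log-MSD space with positivity bounds and a multi-start
    grid of persistence times, followed by a restricted-lag second pass
    around the estimated persistence time.  ``fit_lag_max`` bounds the fit
    domain (default: lags up to one third of the profiled duration, since
    long-lag MSD estimates average few displacement pairs).
    """
    if fit_lag_max is None:
        # profile covers up to max_lag_fraction of the duration; one third of
        # the full duration is recovered via the pair counts
        duration = profile.lags[-1] + profile.n_pairs[-1] * profile.dt
        fit_lag_max = duration / 3.0
    sel = profile.lags <= fit_lag_max + 1e-9
    if sel.sum() < 5:
        sel = np.ones_like(profile.lags, dtype=bool)
    lags = profile.lags[sel]

    Sp, Pp, s2p, res_p, ok_p = _fit_axis_twopass(
        lags, profile.msd_p[sel], profile.dt
    )
    Snp, Pnp, s2np, res_np, ok_np = _fit_axis_twopass(
        lags, profile.msd_np[sel], profile.dt
    )
    return APRWFit(
        Sp=Sp, Pp=Pp, sigma2_p=s2p,
        Snp=Snp, Pnp=Pnp, sigma2_np=s2np,
        residual_p=res_p, residual_np=res_np,
        converged=bool(ok_p and ok_np),
    )


def _empirical_msd_at(profile: MSDProfile, lag: float) -> float:
    """Empirical MSD at the nearest available lag; NaN when out of range."""
    if lag < profile.lags[0] - profile.dt or lag > profile.lags[-1] + profile.dt:
        return np.nan
    idx = int(np.argmin(np.abs(profile.lags - lag)))
    return float(profile.msd_total[idx])


def extract_parameters(
    fit: APRWFit, profile: MSDProfile
) -> MotilityParameters:
    """Derive the eight motility parameters from a converged fit.

    Diffusivities follow D = S^2 P / 4 per axis; the axes are swapped (with
    their speeds and persistence times) if needed so that Dp >= Dnp, making
    phi = Dp/Dnp >= 1 an anisotropy index.  MSD10 and MSD100 are read from
    the empirical profile at the nearest grid lag (MSD100 is missing for
    trajectories too short to reach a 100-min lag).
    """
    if not fit.converged or any(
        not np.isfinite(v) for v in (fit.Sp, fit.Pp, fit.Snp, fit.Pnp)
    ):
        raise ValueError("cannot extract parameters from a failed fit")
    Sp, Pp, Snp, Pnp = fit.Sp, fit.Pp, fit.Snp, fit.Pnp
    Dp = Sp**2 * Pp / 4.0
    Dnp = Snp**2 * Pnp / 4.0
    if Dp < Dnp:
        Dp, Dnp = Dnp, Dp
        Pp, Pnp = Pnp, Pp
    return MotilityParameters(
        MSD10=_empirical_msd_at(profile, 10.0),
        MSD100=_empirical_msd_at(profile, 100.0),
        Dtot=Dp + Dnp,
        Dp=Dp,
        Dnp=Dnp,
        Pp=Pp,
        Pnp=Pnp,
        phi=Dp / Dnp,
    )


def normalized_msd(profile: MSDProfile) -> np.ndarray:
    """MSD(tau)/tau in um^2/min, for comparison across acquisition
    intervals (constant 4D for pure diffusion, linear ramp for ballistic)."""
    return profile.msd_total / profile.lags


@dataclass
class AngularProfile:
    """Polar density of step directions relative to the primary axis."""

    bin_centers: np.ndarray  # radians in (-pi, pi)
    density: np.ndarray  # probability density per radian
    angular_speeds: np.ndarray  # |dtheta|/dt per consecutive step pair, rad/min
    circularity: float  # minor/major radius ratio of the second-moment ellipse


def angular_velocity_profile(
    traj: Trajectory, n_bins: int = 36
) -> AngularProfile:
    """Polar histogram of step directions and a circularity score.

    Directions are measured relative to the cell's primary migration axis.
    Circularity is the minor/major radius ratio of the second-moment ellipse
    of the polar profile, in (0, 1]: near 1 for cells equally likely to move
    in any direction, near 0 for strictly back-and-forth motion.
    """
    decomp = decompose_axes(traj)
    if decomp.degenerate:
        raise ValueError(f"cell {traj.cell_id}: no net displacement, "
                         "angular profile undefined")
    disp = decomp.displacements
    lengths = np.hypot(disp[:, 0], disp[:, 1])
    moving = lengths > 0
    if not moving.any():
        raise ValueError(f"cell {traj.cell_id}: all steps have zero length")
    theta = np.arctan2(disp[moving, 1], disp[moving, 0])

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    density, _ = np.histogram(theta, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # mass-weighted second moment of the unit directions
    mass = density * np.diff(edges)
    u = np.column_stack([np.cos(centers), np.sin(centers)])
    moment = (u * mass[:, None]).T @ u
    eigvals = np.sort(np.linalg.eigvalsh(moment))
    circularity = float(np.sqrt(max(eigvals[0], 0.0) / eigvals[1]))

    dtheta = np.abs(np.angle(np.exp(1j * np.diff(theta))))
    angular_speeds = dtheta / traj.interval
    return AngularProfile(
        bin_centers=centers,
        density=density,
        angular_speeds=angular_speeds,
        circularity=circularity,
    )


def profile_cell(
    traj: Trajectory,
    max_lag_fraction: float = 0.75,
    fit_lag_max: float | None = None,
) -> tuple[MotilityParameters, APRWFit, MSDProfile]:
    """MSD profile, APRW fit and the eight parameters for one cell."""
    profile = compute_msd(traj, max_lag_fraction=max_lag_fraction)
    fit = fit_aprw(profile, fit_lag_max=fit_lag_max)
    params = extract_parameters(fit, profile)
    return params, fit, profile


def fit_dataset(
    ts: TrajectorySet,
    max_lag_fraction: float = 0.75,
    fit_lag_max: float | None = None,
) -> pd.DataFrame:
    """Fit every trajectory; one row per cell, NaNs for failed fits.

    Columns: condition_id, cell_id, the eight motility parameters, and the
    fit internals (Sp, Snp, sigma2_p, sigma2_np, converged).
    """
    rows = []
    for traj in ts.trajectories:
        row = {"condition_id": traj.condition_id, "cell_id": traj.cell_id}
        try:
            params, fit, _ = profile_cell(
                traj, max_lag_fraction=max_lag_fraction,
                fit_lag_max=fit_lag_max,
            )
            row.update({k: getattr(params, k) for k in PARAMETER_NAMES})
            # keep the fit internals consistent with the Dp >= Dnp axis
            # ordering applied in extract_parameters
            swapped = params.Pp != fit.Pp
            Sp, Snp = (fit.Snp, fit.Sp) if swapped else (fit.Sp, fit.Snp)
            s2p, s2np = (
                (fit.sigma2_np, fit.sigma2_p) if swapped
                else (fit.sigma2_p, fit.sigma2_np)
            )
            row.update(
                Sp=Sp, Snp=Snp, sigma2_p=s2p, sigma2_np=s2np,
                converged=fit.converged,
            )
        except (ValueError, FloatingPointError):
            row.update({k: np.nan for k in PARAMETER_NAMES})
            row.update(
                Sp=np.nan, Snp=np.nan, sigma2_p=np.nan, sigma2_np=np.nan,
                converged=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
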