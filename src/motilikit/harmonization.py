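"""Harmonizing trajectories acquired at different time intervals.

Acquisition interval strongly shapes the perceived geometry of a cell path:
coarser sampling straightens trajectories and deflates short-timescale
displacement statistics.  This module quantifies that distortion (geometric
concordance, the summed triangular area between intermediate points and the
chords of a coarser sampling), degrades resolution in-silico, and resamples
trajectories onto a common grid by either plain linear interpolation or the
pseudo-Monte-Carlo (pMC) scheme: linear interpolation plus a chord-scaled
perturbation applied in the dominant displacement dimension,

    x_pmc = x_interp + delta_x,   delta_x = (x_next - x_prev) * u / pMCF
                                  (applied when |dx| >= |dy|; both on ties)

where u = 1 by default (uniform-random variants are selectable) and the pMC
factor is calibrated (default 2.01) so that the eight APRW motility
parameters of reconstructed trajectories are statistically indistinguishable
from those of the original fine-resolution data (Kruskal-Wallis + Dunn).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from motilikit.trajectory_io import (
    ConditionMetadata,
    Trajectory,
    TrajectorySet,
    ValidationError,
)

_TIME_TOL = 1e-9

PERTURBATION_LAWS = ("signed_uniform", "unsigned_uniform", "deterministic")


@dataclass
class PMCConfig:
    """Configuration of the pMC perturbation.

    pmc_factor : chord divisor (dimensionless, calibrated default 2.01).
    rng_seed : seed for the perturbation draws (unused by the
        deterministic law).
    perturbation_law : 'deterministic' (u = 1, the literal update rule;
        default), 'unsigned_uniform' (u ~ U(0,1)) or 'signed_uniform'
        (u ~ U(-1,1)).  The deterministic and unsigned laws both pass the
        Kruskal-Wallis calibration acceptance at factor 2.01 on simulated
        cohorts; the wider signed law does not and is kept for
        experimentation.
    """

    pmc_factor: float = 2.01
    rng_seed: int = 0
    perturbation_law: str = "deterministic"

    def __post_init__(self) -> None:
        if self.pmc_factor <= 0:
            raise ValueError("pmc_factor must be > 0")
        if self.perturbation_law not in PERTURBATION_LAWS:
            raise ValueError(
                f"perturbation_law must be one of {PERTURBATION_LAWS}"
            )


def degrade_resolution(traj: Trajectory, target_interval: float) -> Trajectory:
    """Coarsen a uniform trajectory by dropping intervening samples.

    Keeps every (target/source)-th sample starting at t=0; the target
    interval must be an integer multiple of the source interval.
    """
    if not traj.is_uniform:
        raise ValidationError(f"cell {traj.cell_id}: not uniformly sampled")
    ratio = target_interval / traj.interval
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"target interval {target_interval} is not an integer multiple "
            f"of the source interval {traj.interval}"
        )
    step = int(round(ratio))
    return replace(
        traj,
        t=traj.t[::step] - traj.t[0],
        x=traj.x[::step],
        y=traj.y[::step],
        interval=float(target_interval),
    )


def geometric_concordance(
    reference: Trajectory, candidate: Trajectory
) -> tuple[float, float]:
    """Triangular-area discordance between a path and a coarser sampling.

    For each reference sample falling strictly between two consecutive
    candidate samples, the area of the triangle formed by the intermediate
    reference point and the two bracketing candidate points is accumulated.
    Returns ``(summed_area, mean_area_per_triangle)`` in um^2; both are zero
    when the samplings coincide or all skipped points are collinear with
    their brackets.
    """
    ref_t, cand_t = reference.t, candidate.t
    # candidate times must be a subset of reference times
    matched = np.abs(ref_t[None, :] - cand_t[:, None]) <= _TIME_TOL
    if not np.all(matched.any(axis=1)):
        raise ValueError("candidate sample times are not a subset of the "
                         "reference's")
    cand_idx = matched.argmax(axis=1)

    areas = []
    for a, b, (xa, ya), (xb, yb) in zip(
        cand_idx[:-1],
        cand_idx[1:],
        zip(candidate.x[:-1], candidate.y[:-1]),
        zip(candidate.x[1:], candidate.y[1:]),
    ):
        for m in range(a + 1, b):
            # shoelace area of (bracket A, intermediate, bracket B)
            xm, ym = reference.x[m], reference.y[m]
            areas.append(
                0.5 * abs((xb - xa) * (ym - ya) - (xm - xa) * (yb - ya))
            )
    total = float(np.sum(areas)) if areas else 0.0
    mean = float(np.mean(areas)) if areas else 0.0
    return total, mean


def _target_grid(traj: Trajectory, target_interval: float) -> np.ndarray:
    if not traj.is_uniform:
        raise ValidationError(f"cell {traj.cell_id}: not uniformly sampled")
    if target_interval <= 0:
        raise ValueError("target_interval must be > 0")
    t0, t1 = traj.t[0], traj.t[-1]
    n = int(np.floor((t1 - t0) / target_interval + _TIME_TOL))
    if n < 1:
        raise ValueError(
            f"cell {traj.cell_id}: duration {t1 - t0} min shorter than one "
            f"target interval ({target_interval} min)"
        )
    return t0 + target_interval * np.arange(n + 1)


def _resample(
    traj: Trajectory,
    target_interval: float,
    perturb=None,
) -> Trajectory:
    """Resample onto a uniform grid; observed samples are copied exactly.

    ``perturb(dx_chord, dy_chord) -> (delta_x, delta_y)`` is applied to each
    interpolated (non-observed) point; ``None`` means plain linear
    interpolation.
    """
    grid = _target_grid(traj, target_interval)
    on_sample = np.abs(grid[:, None] - traj.t[None, :]) <= _TIME_TOL
    is_observed = on_sample.any(axis=1)
    src_idx = on_sample.argmax(axis=1)

    x = np.interp(grid, traj.t, traj.x)
    y = np.interp(grid, traj.t, traj.y)
    # copy observed samples exactly (no interpolation rounding)
    x[is_observed] = traj.x[src_idx[is_observed]]
    y[is_observed] = traj.y[src_idx[is_observed]]

    if perturb is not None:
        prev_idx = np.searchsorted(traj.t, grid, side="right") - 1
        for i in np.nonzero(~is_observed)[0]:
            lo = prev_idx[i]
            dx = traj.x[lo + 1] - traj.x[lo]
            dy = traj.y[lo + 1] - traj.y[lo]
            delta_x, delta_y = perturb(dx, dy)
            x[i] += delta_x
            y[i] += delta_y

    return replace(
        traj, t=grid - grid[0], x=x, y=y, interval=float(target_interval)
    )


def linear_interpolate(traj: Trajectory, target_interval: float) -> Trajectory:
    """Resample onto a finer/incommensurate uniform grid by straight-line
    interpolation between the bracketing observed samples.

    Handles symmetric (8 -> 4 min, midpoint) and asymmetric (8 -> 6 min)
    interval ratios; observed samples on the new grid are preserved exactly.
    """
    return _resample(traj, target_interval, perturb=None)


def pmc_interpolate(
    traj: Trajectory, target_interval: float, cfg: PMCConfig | None = None
) -> Trajectory:
    """Resample with the pMC perturbation on top of linear interpolation.

    Each interpolated point is displaced by ``chord * u / pmc_factor`` where
    the chord is the displacement between the bracketing observed samples and
    ``u`` follows ``cfg.perturbation_law``.  The perturbation acts only in
    the dimension with the larger absolute chord displacement; on exact ties
    it acts in both.  Observed samples are fixed points.  Seeded and
    reproducible through ``cfg.rng_seed``.
    """
    cfg = cfg or PMCConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    def draw() -> float:
        if cfg.perturbation_law == "signed_uniform":
            return rng.uniform(-1.0, 1.0)
        if cfg.perturbation_law == "unsigned_uniform":
            return rng.uniform(0.0, 1.0)
        return 1.0

    def perturb(dx: float, dy: float) -> tuple[float, float]:
        delta_x = delta_y = 0.0
        if abs(dx) >= abs(dy):
            delta_x = dx * draw() / cfg.pmc_factor
        if abs(dy) >= abs(dx):
            delta_y = dy * draw() / cfg.pmc_factor
        return delta_x, delta_y

    return _resample(traj, target_interval, perturb=perturb)


def harmonize_dataset(
    ts: TrajectorySet,
    target_interval: float = 5.0,
    cfg: PMCConfig | None = None,
) -> tuple[TrajectorySet, pd.DataFrame]:
    """Bring every condition onto a common acquisition interval.

    Conditions already at the target pass through; finer conditions whose
    interval divides the target are degraded; everything else (coarser, or
    incommensurate like 2 -> 5 min) is pMC-resampled onto the target grid
    using the bracketing observed samples.  Returns the harmonized set and a
    provenance table (condition, original interval, method).
    """
    cfg = cfg or PMCConfig()
    out, prov = [], []
    for k, traj in enumerate(ts.trajectories):
        src = traj.interval
        ratio = target_interval / src
        if abs(src - target_interval) <= _TIME_TOL:
            new, method = traj, "passthrough"
        elif abs(ratio - round(ratio)) <= 1e-9 and round(ratio) >= 1:
            new, method = degrade_resolution(traj, target_interval), "degrade"
        else:
            cell_cfg = replace(cfg, rng_seed=cfg.rng_seed + k)
            new = pmc_interpolate(traj, target_interval, cell_cfg)
            method = "pmc"
        out.append(new)
        prov.append(
            {
                "condition_id": traj.condition_id,
                "cell_id": traj.cell_id,
                "original_interval": src,
                "method": method,
            }
        )
    metadata = {
        cid: ConditionMetadata(
            condition_id=cid,
            total_duration=m.total_duration,
            acquisition_interval=float(target_interval),
            pixel_size=m.pixel_size,
            dimensionality=m.dimensionality,
            description=m.description,
        )
        for cid, m in ts.metadata.items()
    }
    return TrajectorySet(out, metadata), pd.DataFrame(prov)


# ---------------------------------------------------------------------------
# pMC-factor calibration: Kruskal-Wallis + Dunn's post-hoc test
# ---------------------------------------------------------------------------

def dunn_test(groups: list[np.ndarray], comparisons: list[tuple[int, int]],
              adjust: str = "bonferroni") -> np.ndarray:
    """Dunn's rank-based post-hoc z-test with tie correction.

    ``groups`` are the samples that entered a Kruskal-Wallis test;
    ``comparisons`` lists index pairs to compare.  Returns the (optionally
    Bonferroni-adjusted) two-sided p-value per comparison.
    """
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    offsets = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))
    ]
    pvals = []
    for i, j in comparisons:
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - ties)
            * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        )
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(z)
        pvals.append(p)
    pvals = np.asarray(pvals)
    if adjust == "bonferroni":
        pvals = np.minimum(pvals * len(comparisons), 1.0)
    return pvals


def compare_parameter_distributions(
    original: pd.DataFrame,
    reconstructed: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis across {original} + reconstructions per motility
    parameter, followed by Dunn (Bonferroni) comparisons of each
    reconstruction against the original.

    Returns a tidy report: variant x parameter -> KW p, Dunn p, pass flag.
    A variant passes for a parameter when either the omnibus KW test or its
    Dunn comparison against the original is non-significant at ``alpha``.
    """
    from motilikit.aprw import PARAMETER_NAMES

    names = list(reconstructed)
    rows = []
    for param in PARAMETER_NAMES:
        groups = [original[param].dropna().to_numpy()] + [
            reconstructed[n][param].dropna().to_numpy() for n in names
        ]
        kw_stat, kw_p = stats.kruskal(*groups)
        if kw_p >= alpha:
            dunn_p = np.ones(len(names))
        else:
            dunn_p = dunn_test(
                groups, [(0, i + 1) for i in range(len(names))]
            )
        for name, dp in zip(names, dunn_p):
            rows.append(
                {
                    "variant": name,
                    "parameter": param,
                    "kw_p": kw_p,
                    "dunn_p": float(dp),
                    "significant": bool(kw_p < alpha and dp < alpha),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    factor: float
    all_pass: bool
    report: pd.DataFrame = field(repr=False)


def calibrate_pmc_factor(
    high_res: TrajectorySet,
    candidates=(2.0, 2.01, 2.02, 2.03),
    degraded_interval: float = 10.0,
    alpha: float = 0.05,
    cfg: PMCConfig | None = None,
) -> CalibrationResult:
    """Select the pMC factor whose reconstructions are statistically
    indistinguishable from the original fine-resolution trajectories.

    For each candidate factor the high-resolution trajectories are degraded
    to ``degraded_interval``, pMC-reconstructed back to their original
    interval, and the eight APRW motility parameters are refitted.  Each
    parameter's distribution is compared against the originals' with
    Kruskal-Wallis followed by Dunn's test (Bonferroni).  The smallest
    candidate with no significant difference on any parameter wins; if none
    passes, the candidate with the fewest significant differences is
    returned with ``all_pass=False``.
    """
    from motilikit.aprw import fit_dataset

    cfg = cfg or PMCConfig()
    original_params = fit_dataset(high_res).dropna()
    source_interval = high_res.trajectories[0].interval

    reconstructions = {}
    for factor in candidates:
        fac_cfg = replace(cfg, pmc_factor=float(factor))
        recon = []
        for k, traj in enumerate(high_res.trajectories):
            degraded = degrade_resolution(traj, degraded_interval)
            cell_cfg = replace(fac_cfg, rng_seed=fac_cfg.rng_seed + k)
            recon.append(
                pmc_interpolate(degraded, source_interval, cell_cfg)
            )
        reconstructions[f"{factor:g}"] = fit_dataset(
            TrajectorySet(recon, high_res.metadata)
        ).dropna()

    report = compare_parameter_distributions(
        original_params, reconstructions, alpha=alpha
    )
    n_sig = report.groupby("variant")["significant"].sum()
    passing = sorted(float(v) for v in n_sig[n_sig == 0].index)
    if passing:
        return CalibrationResult(passing[0], True, report)
    best = float(n_sig.idxmin())
    return CalibrationResult(best, False, report)
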