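"""Synchrony statistics r_i and <r>, plus the headline parameter sweeps.

The synchrony of a follower ``i`` is the mean Pearson correlation,
over the ``n_l``-step measurement window, between its displacement
trajectory and that of each neighbour inside its field of attention:

    r_i = (1 / N_i) * sum_j corr(x^i, x^j).

The global statistic ``<r>`` averages ``r_i`` over the individuals of
the central ``L_c x L_c`` sub-grid that have at least one neighbour
(leaders contribute an empty sum and are excluded, with the exclusion
count reported), then over ``s_t`` independently seeded replicates.

Degenerate-variance convention (documented constants, not silent
behaviour): when both series are numerically constant
(std < ``DEGENERATE_EPS``) the pair counts as perfectly synchronized
(r = 1) if their means agree to the same eps, else 0; when exactly one
is constant, r = 0.  This makes the fixed-point regime (``mu < 3``,
everyone at ``1 - 1/mu``) report ``<r> = 1`` rather than undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dynamics import TrajectorySet, replicate_seeds, run_simulation
from .logistic import APERIODIC, detect_period

__all__ = [
    "CorrelationSummary",
    "DEGENERATE_EPS",
    "pair_correlation",
    "individual_correlation",
    "individual_correlations",
    "global_correlation",
    "sweep_mu",
    "sweep_phase",
]

#: Std / mean-difference threshold below which a series counts as constant.
DEGENERATE_EPS = 1e-9


@dataclass(frozen=True)
class CorrelationSummary:
    """Global synchrony of a replicate family.

    ``r_global`` is the mean of per-replicate central-sub-grid means
    (``None`` when no replicate had a contributing individual);
    ``n_contributing`` counts individual r_i values entering the average
    across all replicates; ``n_excluded`` counts central individuals
    dropped for having an empty field of attention.
    """

    r_global: float | None
    per_replicate: tuple[float, ...]
    n_contributing: int
    n_excluded: int
    window: int
    s_t: int


def pair_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the degenerate-variance convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"trajectories must be 1-D of equal length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("trajectories must have length >= 2")
    sa, sb = a.std(), b.std()
    a_const, b_const = sa < DEGENERATE_EPS, sb < DEGENERATE_EPS
    if a_const and b_const:
        return 1.0 if abs(a.mean() - b.mean()) < DEGENERATE_EPS else 0.0
    if a_const or b_const:
        return 0.0
    r = float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))
    return float(np.clip(r, -1.0, 1.0))


def individual_correlations(trajs: TrajectorySet) -> np.ndarray:
    """Vector of r_i for every individual; NaN flags leaders (N_i = 0).

    Vectorised equivalent of averaging :func:`pair_correlation` over each
    individual's out-neighbours.
    """
    X = trajs.values  # (n_l, N)
    net = trajs.network
    n_l = X.shape[0]
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    const = stds < DEGENERATE_EPS
    safe_std = np.where(const, 1.0, stds)
    Z = (X - means) / safe_std

    if net.n_edges:
        i, j = net.src, net.dst
        corr = np.einsum("ti,ti->i", Z[:, i], Z[:, j]) / n_l
        corr = np.clip(corr, -1.0, 1.0)
        both_const = const[i] & const[j]
        one_const = const[i] ^ const[j]
        corr[both_const] = np.where(
            np.abs(means[i][both_const] - means[j][both_const]) < DEGENERATE_EPS, 1.0, 0.0
        )
        corr[one_const] = 0.0
        sums = np.bincount(i, weights=corr, minlength=net.n)
    else:
        sums = np.zeros(net.n)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sums / net.out_degree
    r[net.out_degree == 0] = np.nan
    return r


def individual_correlation(i: int, trajs: TrajectorySet) -> float | None:
    """r_i of one individual, or ``None`` when it has no neighbour."""
    net = trajs.network
    if net.out_degree[i] == 0:
        return None
    nbrs = net.dst[net.src == i]
    vals = [pair_correlation(trajs.values[:, i], trajs.values[:, j]) for j in nbrs]
    return float(np.mean(vals))


def _replicate_mean(trajs: TrajectorySet) -> tuple[float | None, int, int]:
    """Central-sub-grid mean r_i of one run: (mean, n_contributing, n_excluded)."""
    r = individual_correlations(trajs)
    central = trajs.population.central_mask()
    contributing = central & ~np.isnan(r)
    n_c = int(contributing.sum())
    n_x = int((central & np.isnan(r)).sum())
    return (float(r[contributing].mean()) if n_c else None, n_c, n_x)


def global_correlation(config: SimulationConfig) -> CorrelationSummary:
    """<r>: run ``s_t`` seeded replicates and average central-sub-grid r_i."""
    seeds = replicate_seeds(config.seed, config.s_t)
    per_rep: list[float] = []
    n_contrib = 0
    n_excl = 0
    for seed in seeds:
        trajs = run_simulation(config.replace(seed=seed))
        mean, n_c, n_x = _replicate_mean(trajs)
        n_contrib += n_c
        n_excl += n_x
        if mean is not None:
            per_rep.append(mean)
    r_global = float(np.mean(per_rep)) if per_rep else None
    return CorrelationSummary(
        r_global=r_global,
        per_replicate=tuple(per_rep),
        n_contributing=n_contrib,
        n_excluded=n_excl,
        window=config.n_l,
        s_t=config.s_t,
    )


def _period_summary(trajs: TrajectorySet, p_max: int = 16) -> dict:
    """Per-individual periods of one run (needs window >= 2 * p_max)."""
    periods = np.array(
        [detect_period(col, p_max=p_max).period for col in trajs.values.T], dtype=int
    )
    finite = periods[periods != APERIODIC]
    return {
        "period_mode": int(np.bincount(finite).argmax()) if finite.size else APERIODIC,
        "n_aperiodic": int((periods == APERIODIC).sum()),
        "odd_period_present": bool(np.any((finite > 1) & (finite % 2 == 1))),
        "periods": periods,
    }


def sweep_mu(
    config: SimulationConfig,
    mu_grid: np.ndarray,
    n_display_samples: int = 64,
    tracked_individual: int = 0,
) -> pd.DataFrame:
    """Bifurcation diagram of the coupled lattice: one row per ``mu``.

    Each row carries ``r_global`` over ``config.s_t`` replicates plus,
    from the first replicate, the spread of asymptotic displacement
    values, a period summary, and one tracked individual's last samples.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(mu_grid <= 1.0) or np.any(mu_grid > 4.0):
        raise ValueError("mu_grid values must lie in (1, 4]")
    rows = []
    for mu in mu_grid:
        cfg = config.replace(mu=float(mu))
        summary = global_correlation(cfg)
        first = run_simulation(cfg.replace(seed=replicate_seeds(cfg.seed, 1)[0]))
        tailn = min(n_display_samples, first.window)
        tail = first.values[-tailn:]
        pinfo = _period_summary(first)
        rows.append(
            {
                "mu": float(mu),
                "r_global": summary.r_global,
                "n_contributing": summary.n_contributing,
                "x_min": float(tail.min()),
                "x_max": float(tail.max()),
                "n_distinct_values": int(
                    len(np.unique(np.round(tail, 6)))
                ),
                "period_mode": pinfo["period_mode"],
                "n_aperiodic": pinfo["n_aperiodic"],
                "odd_period_present": pinfo["odd_period_present"],
                "tracked_values": np.array2string(
                    np.sort(np.unique(np.round(tail[:, tracked_individual], 6)))[:16],
                    separator=";",
                ),
            }
        )
    return pd.DataFrame(rows)


def sweep_phase(
    config: SimulationConfig, D_grid: np.ndarray, rho_grid: np.ndarray
) -> pd.DataFrame:
    """(D, rho) phase diagram of <r> at fixed mu, model and theta."""
    D_grid = np.asarray(D_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(D_grid < 0) or np.any(D_grid > 1):
        raise ValueError("D_grid values must lie in [0, 1]")
    if np.any(rho_grid <= 0) or np.any(rho_grid > 1):
        raise ValueError("rho_grid values must lie in (0, 1]")
    rows = []
    for rho in rho_grid:
        for D in D_grid:
            cfg = config.replace(D=float(D), rho=float(rho))
            summary = global_correlation(cfg)
            rows.append(
                {
                    "D": float(D),
                    "rho": float(rho),
                    "r_global": summary.r_global,
                    "n_contributing": summary.n_contributing,
                    "n_excluded": summary.n_excluded,
                }
            )
    return pd.DataFrame(rows)
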