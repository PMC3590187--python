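"""Closed-form two-individual theory of the coupled logistic pair.

Two coupled males admit only two wiring patterns: **bidirectional**
(each watches the other) and **leader-follower** (master-slave: only the
follower is coupled).  Writing the amplitude difference
``Delta_n = x_i - x_j``, one update multiplies it by

    bidirectional:    (1 - 2 D) * mu * (1 - x_i - x_j)
    leader-follower:  (1 - D)   * mu * (1 - x_i - x_j)

and since ``|1 - x_i - x_j| <= 1`` on the invariant square, the
contraction factor

    nu = |1 - 2 D| * mu      (bidirectional)
    nu = (1 - D) * mu        (leader-follower)

gives a *sufficient* synchronization condition ``nu < 1``.  It is not
necessary: at ``mu = 3.2`` the bidirectional pair is observed numerically
to synchronize for every ``D > ~0.058`` although ``nu < 1`` only holds
for ``D > 0.34375``.  At ``D = 0.5`` the bidirectional factor vanishes,
so any pair synchronizes in a single step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairState",
    "PairCondition",
    "ThresholdEstimate",
    "pair_step",
    "delta_update_factor",
    "sync_condition",
    "estimate_sync_threshold",
]

_MODES = ("bidirectional", "leader-follower")


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


@dataclass(frozen=True)
class PairState:
    """Displacements of the pair; ``delta`` is always ``x_i - x_j``."""

    x_i: float
    x_j: float

    @property
    def delta(self) -> float:
        return self.x_i - self.x_j


@dataclass(frozen=True)
class PairCondition:
    """Contraction factor ``nu`` and whether ``nu < 1`` (sufficient for sync)."""

    nu: float
    sufficient: bool
    mode: str


def pair_step(state: PairState, mu: float, D: float, mode: str) -> PairState:
    """One synchronous update of the two-individual system.

    In leader-follower mode ``x_i`` is the follower and ``x_j`` the
    leader (the leader's dynamics is the pure logistic map).
    """
    _check_mode(mode)
    f_i = mu * state.x_i * (1.0 - state.x_i)
    f_j = mu * state.x_j * (1.0 - state.x_j)
    if mode == "bidirectional":
        return PairState(
            x_i=(1.0 - D) * f_i + D * f_j,
            x_j=(1.0 - D) * f_j + D * f_i,
        )
    return PairState(x_i=(1.0 - D) * f_i + D * f_j, x_j=f_j)


def delta_update_factor(state: PairState, mu: float, D: float, mode: str) -> float:
    """One-step multiplier of the amplitude difference.

    Satisfies ``pair_step(state).delta == factor * state.delta`` exactly
    (up to round-off), because ``f(x_i) - f(x_j) = mu (1 - x_i - x_j) Delta``.
    """
    _check_mode(mode)
    shrink = 1.0 - 2.0 * D if mode == "bidirectional" else 1.0 - D
    return shrink * mu * (1.0 - state.x_i - state.x_j)


def sync_condition(mu: float, D: float, mode: str) -> PairCondition:
    """Analytic sufficient condition: contraction factor ``nu`` and its verdict."""
    _check_mode(mode)
    if not 1.0 < mu <= 4.0:
        raise ValueError(f"mu must satisfy 1 < mu <= 4, got {mu!r}")
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"D must satisfy 0 <= D <= 1, got {D!r}")
    nu = abs(1.0 - 2.0 * D) * mu if mode == "bidirectional" else (1.0 - D) * mu
    return PairCondition(nu=float(nu), sufficient=bool(nu < 1.0), mode=mode)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Numerical synchronization threshold over a coupling grid.

    ``threshold`` is the smallest grid ``D`` such that *every* grid value
    at or above it synchronized all trials (guarding against re-entrant
    desynchronization windows); ``None`` when even the largest grid value
    failed.  ``table`` holds per-``D`` fractions and median sync times.
    """

    threshold: float | None
    table: pd.DataFrame
    mu: float
    mode: str
    trials: int
    max_iter: int
    tol: float


def estimate_sync_threshold(
    mu: float,
    mode: str,
    D_grid: np.ndarray,
    trials: int = 200,
    max_iter: int = 100_000,
    tol: float = 1e-9,
    rng: np.random.Generator | None = None,
) -> ThresholdEstimate:
    """Monte-Carlo estimate of the coupling needed for guaranteed sync.

    For each grid ``D``, iterate the pair from ``trials`` independent
    uniform initial conditions; a trial synchronizes when ``|Delta|``
    drops below ``tol`` within ``max_iter`` steps.  All trials for all
    grid values are advanced together in one vectorised sweep.
    """
    _check_mode(mode)
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials!r}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol!r}")
    D_grid = np.sort(np.asarray(D_grid, dtype=float))
    if D_grid.size == 0:
        raise ValueError("D_grid must not be empty")
    if rng is None:
        rng = np.random.default_rng()

    n_d = D_grid.size
    D_flat = np.repeat(D_grid, trials)
    xi = rng.uniform(size=n_d * trials)
    xj = rng.uniform(size=n_d * trials)
    sync_time = np.full(n_d * trials, -1, dtype=np.int64)

    active = np.flatnonzero(np.abs(xi - xj) >= tol)
    sync_time[np.abs(xi - xj) < tol] = 0
    for step in range(1, max_iter + 1):
        if active.size == 0:
            break
        a_xi, a_xj, a_D = xi[active], xj[active], D_flat[active]
        f_i = mu * a_xi * (1.0 - a_xi)
        f_j = mu * a_xj * (1.0 - a_xj)
        new_i = (1.0 - a_D) * f_i + a_D * f_j
        if mode == "bidirectional":
            new_j = (1.0 - a_D) * f_j + a_D * f_i
        else:
            new_j = f_j
        xi[active], xj[active] = new_i, new_j
        done = np.abs(new_i - new_j) < tol
        if done.any():
            sync_time[active[done]] = step
            active = active[~done]

    synced = (sync_time >= 0).reshape(n_d, trials)
    times = sync_time.reshape(n_d, trials).astype(float)
    times[~synced] = np.nan
    frac = synced.mean(axis=1)
    med = np.array(
        [np.nanmedian(row) if not np.all(np.isnan(row)) else np.nan for row in times]
    )
    table = pd.DataFrame(
        {"D": D_grid, "fraction_synchronized": frac, "median_sync_time": med}
    )

    all_ok = frac == 1.0
    threshold: float | None = None
    if all_ok[-1]:
        idx = n_d - 1
        while idx > 0 and all_ok[idx - 1]:
            idx -= 1
        threshold = float(D_grid[idx])
    return ThresholdEstimate(
        threshold=threshold,
        table=table,
        mu=mu,
        mode=mode,
        trials=trials,
        max_iter=max_iter,
        tol=tol,
    )
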