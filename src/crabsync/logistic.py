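"""The uncoupled logistic map: iteration, period detection, bifurcation scans.

The map ``x -> mu * x * (1 - x)`` is the dynamical kernel of the whole
simulator: each male's claw displacement follows it, coupled or not.  For
``0 < x_0 < 1`` and ``1 < mu <= 4`` every iterate stays in ``[0, 1]``; the
asymptotic behaviour runs from a stable fixed point (``mu < 3``, value
``1 - 1/mu``) through the period-doubling cascade (period 2 at ``mu = 3``,
period 4 at ``mu ~ 3.449``) to chaos past the accumulation point
``mu ~ 3.570``, with periodic windows above it (the widest, period 3,
around ``mu = 3.83``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MapParams",
    "PeriodReport",
    "BifurcationScan",
    "logistic_step",
    "iterate_map",
    "detect_period",
    "scan_bifurcation",
    "bifurcation_landmarks",
    "APERIODIC",
]

#: Sentinel period value meaning "no period <= p_max found".
APERIODIC = -1


@dataclass(frozen=True)
class MapParams:
    """Logistic constant ``mu`` and initial displacement ``x0``."""

    mu: float
    x0: float = 0.1

    def __post_init__(self) -> None:
        if not 1.0 < self.mu <= 4.0:
            raise ValueError(f"mu must satisfy 1 < mu <= 4, got {self.mu!r}")
        if not 0.0 < self.x0 < 1.0:
            raise ValueError(f"x0 must satisfy 0 < x0 < 1, got {self.x0!r}")


@dataclass(frozen=True)
class PeriodReport:
    """Detected cycle of a trajectory tail.

    ``period`` is the smallest ``p`` with ``|x[n+p] - x[n]| < tolerance``
    for every ``n`` in the tail, or :data:`APERIODIC` if none ``<= p_max``
    exists.  ``orbit_values`` holds one cycle (empty when aperiodic).
    """

    period: int
    orbit_values: np.ndarray
    tolerance: float

    @property
    def is_periodic(self) -> bool:
        return self.period != APERIODIC


def logistic_step(x, mu):
    """One application of the logistic map, elementwise on arrays.

    Raises ``ValueError`` naming the offending parameter when ``x`` leaves
    ``[0, 1]`` or ``mu`` leaves ``(0, 4]``.
    """
    x = np.asarray(x, dtype=float)
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x[(x < 0) | (x > 1)][:3]}")
    if np.any(mu_arr <= 0.0) or np.any(mu_arr > 4.0):
        raise ValueError(f"mu must lie in (0, 4], got {mu!r}")
    out = mu_arr * x * (1.0 - x)
    if out.ndim == 0:
        return float(out)
    return out


def iterate_map(params: MapParams, n_steps: int) -> np.ndarray:
    """Iterate from ``params.x0`` for ``n_steps`` steps.

    Returns the full trajectory of length ``n_steps + 1`` (including the
    initial condition).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps!r}")
    traj = np.empty(n_steps + 1)
    traj[0] = params.x0
    x = params.x0
    for n in range(n_steps):
        x = params.mu * x * (1.0 - x)
        traj[n + 1] = x
    return traj


def detect_period(
    tail: np.ndarray, tol: float = 1e-8, p_max: int = 64
) -> PeriodReport:
    """Smallest period ``p <= p_max`` shift-matching the whole tail.

    ``tail`` must already be past the transient and hold at least
    ``2 * p_max`` samples so every candidate shift is tested against at
    least ``p_max`` pairs.
    """
    tail = np.asarray(tail, dtype=float)
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol!r}")
    if tail.size < 2 * p_max:
        raise ValueError(
            f"tail of length {tail.size} too short for p_max={p_max}; need >= {2 * p_max}"
        )
    for p in range(1, p_max + 1):
        if np.all(np.abs(tail[p:] - tail[:-p]) < tol):
            return PeriodReport(period=p, orbit_values=tail[-p:].copy(), tolerance=tol)
    return PeriodReport(period=APERIODIC, orbit_values=np.empty(0), tolerance=tol)


@dataclass(frozen=True)
class BifurcationScan:
    """Asymptotic samples and detected periods over a ``mu`` grid."""

    mu: np.ndarray            # (n_mu,)
    samples: np.ndarray       # (n_mu, n_samples) last iterates after transient
    periods: np.ndarray       # (n_mu,) int, APERIODIC where no cycle found
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (mu, sample_index)."""
        n_mu, n_s = self.samples.shape
        return pd.DataFrame(
            {
                "mu": np.repeat(self.mu, n_s),
                "sample_index": np.tile(np.arange(n_s), n_mu),
                "x_value": self.samples.ravel(),
                "period": np.repeat(self.periods, n_s),
            }
        )


def scan_bifurcation(
    mu_grid: np.ndarray,
    transient: int = 2000,
    samples: int = 128,
    tol: float = 1e-8,
    p_max: int = 64,
    x0: float = 0.1,
) -> BifurcationScan:
    """Asymptotic values and periods for every ``mu`` on the grid.

    All grid points are iterated simultaneously (one vectorised map per
    step) from the common initial condition ``x0``; the last ``samples``
    iterates after ``transient`` steps feed :func:`detect_period`.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if mu_grid.size == 0:
        raise ValueError("mu_grid must not be empty")
    if np.any(mu_grid <= 1.0) or np.any(mu_grid > 4.0):
        raise ValueError("mu_grid values must lie in (1, 4]")
    if transient < 1:
        raise ValueError(f"transient must be >= 1, got {transient!r}")
    if samples < 2 * p_max:
        raise ValueError(f"samples must be >= 2*p_max={2 * p_max}, got {samples!r}")

    x = np.full(mu_grid.shape, x0)
    for _ in range(transient):
        x = mu_grid * x * (1.0 - x)
    out = np.empty((mu_grid.size, samples))
    for s in range(samples):
        x = mu_grid * x * (1.0 - x)
        out[:, s] = x
    periods = np.array(
        [detect_period(row, tol=tol, p_max=p_max).period for row in out], dtype=int
    )
    return BifurcationScan(mu=mu_grid.copy(), samples=out, periods=periods, tolerance=tol)


def bifurcation_landmarks(
    mu_grid: np.ndarray | None = None,
    transient: int = 50_000,
    tol: float = 1e-8,
    p_max: int = 64,
    x0: float = 0.1,
) -> dict:
    """Locate the classic bifurcation landmarks on a ``mu`` grid.

    Returns a dict with the grid values of: ``period2_onset`` and
    ``period4_onset`` (smallest mu whose detected period is >= 2, resp.
    >= 4), ``chaos_onset`` (smallest aperiodic mu above the period-4
    onset — the point where the detected period exceeds ``p_max``), and
    ``period3_window`` (the widest contiguous period-3 run above the
    chaos onset, as a (low, high) pair, or None).

    The long default transient resolves the critical slowing next to each
    period-doubling point; exactly-neutral grid points (mu = 3 itself)
    never converge at any finite transient, which is why the chaos onset
    is anchored above the period-4 onset.
    """
    if mu_grid is None:
        mu_grid = 2.5 + 0.005 * np.arange(301)  # 2.5 .. 4.0 inclusive
    scan = scan_bifurcation(
        mu_grid, transient=transient, samples=2 * p_max, tol=tol, p_max=p_max, x0=x0
    )
    mu, periods = scan.mu, scan.periods

    def first(mask: np.ndarray) -> float | None:
        idx = np.flatnonzero(mask)
        return float(mu[idx[0]]) if idx.size else None

    p2 = first(periods >= 2)
    p4 = first(periods >= 4)
    chaos = None
    if p4 is not None:
        chaos = first((periods == APERIODIC) & (mu > p4))

    window = None
    if chaos is not None:
        above = (mu > chaos) & (periods == 3)
        runs: list[tuple[float, float]] = []
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append((float(mu[start]), float(mu[i - 1])))
                start = None
        if start is not None:
            runs.append((float(mu[start]), float(mu[-1])))
        if runs:
            window = max(runs, key=lambda r: r[1] - r[0])

    return {
        "period2_onset": p2,
        "period4_onset": p4,
        "chaos_onset": chaos,
        "period3_window": window,
        "scan": scan,
    }
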