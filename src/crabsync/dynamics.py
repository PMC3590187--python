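"""Coupled logistic update over the interaction network.

Every male updates synchronously as

    x'_i = (1 - D) * f_mu(x_i) + D * f_mu(Xbar_i),      f_mu(x) = mu x (1 - x),

where ``Xbar_i`` is the mean claw displacement of the individuals inside
i's field of attention.  A leader (nobody in its sector) follows the pure
logistic map ``x'_i = f_mu(x_i)``.  Since both terms lie in ``[0, mu/4]``
and the update is a convex combination, the state stays in ``[0, 1]`` for
any network and any ``D`` in ``[0, 1]``.

Two optional variations: ``coupling_variant="distance-weighted"`` weights
the neighbourhood mean by ``1 / d**weight_exponent`` (closer neighbours
count more), and ``coupling_form="mean_of_map"`` couples through the
average of the mapped neighbour values ``mean_j f_mu(x_j)`` instead of
the map of the average — the two coincide on single-neighbour graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .spatial import (
    InteractionNetwork,
    Population,
    build_network,
    orient_preferential,
    orient_random,
    place_individuals,
)

__all__ = [
    "TrajectorySet",
    "neighborhood_mean",
    "coupled_step",
    "run_simulation",
    "replicate_seeds",
]


@dataclass
class TrajectorySet:
    """Measured displacement window plus the network and config that made it."""

    values: np.ndarray              # (n_l, N) displacements, transient removed
    network: InteractionNetwork
    population: Population
    config: SimulationConfig
    initial_state: np.ndarray       # (N,) displacements at n = 0

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def window(self) -> int:
        return self.values.shape[0]


def _edge_weights(net: InteractionNetwork, variant: str, exponent: float) -> np.ndarray:
    """Per-edge weights normalised to sum to one within each source."""
    if variant == "plain":
        w = np.ones(net.n_edges)
    elif variant == "distance-weighted":
        w = 1.0 / np.power(net.dist, exponent)
    else:
        raise ValueError(
            f"coupling_variant must be 'plain' or 'distance-weighted', got {variant!r}"
        )
    sums = np.bincount(net.src, weights=w, minlength=net.n)
    return w / sums[net.src]


def neighborhood_mean(
    state: np.ndarray,
    net: InteractionNetwork,
    i: int | None = None,
    variant: str = "plain",
    weight_exponent: float = 1.0,
) -> float | np.ndarray | None:
    """Mean displacement inside each field of attention (Xbar_i).

    With ``i`` given, returns that individual's value or ``None`` when it
    has no neighbour (the mean is an empty sum); otherwise returns the
    full vector with ``NaN`` flagging neighbour-less individuals.
    """
    state = np.asarray(state, dtype=float)
    w = _edge_weights(net, variant, weight_exponent)
    sums = np.bincount(net.src, weights=w * state[net.dst], minlength=net.n)
    means = np.where(net.out_degree > 0, sums, np.nan)
    if i is None:
        return means
    return None if net.out_degree[i] == 0 else float(means[i])


def coupled_step(
    state: np.ndarray,
    net: InteractionNetwork,
    mu: float,
    D: float,
    variant: str = "plain",
    form: str = "map_of_mean",
    weight_exponent: float = 1.0,
    _weights: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update of the whole lattice."""
    state = np.asarray(state, dtype=float)
    fx = mu * state * (1.0 - state)
    if net.n_edges == 0:
        return fx
    w = _edge_weights(net, variant, weight_exponent) if _weights is None else _weights
    if form == "map_of_mean":
        xbar = np.bincount(net.src, weights=w * state[net.dst], minlength=net.n)
        coupled = mu * xbar * (1.0 - xbar)
    elif form == "mean_of_map":
        coupled = np.bincount(net.src, weights=w * fx[net.dst], minlength=net.n)
    else:
        raise ValueError(f"coupling_form must be 'map_of_mean' or 'mean_of_map', got {form!r}")
    has_nb = net.out_degree > 0
    return np.where(has_nb, (1.0 - D) * fx + D * coupled, fx)


def prepare_population(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Population, InteractionNetwork, np.ndarray]:
    """Place, draw initial displacements, orient, and wire up one lattice.

    Initial displacements are drawn before orientation so the M2
    similarity tie-break can consult them (orientation precedes the
    dynamics; displacements at orientation time are the initial values).
    """
    pop = place_individuals(config.grid, rng, R=config.R, theta=config.theta)
    x0 = rng.uniform(0.0, 1.0, size=pop.n)
    if config.model == "M1":
        orient_random(pop, rng)
    else:
        orient_preferential(pop, rng, tie_rule=config.tie_rule, displacements=x0)
    net = build_network(pop, boundary_rule=config.boundary_rule)
    return pop, net, x0


def run_simulation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TrajectorySet:
    """Full lattice run: place, orient, couple, iterate, measure.

    Iterates ``n_transient + n_l`` synchronous steps from independent
    uniform initial displacements and returns the final ``n_l`` states.
    Deterministic given ``config.seed`` (when ``rng`` is not supplied).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop, net, x = prepare_population(config, rng)
    weights = (
        _edge_weights(net, config.coupling_variant, config.weight_exponent)
        if net.n_edges
        else None
    )
    x0 = x.copy()
    window = np.empty((config.n_l, pop.n))
    total = config.n_transient + config.n_l
    for n in range(total):
        x = coupled_step(
            x,
            net,
            config.mu,
            config.D,
            variant=config.coupling_variant,
            form=config.coupling_form,
            weight_exponent=config.weight_exponent,
            _weights=weights,
        )
        if n >= config.n_transient:
            window[n - config.n_transient] = x
    return TrajectorySet(
        values=window, network=net, population=pop, config=config, initial_state=x0
    )


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, order-independent child seeds (< 2**31) for replicates."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
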