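"""Lattice populations, sector-shaped fields of attention, interaction networks.

Each male occupies one lattice site (its burrow) and watches a circular
sector of reach ``R`` and angle ``theta`` centred on its orientation
``phi``.  Two orientation rules are provided: **M1** draws ``phi``
uniformly at random; **M2** points the sector so as to maximise the
number of neighbours inside it (ties between distinct best coverages are
broken at random, or by displacement similarity).  The directed edge
``i -> j`` means "j is inside i's field of attention"; a *leader* has
out-degree zero, a *follower* out-degree >= 1.

Geometry conventions: sites sit at integer coordinates, distances are
Euclidean between site centres, and both the distance (<= R) and angular
(<= theta/2) tests are inclusive.  The lattice has absorbing boundaries:
no wrap-around, sectors are simply clipped by the grid edge (the
out-of-grid area contains nobody).  A stricter reading — individuals
whose sector leaves the grid receive no coupling at all — is available
as ``boundary_rule="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import GridConfig

__all__ = [
    "Population",
    "InteractionNetwork",
    "NetworkStats",
    "place_individuals",
    "in_sector",
    "orient_random",
    "orient_preferential",
    "build_network",
    "network_statistics",
]

#: Absolute slack (degrees / site units) keeping inclusive boundary tests
#: stable under floating-point rounding of angles and distances.
GEOM_TOL = 1e-9


@dataclass
class Population:
    """Occupied lattice sites plus each male's attention sector."""

    grid: GridConfig
    positions: np.ndarray          # (N, 2) int, distinct (col, row) in [0, L)^2
    R: float
    theta: float
    phi: np.ndarray | None = None  # (N,) orientation in [0, 360), None before orienting
    model_tag: str | None = None

    @property
    def n(self) -> int:
        return len(self.positions)

    def central_mask(self) -> np.ndarray:
        """Boolean mask of individuals inside the centred ``L_c x L_c`` sub-grid."""
        off = self.grid.central_offset()
        hi = off + self.grid.L_c
        p = self.positions
        return (
            (p[:, 0] >= off) & (p[:, 0] < hi) & (p[:, 1] >= off) & (p[:, 1] < hi)
        )

    def sector_fits_inside(self) -> np.ndarray:
        """Mask of individuals whose full attention disc lies within the grid.

        Conservative (disc-based) test used only by the literal boundary
        rule; with the default clipping rule it is irrelevant.
        """
        p = self.positions
        L = self.grid.L
        return (
            (p[:, 0] - self.R >= 0)
            & (p[:, 0] + self.R <= L - 1)
            & (p[:, 1] - self.R >= 0)
            & (p[:, 1] + self.R <= L - 1)
        )


@dataclass
class InteractionNetwork:
    """Directed "watches" relation: edge ``src -> dst`` iff dst is in src's sector."""

    n: int
    src: np.ndarray        # (E,) int
    dst: np.ndarray        # (E,) int
    dist: np.ndarray       # (E,) float, Euclidean src->dst distance
    out_degree: np.ndarray  # (n,) int, the neighbour count N_i of the update rule

    reciprocal: np.ndarray = field(init=False)  # (E,) bool: reverse edge exists

    def __post_init__(self) -> None:
        keys = self.src.astype(np.int64) * self.n + self.dst
        rev = self.dst.astype(np.int64) * self.n + self.src
        self.reciprocal = np.isin(rev, keys)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def undirected_graph(self) -> nx.Graph:
        """Undirected projection, including isolated individuals."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(zip(self.src.tolist(), self.dst.tolist()))
        return g


@dataclass(frozen=True)
class NetworkStats:
    """Leader/follower and reciprocity diagnostics of one network.

    ``leaders_per_follower`` is the mean, over followers (optionally only
    central-sub-grid ones), of the number of *leaders* inside that
    follower's field of attention; ``None`` when there are no followers.
    ``reciprocal_per_participant`` is the mean number of bidirectional
    links per individual that has at least one; ``None`` when nobody does.
    """

    n_leaders: int
    n_followers: int
    leaders_per_follower: float | None
    reciprocal_per_participant: float | None
    component_sizes: tuple[int, ...]
    n_central_followers: int
    upstream_leaders_per_follower: float | None = None


# ---------------------------------------------------------------------------
# placement and geometry


def place_individuals(
    grid: GridConfig, rng: np.random.Generator, R: float = 3.0, theta: float = 60.0
) -> Population:
    """Occupy ``round(rho * L**2)`` distinct sites uniformly at random."""
    n = grid.n_individuals
    sites = rng.choice(grid.L * grid.L, size=n, replace=False)
    positions = np.column_stack((sites % grid.L, sites // grid.L)).astype(int)
    return Population(grid=grid, positions=positions, R=R, theta=theta)


def _wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Fold angular offsets into [-180, 180)."""
    return (deg + 180.0) % 360.0 - 180.0


def in_sector(origin, phi: float, target, R: float, theta: float) -> bool:
    """Is ``target`` inside the sector at ``origin`` oriented along ``phi``?

    Inclusive on both boundaries: distance exactly ``R`` and angular
    offset exactly ``theta / 2`` both count.  ``theta = 360`` skips the
    angular test entirely (global attention).
    """
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.array_equal(origin, target):
        raise ValueError("origin and target coincide: an individual is not its own neighbor")
    delta = target - origin
    if np.hypot(delta[0], delta[1]) > R + GEOM_TOL:
        return False
    if theta >= 360.0:
        return True
    bearing = np.degrees(np.arctan2(delta[1], delta[0]))
    return bool(abs(_wrap_angle(np.asarray(bearing - phi))) <= theta / 2.0 + GEOM_TOL)


def _neighbor_geometry(pop: Population):
    """Pairs within reach: (src, dst, distance, bearing in degrees)."""
    p = pop.positions.astype(float)
    diff = p[None, :, :] - p[:, None, :]          # diff[i, j] = p_j - p_i
    dmat = np.hypot(diff[..., 0], diff[..., 1])
    within = dmat <= pop.R + GEOM_TOL
    np.fill_diagonal(within, False)
    src, dst = np.nonzero(within)
    bearings = np.degrees(np.arctan2(diff[src, dst, 1], diff[src, dst, 0]))
    return src, dst, dmat[src, dst], bearings


# ---------------------------------------------------------------------------
# orientation rules


def orient_random(pop: Population, rng: np.random.Generator) -> Population:
    """M1: orientations independent and uniform on [0, 360)."""
    pop.phi = rng.uniform(0.0, 360.0, size=pop.n)
    pop.model_tag = "M1"
    return pop


def orient_preferential(
    pop: Population,
    rng: np.random.Generator,
    tie_rule: str = "count-random",
    displacements: np.ndarray | None = None,
) -> Population:
    """M2: each sector oriented to maximise the number of visible neighbours.

    The maximum of a neighbour count over continuous ``phi`` is always
    attained with some neighbour on a sector edge, so it suffices to
    evaluate the finite candidate set {bearing to k, bearing +- theta/2}
    over neighbours k within reach.  Candidates achieving the maximal
    count are grouped by the *set* of neighbours they cover; one group is
    chosen uniformly at random (``count-random``) or, under the
    ``similarity`` rule, the group whose members' mean displacement is
    closest to the focal male's own current displacement (``displacements``
    required; remaining ties fall back to the first group).  Individuals
    with nobody in reach get a uniform random orientation.

    With ``theta = 360`` orientation is irrelevant and this is an alias of
    :func:`orient_random`, so M1 and M2 coincide exactly.
    """
    if pop.theta >= 360.0:
        orient_random(pop, rng)
        pop.model_tag = "M2"
        return pop
    if tie_rule not in ("count-random", "similarity"):
        raise ValueError(f"tie_rule must be 'count-random' or 'similarity', got {tie_rule!r}")
    if tie_rule == "similarity" and displacements is None:
        raise ValueError("similarity tie_rule requires current displacement values")

    src, dst, _, bearings = _neighbor_geometry(pop)
    half = pop.theta / 2.0
    phi = np.empty(pop.n)
    order = np.argsort(src, kind="stable")
    src_s, dst_s, bear_s = src[order], dst[order], bearings[order]
    starts = np.searchsorted(src_s, np.arange(pop.n + 1))

    for i in range(pop.n):
        lo, hi = starts[i], starts[i + 1]
        if lo == hi:
            phi[i] = rng.uniform(0.0, 360.0)
            continue
        ang = bear_s[lo:hi]
        nbrs = dst_s[lo:hi]
        cands = np.concatenate([ang, ang + half, ang - half])
        off = np.abs(_wrap_angle(ang[None, :] - cands[:, None]))
        cover = off <= half + GEOM_TOL
        counts = cover.sum(axis=1)
        best = np.flatnonzero(counts == counts.max())
        groups: dict[bytes, int] = {}
        for ci in best:
            groups.setdefault(cover[ci].tobytes(), int(ci))
        reps = list(groups.values())
        if len(reps) == 1:
            pick = reps[0]
        elif tie_rule == "similarity":
            own = displacements[i]
            dissim = [
                abs(float(displacements[nbrs[cover[ci]]].mean()) - own) for ci in reps
            ]
            pick = reps[int(np.argmin(dissim))]
        else:
            pick = reps[rng.integers(len(reps))]
        phi[i] = cands[pick] % 360.0

    pop.phi = phi
    pop.model_tag = "M2"
    return pop


# ---------------------------------------------------------------------------
# network construction and statistics


def build_network(pop: Population, boundary_rule: str = "clip") -> InteractionNetwork:
    """Directed interaction network from assigned orientations.

    ``boundary_rule="clip"`` (default): sectors truncated by the grid edge
    simply see fewer individuals.  ``"literal"``: an individual whose
    attention disc extends beyond the grid receives no coupling at all
    (its out-edges are dropped; it still appears in others' sectors).
    """
    if pop.phi is None:
        raise ValueError("orientations not assigned; call orient_random/orient_preferential")
    if boundary_rule not in ("clip", "literal"):
        raise ValueError(f"boundary_rule must be 'clip' or 'literal', got {boundary_rule!r}")
    src, dst, dists, bearings = _neighbor_geometry(pop)
    if pop.theta >= 360.0:
        keep = np.ones(len(src), dtype=bool)
    else:
        keep = np.abs(_wrap_angle(bearings - pop.phi[src])) <= pop.theta / 2.0 + GEOM_TOL
    if boundary_rule == "literal":
        keep &= pop.sector_fits_inside()[src]
    src, dst, dists = src[keep], dst[keep], dists[keep]
    out_degree = np.bincount(src, minlength=pop.n)
    return InteractionNetwork(n=pop.n, src=src, dst=dst, dist=dists, out_degree=out_degree)


def _upstream_leader_counts(net: InteractionNetwork, followers: np.ndarray) -> np.ndarray:
    """Distinct leaders reachable from each follower along watch-edges.

    Influence propagates through the coupled dynamics: if i watches j and
    j watches a leader, the leader's rhythm reaches i through j.  The
    count of leaders whose dynamics feed (directly or transitively) into
    a follower is therefore the quantity deciding whether the follower is
    pulled by several independent pure-logistic sources at once.
    """
    adj: list[list[int]] = [[] for _ in range(net.n)]
    for s, d in zip(net.src.tolist(), net.dst.tolist()):
        adj[s].append(d)
    is_leader = net.out_degree == 0
    counts = np.zeros(len(followers), dtype=int)
    for k, f in enumerate(followers):
        seen = {int(f)}
        stack = [int(f)]
        total = 0
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    if is_leader[nxt]:
                        total += 1
                    else:
                        stack.append(nxt)
        counts[k] = total
    return counts


def network_statistics(
    net: InteractionNetwork,
    pop: Population,
    central_only: bool = True,
    include_upstream: bool = False,
) -> NetworkStats:
    """Leader/follower counts, leaders-per-follower, reciprocity, components.

    A leader watches nobody (out-degree 0); every other individual is a
    follower.  ``leaders_per_follower`` averages, over followers (by
    default only those inside the central sub-grid, to avoid boundary
    effects), the number of leaders *directly* inside each follower's
    sector.  With ``include_upstream=True`` the transitive variant —
    distinct leaders whose dynamics reach the follower through any chain
    of watch-edges — is also reported; this is the count that governs
    whether a follower is torn between independent rhythm sources.
    """
    is_leader = net.out_degree == 0
    n_leaders = int(is_leader.sum())
    n_followers = net.n - n_leaders

    leaders_seen = np.bincount(net.src, weights=is_leader[net.dst].astype(float), minlength=net.n)
    follower_mask = ~is_leader
    if central_only:
        follower_mask &= pop.central_mask()
    n_central_followers = int(follower_mask.sum())
    leaders_per_follower = (
        float(leaders_seen[follower_mask].mean()) if n_central_followers else None
    )

    recip_count = np.bincount(net.src[net.reciprocal], minlength=net.n)
    participants = recip_count > 0
    reciprocal_per_participant = (
        float(recip_count[participants].mean()) if participants.any() else None
    )

    sizes = tuple(
        sorted(len(c) for c in nx.connected_components(net.undirected_graph()))
    )

    upstream = None
    if include_upstream and n_central_followers:
        counts = _upstream_leader_counts(net, np.flatnonzero(follower_mask))
        upstream = float(counts.mean())

    return NetworkStats(
        n_leaders=n_leaders,
        n_followers=n_followers,
        leaders_per_follower=leaders_per_follower,
        reciprocal_per_participant=reciprocal_per_participant,
        component_sizes=sizes,
        n_central_followers=n_central_followers,
        upstream_leaders_per_follower=upstream,
    )
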