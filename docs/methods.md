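# Methods

## Model

Space is an `L × L` square lattice of burrow sites; `round(ρL²)` males
occupy distinct sites drawn uniformly at random, one per site, and never
move. Each male `i` has a *field of attention*: a circular sector of
reach `R` (site units), angle `θ` (degrees) and orientation `φ_i`,
covering area `θπR²/360`. Individual `j` is inside `i`'s field when the
Euclidean distance between site centres is `≤ R` **and** the angular
offset between `φ_i` and the `i→j` bearing is `≤ θ/2`; both comparisons
are inclusive, with an absolute slack of `1e−9` (degrees / site units)
so boundary-touching configurations are counted stably under float
rounding. At `θ = 360°` the angular test is skipped.

The claw displacement `x_n^i ∈ [0, 1]` evolves synchronously as

```
x_{n+1}^i = (1 − D) f_µ(x_n^i) + D f_µ(X̄_n^i),    f_µ(x) = µ x (1 − x),
```

with `X̄_n^i` the arithmetic mean displacement over the `N^i`
individuals in `i`'s field. When `N^i = 0` (a *leader*), the update is
the pure logistic map. Because both terms lie in `[0, µ/4] ⊆ [0, 1]` and
the update is a convex combination for `D ∈ [0, 1]`, states are bounded
for any network. The coupling term applies the map to the neighbourhood
*average* (`f_µ(X̄)`); this form reproduces the pair identities below
exactly. The alternative form — the average of mapped values,
`mean_j f_µ(x_j)` — coincides with it on single-neighbour graphs and is
available as `coupling_form="mean_of_map"` for sensitivity checks. A
second optional variation weights the neighbourhood mean by
`1/d^{i,j}` (exponent configurable, default 1), letting closer
neighbours count more.

### Orientation rules

* **M1** — `φ_i` independent, uniform on `[0, 360)`.
* **M2** — `φ_i` maximizes the number of individuals covered. The count,
  as a function of continuous `φ`, attains its maximum with some
  neighbour on a sector edge, so the finite candidate set
  `{bearing(i→k), bearing ± θ/2 : k within R}` contains an optimum;
  candidates achieving the maximal count are grouped by the exact set of
  neighbours covered, and one group is chosen uniformly at random.
  Under the `similarity` tie rule the group whose members' mean
  displacement is closest to the focal male's own (initial)
  displacement wins instead; displacements are drawn before orientation
  so this rule is well defined. A male with nobody in reach gets a
  uniform random orientation; by distance symmetry it then participates
  in no edge. At `θ = 360°` orientation is irrelevant and M2 is an alias
  of M1.

### Boundaries

The lattice is absorbing: no wrap-around, and a sector extending beyond
the grid simply contains nobody (clipping). A stricter reading — a male
whose attention disc leaves the grid receives *no* coupling at all — is
implemented as `boundary_rule="literal"` but is not the default; under
clipping, boundary males just see fewer neighbours, which is the less
surprising behaviour and leaves interior dynamics untouched.

## Synchrony statistics

`r_i` is the mean Pearson correlation between `x^i` and each visible
neighbour `x^j` over the `n_l`-step measurement window. The global
statistic `⟨r⟩` averages `r_i` over individuals inside the centred
`L_c × L_c` sub-grid (to suppress boundary effects) that have `N^i ≥ 1`,
then over `s_t` independently seeded replicates; excluded (neighbourless)
individuals are counted and reported.

Degenerate-variance convention: a series with standard deviation below
`1e−9` counts as constant. Two constant series correlate at 1 when their
means agree within the same threshold, else 0; a constant against an
oscillating series correlates at 0. This makes the fixed-point regime
(`µ < 3`, everyone at `1 − 1/µ`) report `⟨r⟩ = 1` rather than an
undefined value, and scores a frozen male against oscillating
neighbours as unsynchronized.

## Network diagnostics

A *leader* has out-degree 0; everyone else is a *follower*. Reported per
network: leader/follower counts; `leaders_per_follower` — the mean, over
central-sub-grid followers, of the number of leaders directly inside the
follower's field of attention (`None`, never 0, when there are no
followers); `reciprocal_per_participant` — mean number of bidirectional
links per individual having at least one; connected-component sizes of
the undirected projection ("unlinked groups"). An optional transitive
variant, `upstream_leaders_per_follower`, counts the distinct leaders
whose dynamics reach a follower through any chain of watch-edges — the
quantity that decides whether a follower is pulled by several
independent pure-logistic rhythm sources at once. The direct and
transitive counts differ sharply at intermediate densities (at M1,
θ=60°, ρ=0.3: ≈0.3 direct vs ≈2 transitive) and the transitive one is
the better predictor of the synchrony dip there.

## Two-individual theory

For an isolated pair the update reduces to closed form. Writing
`Δ_n = x^i − x^j`:

* mutual coupling: `Δ_{n+1} = (1 − 2D) µ (1 − x^i − x^j) Δ_n`,
* leader–follower: `Δ_{n+1} = (1 − D) µ (1 − x^i − x^j) Δ_n`.

Since `|1 − x^i − x^j| ≤ 1`, the contraction factor `ν = |1−2D| µ`
(resp. `(1−D) µ`) bounds `|Δ_{n+1}| ≤ ν |Δ_n|`, and `ν < 1` is
sufficient for synchronization; at `D = 0.5` a mutual pair synchronizes
in one step. The condition is not necessary, so the package also
estimates the empirical threshold: for each `D` on a grid, `trials`
uniform random pairs are iterated until `|Δ| < tol` (synchronized) or
`max_iter` steps elapse; the reported threshold is the smallest grid `D`
whose entire upper grid tail synchronized every trial, guarding against
re-entrant desynchronization windows. Defaults: grid step 0.002,
200 trials, `max_iter = 10⁵`, `tol = 1e−9`. At `µ = 3.2` this yields a
threshold of 0.060 on that grid (the sufficient condition alone would
require `D > 0.34375`).

## Period detection and bifurcation landmarks

`detect_period` reports the smallest `p ≤ p_max` with
`|x_{n+p} − x_n| < tol` across a tail of at least `2·p_max` samples
(defaults `tol = 1e−8`, `p_max = 64`; aperiodic flag otherwise). The
general-purpose bifurcation scan uses a 2000-step transient. The
landmark locator uses a 50 000-step transient instead: next to each
period-doubling point the new cycle is approached at a rate
`1 − O(µ − µ_c)`, so grid points within ~10⁻³ of an onset need tens of
thousands of steps to settle below `tol`. Exactly at `µ = 3` the fixed
point is neutral and never settles at any finite transient, which is why
the "onset of chaos" landmark is defined as the smallest aperiodic grid
`µ` *above the period-4 onset*. On the default grid (2.5 to 4.0, step
0.005, `x0 = 0.1`) the landmarks come out at 3.005 (period 2), 3.450
(period 4), 3.570 (period > 64) and the period-3 window [3.830, 3.840].

## Run protocol and reproducibility

A run draws placement, initial displacements (independent uniform on
(0, 1) — the single-map figure convention `x0 = 0.1` applies only to the
uncoupled scan), then orientation, then iterates
`n_transient + n_l` steps and keeps the final `n_l` states. Defaults
follow the reference conditions: `R = 3`, `L = 30`, `L_c = 10`,
`θ = 60°`, `n_transient = n_l = 500`, `s_t = 500`. One master seed
spawns per-replicate child seeds through `numpy.random.SeedSequence`
(each reduced below 2³¹), so replicates are individually reproducible
and order-independent; every stochastic operation is a pure function of
its inputs and seed, and repeated runs are bit-identical.

Desk-scale defaults used by the test suite and the acceptance script:
500 network placements for the leader statistics, 200 for reciprocity,
and `s_t = 50` dynamical replicates for `⟨r⟩` — at these sizes the
replicate standard error of `⟨r⟩` is well under 0.02, an order of
magnitude below the tolerances being checked, while a full suite run
stays around half a minute.

## Design choices where the model was genuinely open

* Population size rounds `ρL²` to the nearest integer.
* `D = 1` is admitted (pure neighbourhood-driven update) although the
  interesting regime is `0 < D < 1`; it makes the convexity-based
  boundedness property testable at its endpoint.
* A constant trajectory is reported with period 1, which the period-two
  claims treat as a degenerate 2-cycle: in coupled lattices a few
  individuals (≈2 % at µ=3.2, ρ=0.4, D=0.5) are genuinely stabilized
  onto a fixed value by their neighbours' antiphase rhythms.
* Ties between equally dissimilar M2 candidate groups under the
  `similarity` rule fall back to the first group in deterministic
  construction order.
* `leaders_per_follower` is `None` (undefined) when a network has no
  followers; means over replicates skip undefined values rather than
  imputing 0.

## What the generator emulates — and what it does not

The simulator reproduces the study conditions exactly as configured:
uniform random occupancy of a finite lattice, fixed sectors, synchronous
deterministic dynamics, homogeneous `µ` and `D`. Real colonies violate
most of these idealizations — crabs move between burrows, display in
bouts rather than continuously, differ in size and stamina (heterogeneous
`µ`, `D`), perceive neighbours through a graded visual system rather
than a hard sector, and experience exogenous interruptions (predators,
females, tides). Passing tests therefore validate the model's internal
consistency and its stated emergent behaviours, not the claim that real
fiddler crab synchrony follows these equations.

## Known limitations

* The transitive upstream-leader count is computed by per-follower
  depth-first search; at high density it touches most of the lattice per
  follower, so it is off by default in replicate statistics.
* Synchronized-manifold invariance is exact in exact arithmetic but only
  round-off-accurate numerically (the weighted neighbourhood mean of
  equal values rounds by 1 ulp); in chaotic regimes (`µ > 3.57`) that
  ulp is amplified, so equal-state lattices decorrelate numerically on
  Lyapunov timescales, as any finite-precision implementation must.
* Period detection near bifurcation points is transient-limited; the
  landmark scan's 50 000-step transient resolves a 0.005 grid but finer
  grids need proportionally longer transients.
* `estimate_sync_threshold` declares a trial synchronized on its first
  `|Δ| < tol` crossing; with `tol = 1e−9` spurious transversal crossings
  are measure-rare but not impossible in chaotic regimes.
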