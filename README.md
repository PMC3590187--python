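# crabsync

A spatially explicit simulator of synchronized waving displays in fiddler
crab (*Uca* spp.) aggregations, built on coupled logistic maps.

Male fiddler crabs wave their enlarged claw in rhythmic courtship
displays and often synchronize with their neighbours, forming local
"waving neighbourhoods". `crabsync` models a colony as a square lattice
of burrows: each male's claw displacement `x_n ∈ [0, 1]` follows the
logistic map `f_µ(x) = µx(1−x)`, coupled to the males inside its
sector-shaped *field of attention* (reach `R`, angle `θ`, orientation
`φ`):

```
x_{n+1}^i = (1 − D) f_µ(x_n^i) + D f_µ(X̄_n^i),     X̄_n^i = (1/N^i) Σ_j x_n^j
```

where the sum runs over the `N^i` individuals in i's sector and `D` is
the coupling constant. A male with an empty sector (a *leader*) follows
the pure logistic map. Two orientation rules are compared: **M1** points
each sector at random; **M2** points it so the number of visible
neighbours is maximal (they coincide at `θ = 360°`). Synchrony is
quantified by `r_i`, the mean Pearson correlation between a male's
trajectory and its visible neighbours' over a measurement window, and by
the global average `⟨r⟩` over the central sub-grid and many replicates.
For an isolated pair the amplitude difference `Δ = x^i − x^j` contracts
by `ν = |1−2D| µ` (mutual coupling) or `ν = (1−D) µ` (leader–follower)
per step, so `ν < 1` is a sufficient — not necessary — condition for
synchronization.

The package is aimed at researchers in collective animal behaviour who
want a tested, reproducible implementation of this model family for
parameter sweeps, network diagnostics, and comparison with field data.

## Worked example

```python
import numpy as np
from crabsync import SimulationConfig, global_correlation, sync_condition

# M1 lattice in the period-two regime (mu=3.2, rho=0.4, D=0.5)
cfg = SimulationConfig(mu=3.2, D=0.5, model="M1", theta=60.0, s_t=50, seed=1)
print(global_correlation(cfg).r_global)   # 0.8679811101631577
print(global_correlation(cfg.replace(model="M2")).r_global)  # 0.9799824017837784

cond = sync_condition(mu=3.2, D=0.5, mode="bidirectional")
print(cond.nu, cond.sufficient)           # 0.0 True
```

The first number says that with random sector orientation the colony
keeps a global correlation of about 0.87 — synchronized, but visibly
below 1 because some followers are caught in antiphase between leaders.
Re-orienting sectors toward neighbours (M2) pushes `⟨r⟩` to 0.98. The
last line confirms that at `D = 0.5` a mutually coupled pair has
contraction factor `ν = 0`: it synchronizes in a single time step.

The same functionality is exposed on the command line:

```bash
crabsync simulate --seed 1 --out run/           # trajectories + edge list
crabsync sweep-mu --seed 1 --uncoupled --out bif/  # bare-map bifurcation scan
crabsync sweep-phase --seed 1 --replicates 50 --out phase/  # <r> over (D, rho)
crabsync network-stats --seed 1 --model M2 --rho 0.65 --replicates 200 --out net/
crabsync pair-threshold --seed 1 --d-min 0.03 --d-max 0.12 --out thr/
crabsync pair-condition --mu 3.2 --coupling 0.5
```

All stochastic commands require `--seed` and write CSV tables plus a
JSON metadata record (config echo, seed, version, file checksums);
re-running with the same seed reproduces byte-identical payloads.

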