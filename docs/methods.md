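# Methods

## Model

Each node of a network is a sinusoidal (Kuramoto) oscillator standing
for a mesoscopic neural population. Two mechanisms are combined:

1. **Adaptive coupling.** The interaction gain of node *i* is
   modulated by its local synchrony
   `r_i = |Σ_j W_ij e^{iθ_j}| / Σ_j W_ij ∈ [0, 1]` — the coherence of
   its (weighted) input neighbourhood. This caricatures
   synchrony-dependent plasticity between populations: coherent drive
   couples more strongly. On binary graphs the in-strength
   normalisation reduces to the usual in-degree normalisation.
2. **Resource constraint.** Node *i* holds an excitability resource
   `λ_i` (a stand-in for metabolic reserves such as ATP/oxygen) that
   recovers toward a bath capacity `λ_o` at rate `α` and is consumed
   in proportion to local synchrony at rate `β r_i`:
   `dλ_i/dt = α(λ_o − λ_i) − β r_i`.

The phase equation is
`dθ_i/dt = ω_i + λ_i r_i Σ_j W_ij sin(θ_j − θ_i)` with
`ω_i ~ U[−1, 1]`. The coupling sum uses the raw weights with no degree
normalisation, so the resource scale that synchronizes a network grows
with its typical in-strength: a binary small-world graph with mean
degree 40 transitions at fixed resources Λ of order 0.1, whereas a
weighted connectome with in-strengths of order one transitions at Λ of
order 1. Global coherence is summarised by `R = |⟨e^{iθ}⟩|`.

**Mechanism of transient episodes.** With resources *fixed* at Λ, the
adaptive network shows an abrupt, hysteretic (explosive) transition:
forward and backward critical points `Λ_c(fw) > Λ_c(bw)` bracket a
region where both states are stable. With resource *dynamics*, `⟨λ⟩`
plays the role of Λ but is consumed by synchrony and replenished in
quiescence, so for intermediate `λ_o` the system cycles: resources
accumulate → crossing `Λ_c(fw)` ignites hypersynchronization →
consumption drags `⟨λ⟩` below `Λ_c(bw)` → collapse and recovery. On
the benchmark small-world network the package measures
`Λ_c(fw) ≈ 0.06–0.08` and `Λ_c(bw) ≈ 0.039`, and mean resources at
upward transitions (≈ 0.08) exceed those at downward transitions
(≈ 0.036), confirming the cycle.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | resource recovery rate (1/time) | 0.01 | recovery timescale 100 time units |
| `beta` | maximal consumption rate (1/time) | 0.002 | consumption at full local synchrony |
| `lambda_o` | resource-bath capacity | — | swept; bistable on SWN for ≈ 0.11–0.20 |
| `fixed_lambda` | fixed resource Λ | — | mutually exclusive with `lambda_o` |
| `dt` | Euler step | 0.05 | |
| `omega_range` | natural-frequency support | [−1, 1] | uniform |
| record stride | sampling of R, ⟨λ⟩, panels | 0.2 | 4 Euler steps |

Sweep conventions: adiabatic fixed-Λ sweeps carry the oscillator state
between consecutive Λ values (that is what makes them adiabatic) and
take stationary R as the mean over the last 25 % of each dwell;
bifurcation sweeps over `λ_o` discard the first 20 % of each dwell as
burn-in and classify a grid point as *incoherent* (R never above
`R_high`), *synchronized* (never below `R_low`) or *bistable* (both
visited), with defaults `R_low = 0.2`, `R_high = 0.5`. The synchronized
plateau of a weighted connectome is partial (R ≈ 0.6–0.75), so
connectome presets lower `R_high` to 0.45. Dwell lengths: 50 time
units (1,000 Euler steps) per Λ for the small-world hysteresis, 500
time units per `λ_o` for bifurcation classification, 2,000 for
connectome-scale sweeps. Tipping points are located as the grid value
at which the largest supra-threshold (default ΔR > 0.2) single-step
jump of a branch lands — robust on coarse grids where derivative
fitting is not.

For the recovery-to-consumption (α/β) analysis, the bistable window
scales roughly with β/α (consumption depresses the steady resource
level by about `(β/α)·r`), so each β gets a `λ_o` grid spanning
`[stop/n, 0.1 + 1.25 β/α]` and a dwell of at least `0.75/β` — a fixed
grid would let the upper boundary escape at large β and under-resolve
the narrow region at small β. The tES probability of a diagram is the
trapezoidal area under the synchronized-time fraction across the
bistable region, normalised by the region's width.

## Transients, communities, cluster tracking

A transient episode is anchored at its **onset index**: the last
instant with `R < desync_threshold` before an upward crossing of
`sync_threshold` (defaults 0.1 and 0.5; crossings within a 100-time-
unit refractory window of the previous event are skipped). Fixed
50-time-unit windows of per-node phases and local synchrony are cut
from that anchor. **Active nodes** of a window are those whose mean
`r_i` over its final 20 % (the forming plateau) exceeds 0.7.

Community structure is obtained by Louvain on the max-symmetrized
weighted graph (resolution 1); the reported modularity is evaluated
directly on the returned partition. Intramodular synchrony is the
modulus of a community's mean phasor, `IMS_c = |P_c|`; intermodular
synchrony of a pair is `|(P_{c1} + P_{c2})/2|`, the exact algebraic
reduction of the mean pairwise phasor sum (the literal double sum
factorises; tests verify the identity to 1e-12). Trial averaging
averages IMS values, not phasors, across windows.

The **synchronization cluster tracking algorithm** builds clusters at
each evaluation instant (default every 0.2 time units) by seeded
breadth-first expansion over the undirected skeleton: a node joins iff
its own `r_i` is at or above the threshold (default 0.5), and the
frontier advances only through joined nodes, so a sub-threshold node
blocks the path. Previous clusters re-seed first (in descending
previous size), each from its carried-over central node of highest
current `r`, and inherit their id; remaining supra-threshold nodes
seed fresh clusters in descending-`r` order; each cluster's up-to-five
highest-`r` members become the next instant's central nodes. The
member sets produced this way are exactly the connected components of
the supra-threshold induced subgraph — the seeding machinery only adds
temporal identity. Ties are fixed and documented: main cluster =
largest, ties to smallest id; variance of residence times uses the
population (divide-by-n) convention. A node's time in the main
(largest) cluster is the window duration times the fraction of
evaluation instants at which it belonged to it. Driver candidates
combine high out-degree (> 30), high median residence (> 35 of 50 time
units) and low variance (< 49) across windows.

## Graph metrics

Path length is the exact BFS mean over ordered node pairs (largest
component if disconnected; directed graphs are measured on their
binarized undirected skeleton). Clustering is the mean local
triangle density. The small-world coefficient
`ω = L_rand/L − C/C_latt` uses 10 degree-preserving randomized
references (double-edge swaps, all valid swaps accepted) for `L_rand`
and a degree-preserving *latticized* reference (swaps accepted only
when they shorten ring distance, 4000 attempted swaps per edge — past
the point where acceptances stall) for `C_latt`; ω is −1-ish for a
ring lattice, +1-ish for a random graph and near 0 for a small world.
A fresh ring lattice would overestimate `C_latt` (0.73 vs ≈ 0.53
achievable by degree-preserving latticization of these graphs) and
push ω up by ≈ 0.17. The degree-distribution exponent is a
least-squares slope of log-count versus log-degree over occupied
integer bins — a deliberately crude summary adequate for
distinguishing heavy-tailed from Gaussian-like degree distributions,
not a maximum-likelihood tail estimate.

## Synthetic connectome fixture

`make_synthetic_connectome` emulates the gross features of a mesoscale
mammalian connectome so the whole pipeline runs without external data:
weighted, directed, bilaterally mirrored (hemisphere 1 is an exact
mirror copy of hemisphere 0, including its cross-hemisphere block),
modular (planted modules span both hemispheres and are linked by dense
homotopic, callosal-like edges at the intra-module density), with
heavy-tailed Pareto weights (tail index 3) rescaled to [0, 1].
`module_strengths` scales each module's *input* rows, creating weakly
integrated modules that are not recruited into global
synchronization — scaling only within-module weights does not achieve
this, because a module can still be entrained through its incoming
cross-module edges.

What the fixture does **not** emulate: real anatomical hierarchy and
spatial embedding, hub architecture, the empirical weight-degree
correlations, or the exact size (60 regions rather than 426).
Consequently, tests on the fixture establish the *mechanisms* —
recurrence of onset-anchored transients, a partial plateau with a
non-participating weak module, wave-like earlier/higher
synchronization of strongly coupled modules, threshold-robust core
nodes — not the connectome-specific numbers, which require supplying
the real dataset (see `tests/test_external_connectome.py`).

Fixture study conditions (chosen once, then frozen): 60 regions, 3
modules, densities 0.5/0.05, input strengths (1, 1, 0.1),
`α = 0.01, β = 0.002, λ_o = 1.0`, four 2,000-time-unit runs with
consecutive seeds; onset thresholds 0.2/0.6 because the finite-size
incoherent floor at n = 60 (≈ 1/√60) sits above the defaults that suit
n = 400.

## Numerical choices and limitations

- Explicit Euler with `dt = 0.05`; phase and resource updates are both
  evaluated from the same pre-step state; phases are stored wrapped to
  [0, 2π) (wrapping does not affect sine differences). The integrator
  is a compiled (numba) CSR kernel; a vectorized numpy implementation
  of the derivatives is kept as the reference and the two are tested
  against each other and against a literal nested-loop evaluation.
- `λ` is not clamped below zero; the dynamics floor is
  `λ_o − β/α` at full synchrony. `λ_i ≤ λ_o` holds whenever started
  there (tested).
- Isolated nodes get `r_i = 0`: no coupling, no consumption.
- Determinism: every random draw derives from explicit integer seeds
  (numpy `default_rng`); identical inputs give bit-identical
  trajectories, and multi-run protocols derive run *k*'s seed as
  `seed + k`.
- Classification thresholds, dwell lengths, onset thresholds and the
  cluster threshold are all exposed parameters; the defaults above are
  the package's study conditions.
- Higher-order integrators, noise-driven dynamics, delay coupling, and
  analytical (mean-field/continuation) treatments of the tipping
  points are out of scope.
- Simulation sizes used by the test suite and the acceptance script
  (400-node benchmark graphs, 500-time-unit dwells, five to ten seeds,
  three consumption rates for the ratio analysis) are chosen as the
  smallest sizes at which the measured quantities are stable across
  seeds; all are parameters, and larger replications only require
  larger arguments.
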