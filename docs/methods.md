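# Methods

## Model and signal theory

We consider noisy dynamics `dx = F(x) dt + B dW` on an undirected, unweighted
network of `N` nodes. Linearizing around a stable equilibrium `x*` gives a
multivariate Ornstein–Uhlenbeck process `dz = -A z dt + B dW`, with `A` the
sign-flipped Jacobian (stable iff every eigenvalue has positive real part)
and `B = diag(σ_1, …, σ_N)` throughout this package. The stationary
covariance `C` solves `A C + C Aᵀ = B Bᵀ`; we use a direct Bartels–Stewart
solve (`scipy.linalg.solve_continuous_lyapunov`), symmetrize the result, and
reject solutions whose residual exceeds `1e-10` times `‖BBᵀ‖_max`. The
stability check demands min Re λ(A) > `1e-12`; near-critical systems are
legitimately close to this margin, which is why the tolerance is tight
rather than generous.

The early warning signal of a sentinel set `S` of `n` nodes is the unbiased
sample variance of each member node, averaged over `S`. Under the assumption
that the `L` samples per node are i.i.d. Gaussian,

* `E[V̂_S] = (1/n) Σ_{i∈S} C_ii`,
* `var[V̂_S] = 2/(n²(L-1)) Σ_{i,j∈S} C_ij²`,
* `CV = sqrt(2/(L-1)) · sqrt(Σ λ_i²)/Σ λ_i` in terms of the eigenvalues of
  the principal submatrix of `C` on `S`.

Three consequences shape the method: the CV of any *single* node is the
universal constant `sqrt(2/(L-1))`, so a big signal is not a better signal;
averaging over `n ≥ 2` nodes strictly reduces the CV unless the submatrix is
rank one; and for two exchangeable nodes the averaged signal has
`var[V̂_{1,3}] = var[V̂_1](1+Corr)/2`, where `Corr = corr(V̂_1, V̂_3)` equals
the squared state correlation — averaging helps exactly to the extent that
the member signals are not redundant. Temporal correlation between
consecutive samples violates the i.i.d. assumption in simulation data; no
correction is applied, which slightly biases the variance formula but leaves
the ranking of node sets essentially untouched at the sampling intervals
used (about one autocorrelation time).

Candidate sets are scored by `d = |μ₁-μ₂| / sqrt(var₁+var₂)`, the
separability of the signal's distributions at two bifurcation-parameter
values; the maximizer of `d` is the proposed sentinel set. Only the two
covariance matrices are needed — not the network or the model equations.

## Analytic toy models

Both toy models build on the saddle-node normal form `dx/dt = r + x²`
(stable branch `x* = -sqrt(-r)`, tipping at `r = 0`) with coupling
`w (x_neighbor + 1)`.

*Two nodes, directed edge.* Node 1 is autonomous; node 2 carries an extra
stress offset `Δr` and receives `w (x_1 + 1)`. Equilibrium and covariance
are closed-form; all entries diverge as `(-r)^{-1/2}`. Because node 1 is
upstream, `d(V̂_1)` is independent of `Δr` and `σ₂` (2.58 at the reference
parameters in every scenario).

*Three-node chain* (1–2–3, `σ₃ = σ₁`). The symmetric equilibrium solves two
coupled quadratics; we use a damped Newton iteration with the analytic
Jacobian, continued in `w` from the decoupled root, and verify residuals
below `1e-12` plus positive definiteness of `A` (this selects the stable
branch without reproducing the uniqueness proof; scipy's hybrid root solver
was avoided because it rejects tolerances at machine precision). The first
saddle-node bifurcation lies between the closed-form bound
`r_c'' = 2w[-(w+1)+sqrt(w(w+1))]` and 0; `chain_critical_r` brackets it by
bisection on equilibrium existence, and at `w = 0.05` the two agree to about
`4e-5`.

`d_table` rounds nothing internally; printed comparisons round half away
from zero to two decimals, matching the reporting precision of the reference
values.

## Networks

* **ER, fixed edge count** — uniformly random simple graphs with exactly the
  requested number of edges (the 50-node, 125-edge default has mean degree
  5). Connectivity is not enforced; it is queryable and reported by the CLI.
* **Barabási–Albert** — grown from a complete triangle; each new node
  attaches to `m = 2` *distinct* existing nodes with probability
  proportional to current degree. Sampling without replacement prevents
  multi-edges, making the edge count exactly `3 + m(N-3)` (97 at `N = 50`).
* **Fitness model** — scores `f_i = (i + i0 - 1)^{-α}` with
  `i0 = N^{1-1/α}(10√2 |1-α|)^{1/α}` (the absolute value keeps `i0` real for
  `α = 2`); pair `(i,j)` connects independently with probability
  `min(1, 2M f_i f_j/(Σf)²)` where `M = ⟨k⟩N/2` is the target edge count
  (default `⟨k⟩ = 5`). The `2M` factor is required for the stated density —
  without it the expected edge count is below one — and matches the static
  fitness-model construction this generator follows. The largest connected
  component is returned by default.

## Dynamics models and sweep protocol

Four models are implemented with the following defaults (per-node stress
`u_i = u + Δu_i`, noise `σ_i`):

| model | constants | base σ | start state | stop when | sweep start, step |
|---|---|---|---|---|---|
| double-well | r₁,r₂,r₃ = 1,3,5 | 0.05 | x=1 | any x ≥ 3 | u: (u=0, D=0.05), +0.025; D: (0,0), +0.0025 |
| mutualistic | B=0.1+u, C=1, D̃=5, E=0.9, H=0.1, K=5 | 0.25 | x=5 | any x < 0.1 | u: (0,1), −0.1; D: (0,1), −0.01 |
| gene regulatory | B=1, f=1, h=2 | 5e-6 | x=5 | any x < 0.1 | u: (0,1), −0.01; D: (0,1), −0.01 |
| SIS | μ=1 | 5e-4 | x=0.001 | any x ≥ 0.1 | λ: 0, +0.0025 |

Upward sweeps (double-well, SIS) approach the transition by increasing the
parameter; the mutualistic and gene-regulatory models start in their upper
state and decrease it, since loss of resilience is the transition of
practical concern there. SIS has no stress parameter: a constant influx term
would create infecteds from nothing, so only λ is swept and stress
heterogeneity is rejected for this model. Gene-regulatory and SIS states are
clamped at zero after every step (dynamical noise would otherwise drive the
nonnegative quantities negative); the other two models are unclamped.

Heterogeneity, when enabled, draws `Δu_i ~ U[-0.25, 0.25]` and
`Δσ_i ~ U[-0.9σ, 0.9σ]` once per sweep series — node properties, not
per-simulation noise.

Each simulation restarts from the common initial state, integrates with
Euler–Maruyama at `dt = 0.01`, discards a 100 TU transient, and records
`L = 100` samples spaced 1 TU apart (10 TU and 0.1 TU for the mutualistic
model, whose characteristic time is shorter). The sweep stops at the first
parameter value whose simulation trips the stop condition (checked at every
integration step); the `K̃` pre-transition values are kept, and covariances
are estimated at indices `round(0.1 K̃)` and `round(0.9 K̃)` (half away from
zero, the lower index clipped to 1). A hard cap (default 10⁴ parameter
values) guarantees termination on misconfigured sweeps. Every simulation
draws from its own child of a single master seed sequence, so runs are
bit-reproducible regardless of execution order.

## Selection and evaluation

`C` is estimated by the unbiased sample covariance (divisor `L-1`); no
shrinkage is applied, which is adequate here because `L = 100` comfortably
exceeds the network sizes used, but would matter for `L ≲ N`. Sets of size
`n` are enumerated exhaustively when `C(N,n) ≤ 5000` and uniformly sampled
(distinct) otherwise; ties in the `d`-argmax and in the baseline rankings
break toward the lexicographically smallest set, for determinism. The
Large-SD baseline ranks nodes by sample standard deviation at the second
measurement point; High/Low-Input ranks by total neighbour input
`Σ_j w_ij x_j` with the time-averaged state at the second measurement point
(highest for upward, lowest for downward transitions). The time-average is a
design choice; instantaneous states give nearly identical rankings at these
noise levels.

Performance of a set is Kendall's τ (tau-b) between its signal series and
the parameter; constant series yield a missing value rather than 0. For
downward sweeps all τ comparisons use `-τ`. The indices `p₁` (twice the
fraction of examined sets with τ strictly greater than the maximizer's τ*,
ties not counting against it) and `p₂ = (τ_max - τ*)/(τ_max - ⟨τ⟩)` are
computed over exactly the examined sets, with the optimized set always
included in the pool; under this convention a worst-case maximizer scores
`2(m-1)/m → 2` in the set counts used in practice.

## What the synthetic data does and does not show

All validation inputs are generated internally: random networks, analytic
covariances, and simulated sweeps. The simulation study in the test suite
uses five series of double-well `u`-sweeps on a 20-node Barabási–Albert
network with homogeneous stress and noise — a problem size chosen so the
full protocol (about 100 parameter values × 20 000 integration steps per
series) completes in a couple of minutes while still exercising every stage
of the pipeline. It checks direction and magnitude-class claims (mean `p₁`
and `p₂` below 1 for `n ∈ {1,2}`; positive τ–d correlation), not
scatter-level reproduction: individual series on a 20-node network are
noisy, and occasionally a single series picks a poor maximizer, exactly as
larger studies show for individual realizations. Passing these tests
demonstrates the machinery and the qualitative advantage of the `d`
criterion under the modelled conditions — equilibrium dynamics, additive
diagonal noise, one slowly swept parameter. Real observational data add
non-stationarity, measurement noise, unknown sampling intervals, and far
fewer effective samples, none of which the generator emulates.

## Known limitations

* The moment formulas assume i.i.d. Gaussian samples; strongly correlated
  sampling (spacing ≪ the relaxation time) inflates the true signal variance
  relative to the formula.
* Combinatorial search is exhaustive/sampled only; no metaheuristic search
  for large `n`.
* Autocorrelation-based signals and covariance-shrinkage estimation are out
  of scope.
* The mutualistic migration rate `B_i = 0.1 + u + Δu_i` may go negative in
  deep downward `u`-sweeps; the drift permits it and emits a warning rather
  than failing.
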