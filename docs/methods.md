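# Methods

## Model

A fully-aligned multiplex network `G = (V, E₁, …, E_L)` has one shared node
set of size `n` and `L` intra-layer edge sets. Its supra-adjacency matrix is
the `N×N` block matrix (`N = n·L`) with the layer adjacencies `A_l` on the
diagonal and identity coupling everywhere else; the copy of node `i` in
layer `j` has supra index `i + n·j`. Coupling is always unweighted and
bidirectional — it encodes node identity, not an interaction — even when the
intra-layer edges are directed.

Epidemics follow the discrete-time SIS model: at each timestep a susceptible
copy in layer `j` is independently exposed by each infected in-neighbor with
probability `β(j)` and an infected copy recovers with probability `δ(j)`.
In the fully-mixed limit the infected fraction obeys the logistic equation
`di/dt = (β − δ)i − βi²`, so the ratio `β/δ` governs whether the epidemic
dies out (`β/δ ≤ 1`) or settles at the endemic level `1 − δ/β`. That ratio
is used as the per-layer propagation-rate weight in the ranking below, and
`mean_field_sis` integrates the ODE as an analytic cross-check.

## Protection Value

Selecting the `k`-node set maximizing survival is a hard combinatorial
problem, so the package ranks nodes by a composite heuristic score:

* **bridges** — the magnitude of the copy's entry in the Fiedler vector `μ`
  of the random-walk normalized Laplacian `L_rw = I − D⁻¹A` of the supra
  graph. `L_rw` is preferred over the unnormalized and symmetric normalized
  Laplacians because its Fiedler vector approximates the normalized-cut
  relaxation with plain cluster-indicator eigenvectors and behaves well on
  irregular degree distributions. Positive and negative entries are treated
  equally (absolute value).
* **centers** — the copy's intra-layer degree (out-degree when directed:
  the number of neighbors it can infect). Coupling edges are excluded: every
  copy has exactly `L − 1` of them, so they would only shift scores.
* **rate** — the layer's propagation rate `β(j)/δ(j)`.

Layer-wise: `PV(i + n·j) = d(i+n·j)·|μ(i+n·j)|·β(j)/δ(j)`. The
multiplex-level PV of node `i` is the sum of its copies' layer-wise PVs,
which makes the node score the exact aggregate of the copy scores and keeps
the per-layer rates meaningful. The three factors enter as a bare product
(an exponent hook for re-weighting bridges vs centers exists and is fixed
at 1; the right weighting is an open question). Ties in all deterministic
rankings break toward the lowest id, which makes every selection bitwise
reproducible.

Protection removes every edge incident to a protected copy. The multiplex
scheme expands a node to all `L` copies; the layer scheme isolates single
copies. Protected copies can never be infected.

## Spectral computation

The Fiedler pair is computed on the symmetric normalized Laplacian
`L_sym = I − D^{-1/2} A D^{-1/2}` (similar to `L_rw`) and back-transformed
by `μ = D^{-1/2} v`, renormalized and sign-canonicalized (first entry of
magnitude above 1e-12 is positive). Below 500 nodes a dense symmetric
eigendecomposition is used; above, ARPACK shift-invert (`σ = −0.01`,
requesting the two smallest eigenvalues, fixed all-ones start vector for
determinism, tolerance 1e-8, iteration cap 50·N). Degenerate Fiedler spaces
(possible on symmetric graphs) yield whatever canonical vector the
deterministic solver returns.

Degenerate-input conventions: directed adjacencies are symmetrized
(`A + Aᵀ`, binarized) before any Laplacian, since no directed Laplacian is
defined here; zero-degree rows and columns of both normalized Laplacians are
zero, so isolated copies carry a zero Fiedler entry and never rank as
bridges. The zero-eigenvalue multiplicity is cross-checked against a
graph-traversal component count, which is authoritative; disagreement raises
rather than returning either number.

## Simulation protocol

Updates are synchronous from the pre-step state with independent Bernoulli
transmissions per infected in-neighbor; directed edges transmit source →
target. Infection crosses coupling edges by default (an infected copy can
expose its siblings at the sibling layer's rate); this can be switched off,
since cross-layer transmission is a modeling choice rather than a forced
consequence of the coupling blocks.

A copy **survives** a run if it was never infected at any timestep. SIS
recovery returns nodes to susceptible, so "susceptible at the end" would be
trivially inflated; the never-infected reading is the one that makes
`θ = 100·η/N` a protection metric. A run ends at a horizon of `T` steps
(default 100) or as soon as no copy is infected — SIS has no intrinsic end
point, so the horizon is part of the protocol. `θ` is counted over all
`N = n·L` copies for both schemes so that the two schemes are comparable on
one scale; protected copies count as survivors.

Attack seeding places `φ` initial infections among unprotected copies,
allocated as equally as possible across layers (remainder to the
lowest-indexed layers): uniformly at random within each layer, or on the
highest intra-layer-degree copies (targeted attack, ties to lowest id).

Monte-Carlo runs derive per-run seeds from `(base_seed, run_index)` with
separate sub-streams for strategy randomness and epidemic randomness;
deterministic strategies keep one protected set across runs while random and
acquaintance selection re-draw per run. Reported are the mean and sample
standard deviation of `θ` (a single run, or runs with identical outcomes,
report a standard deviation of exactly 0).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `β(j)`, `δ(j)` | `linspace(0.5, 0.9, L)` each | per-layer infection / recovery probabilities, assigned incrementally across layers over the conventional [0.5, 0.9] range; a single layer gets 0.5 |
| `k` | `floor(0.25·n)` | protection budget (floor never exceeds the stated fraction) |
| `φ` | `k` | initial infections |
| horizon `T` | 100 steps | epidemic cutoff |
| runs | 100 | Monte-Carlo repetitions |
| solver tolerance | 1e-8 | eigensolver convergence |
| coupling transmission | on | infection may cross inter-layer coupling |

`δ = 0` (no recovery) is accepted by the simulator — it is the flooding
regime used in invariant checks — but the ratio `β/δ` raises where a
strategy actually consumes it.

## Synthetic data

Layers are independent uniform `G(n, m)` samples: exactly `m` distinct
simple edges per layer (not the binomial `G(n, p)`), drawn from independent
sub-streams of one seeded generator, so realized per-layer mean degrees are
deterministic (`2m/n` undirected) and the whole graph is reproducible from
its parameter tuple. Requests above the simple-graph maximum produce a
complete layer (logged). The scalability harness sweeps
`n ∈ {100, …, 6000}` at `m = 10,000` per layer and
`m ∈ {1000, …, 200,000}` at `n = 1,000`, `L = 3`, timing the selection
algorithm alone — the epidemic is evaluation, not part of the method's cost.

ER layers are homogeneous: they have no community structure, weak
degree heterogeneity and no inter-layer degree correlation. Results on them
therefore probe correctness, ordering against baselines and scaling — not
the full advantage of the bridge term, which needs modular topologies, nor
the behavior on heavy-tailed real networks. On ER graphs pure degree
rankings can match or beat the spectral score; the effectiveness check
accordingly asserts ordering against the random baselines and against no
protection, not against TIM/SpreadingDegree. With the default rates on a
mean-degree-6 multiplex the epidemic is strongly supercritical and every
unprotected copy is eventually infected, so `θ` saturates at the protected
fraction for every selection method; the sparser regime (mean degree ≲ 2)
differentiates methods.

## Known limitations

* Static networks and one-shot pre-emptive budgets only; no adaptive or
  temporal protection.
* No partial alignment: every node exists in every layer, and inter-layer
  edges other than identity coupling are out of scope.
* Directed graphs are handled by symmetrizing before spectral analysis;
  transmission still follows edge direction.
* SIS only (no SIR/SEIR variants).
* The acquaintance baseline's neighbor pool on the multiplex scheme draws a
  uniformly chosen layer first — one of several defensible readings of
  "random neighbor of a randomly chosen node" in a multiplex setting.
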