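# Methods

## Problem and model

`spreadpred` addresses the influential-spreader problem: rank the nodes
of a contact network by how large an epidemic they would seed.  Ground
truth is defined by the continuous-time Markov SIR process — a
susceptible node is infected by each infected neighbour at rate β,
infected nodes recover at rate γ (both Poisson), and the spreading
influence *s_i* of node *i* is the expected final outbreak size when
*i* is the only initially infected node.  Throughout, γ = 1, so the
process is governed by the effective rate λ = β/γ.  Influence
prediction is most informative near the epidemic threshold λ_c, where
nodal influences differ most; λ_c is estimated numerically as the λ
maximizing the variability √(⟨ρ²⟩ − ⟨ρ⟩²)/⟨ρ⟩ of influence across
nodes.

The prediction method maps each node to the sequence of its first *K*
iterative metric values and regresses influence on them, training on a
small random fraction *q* of nodes whose influence is assumed known:

* **NWC** — normalized walk count, the power-iteration truncation
  w(k) = A w(k−1)/‖·‖₂ started from u/√N; order *k* counts distinct
  *k*-hop walks and converges to eigenvector centrality;
* **VP** — visiting probability, the PageRank iteration with
  teleportation α = 0.85 started from u/N; converges to PageRank
  (order *k* encodes (k+1)-hop information because neighbour degrees
  enter the update);
* **HI** — iterated H-index, starting from degree and applying the
  Hirsch operator to neighbour values; integer, per-node
  non-increasing, fixed point equal to the coreness.

The comparison model uses 7 classic centralities (degree,
neighbourhood, two-hop neighbourhood, coreness, eigenvector centrality,
PageRank, closeness).  The cost of an iterative metric set is
O(K·|E|), versus O(|V|·|E|) for closeness alone, which is the point of
the method: near-benchmark prediction quality from strictly local
topology.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| λ (SIR) | λ_c per network | influence is most heterogeneous near threshold |
| γ | 1 | time-scale normalization; only λ = β/γ matters (tested) |
| runs *r* | 10⁴ (API default) | Monte-Carlo replication per seed node; reduced-replicate runs are first-class and quote standard errors |
| K | 4 | the smallest order at which prediction quality plateaus on small-world networks |
| α (VP) | 0.85 | conventional PageRank teleportation |
| q | 0.10 | assumed known fraction of nodal influences |
| realizations | 50 (API default) | re-samplings of the training set S_q |
| f | 10 % | top-list size for the recognition rate |
| random forest | 100 trees, unlimited depth, squared error | conventional defaults; seeded per realization |

## Synthetic benchmark (LFR)

The generator produces Lancichinetti–Fortunato–Radicchi benchmark
networks with the study parameterization: N = 1000 (or 10000), degree
exponent τ₁ = 2, community-size exponent τ₂ = 3, mean degree 10,
maximum degree √(10N)/2, community sizes in [50, √(10N)], mixing
parameter μ ∈ {0.02, 0.05, 0.1, 0.2, 0.3, 0.4}.

The construction is implemented in the package: degrees are drawn from
the discrete power law p(k) ∝ k^−τ₁ on the integers [d_min, d_max],
with the integer lower cut-off solved so the distribution mean matches
the target (d_min = 4 for the N = 1000 suite, mean ≈ 10.1); each
node's external degree is μ·d with
*stochastic rounding*, so realized per-node mixing averages μ even
where μ·d < 1; nodes are placed into power-law-sized communities under
the constraint that intra-degree fits the community; intra- and
inter-community edges are wired by configuration models made simple by
rewiring conflicting stub pairs against already-accepted edges
(unresolvable stubs — a handful per graph — are dropped).  Every graph
is validated (simple-graph invariants, realized mean degree within 15%
of target, realized mixing close to μ) and returned as its largest
connected component with the planted partition.  We implemented the
wiring ourselves after finding that a widely used library generator
systematically inflates realized mixing (≈ 0.40 at μ = 0.3): nodes
whose degree is exhausted by other nodes' inter-community edges never
receive their intra-community quota.

What the generator does *not* emulate: degree–degree correlations,
clustering beyond what the configuration model induces, overlapping
communities, and the spatial structure of infrastructure networks.
Conclusions from passing tests therefore transfer to small-world
community networks, not to lattice-like graphs with very large
diameter, where higher orders K are known to be needed.

## SIR engine

The final outbreak size of the Markov SIR process depends only on
which transmissions beat the infector's recovery clock, not on their
time order: once node *v* is infected it draws R_v ~ Exp(γ), and the
attempt on neighbour *u* succeeds iff an independent Exp(β) delay is
below R_v.  The ever-infected set is the set reachable from the seed
through successful attempts (the classical SIR/bond-percolation
correspondence, with the attempts out of one node correlated through
the shared R_v).  The engine therefore performs a breadth-first sweep
over sampled attempts — exact for final sizes, O(edges touched) per
realization, and JIT-compiled with numba.  A time-ordered next-reaction
simulator (full event queue, stale-event discard) lives in the test
suite as an independent oracle; the two agree under a two-sample KS
test, and the engine also matches the dyad closed form
1 + λ/(λ+1) and exact 3-node CTMC enumeration.

Reproducibility: one root seed; per-seed-node substreams are derived
from it (`SeedSequence`), so influence tables are identical no matter
which subset of nodes is computed or in which order.  The runs-per-node
counter is the only accuracy knob; standard errors are reported per
node.

## Numerical choices

* "Converged" eigenvector/PageRank benchmarks stop at L1 change
  < 1e−10 or 1000 iterations.
* NWC normalizes in L2 (the iteration starts from u/√N).
* The H-operator of an empty neighbour list is 0; degree-0 nodes never
  occur after LCC restriction.
* Threshold grids must be strictly ascending; variability ties break
  toward smaller λ.  The default grid spans [0.1, 3] × ⟨d⟩/(⟨d²⟩−⟨d⟩)
  (a mean-field first guess); the LFR experiments use the fixed grid
  0.01…0.20, step 0.01.
* Top-f% lists have length ⌈f%·n⌉ (never empty); boundary ties break
  by node index after sorting by value, for determinism.
* τ-b is undefined (error) when either argument is entirely tied; r²
  is undefined when the true values have zero variance.
* All analyses run on the largest connected component: diameter and
  closeness are otherwise undefined.
* Modularity of real networks needs a user-supplied partition; LFR
  networks use the planted one.

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` run the full pipeline at
reduced replication, chosen so Monte-Carlo error is small relative to
the quantities checked: influence with 10³ runs per node (the headline
tables in the source study use 10⁴), threshold scans with 300–400 runs
per seed node (sampling 400 seed nodes for the non-anchor networks),
and 10–20 training-set realizations.  All stochastic checks quote
Monte-Carlo tolerances (standard errors, KS tests, or one grid step).

## Known limitations

* The outbreak-size engine returns final sizes only; time courses
  (peak height, duration) would need the event-driven formulation.
* Discrete-time SIR, SIS/SEIR and temporal networks are out of scope.
* Variability is computed across per-node mean influences; an
  alternative definition over individual outbreak realizations exists
  in the literature and is not implemented.
* Feature importances of the fitted forests are not interpreted; the
  orders of one iterative metric are strongly correlated.
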