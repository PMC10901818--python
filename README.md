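# spreadpred

Predicting nodal spreading influence in networks from **local iterative
topological metrics**, with ground truth from continuous-time SIR
simulation.

## The problem

In epidemiology and information diffusion alike, one wants to know
*which nodes of a contact network would seed the largest outbreaks*.
The gold standard — simulating the susceptible–infected–recovered (SIR)
process from every node — is expensive, and the best topological
predictors (eigenvector centrality, PageRank, closeness, coreness) are
*global* quantities that need the whole network to compute.

This package implements an alternative: truncate the iterative
processes that *compute* those global centralities after K steps and
use the whole trajectory `{M(1), …, M(K)}` as node features in a
regression model trained on the few nodes whose influence is known.
Three iterative families are provided:

| metric | update | converges to |
|---|---|---|
| NWC (normalized walk count) | `w(k) = A w(k−1) / ‖·‖₂`, from `u/√N` | eigenvector centrality |
| VP (visiting probability) | `p(k) = α Aᵀ D⁻¹ p(k−1) + (1−α)/N · u`, α = 0.85 | PageRank |
| HI (iterated H-index) | Hirsch operator on neighbour values, from degree | coreness |

Order k uses only the k-hop neighbourhood of a node ((k+1)-hop for VP),
and the whole set costs O(K·|E|) — so with the empirical finding that
quality plateaus at K ≈ 4 on small-world networks, near-benchmark
prediction comes at a fraction of the cost of global centralities.

Ground-truth influence s_i is the mean final outbreak size of the
continuous-time SIR process seeded at node i (infection rate β per
infected neighbour, recovery rate γ = 1, effective rate λ = β/γ),
evaluated near the epidemic threshold λ_c, which the package estimates
as the λ maximizing the across-node variability of influence.  Models
(Random Forest by default, trained on a random 10% of nodes) are scored
on held-out nodes by r², Kendall's τ-b and the top-10% recognition
rate.  An LFR benchmark generator (power-law degrees τ₁ = 2, power-law
community sizes τ₂ = 3, mean degree 10, tunable mixing μ) reproduces
the synthetic study conditions.  See `docs/methods.md` for the details.

## Worked example

```python
import numpy as np
from spreadpred import (LFRConfig, SIRConfig, ExperimentConfig,
                        generate_lfr, estimate_threshold,
                        estimate_influence, nwc_iterate, run_experiment)
from spreadpred.metrics import benchmark_feature_matrix

# an LFR network with strong communities (N=1000, mu=0.05)
g, communities = generate_lfr(LFRConfig(n=1000, mu=0.05, rng_seed=0))

# epidemic threshold on a 0.01-step grid
scan = estimate_threshold(g, np.round(np.arange(0.01, 0.201, 0.01), 3),
                          SIRConfig(beta=1.0, runs=300, rng_seed=0))
print(f"lambda_c = {scan.lambda_c:g}")

# ground-truth influence at the threshold, 1000 SIR runs per node
influence = estimate_influence(
    g, SIRConfig(beta=scan.lambda_c, runs=1000, rng_seed=1))

# NWC(K=4) model vs the 7-centrality benchmark model
cfg = ExperimentConfig(q=0.10, realizations=20, K=4, rng_seed=3)
nwc = run_experiment(nwc_iterate(g, 4).values, influence, cfg)
bench = run_experiment(benchmark_feature_matrix(g), influence, cfg)
print(nwc.mean.round(3).to_dict())
print(bench.mean.round(3).to_dict())
```

Output:

```
lambda_c = 0.09
{'r2': 0.959, 'kendall': 0.876, 'recognition': 0.919}
{'r2': 0.933, 'kendall': 0.843, 'recognition': 0.892}
```

Read: at λ = λ_c the four-order walk-count model explains 96% of the
variance of nodal influence on held-out nodes, ranks them with
τ ≈ 0.88, and retrieves ≈ 92% of the true top-10% spreaders — slightly
*better* than the benchmark model built from seven global centralities,
while using only 4-hop information.

## Command line

```sh
spreadpred lfr-generate --n 1000 --mu 0.05 --seed 0 \
    --out-edges lfr.edges --out-communities lfr_comm.csv
spreadpred threshold --graph lfr.edges --grid 0.01:0.2:0.01 --runs 300 --out scan.csv
spreadpred influence --graph lfr.edges --lambda 0.09 --runs 1000 --out influence.csv
spreadpred metrics --graph lfr.edges --metric nwc --K 4 --out nwc.csv
spreadpred predict --graph lfr.edges --influence influence.csv \
    --features nwc --K 4 --out eval.csv
spreadpred experiment run manifest.yaml   # full sweeps from a YAML manifest
```

Edge lists are whitespace-separated pairs; the KONECT `out.*` dialect
(`%` comment headers, optional weight columns) is supported via
`--dialect konect`.  All analyses run on the largest connected
component.

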