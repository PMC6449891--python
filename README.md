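# grnfuse

Gene regulatory network (GRN) inference that fuses gene-expression data
with protein–protein interaction networks (PPIN), for systems biologists
who have both an expression matrix and a (sparse, incomplete) interaction
network for the same genes and want a single coherent regulatory network
out of them.

## The method

The pipeline runs four probabilistic stages:

1. **Pathway soft-clustering.** Expression profiles x_i ∈ R^J are modelled
   by a Gaussian mixture p(x_i) = Σ_l θ_l N(x_i; μ_l, Σ_l); a pathway is a
   mixture component and τ_il = p(γ_i = l | x_i) is gene i's soft
   membership. The number of pathways L is selected by component-wise EM
   under a minimum-message-length criterion that annihilates
   under-supported components, starting from L_max. The co-membership
   matrix G = ττᵀ is the expression-only interaction estimate.

2. **Transitive network extension.** Observed interaction networks miss
   many real interactions. A shortest path of d hops between proteins
   carries implicit-interaction confidence c_d = ζ^(d−1), with ζ solving
   Σ_{d≥1} ζ^d = 1 (ζ = 1/2, so c_1 = 1, c_2 = 0.5, c_3 = 0.25, …).
   Path confidence adds to expression correlation, W_ij = ρ_ij + c_{d_ij};
   a damped random walk on W is iterated to its equilibrium T̂, and the
   final confidence C = ½W + ½WT̂ (symmetrized, min-max normalized)
   is thresholded at 0.5 to give the extended network.

3. **Evidence fusion.** C becomes the neighbourhood structure of a hidden
   Markov random field over pathway assignments: the Gibbs prior
   p(Γ|C) ∝ exp(Σ_{i,j≠i} −C_ij·[γ_j ≠ γ_i]) pulls strongly interacting
   genes into the same pathway during the mixture fit. The refined
   interaction score is R = ½G + ½C.

4. **Directed structure learning.** A Bayesian network with conjugate
   linear-Gaussian local models (experiments hard-partitioned into K
   mixture components) is sampled by Metropolis–Hastings over single-edge
   moves, with parents restricted to same-pathway genes among the top-k
   neighbours by R and a Gibbs structure prior
   p(𝒢|R) ∝ exp(−Σ R_ji(1 − 𝒢_ji)) rewarding consistency with R. Edge
   confidence is the model-averaged frequency of the edge across sampled
   DAGs, thresholded at 0.5; evaluation matches edges regardless of
   direction.

Everything is testable offline: `grnfuse.synthetic_fixtures` generates
expression, interaction networks and ground truth with the statistical
structure the method assumes.

## Worked example

`examples/05_full_pipeline.py` builds the default synthetic scenario
(30 genes, 40 experiments, 4 overlapping pathways, a protein network
keeping 60% of true edges plus 5% spurious pairs) and compares the fused
pipeline against the expression-only ablation:

```
inputs: 30 genes x 40 experiments, 93 observed interactions, 144 true regulations
fused            L=6  edges=36  precision 0.72  recall 0.18  F1 0.29  AUROC 0.597
expression-only  L=6  edges=25  precision 0.76  recall 0.13  F1 0.22  AUROC 0.595
```

The fused run finds more true regulations at comparable precision —
protein evidence mainly buys recall. `examples/03_fuse_evidence.py` shows
the same effect at the score level:

```
expression-only G      AUROC 0.679  AUPR 0.579
field-regularized G    AUROC 0.696  AUPR 0.562
refined R              AUROC 0.907  AUPR 0.850
```

and `examples/02_extend_network.py` shows the extension recovering
missing interactions:

```
observed network: 83 edges; truth: 143 edges (69 missing)
extension adds 46 new edges at confidence >= 0.5, 28 of them truly missing interactions
```

The other examples cover pathway clustering with automatic model
selection (`01`) and directed structure recovery by MCMC (`04`). A thin
CLI wraps the same functions: `grnfuse simulate | cluster | extend-ppin |
ghmm | bgm | eval | run` (see `grnfuse --help`).

## Documentation

`docs/methods.md` describes the model assumptions, the tunable parameters
and their defaults, what the synthetic generators do and do not emulate,
and the numerical choices made where the underlying method leaves them
open.
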