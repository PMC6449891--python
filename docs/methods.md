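# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `grnfuse`, in the order the pipeline runs.

## Pathway mixture and model selection

**Model.** Genes are i.i.d. draws from a finite mixture of multivariate
Gaussians over the J experiments; pathway assignments γ_i follow a
multinomial with weights Θ under a uniform Dirichlet prior (α_l = 1, no
effective smoothing). The default covariance is diagonal with a variance
floor of 1e−6; full covariances are available with an additive ridge
λI (λ = 1e−3). Diagonal is the default because J can exceed the gene
count in realistic inputs (e.g. 30 genes × 77 experiments), where full
J×J sample covariances are singular.

**Selection of L.** Fitting starts at L_max (default min(I, 15)) and
repeatedly annihilates the weakest component, recording the
minimum-message-length (MML) value
−log L + (P/2)Σ_l log(Iθ_l/12) + (L/2)log(I/12) + L(P+1)/2 (P free
parameters per component) at each visited L and returning the argmin.
Three mechanisms make this reliable at desk scale, where the bare MML
penalty is weaker than the likelihood gain of an overfit split:

* *MAP variances.* Each component's variance blends one pseudo-observation
  of the global variance. A component supported by a handful of genes
  cannot collapse its variance and buy spurious likelihood.
* *Mass-discounted weights.* In the component-wise sweep a component's
  weight is proportional to max(mass − P/2, 0.1·mass): a component must
  carry its parameters' message cost in responsibility mass or it starves.
  At most one component is annihilated per sweep (the smallest), so mass
  drains gradually to neighbours instead of cascading; three unpenalized
  warm-up sweeps precede the first discount. When every component would
  starve (I small relative to P), plain weights apply and selection rests
  on the criterion alone.
* *Final polish.* After selection, plain EM at the chosen L removes the
  slight assignment-boundary bias the discounted normalization introduces.

Components whose weight falls below 1/I are likewise annihilated
(smallest first). All stochastic behaviour flows from one seed through
the k-means initialization; fits are deterministic given it.

**Co-membership.** G = ττᵀ with the diagonal zeroed for all network uses;
a gene's self-interaction is meaningless downstream and the mixture model
gives it no interpretation either.

## Transitive extension and confidence scores

ζ = 1/2 is computed from its defining series constraint at run time (root
finding, tolerance 1e−14), not hard-coded. Shortest paths are unweighted
hop counts; disconnected pairs score 0. By default paths run inside the
target gene set ("subnet" scope); a larger same-species network can be
supplied, in which case paths may route through outside genes and the
result is projected back.

Decisions the scoring formulas leave open:

* Pearson correlation can be negative while random-walk transition mass
  cannot. W is clipped at zero for the transition matrix only; the signed
  W is kept in the additive and product terms, so anticorrelation
  information is not discarded.
* Rows of the transition matrix with no positive mass become uniform
  (the standard dangling-node fix); damping defaults to 0.85.
* The walk limit T̂ is computed by repeated squaring until the change is
  below 1e−9 (at most 64 squarings), and errors out with the last delta
  if it does not converge.
* The product term WT̂ is asymmetric; C is averaged with its transpose
  because every downstream use is undirected, and min-max normalization is
  applied to the final C (after combining the terms), with the diagonal
  fixed at 0. Zero-variance genes get zero correlations, with a warning.

## Field-regularized fusion

The fused fit replaces the E-step responsibilities with
τ_il ∝ [GMM responsibility] · exp(Σ_{j≠i} −C_ij(1 − τ_jl)), the soft
relaxation of the Gibbs disagreement indicator. Two choices resolve the
self-reference of this update:

* The right-hand τ is the previous iteration's (mean-field/ICM style);
  after any component annihilation the previous memberships no longer
  align and the update falls back to the current responsibilities once.
* Rows are renormalized after the field term so τ remains a probability
  row — required for the M-step weights and for G to stay in [0, 1].

With C = 0 the fit is exactly the plain mixture fit (same seed, same
schedule); this reduction is asserted in the tests. R = ½G + ½C.

The pairwise agreement statistic Σ_l τ_il τ_jl is exposed
(`membership_agreement`) for users who want to quantify how consistent a
pathway fit is with an interaction network; the package draws no
conclusion from it.

## Constrained structure MCMC

**Local model.** Gene i given parents π_i is a Bayesian linear regression
with intercept under a conjugate normal-inverse-gamma prior: zero prior
mean, prior precision 1·I, noise-variance shape 1 and scale 1
(configurable). The marginal likelihood Ψ is analytic; the mixture over
experiment partitions is log Σ_k θ_k Ψ_k. Partitions smaller than the
regressor count are allowed — the proper prior keeps Ψ finite — with a
logged warning that the score is prior-dominated. Scores are cached by
(gene, parent set).

**Experiment mixture.** Columns are clustered by the same CEM machinery on
the transposed matrix with hard argmax assignment; θ_k are the partition
fractions. K_max defaults to 5 — expression compendia rarely support more
hard condition regimes at these sizes, and K=1 recovers the classical
single-regression score.

**Candidates.** Parents must share a pathway (τ_il ≥ 0.1) and rank in the
gene's top-k (default 5) neighbours by R, ties broken by gene order. A
global top-N pair variant is available behind a flag.

**Sampler.** Metropolis–Hastings over single-edge moves (add, delete,
reverse) with a uniform proposal over currently admissible moves and the
exact |moves(G)|/|moves(G′)| Hastings correction. Admissibility =
candidate membership + acyclicity, checked by boolean-matrix reachability
closure per state (reversals check the two-step delete+add path); at the
tool's scale (tens to a few hundred genes, capped candidate sets) this
costs microseconds per proposal. Score deltas touch only the one or two
genes whose parent set changes (decomposability, asserted in tests). If no
move is admissible the chain records its state and continues.

**Averaging.** Chains run with distinct seeds (default 10 × 1000
iterations); the first 20% of each is discarded as burn-in; directed edge
confidence is the pooled frequency. The final network thresholds the
either-direction confidence F + Fᵀ at 0.5 — a draw never contains both
orientations, so this is the probability of the edge ignoring direction,
matching the direction-blind evaluation convention.

## Evaluation

Confusion counts compare unordered pairs (duplicates collapsed); a
predicted edge matching a reference edge in either direction is one true
positive. The negative universe for ranking metrics is every unordered
pair absent from the reference, excluding self-pairs, minus an optional
exclusion list. AUROC uses the midrank Mann–Whitney form (thresholded
matrices tie heavily at 0); AUPR uses step interpolation over all
thresholds — minor interpolation variants exist in the literature and can
differ in the third decimal. Zero denominators yield 0 with a warning.
The significance grouping orders methods by mean, pools the best with any
successor not distinguishable by an unpaired equal-variance t-test at
α = 0.05, and reports the pooled-top vs rest test.

## Synthetic data: what it does and does not emulate

The generator draws each gene's profile from its pathway's Gaussian
(multi-membership genes from the mixture of theirs), with pathway means on
orthogonal experiment axes at pairwise distance `mean_separation` × the
within-pathway sd (default 5 — well separated). The ground-truth network
is the co-membership graph — appropriate because every stage of the method
models co-pathway structure — and the observed protein network keeps each
truth edge with probability `ppin_retention` (default 0.6) and adds each
non-truth pair with probability `ppin_noise` (default 0.05). The default
scenario is 30 genes × 40 experiments × 4 pathways with 20% multi-pathway
genes. A separate linear-Gaussian DAG generator (weights ±0.8, noise
sd 0.3, roots standard normal) serves directed-recovery tests.

Not emulated: microarray technical noise, time-course autocorrelation
between experiments, hub-dominated (scale-free) interaction topology, and
measurement-level expression preprocessing (the loader applies no
transformation — log-scaling and centering are left to the user, and
results on raw-scale data will differ). Passing tests therefore show the
machinery is correct under the model's own assumptions, not that the
assumptions hold for any particular real compendium.

Recovery experiments in the tests and the acceptance script use
deliberately small problem sizes — 60 genes for pathway recovery (J = 6
experiments, where the message-length selection operates comfortably), 10
genes for structure recovery, 5 replicate or paired seeds, 10 hold-out
repeats — chosen so the full suite runs in minutes while keeping the
statistical comparisons meaningful; medians over replicates are reported
where a single run would be dominated by fit stochasticity.

## Known limitations

* Model selection for the pathway count is inherently marginal when the
  per-component parameter count P approaches the genes-per-pathway ratio;
  in that regime the fit keeps more components than the generative truth
  and the memberships over-segment (harmless to the downstream candidate
  construction, which only needs shared-pathway structure).
* The Gibbs structure prior is improper up to its intractable normalizer;
  only ratios are used, so the prior strength is effectively fixed by the
  scale of R (in [0, 1]) against log-likelihood differences. Very strong
  likelihood signals will dominate it.
* The sampler explores by single-edge moves only; on strongly equivalent
  structures mixing relies on the reverse move, and the 3-gene exact
  comparison in the tests is the calibration point.
* `significance_group` assumes equal variances (classical unpaired
  t-test); heteroscedastic method comparisons should use Welch externally.
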