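# Methods

## The model

`phylobeta` models binary occurrence of taxa across sites as a logistic
regression whose slopes are pooled along a phylogeny.  For taxon *j* at
site *i* with covariate *x_i* (stream pH in the motivating application):

    O[i,j] ~ Bernoulli(P[i,j])
    logit(P[i,j]) = alpha_j + beta_j * x_i

Every node of a rooted tree topology — leaves and internal nodes alike —
carries a slope `beta` and a precision `tau`.  Slopes cascade: each
node's slope is Normal around its parent's slope with the node's own
precision, and the root slope is Normal around a fixed mean (0 by
default).  Leaves additionally carry an intercept `alpha` with a diffuse
Normal prior; internal nodes have no data and hence no intercept.

    beta_node ~ Normal(mean = beta_parent, precision = tau_node)
    beta_root ~ Normal(mean = 0,           precision = tau_root)
    tau_node  ~ Gamma(shape = 0.001, rate = 0.001)
    alpha_leaf ~ Normal(mean = 0, precision = 1e-6)
    sigma_node = 1 / tau_node            (derived variance, never sampled)

All Normal distributions are parameterized by **precision**, the
BUGS-family convention.  The source analysis was run in BUGS and its
"high variance (1.0 × 10⁻⁶)" prior only makes sense under that
convention (precision 1e-6, i.e. variance 1e6); a literal SD reading
would contradict itself.  `sigma = 1/tau` is therefore the per-node
*variance*, kept as a reporting quantity.

The cascade is the scientific content: occurrence–environment slopes are
treated as a heritable trait diffusing through cladogenesis events
(niche conservatism), so a taxon observed at few sites borrows its
slope's centre from an ancestor informed by better-sampled relatives.
Branch lengths are deliberately ignored — the topology alone determines
who pools with whom — and polytomies are allowed (every child of a
polytomy draws from the same parent slope).

Assumptions worth keeping in mind: occurrences are independent across
sites and taxa given the parameters (no spatial autocorrelation, no
detection sub-model), a single covariate enters linearly on the logit
scale, and one precision per tree edge governs each diffusion step.

## Inference

`sample_posterior` runs Metropolis-within-Gibbs.  The tree interior is
conditionally conjugate and is updated with exact draws — this is the
model's computational heart and is implemented directly rather than
delegated to a probabilistic-programming runtime:

* precision of node *j*:  `Gamma(shape + 1/2, rate + (beta_j - beta_parent)^2 / 2)`
  (one Normal increment per edge);
* internal slope of node *j*: Normal with precision
  `tau_j + sum_children tau_c` and mean the precision-weighted average of
  the parent's and children's slopes (the root uses its prior mean as
  "parent").

Leaf `(alpha, beta)` pairs face the Bernoulli likelihood and are updated
componentwise (alpha, then beta) by Gaussian random-walk Metropolis.
Only local terms enter the acceptance ratio: the leaf's data column, its
intercept prior, and its slope's parent edge.  Proposal scales adapt
during burn-in by Robbins–Monro on the log scale (gain t^-0.6) toward
0.44 acceptance — the standard one-dimensional optimum — and are frozen
afterwards so the post-burn-in kernel has the correct stationary
distribution.  In the sweep the leaf updates are vectorized across
leaves (their conditionals are independent given the internal slopes);
`update_leaf_params` exposes the same mathematics one leaf at a time.

Defaults mirror the source analysis: 5 independent chains, 1,000
burn-in sweeps, 1,000 kept draws per chain thinned at interval 5.
Chains are seeded from one root seed via fixed `SeedSequence` spawn
keys; identical configurations reproduce bit-identical draws.

Other inference choices:

* **Initialization** (deterministic): `alpha` at the logit of observed
  occupancy clamped to [-3, 3]; `beta = 0`; `tau = 1`.
* **tau cap**: draws are capped at 1e12.  Gamma(0.001, 0.001) is nearly
  improper and an exactly-equal parent/child slope pair would otherwise
  generate astronomically large precisions; the cap is far above
  anything the data can support and does not materially change the
  posterior.
* **Covariate centering** (`center_covariate=True`, off by default):
  subtracts the covariate mean before fitting.  Slopes are unchanged;
  intercepts shift by `beta * mean(x)`.  With a covariate far from zero
  (pH ≈ 7.3) the intercept/slope posterior correlation approaches −0.99
  and the componentwise walk mixes very slowly, so centering is
  recommended there; the fit records the offset and downstream
  prediction honours it.
* **fix_tau / sample_root**: diagnostic switches that hold all
  precisions at a constant and clamp the root slope at its prior mean.
  Together they turn a one-taxon fit into ordinary 2-parameter Bayesian
  logistic regression, which is verified against a two-dimensional
  quadrature oracle.
* **Convergence**: `gelman_rubin` implements split-chain R-hat.  Two
  degenerate cases report exactly 1: bit-identical chains and zero
  between-half variance.

## Evidence bands and the no-phylogeny comparator

Each node's slope draws reduce to a tail probability
`p = min(P(beta > 0), P(beta < 0))` — the posterior mass on the minority
sign, i.e. the probability of rejecting the lack of effect; draws
exactly zero split evenly.  One-sided variants exist behind a flag; the
two-sided form is the default because the reported outputs (a sign plus
an evidence level per node) require exactly that quantity.  Bands are
fixed and left-closed:

| tail probability | evidence |
|---|---|
| p < 0.05 | very strong |
| 0.05 ≤ p < 0.15 | strong |
| 0.15 ≤ p < 0.30 | acceptable |
| p ≥ 0.30 | little evidence |

Exact boundary hits are measure-zero; the left-closed convention is
fixed and documented rather than consequential.

The "no phylogeny" comparator (`fit_plain`) is the same machinery on a
star topology with the root slope clamped at its prior mean, making each
taxon's slope prior independent: ordinary per-taxon Bayesian logistic
regression under identical decision rules.  `compare_models` tabulates
per-taxon band movements and sign flips between the two fits.

## Cross-validation

`cross_validate` performs leave-genera-out validation.  Per round: hold
out `max(1, round(0.05 * n_taxa))` taxa chosen uniformly (deterministic
per round index), prune them from tree and data, refit, then score each
held-out taxon's observed occurrences with

    score_i = logistic(alpha_bar + beta_bar_anc * x_i)

where `beta_bar_anc` is the posterior mean slope of the held-out leaf's
nearest surviving ancestor (first ancestor not pruned away; a leaf that
hung directly off the root attaches at the pruned tree's root).  The
held-out taxon has no fitted intercept, so `alpha_bar` is the pooled
mean of the training taxa's intercepts.  Per-taxon AUC is invariant to
that choice (AUC ignores monotone shifts); the pooled-across-taxa AUC is
not, which is why the convention is stated.

One AUC is computed per round over all held-out (site, taxon) pairs
pooled (a per-taxon-averaged variant is available); AUC uses the
Mann–Whitney form with ties counted one half.  Rounds whose pooled
labels are single-class are recorded as skipped.  The rounds aggregate
into a mean AUC and a percentile interval (2.5/97.5 for the default 95%
level) — the interval method is a package choice.  Every round's MCMC
gets its own derived seed; the whole loop is bit-reproducible.

A null switch (`shuffle_labels`) permutes each held-out taxon's labels
across sites before scoring, collapsing the expected AUC to 0.5 — used
to calibrate the validation machinery itself.

## Tree operations

Topologies are preorder-numbered (root id 1, parent id < child id),
which gives the cascade a natural indexing.  Newick I/O goes through
dendropy; branch lengths and internal labels are discarded on input.

* `bipartitions` returns one canonical non-trivial unrooted split per
  internal edge (canonical side: lexicographically smaller sorted label
  tuple; the two edges of a bifurcating root count once).
* `robinson_foulds` is the size of the symmetric difference of the two
  split sets, defined for identical leaf sets.
* `prune_leaves` removes leaves, suppresses resulting unary nodes
  (including an unary root), renumbers, and returns an old-id → new-id
  map with `None` marking removed/suppressed nodes — the map the
  cross-validation uses to find nearest surviving ancestors.
* `build_supertree` combines source trees over the union of their
  leaves.  Every clade of every input is a candidate, ranked by support
  (fraction of trees that could display it and do), then smaller size,
  then label order; candidates are accepted greedily when supported by
  at least half of their informative trees and laminar with the accepted
  family, and the tree is read off that family.  The majority filter is
  what makes the construction principled with respect to the
  Robinson–Foulds metric: for inputs sharing a leaf set the result is a
  majority-rule-style consensus, an RF median, so its total RF distance
  to the inputs never exceeds that of any single input.  A pure greedy
  without the filter can violate that bound on conflicting inputs.
  Working with rooted clades (not unrooted splits) makes the output's
  rooting automatic.  Agreeing inputs are reproduced exactly;
  irreconcilable structure degrades to polytomies, never to an error.

## The synthetic generator

`simulate_dataset` emulates the motivating survey's printed marginals:
101 sites, 24 taxa, covariate from Normal(7.29, 0.92) truncated to
[3.72, 8.80].  (The upper bound sits 1.64 SD above the mean, so the
truncated distribution's true mean is 7.195 and SD 0.83 — the tests
check against these exact truncated-normal values.)  Slopes follow the
model's own cascade generatively — root slope 1.0, per-edge precision
4.0 (SD 0.5 per cladogenesis event): predominantly positive slopes with
visible but moderate phylogenetic divergence, and self-consistency with
the fitted model enables calibration testing.  Trees are random rooted
binary trees grown by uniform random edge attachment.

Intercepts are parameterized through the **baseline logit at the mean
environment**: `alpha_j = baseline_j - beta_j * mean(x)` with
`baseline_j ~ Normal(-2.1, 1.5)`.  Drawing raw intercepts instead would
couple occupancy to the slope through the large covariate mean (a slope
one unit lower shifts occupancy by seven logits), making negative-slope
taxa unobservable; the baseline parameterization reproduces the survey's
occupancy skew — median near 11% of sites, range roughly 1–70% against
the survey's 1–47% — under any slope.  Like a real occurrence survey,
the generator conditions on observation: a taxon whose simulated column
is empty has its intercept and column redrawn.

What the generator does **not** emulate: spatial structure among sites,
imperfect detection, abundance, the survey's actual (undeposited)
pH–occurrence coupling, or its real phylogeny.  Passing tests therefore
demonstrate that the machinery is correct and calibrated *under the
model's own assumptions at the study's scale* — not that the model is
adequate for any particular real community.

The observed survey tally (24 genera, occurrence and abundance; 2,027
individuals) ships verbatim as `table1_fixture()` for fixture-integrity
checks and realistic occupancy references.

## Numerical choices

* Bernoulli log-likelihoods use `log_expit`, exact and stable for any
  finite linear predictor (no probability clamping needed).
* Conjugate updates are verified against brute-force grid-normalized
  full conditionals (the precision conditional on a log-precision grid
  with Jacobian, 20,001 points; KS distance on 10⁴ draws).
* The one-taxon quadrature oracle integrates the exact posterior on an
  801 × 801 grid over ±6 in both parameters; Monte-Carlo standard errors
  use effective sample sizes.
* Test problem sizes are the package's own choices: calibration uses 20
  replicates at study scale with 2 × 500 kept draws; the shrinkage
  contrast uses the source chain schedule at 2 chains (1,000 kept, thin
  5); cross-validation checks use 50 rounds with a 600-sweep refit per
  round.  The study-scale fit runs at well under a millisecond per sweep,
  so the full default schedule (5 × 6,000 sweeps) takes seconds.

## Known limitations

* **Quasi-separation of rare taxa.**  A taxon with a lone presence at an
  extreme covariate value has a likelihood maximized at infinite slope.
  Under the nearly improper Gamma(0.001, 0.001) precision prior the
  marginal slope prior is t-like with ~0.002 degrees of freedom, so the
  posterior for such a taxon is proper but has an essentially
  scale-free tail — its *mean* is not finite, and MCMC estimates of it
  drift with chain length in both the phylogenetic and the star fits.
  The phylogenetic prior still centres the taxon on its ancestor
  (medians and intervals behave sensibly); but mean-based summaries for
  separated taxa should be treated as unstable, and the rare-taxon
  improvement contrast is correspondingly noisy across generator seeds.
* **Per-edge precisions are weakly identified**: each tau sees a single
  Normal increment, so the Gamma prior dominates; tau values are
  nuisance parameters, not interpretable rate estimates.
* The supertree heuristic is a deterministic consensus-style
  construction, not an exact optimizer over supertree space.
* One covariate, no branch-length weighting — extensions the model
  family invites but this package deliberately excludes.
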