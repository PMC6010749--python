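# phylobeta

Phylogeny-based explicit Bayesian logistic regression for taxon
occurrence.

Ecologists modelling where a taxon occurs along an environmental
gradient usually fit each taxon separately, which fails for the many
taxa observed at only a handful of sites.  Related taxa tend to retain
similar environmental tolerances (niche conservatism), so their
occurrence–environment slopes are not independent.  `phylobeta`
implements a hierarchical logistic regression that makes this explicit:
every node of a phylogenetic tree carries a slope, and each slope is
drawn around its parent's, so rare taxa borrow statistical strength from
well-sampled relatives.  It was built for presence/absence surveys of
stream insects against water chemistry (caddisfly genera vs pH), but
applies to any binary occurrence matrix, covariate vector, and rooted
tree topology.

## The model

For taxon *j* at site *i* with covariate *x_i*:

    O[i,j] ~ Bernoulli(P[i,j])
    logit(P[i,j]) = alpha_j + beta_j * x_i

    beta_j ~ Normal(mean = beta_parent(j), precision = tau_j)   for every tree node j
    beta_root ~ Normal(0, precision = tau_root)
    tau_j ~ Gamma(0.001, 0.001)
    alpha_j ~ Normal(0, precision = 1e-6)                        for leaves
    sigma_j = 1 / tau_j                                          (derived variance)

Normals are precision-parameterized (BUGS convention).  Inference is
Metropolis-within-Gibbs: exact conjugate draws for all precisions and
internal slopes, adaptive random-walk Metropolis for leaf
intercept/slope pairs; defaults are 5 chains with 1,000 kept draws each
after 1,000 burn-in sweeps, thinned at 5.  Posterior slopes are
summarized into four evidence bands on the tail probability of no
effect (< 0.05 very strong, 0.05–0.15 strong, 0.15–0.30 acceptable,
≥ 0.30 little evidence), and the fit is validated by leave-genera-out
cross-validation: held-out taxa are scored with the slope of their
nearest surviving ancestor node, summarized by ROC AUC across rounds.

The package also ships the tree utilities the workflow needs
(Robinson–Foulds distance, a majority-filtered greedy supertree,
pruning with a node map) and a synthetic-data generator that emulates
the motivating survey's scale (101 sites, 24 taxa, pH-like covariate,
strong occupancy skew).  See `docs/methods.md` for the full account.

## Worked example

```python
import phylobeta as pb

# a study-scale synthetic dataset with known ground truth
truth = pb.simulate_dataset(pb.SimConfig(seed=7))

cfg = pb.McmcConfig(n_chains=2, burn_in=1000, kept_per_chain=1000, thin=5, seed=1)
fit = pb.sample_posterior(truth.data, truth.topology, cfg=cfg, center_covariate=True)
print("acceptance rates:", {k: round(v, 2) for k, v in fit.acceptance_rates.items()})
print("worst split R-hat:", round(max(pb.gelman_rubin(fit).values()), 3))

report = pb.make_report(fit)
print(report.table.head(6).round(3).to_string(index=False))

plain = pb.fit_plain(truth.data, cfg=cfg, center_covariate=True)       # star tree
print(pb.compare_models(report, pb.make_report(plain))["change"].value_counts().to_dict())

cv = pb.cross_validate(
    truth.data, truth.topology,
    mcmc_cfg=pb.McmcConfig(n_chains=1, burn_in=300, kept_per_chain=300, thin=1),
    cv_cfg=pb.CVConfig(n_rounds=50, seed=3),
    center_covariate=True,
)
print(f"mean AUC {cv.mean_auc:.3f}, 95% CI [{cv.ci[0]:.3f}, {cv.ci[1]:.3f}]")
```

Output:

```
acceptance rates: {'alpha': 0.43, 'beta_leaf': 0.44}
worst split R-hat: 1.028
 node taxon   mean  variance sign     p    category
    1       -0.546     0.471    - 0.187  acceptable
    2       -0.984     0.601    - 0.050      strong
    3       -1.142     0.774    - 0.060      strong
    4   t12 -0.982     0.842    - 0.126      strong
    5       -1.552     0.572    - 0.018 very_strong
    6       -2.079     1.494    - 0.006 very_strong
{'no change': 17, 'improved': 7}
mean AUC 0.792, 95% CI [0.630, 0.946]
```

Reading it: the Metropolis blocks sit at the 0.44 adaptation target and
the chains agree (R-hat ≈ 1).  The report gives one row per tree node —
internal nodes are ancestral slope estimates (blank taxon), leaves are
observed taxa — with the posterior mean and variance of the slope, its
sign, the tail probability `p`, and the evidence band.  In this
simulated community the slopes happen to drift negative from the root.
Against the star-tree fit (independent per-taxon regressions), 7 of 24
taxa move to a stronger evidence band when the phylogeny is used.  The
cross-validated AUC well above 0.5 means ancestor slopes genuinely
predict held-out taxa's occurrences.

A command-line interface wraps the same workflow:

```sh
phylobeta simulate --out-dir sim --seed 7
phylobeta fit --tree sim/tree.nwk --occurrence sim/occurrence.csv \
              --env sim/environment.csv --center --out posterior.nc
phylobeta decide posterior.nc --out report.csv
phylobeta validate --tree sim/tree.nwk --occurrence sim/occurrence.csv \
                   --env sim/environment.csv --out cv.json
phylobeta tree rf a.nwk b.nwk
phylobeta tree supertree a.nwk b.nwk -o super.nwk
```

Every command writes a manifest with the config, seed, and SHA-256 of
each artifact; identical configs give identical manifests.

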