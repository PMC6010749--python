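"""Leave-genera-out cross-validation scored by ROC AUC.

Each round holds out a small random subset of taxa (5% by default,
minimum one), prunes them from both tree and data, refits the model, and
scores every held-out taxon's observed occurrences with the posterior
mean slope of its nearest surviving ancestor node — the model's claim
being that phylogenetic neighbours carry usable information about a taxon
never seen in training.  Rounds are aggregated into a mean AUC with a
percentile confidence interval; a mean above 0.5 indicates genuine
predictive signal.

The held-out taxon has no fitted intercept; scores use the pooled mean of
the training taxa's intercepts.  AUC is invariant to any monotone shift
of the scores, so per-taxon AUC does not depend on that convention; the
pooled-across-taxa AUC does, and is therefore flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .model import HyperParams, OccurrenceData
from .sampler import McmcConfig, PosteriorSamples, sample_posterior
from .trees import Topology, prune_leaves

__all__ = [
    "CVConfig",
    "CVReport",
    "split_validation",
    "predict_heldout",
    "roc_auc",
    "cross_validate",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation schedule.

    holdout_fraction : fraction of taxa per validation set (default 0.05;
        the holdout count is max(1, round(fraction * n_taxa)), so 24 taxa
        give one held-out genus per round).
    n_rounds : validation rounds (study default 1,000).
    auc_threshold : the "good fit" bar for the mean AUC (0.5).
    ci_level : percentile interval level over rounds (0.95).
    pooling : "pooled" computes one AUC per round over all held-out
        (site, taxon) pairs; "per_taxon" averages per-taxon AUCs.
    shuffle_labels : permute observed labels across sites before scoring
        (null calibration — AUC should collapse to 0.5).
    """

    holdout_fraction: float = 0.05
    n_rounds: int = 1000
    auc_threshold: float = 0.5
    ci_level: float = 0.95
    seed: int = 0
    pooling: str = "pooled"
    shuffle_labels: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.pooling not in ("pooled", "per_taxon"):
            raise ValueError("pooling must be 'pooled' or 'per_taxon'")

    def holdout_count(self, n_taxa: int) -> int:
        return max(1, int(math.floor(self.holdout_fraction * n_taxa + 0.5)))


@dataclass
class CVReport:
    """Aggregated cross-validation result.

    ``aucs`` has one entry per round (NaN where the round's AUC was
    undefined and skipped); the CI is the percentile interval over the
    defined rounds.
    """

    aucs: np.ndarray
    mean_auc: float
    ci: tuple[float, float]
    per_taxon: Mapping[str, float]
    n_skipped: int
    passed: bool
    config: CVConfig

    @property
    def n_rounds(self) -> int:
        return len(self.aucs)


def split_validation(
    taxa: Sequence[str], cfg: CVConfig, round_index: int
) -> tuple[list[str], list[str]]:
    """Deterministic random train/validation partition for one round."""
    taxa = list(taxa)
    k = cfg.holdout_count(len(taxa))
    if k >= len(taxa):
        raise ValueError("holdout would remove every taxon")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(round_index,))
    )
    val_idx = set(rng.choice(len(taxa), size=k, replace=False).tolist())
    val = [t for i, t in enumerate(taxa) if i in val_idx]
    train = [t for i, t in enumerate(taxa) if i not in val_idx]
    return train, val


def nearest_surviving_ancestor(
    taxon: str, original_topo: Topology, prune_map: Mapping[int, int | None]
) -> int:
    """New-tree node id of the held-out leaf's closest ancestor that
    survived pruning.

    A leaf hanging directly off the root can lose every strict ancestor
    (dropping it leaves the old root unary, which is suppressed); such a
    taxon attaches at the pruned tree's root, so the root slope is its
    nearest phylogenetic information.
    """
    leaf_id = {original_topo.label(i): i for i in original_topo.leaf_ids}[taxon]
    for anc in original_topo.ancestors(leaf_id):
        new_id = prune_map.get(anc)
        if new_id is not None:
            return new_id
    return 1  # pruned tree's root


def predict_heldout(
    taxon: str,
    pruned_fit: PosteriorSamples,
    original_topo: Topology,
    prune_map: Mapping[int, int | None],
    x: np.ndarray,
) -> np.ndarray:
    """Per-site occurrence scores for a held-out taxon.

    score_i = logistic(alpha_bar + beta_bar * x_i) with beta_bar the
    posterior mean slope of the nearest surviving ancestor node and
    alpha_bar the pooled mean of the fitted leaf intercepts.
    """
    anc = nearest_surviving_ancestor(taxon, original_topo, prune_map)
    beta_bar = pruned_fit.mean(f"beta[{anc}]")
    alpha_names = [n for n in pruned_fit.parameter_names if n.startswith("alpha[")]
    alpha_bar = float(np.mean([pruned_fit.mean(n) for n in alpha_names]))
    return expit(alpha_bar + beta_bar * (np.asarray(x, float) - pruned_fit.x_offset))


def roc_auc(scores, labels) -> float | None:
    """Area under the ROC curve (Mann-Whitney form: fraction of
    (presence, absence) pairs ranked correctly, ties counting one half).
    Returns ``None`` when the labels are single-class (AUC undefined)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def cross_validate(
    data: OccurrenceData,
    topo: Topology,
    h: HyperParams | None = None,
    mcmc_cfg: McmcConfig | None = None,
    cv_cfg: CVConfig | None = None,
    center_covariate: bool = False,
) -> CVReport:
    """Run the full leave-genera-out validation loop.

    Per round: split taxa, prune the validation taxa from tree and data,
    refit (each round's MCMC gets its own derived seed), score each
    held-out taxon via its nearest surviving ancestor, and compute the
    round's AUC.  Rounds whose labels end up single-class are recorded as
    skipped.  Fully reproducible given the two config seeds.
    """
    h = h or HyperParams()
    mcmc_cfg = mcmc_cfg or McmcConfig()
    cv_cfg = cv_cfg or CVConfig()
    data.check_against(topo)
    taxa = [topo.label(i) for i in topo.leaf_ids]

    aucs = np.full(cv_cfg.n_rounds, np.nan)
    taxon_sums: dict[str, list[float]] = {t: [] for t in taxa}

    for r in range(cv_cfg.n_rounds):
        train, val = split_validation(taxa, cv_cfg, r)
        pruned_topo, pmap = prune_leaves(topo, val)
        train_data = data.subset_taxa(train)
        fit_seed = int(
            np.random.SeedSequence(entropy=cv_cfg.seed, spawn_key=(r, 1)).generate_state(1)[0]
            % (2**31)
        )
        fit = sample_posterior(
            train_data,
            pruned_topo,
            h,
            replace(mcmc_cfg, seed=fit_seed),
            center_covariate=center_covariate,
        )
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cv_cfg.seed, spawn_key=(r, 2))
        )
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        taxon_aucs: list[float] = []
        for taxon in val:
            scores = predict_heldout(taxon, fit, topo, pmap, data.covariate)
            labels = data.column(taxon)
            if cv_cfg.shuffle_labels:
                labels = shuffle_rng.permutation(labels)
            pooled_scores.append(scores)
            pooled_labels.append(labels)
            a = roc_auc(scores, labels)
            if a is not None:
                taxon_aucs.append(a)
                taxon_sums[taxon].append(a)
        if cv_cfg.pooling == "pooled":
            round_auc = roc_auc(
                np.concatenate(pooled_scores), np.concatenate(pooled_labels)
            )
        else:
            round_auc = float(np.mean(taxon_aucs)) if taxon_aucs else None
        if round_auc is not None:
            aucs[r] = round_auc

    valid = aucs[~np.isnan(aucs)]
    if valid.size == 0:
        raise ValueError("every round had an undefined AUC")
    tail = 100 * (1 - cv_cfg.ci_level) / 2
    ci = (
        float(np.percentile(valid, tail)),
        float(np.percentile(valid, 100 - tail)),
    )
    mean_auc = float(valid.mean())
    per_taxon = {
        t: float(np.mean(v)) for t, v in taxon_sums.items() if v
    }
    return CVReport(
        aucs=aucs,
        mean_auc=mean_auc,
        ci=ci,
        per_taxon=per_taxon,
        n_skipped=int(np.isnan(aucs).sum()),
        passed=mean_auc > cv_cfg.auc_threshold,
        config=cv_cfg,
    )
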