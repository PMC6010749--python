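"""Data model and exact log-density of the phylogeny-based logistic model.

The model: occurrence of taxon ``j`` at site ``i`` is Bernoulli with

    logit(P[i, j]) = alpha_j + beta_j * x_i

where ``x`` is a per-site environmental covariate (stream pH in the
motivating study).  The slopes ``beta`` are not independent: every tree
node carries a slope, and each node's slope is Normal around its parent's
slope — a cascade running from the root (whose slope is Normal around a
fixed mean, zero by default) down to the leaves.  Relatedness therefore
pools information: a rarely observed taxon borrows strength from the slope
of its ancestor, which is informed by better-sampled relatives.

All Normal distributions are parameterized by *precision* tau (the BUGS
convention); each node's precision gets a diffuse Gamma(0.001, 0.001)
prior, and sigma = 1/tau is the derived variance, reported but never
sampled.  Leaf intercepts alpha are Normal with mean 0 and precision 1e-6
(variance 1e6), i.e. essentially flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, log_expit

from .trees import ROOT_PARENT, Topology

__all__ = [
    "HyperParams",
    "OccurrenceData",
    "ModelState",
    "occurrence_probability",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "read_occurrence_table",
    "read_environment_table",
]


@dataclass(frozen=True)
class HyperParams:
    """Fixed hyperparameters of the hierarchical prior.

    alpha_precision : precision of the Normal prior on leaf intercepts
        (default 1e-6, i.e. variance 1e6 — effectively uninformative).
    tau_shape, tau_rate : Gamma prior on every node precision
        (default 0.001, 0.001 — diffuse).
    root_beta_mean : prior mean of the root slope (default 0).
    """

    alpha_precision: float = 1.0e-6
    tau_shape: float = 0.001
    tau_rate: float = 0.001
    root_beta_mean: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_precision", "tau_shape", "tau_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


class OccurrenceData:
    """Site x taxon binary occurrence matrix plus per-site covariate.

    Parameters
    ----------
    occurrence : (n_sites, n_taxa) array of 0/1
    covariate : (n_sites,) array of finite reals (e.g. pH per stream)
    site_ids, taxon_ids : names; taxon_ids must match tree leaf labels
    require_occupancy : if True (default), every taxon must occur at
        least one site — observed-taxa datasets satisfy this by design.
    """

    def __init__(
        self,
        occurrence: np.ndarray,
        covariate: np.ndarray,
        site_ids: Sequence[str] | None = None,
        taxon_ids: Sequence[str] | None = None,
        require_occupancy: bool = True,
    ):
        O = np.asarray(occurrence)
        x = np.asarray(covariate, dtype=float)
        if O.ndim != 2:
            raise ValueError("occurrence must be a 2-D site x taxon matrix")
        if np.isnan(O.astype(float)).any():
            raise ValueError("occurrence matrix has missing cells")
        if not np.isin(O, (0, 1)).all():
            raise ValueError("occurrence matrix must be binary 0/1")
        if x.shape != (O.shape[0],):
            raise ValueError(
                f"covariate length {x.shape} does not match "
                f"{O.shape[0]} sites"
            )
        if not np.isfinite(x).all():
            raise ValueError("covariate must be finite")
        self.occurrence = O.astype(np.int8)
        self.covariate = x
        self.site_ids = (
            list(site_ids)
            if site_ids is not None
            else [f"site_{i+1}" for i in range(O.shape[0])]
        )
        self.taxon_ids = (
            list(taxon_ids)
            if taxon_ids is not None
            else [f"taxon_{j+1}" for j in range(O.shape[1])]
        )
        if len(self.site_ids) != O.shape[0] or len(self.taxon_ids) != O.shape[1]:
            raise ValueError("id lists do not match matrix dimensions")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if require_occupancy and (self.occurrence.sum(axis=0) == 0).any():
            empty = [
                t
                for t, s in zip(self.taxon_ids, self.occurrence.sum(axis=0))
                if s == 0
            ]
            raise ValueError(f"taxa never observed: {empty}")

    @property
    def n_sites(self) -> int:
        return self.occurrence.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.occurrence.shape[1]

    def occupancy(self) -> np.ndarray:
        """Fraction of sites occupied, per taxon."""
        return self.occurrence.mean(axis=0)

    def column(self, taxon: str) -> np.ndarray:
        return self.occurrence[:, self.taxon_ids.index(taxon)]

    def subset_taxa(self, keep: Sequence[str]) -> "OccurrenceData":
        """Restrict to the given taxa, preserving the given order."""
        idx = [self.taxon_ids.index(t) for t in keep]
        return OccurrenceData(
            self.occurrence[:, idx],
            self.covariate,
            site_ids=self.site_ids,
            taxon_ids=list(keep),
            require_occupancy=False,
        )

    def check_against(self, topo: Topology) -> None:
        if set(self.taxon_ids) != set(topo.leaf_labels):
            raise ValueError(
                "taxon set does not match tree leaves; difference: "
                f"{sorted(set(self.taxon_ids) ^ set(topo.leaf_labels))}"
            )


@dataclass
class ModelState:
    """One full parameter assignment.

    alpha : (n_leaves,) leaf intercepts, ordered as ``topo.leaf_ids``
    beta : (n_nodes + 1,) per-node slopes indexed by node id (entry 0 unused)
    tau : (n_nodes + 1,) per-node precisions, same indexing
    """

    alpha: np.ndarray
    beta: np.ndarray
    tau: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        """Per-node variance, the derived quantity sigma = 1/tau."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.tau

    def copy(self) -> "ModelState":
        return ModelState(self.alpha.copy(), self.beta.copy(), self.tau.copy())

    @staticmethod
    def initial(data: OccurrenceData, topo: Topology) -> "ModelState":
        """Deterministic start: alpha at the logit of observed occupancy
        (clamped to [-3, 3]), beta = 0, tau = 1."""
        if data.n_sites == 0:  # prior-only runs
            alpha = np.zeros(len(topo.leaf_ids))
        else:
            occ = data.occupancy()
            # order alpha by leaf id, matching topo.leaf_ids
            cols = {t: j for j, t in enumerate(data.taxon_ids)}
            freq = np.array([occ[cols[topo.label(i)]] for i in topo.leaf_ids])
            freq = np.clip(freq, 1e-12, 1 - 1e-12)
            alpha = np.clip(np.log(freq / (1 - freq)), -3.0, 3.0)
        n = len(topo.nodes)
        return ModelState(
            alpha=alpha,
            beta=np.zeros(n + 1),
            tau=np.ones(n + 1),
        )


def occurrence_probability(alpha, beta, x):
    """P(occurrence) = logistic(alpha + beta * x); stable for any finite
    linear predictor.  Broadcasts like numpy."""
    return expit(np.asarray(alpha) + np.asarray(beta) * np.asarray(x))


def _leaf_columns(topo: Topology, data: OccurrenceData) -> np.ndarray:
    """Column index in ``data`` for each leaf, in ``topo.leaf_ids`` order."""
    data.check_against(topo)
    cols = {t: j for j, t in enumerate(data.taxon_ids)}
    return np.array([cols[topo.label(i)] for i in topo.leaf_ids])


def log_likelihood(
    data: OccurrenceData, state: ModelState, topo: Topology
) -> float:
    """Bernoulli log-likelihood summed over all (site, taxon) cells."""
    cols = _leaf_columns(topo, data)
    if state.alpha.shape != (len(cols),) or state.beta.shape != (
        len(topo.nodes) + 1,
    ):
        raise ValueError("state dimensions do not match data/topology")
    beta_leaf = state.beta[list(topo.leaf_ids)]
    z = state.alpha[None, :] + np.outer(data.covariate, beta_leaf)
    O = data.occurrence[:, cols]
    return float(np.sum(O * log_expit(z) + (1 - O) * log_expit(-z)))


def log_prior(state: ModelState, topo: Topology, h: HyperParams) -> float:
    """Log-density of the hierarchical prior at ``state``.

    Sum of (a) Normal terms for every node slope given its parent's slope
    (the root given ``root_beta_mean``) with the node's own precision,
    (b) Gamma terms for every node precision, and (c) Normal terms for the
    leaf intercepts.
    """
    n = len(topo.nodes)
    tau = state.tau[1:]
    if not (tau > 0).all():
        raise ValueError("all precisions must be strictly positive")
    parent_beta = np.empty(n)
    for i in topo.node_ids:
        p = topo.parent(i)
        parent_beta[i - 1] = (
            h.root_beta_mean if p == ROOT_PARENT else state.beta[p]
        )
    lp = float(
        np.sum(stats.norm.logpdf(state.beta[1:], parent_beta, 1.0 / np.sqrt(tau)))
    )
    lp += float(
        np.sum(
            stats.gamma.logpdf(tau, a=h.tau_shape, scale=1.0 / h.tau_rate)
        )
    )
    lp += float(
        np.sum(
            stats.norm.logpdf(
                state.alpha, 0.0, 1.0 / np.sqrt(h.alpha_precision)
            )
        )
    )
    return lp


def log_posterior(
    data: OccurrenceData,
    state: ModelState,
    topo: Topology,
    h: HyperParams,
) -> float:
    """Unnormalized log posterior: log-likelihood + log-prior."""
    return log_likelihood(data, state, topo) + log_prior(state, topo, h)


# -- delimited-file readers ----------------------------------------------


def read_occurrence_table(path: str | Path) -> pd.DataFrame:
    """Read a sites x taxa 0/1 matrix: header row of taxon names, first
    column of site ids.  Comma-delimited by default; tabs accepted."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells in occurrence matrix")
    return df

def read_environment_table(path: str | Path) -> pd.Series:
    """Read a two-column site,covariate table into a Series."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one covariate column")
    return df.iloc[:, 0].astype(float)


def make_occurrence_data(
    occ: pd.DataFrame, env: pd.Series, require_occupancy: bool = True
) -> OccurrenceData:
    """Join an occurrence matrix and an environment table on site id."""
    missing = [s for s in occ.index if s not in env.index]
    if missing:
        raise ValueError(f"sites without a covariate value: {missing}")
    x = env.loc[occ.index].to_numpy()
    return OccurrenceData(
        occ.to_numpy(),
        x,
        site_ids=[str(s) for s in occ.index],
        taxon_ids=[str(t) for t in occ.columns],
        require_occupancy=require_occupancy,
    )
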