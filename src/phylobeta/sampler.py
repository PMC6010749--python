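"""Metropolis-within-Gibbs sampler for the tree-cascade logistic model.

The tree interior is conditionally Gaussian/Gamma and is updated with
exact conjugate draws — this tree-structured conjugacy is the
computational heart of the model:

* each node precision tau_j has full conditional
  Gamma(shape + 1/2, rate + (beta_j - beta_parent)^2 / 2);
* each internal slope beta_j has a Gaussian full conditional combining its
  parent edge and one term per child edge.

Leaf (alpha, beta) pairs face the Bernoulli likelihood and are updated
componentwise by random-walk Metropolis, with per-parameter proposal
scales adapted during burn-in (Robbins-Monro on the log scale, target
acceptance 0.44) and frozen afterwards so the post-burn-in kernel leaves
the posterior invariant.

The default chain schedule follows the study: five independent chains,
1,000 burn-in sweeps, then 1,000 kept draws per chain thinned at 5.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
from scipy.special import log_expit

from .model import HyperParams, ModelState, OccurrenceData, _leaf_columns
from .trees import ROOT_PARENT, Topology, write_newick

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "sample_posterior",
    "update_tau",
    "update_internal_beta",
    "update_leaf_params",
    "gelman_rubin",
]

TAU_CAP = 1.0e12  # numerical guard on nearly-improper Gamma(0.001, 0.001)
ACCEPT_TARGET = 0.44  # standard optimum for 1-D random-walk Metropolis


@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule and proposal settings.

    Defaults mirror the study: 5 chains, 1,000 kept draws per chain after
    1,000 burn-in sweeps, thinning every 5th sweep.
    """

    n_chains: int = 5
    burn_in: int = 1000
    kept_per_chain: int = 1000
    thin: int = 5
    seed: int = 0
    proposal_sd_init: float = 0.5
    adapt_during_burnin: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.kept_per_chain) < 1:
            raise ValueError("chain counts must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_sd_init <= 0:
            raise ValueError("proposal_sd_init must be positive")


class PosteriorSamples:
    """Kept posterior draws, stacked per chain.

    ``draws`` maps parameter names — ``alpha[taxon]``, ``beta[node]``,
    ``tau[node]`` — to arrays of shape (n_chains, kept_per_chain).
    """

    def __init__(
        self,
        draws: Mapping[str, np.ndarray],
        config: McmcConfig,
        topology: Topology,
        acceptance_rates: Mapping[str, float],
        x_offset: float = 0.0,
    ):
        self.draws = dict(draws)
        self.config = config
        self.topology = topology
        self.acceptance_rates = dict(acceptance_rates)
        self.x_offset = float(x_offset)
        kept = config.kept_per_chain
        for name, arr in self.draws.items():
            if arr.shape != (config.n_chains, kept):
                raise ValueError(f"draws[{name}] has shape {arr.shape}")

    def flat(self, name: str) -> np.ndarray:
        """All kept draws for one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.flat(name).mean())

    def var(self, name: str) -> float:
        return float(self.flat(name).var(ddof=1))

    def beta_node(self, node_id: int) -> np.ndarray:
        return self.flat(f"beta[{node_id}]")

    def alpha_taxon(self, taxon: str) -> np.ndarray:
        return self.flat(f"alpha[{taxon}]")

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def to_dataframe(self):
        """Long-format export: chain, draw, parameter, value."""
        import pandas as pd

        frames = []
        for name, arr in self.draws.items():
            n_chains, kept = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chains), kept),
                        "draw": np.tile(np.arange(kept), n_chains),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        """Write a self-describing NetCDF container (xarray, scipy engine)."""
        import xarray as xr

        ds = xr.Dataset(
            {name: (("chain", "draw"), arr) for name, arr in self.draws.items()},
            attrs={
                "config": json.dumps(asdict(self.config)),
                "tree": write_newick(self.topology),
                "x_offset": self.x_offset,
                "acceptance_rates": json.dumps(self.acceptance_rates),
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @staticmethod
    def load(path) -> "PosteriorSamples":
        import xarray as xr

        from .trees import parse_newick

        with xr.open_dataset(path, engine="scipy") as ds:
            draws = {name: ds[name].values.copy() for name in ds.data_vars}
            cfg = McmcConfig(**json.loads(ds.attrs["config"]))
            topo = parse_newick(ds.attrs["tree"])
            rates = json.loads(ds.attrs["acceptance_rates"])
            x_off = float(ds.attrs["x_offset"])
        return PosteriorSamples(draws, cfg, topo, rates, x_off)


# -- single-site updates (reference API, also used by the sweep) ---------


def update_tau(
    node: int,
    state: ModelState,
    topo: Topology,
    h: HyperParams,
    rng: np.random.Generator,
) -> float:
    """Exact conjugate Gamma draw for one node precision."""
    p = topo.parent(node)
    parent_beta = h.root_beta_mean if p == ROOT_PARENT else state.beta[p]
    ss = (state.beta[node] - parent_beta) ** 2
    draw = rng.gamma(h.tau_shape + 0.5, 1.0 / (h.tau_rate + 0.5 * ss))
    return float(min(draw, TAU_CAP))


def update_internal_beta(
    node: int,
    state: ModelState,
    topo: Topology,
    h: HyperParams,
    rng: np.random.Generator,
) -> float:
    """Exact Gaussian draw from an internal slope's full conditional.

    Precision is tau_node + sum of child taus; the mean is the
    precision-weighted average of the parent's slope and the children's.
    """
    if topo.is_leaf(node):
        raise ValueError(f"node {node} is a leaf")
    p = topo.parent(node)
    parent_beta = h.root_beta_mean if p == ROOT_PARENT else state.beta[p]
    prec = state.tau[node]
    mean_num = state.tau[node] * parent_beta
    for c in topo.children(node):
        prec += state.tau[c]
        mean_num += state.tau[c] * state.beta[c]
    return float(rng.normal(mean_num / prec, 1.0 / math.sqrt(prec)))


def _column_loglik(o_col: np.ndarray, x: np.ndarray, alpha: float, beta: float) -> float:
    z = alpha + beta * x
    return float(np.sum(o_col * log_expit(z) + (1 - o_col) * log_expit(-z)))


def update_leaf_params(
    leaf: int,
    data: OccurrenceData,
    state: ModelState,
    topo: Topology,
    h: HyperParams,
    rng: np.random.Generator,
    scales: tuple[float, float] = (0.5, 0.5),
) -> tuple[float, float, tuple[bool, bool]]:
    """Componentwise random-walk Metropolis on one leaf's (alpha, beta).

    Returns the new values and which of the two proposals were accepted.
    The acceptance ratio uses only the leaf's local posterior terms: its
    data column, its intercept prior, and its slope's parent edge.
    """
    cols = _leaf_columns(topo, data)
    leaf_pos = list(topo.leaf_ids).index(leaf)
    o_col = data.occurrence[:, cols[leaf_pos]]
    x = data.covariate
    p = topo.parent(leaf)
    parent_beta = h.root_beta_mean if p == ROOT_PARENT else state.beta[p]

    alpha, beta = float(state.alpha[leaf_pos]), float(state.beta[leaf])
    accepted = [False, False]

    cur_ll = _column_loglik(o_col, x, alpha, beta)
    prop = alpha + scales[0] * rng.normal()
    delta = (
        _column_loglik(o_col, x, prop, beta)
        - cur_ll
        - 0.5 * h.alpha_precision * (prop**2 - alpha**2)
    )
    if math.log(rng.random()) < delta:
        alpha = prop
        accepted[0] = True

    cur_ll = _column_loglik(o_col, x, alpha, beta)
    prop = beta + scales[1] * rng.normal()
    delta = (
        _column_loglik(o_col, x, alpha, prop)
        - cur_ll
        - 0.5 * state.tau[leaf] * ((prop - parent_beta) ** 2 - (beta - parent_beta) ** 2)
    )
    if math.log(rng.random()) < delta:
        beta = prop
        accepted[1] = True

    return alpha, beta, (accepted[0], accepted[1])


# -- full sampler --------------------------------------------------------


class _ChainRunner:
    """One chain's state and vectorized sweep kernel."""

    def __init__(
        self,
        data: OccurrenceData,
        topo: Topology,
        h: HyperParams,
        cfg: McmcConfig,
        rng: np.random.Generator,
        x_offset: float,
        fix_tau: float | None,
        sample_root: bool,
    ):
        self.topo = topo
        self.h = h
        self.cfg = cfg
        self.rng = rng
        self.fix_tau = fix_tau
        self.sample_root = sample_root

        cols = _leaf_columns(topo, data)
        self.O = data.occurrence[:, cols].astype(float)  # sites x leaves
        self.x = data.covariate - x_offset
        self.leaf_ids = np.array(topo.leaf_ids)
        n = len(topo.nodes)
        self.n_nodes = n
        self.parent = np.array([topo.parent(i) for i in topo.node_ids])
        # internal nodes updated in increasing id order (parents first)
        self.internal = [
            i
            for i in topo.internal_ids
            if sample_root or i != topo.root_id
        ]
        self.children = {i: np.array(topo.children(i)) for i in self.internal}

        self.state = ModelState.initial(data, topo)
        if fix_tau is not None:
            self.state.tau[:] = fix_tau
        if not sample_root:
            self.state.beta[topo.root_id] = h.root_beta_mean
        self.log_scale = np.full((2, len(self.leaf_ids)), math.log(cfg.proposal_sd_init))
        self.adapt_step = 0
        self.accept_count = np.zeros(2)
        self.accept_tries = 0

    # parent slope per node, with the root's prior mean standing in
    def _parent_beta(self) -> np.ndarray:
        out = np.empty(self.n_nodes)
        for i in range(1, self.n_nodes + 1):
            p = self.parent[i - 1]
            out[i - 1] = self.h.root_beta_mean if p == ROOT_PARENT else self.state.beta[p]
        return out

    def _leaf_loglik(self, alpha: np.ndarray, beta_leaf: np.ndarray) -> np.ndarray:
        """Per-leaf Bernoulli log-likelihood, vectorized across leaves."""
        z = alpha[None, :] + np.outer(self.x, beta_leaf)
        return np.sum(self.O * log_expit(z) + (1 - self.O) * log_expit(-z), axis=0)

    def sweep(self, adapting: bool, count_acceptance: bool) -> None:
        st, h, rng = self.state, self.h, self.rng

        # 1. precisions: independent conjugate Gamma draws, all at once
        if self.fix_tau is None:
            ss = (st.beta[1:] - self._parent_beta()) ** 2
            draws = rng.gamma(
                h.tau_shape + 0.5, 1.0 / (h.tau_rate + 0.5 * ss)
            )
            st.tau[1:] = np.minimum(draws, TAU_CAP)

        # 2. internal slopes: sequential exact Gaussian draws
        for v in self.internal:
            p = self.parent[v - 1]
            pb = h.root_beta_mean if p == ROOT_PARENT else st.beta[p]
            ch = self.children[v]
            prec = st.tau[v] + st.tau[ch].sum()
            mean = (st.tau[v] * pb + (st.tau[ch] * st.beta[ch]).sum()) / prec
            st.beta[v] = rng.normal(mean, 1.0 / math.sqrt(prec))

        # 3. leaf intercepts and slopes: vectorized componentwise Metropolis
        beta_leaf = st.beta[self.leaf_ids]
        parent_leaf_beta = np.array(
            [
                h.root_beta_mean if p == ROOT_PARENT else st.beta[p]
                for p in self.parent[self.leaf_ids - 1]
            ]
        )
        tau_leaf = st.tau[self.leaf_ids]
        cur_ll = self._leaf_loglik(st.alpha, beta_leaf)

        # alpha block
        prop = st.alpha + np.exp(self.log_scale[0]) * rng.normal(size=st.alpha.shape)
        delta = (
            self._leaf_loglik(prop, beta_leaf)
            - cur_ll
            - 0.5 * h.alpha_precision * (prop**2 - st.alpha**2)
        )
        acc_a = np.log(rng.random(size=st.alpha.shape)) < delta
        st.alpha = np.where(acc_a, prop, st.alpha)

        # beta block
        cur_ll = self._leaf_loglik(st.alpha, beta_leaf)
        prop = beta_leaf + np.exp(self.log_scale[1]) * rng.normal(size=beta_leaf.shape)
        delta = (
            self._leaf_loglik(st.alpha, prop)
            - cur_ll
            - 0.5
            * tau_leaf
            * ((prop - parent_leaf_beta) ** 2 - (beta_leaf - parent_leaf_beta) ** 2)
        )
        acc_b = np.log(rng.random(size=beta_leaf.shape)) < delta
        st.beta[self.leaf_ids] = np.where(acc_b, prop, beta_leaf)

        if adapting:
            self.adapt_step += 1
            gain = self.adapt_step ** -0.6
            self.log_scale[0] += gain * (acc_a.astype(float) - ACCEPT_TARGET)
            self.log_scale[1] += gain * (acc_b.astype(float) - ACCEPT_TARGET)
        if count_acceptance:
            self.accept_count += np.array([acc_a.mean(), acc_b.mean()])
            self.accept_tries += 1


def sample_posterior(
    data: OccurrenceData,
    topo: Topology,
    h: HyperParams | None = None,
    cfg: McmcConfig | None = None,
    center_covariate: bool = False,
    fix_tau: float | None = None,
    sample_root: bool = True,
) -> PosteriorSamples:
    """Run the full MCMC and return kept draws.

    Parameters
    ----------
    center_covariate : subtract the covariate mean before fitting.  Slopes
        are unaffected; intercepts shift by ``beta * mean(x)``.  Off by
        default; recommended when the covariate is far from zero, where it
        removes the intercept/slope collinearity that slows mixing.
    fix_tau : hold every node precision at this value instead of sampling
        (diagnostic/comparison use).
    sample_root : if False, clamp the root slope at its prior mean, which
        makes each root child's slope prior independent — the "no
        phylogeny" comparator when the tree is a star.
    """
    h = h or HyperParams()
    cfg = cfg or McmcConfig()
    data.check_against(topo)
    x_offset = float(data.covariate.mean()) if center_covariate else 0.0

    names = (
        [f"alpha[{topo.label(i)}]" for i in topo.leaf_ids]
        + [f"beta[{i}]" for i in topo.node_ids]
        + [f"tau[{i}]" for i in topo.node_ids]
    )
    kept = cfg.kept_per_chain
    store = {name: np.empty((cfg.n_chains, kept)) for name in names}
    acc_totals = np.zeros(2)

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(chain,))
        )
        runner = _ChainRunner(
            data, topo, h, cfg, rng, x_offset, fix_tau, sample_root
        )
        for _ in range(cfg.burn_in):
            runner.sweep(adapting=cfg.adapt_during_burnin, count_acceptance=False)
        for k in range(kept):
            for _ in range(cfg.thin):
                runner.sweep(adapting=False, count_acceptance=True)
            st = runner.state
            for pos, i in enumerate(topo.leaf_ids):
                store[f"alpha[{topo.label(i)}]"][chain, k] = st.alpha[pos]
            for i in topo.node_ids:
                store[f"beta[{i}]"][chain, k] = st.beta[i]
                store[f"tau[{i}]"][chain, k] = st.tau[i]
        acc_totals += runner.accept_count / max(runner.accept_tries, 1)

    rates = {
        "alpha": float(acc_totals[0] / cfg.n_chains),
        "beta_leaf": float(acc_totals[1] / cfg.n_chains),
    }
    return PosteriorSamples(store, cfg, topo, rates, x_offset)


# -- convergence ---------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Each chain is split in half; R-hat compares between- and within-half
    variances.  Values near 1 indicate the chains agree.  Two degenerate
    cases report exactly 1: bit-identical chains (no between-chain
    disagreement to measure) and zero between-half variance.
    """
    if samples.config.n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    out: dict[str, float] = {}
    for name, arr in samples.draws.items():
        if (arr == arr[0]).all():
            out[name] = 1.0
            continue
        n_chains, kept = arr.shape
        half = kept // 2
        halves = np.concatenate(
            [arr[:, :half], arr[:, half : 2 * half]], axis=0
        )
        n = halves.shape[1]
        means = halves.mean(axis=1)
        B = n * means.var(ddof=1)
        W = halves.var(axis=1, ddof=1).mean()
        if B == 0.0:
            out[name] = 1.0
        elif W == 0.0:
            out[name] = math.inf
        else:
            v_hat = (n - 1) / n * W + B / n
            out[name] = math.sqrt(v_hat / W)
    return out
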