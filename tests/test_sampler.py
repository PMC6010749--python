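"""Sampler correctness: conjugate updates, detailed balance, diagnostics."""

import math

import numpy as np
import pytest

import phylobeta as pb
from phylobeta.sampler import _ChainRunner  # noqa: F401  (import guard)

from conftest import tiny_data


def make_state(topo, rng, tau=1.0):
    n = len(topo.nodes)
    return pb.ModelState(
        rng.normal(size=len(topo.leaf_ids)),
        rng.normal(size=n + 1),
        np.full(n + 1, tau),
    )


class TestUpdateTau:
    def test_conjugate_parameters_when_slopes_equal(self):
        """beta_node == beta_parent leaves only the prior sufficient
        statistics: Gamma(shape + 1/2, rate), mean 0.501/0.001."""
        topo = pb.parse_newick("(A,B);")
        h = pb.HyperParams()
        state = make_state(topo, np.random.default_rng(0))
        state.beta[2] = state.beta[1]
        rng = np.random.default_rng(1)
        draws = np.array(
            [pb.update_tau(2, state, topo, h, rng) for _ in range(200_000)]
        )
        analytic_mean = (h.tau_shape + 0.5) / h.tau_rate
        # heavy-tailed: compare on the log scale against the analytic value
        from scipy import stats

        analytic_log_mean = stats.loggamma.mean(h.tau_shape + 0.5) - math.log(
            h.tau_rate
        )
        se = stats.loggamma.std(h.tau_shape + 0.5) / math.sqrt(len(draws))
        assert np.log(draws).mean() == pytest.approx(analytic_log_mean, abs=4 * se)
        assert draws.mean() < 10 * analytic_mean  # sane scale
        assert (draws > 0).all()

    def test_long_run_mean_matches_analytic(self):
        topo = pb.parse_newick("(A,B);")
        h = pb.HyperParams(tau_shape=2.0, tau_rate=2.0)
        state = make_state(topo, np.random.default_rng(3))
        node = 3
        ss = (state.beta[node] - state.beta[1]) ** 2
        shape, rate = 2.0 + 0.5, 2.0 + ss / 2
        rng = np.random.default_rng(4)
        draws = np.array(
            [pb.update_tau(node, state, topo, h, rng) for _ in range(100_000)]
        )
        se = math.sqrt(shape) / rate / math.sqrt(len(draws))
        assert draws.mean() == pytest.approx(shape / rate, abs=4 * se)


class TestUpdateInternalBeta:
    def test_single_child_equal_tau_gives_midpoint_mean(self):
        # chain root(1) - internal(2) - leaf(3)
        topo = pb.parse_newick("((A));")
        h = pb.HyperParams()
        state = make_state(topo, np.random.default_rng(0), tau=2.0)
        rng = np.random.default_rng(1)
        draws = np.array(
            [pb.update_internal_beta(2, state, topo, h, rng) for _ in range(50_000)]
        )
        midpoint = 0.5 * (state.beta[1] + state.beta[3])
        se = 1 / math.sqrt(4.0) / math.sqrt(len(draws))
        assert draws.mean() == pytest.approx(midpoint, abs=4 * se)

    def test_dominant_parent_precision_pins_to_parent(self):
        topo = pb.parse_newick("((A));")
        h = pb.HyperParams()
        state = make_state(topo, np.random.default_rng(0))
        state.tau[2] = 1e8
        state.tau[3] = 1e-3
        rng = np.random.default_rng(2)
        draws = np.array(
            [pb.update_internal_beta(2, state, topo, h, rng) for _ in range(2000)]
        )
        assert abs(draws.mean() - state.beta[1]) < 1e-3

    def test_matches_grid_normalized_conditional(self):
        """Empirical conditional agrees with brute-force grid normalization
        on a root-internal-leaf chain (KS check, scaled down)."""
        topo = pb.parse_newick("((A));")
        h = pb.HyperParams(root_beta_mean=0.3)
        state = make_state(topo, np.random.default_rng(5), tau=1.7)
        rng = np.random.default_rng(6)
        draws = np.sort(
            [pb.update_internal_beta(2, state, topo, h, rng) for _ in range(4000)]
        )
        grid = np.linspace(draws[0] - 2, draws[-1] + 2, 4001)
        logd = -0.5 * state.tau[2] * (grid - state.beta[1]) ** 2
        logd += -0.5 * state.tau[3] * (state.beta[3] - grid) ** 2
        dens = np.exp(logd - logd.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        grid_cdf = np.interp(draws, grid, cdf)
        ks = np.max(np.abs(grid_cdf - np.arange(1, len(draws) + 1) / len(draws)))
        assert ks < 0.035


class TestLeafUpdate:
    def test_writes_positive_finite_values_and_detailed_balance_shape(self):
        topo = pb.parse_newick("(A,B);")
        data = tiny_data(0, n_taxa=2)
        data.taxon_ids = list(topo.leaf_labels)
        h = pb.HyperParams()
        state = make_state(topo, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        accepts = 0
        for _ in range(300):
            for pos, leaf in enumerate(topo.leaf_ids):
                a, b, acc = pb.update_leaf_params(
                    leaf, data, state, topo, h, rng
                )
                state.alpha[pos] = a
                state.beta[leaf] = b
                accepts += sum(acc)
        assert np.isfinite(state.alpha).all()
        assert 0 < accepts  # chain moves

    def test_acceptance_rate_lands_near_target_after_adaptation(self, quick_mcmc):
        truth = pb.simulate_dataset(pb.SimConfig(n_taxa=8, n_sites=60, seed=5))
        fit = pb.sample_posterior(
            truth.data, truth.topology, cfg=quick_mcmc, center_covariate=True
        )
        for rate in fit.acceptance_rates.values():
            assert 0.15 <= rate <= 0.6


class TestSamplePosterior:
    def test_bit_identical_given_seed(self, quick_mcmc, small_truth):
        a = pb.sample_posterior(
            small_truth.data, small_truth.topology, cfg=quick_mcmc,
            center_covariate=True,
        )
        b = pb.sample_posterior(
            small_truth.data, small_truth.topology, cfg=quick_mcmc,
            center_covariate=True,
        )
        assert a.parameter_names == b.parameter_names
        for name in a.parameter_names:
            assert (a.draws[name] == b.draws[name]).all()

    def test_kept_draw_shape_and_tau_positive(self, quick_mcmc, small_truth):
        fit = pb.sample_posterior(
            small_truth.data, small_truth.topology, cfg=quick_mcmc,
            center_covariate=True,
        )
        n_nodes = len(small_truth.topology.nodes)
        n_leaves = small_truth.topology.leaf_count
        assert len(fit.parameter_names) == n_leaves + 2 * n_nodes
        for name, arr in fit.draws.items():
            assert arr.shape == (quick_mcmc.n_chains, quick_mcmc.kept_per_chain)
            if name.startswith("tau["):
                assert (arr > 0).all()

    def test_prior_only_run_recovers_cascade_variance(self):
        """With no data and precisions held fixed, the leaf slope marginal
        is the sum of independent edge increments: var = depth / tau."""
        topo = pb.parse_newick("((A));")  # root -> internal -> leaf
        data = pb.OccurrenceData(
            np.zeros((0, 1), dtype=int),
            np.zeros(0),
            taxon_ids=["A"],
            require_occupancy=False,
        )
        cfg = pb.McmcConfig(
            n_chains=2, burn_in=200, kept_per_chain=4000, thin=1, seed=9
        )
        fit = pb.sample_posterior(data, topo, cfg=cfg, fix_tau=4.0)
        leaf_draws = fit.beta_node(3)
        n = leaf_draws.size
        expected_var = 3 / 4.0  # three edges at precision 4
        se = expected_var * math.sqrt(2 / (n - 1)) * 3  # mild autocorrelation slack
        assert leaf_draws.mean() == pytest.approx(0.0, abs=0.15)
        assert leaf_draws.var(ddof=1) == pytest.approx(expected_var, abs=5 * se)

    def test_persistence_roundtrip(self, quick_mcmc, small_truth, tmp_path):
        fit = pb.sample_posterior(
            small_truth.data, small_truth.topology, cfg=quick_mcmc,
            center_covariate=True,
        )
        path = tmp_path / "post.nc"
        fit.save(path)
        back = pb.PosteriorSamples.load(path)
        assert back.config == fit.config
        assert back.x_offset == fit.x_offset
        for name in fit.parameter_names:
            assert (back.draws[name] == fit.draws[name]).all()


class TestJointDistribution:
    def test_geweke_successive_vs_marginal_conditional(self):
        """Joint-distribution check on a 4-leaf tree: the chain that
        alternates parameter sweeps with data redraws must match the
        plain prior-then-data simulator in its parameter moments."""
        topo = pb.simulate_tree(4, seed=2)
        h = pb.HyperParams(alpha_precision=1.0, tau_shape=3.0, tau_rate=3.0)
        n = len(topo.nodes)
        n_sites = 8
        x = np.linspace(-1.5, 1.5, n_sites)
        leaf_ids = list(topo.leaf_ids)

        def draw_prior(rng):
            tau = np.empty(n + 1)
            tau[1:] = rng.gamma(h.tau_shape, 1 / h.tau_rate, size=n)
            beta = np.empty(n + 1)
            for i in topo.node_ids:
                p = topo.parent(i)
                mean = h.root_beta_mean if p == 0 else beta[p]
                beta[i] = rng.normal(mean, 1 / math.sqrt(tau[i]))
            alpha = rng.normal(0, 1, size=len(leaf_ids))
            return pb.ModelState(alpha, beta, tau)

        def draw_data(state, rng):
            p = pb.occurrence_probability(
                state.alpha[None, :], state.beta[leaf_ids][None, :], x[:, None]
            )
            occ = (rng.random(p.shape) < p).astype(int)
            return pb.OccurrenceData(
                occ, x, taxon_ids=[topo.label(i) for i in leaf_ids],
                require_occupancy=False,
            )

        def stats_of(state):
            return (
                state.beta[1],
                state.beta[leaf_ids[0]],
                float(state.alpha.mean()),
                state.tau[leaf_ids[0]],
            )

        rng = np.random.default_rng(12)
        n_marg, n_succ = 6000, 6000
        marg = np.array([stats_of(draw_prior(rng)) for _ in range(n_marg)])

        state = draw_prior(rng)
        succ = np.empty((n_succ, 4))
        for it in range(n_succ):
            data = draw_data(state, rng)
            for node in topo.node_ids:
                state.tau[node] = pb.update_tau(node, state, topo, h, rng)
            for node in topo.internal_ids:
                state.beta[node] = pb.update_internal_beta(node, state, topo, h, rng)
            for pos, leaf in enumerate(leaf_ids):
                a, b, _ = pb.update_leaf_params(
                    leaf, data, state, topo, h, rng, scales=(0.8, 0.8)
                )
                state.alpha[pos] = a
                state.beta[leaf] = b
            succ[it] = stats_of(state)

        # batch-means SE for the autocorrelated chain
        batches = succ[: n_succ - n_succ % 30].reshape(30, -1, 4).mean(axis=1)
        se_succ = batches.std(axis=0, ddof=1) / math.sqrt(len(batches))
        se_marg = marg.std(axis=0, ddof=1) / math.sqrt(n_marg)
        se = np.sqrt(se_succ**2 + se_marg**2)
        z = np.abs(succ.mean(axis=0) - marg.mean(axis=0)) / se
        assert (z < 4.0).all(), f"z-scores {z}"


class TestGelmanRubin:
    def _samples(self, arrs):
        draws = {"beta[1]": np.asarray(arrs, dtype=float)}
        cfg = pb.McmcConfig(
            n_chains=len(arrs), burn_in=1,
            kept_per_chain=len(arrs[0]), thin=1, seed=0,
        )
        topo = pb.parse_newick("(A,B);")
        return pb.PosteriorSamples(draws, cfg, topo, {})

    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=400)
        rhat = pb.gelman_rubin(self._samples([chain, chain, chain]))
        assert rhat["beta[1]"] == 1.0

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(1)
        rhat = pb.gelman_rubin(self._samples(rng.normal(size=(4, 1000))))
        assert rhat["beta[1]"] < 1.05

    def test_disjoint_chains_blow_up(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=500)
        b = rng.normal(10, 0.1, size=500)
        assert pb.gelman_rubin(self._samples([a, b]))["beta[1]"] > 5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            pb.gelman_rubin(self._samples([np.arange(10.0)]))

    def test_agrees_with_arviz_split_rhat(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        arrs = rng.normal(size=(4, 800)) + rng.normal(size=(4, 1))
        ours = pb.gelman_rubin(self._samples(arrs))["beta[1]"]
        theirs = float(arviz.rhat(arrs, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)
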