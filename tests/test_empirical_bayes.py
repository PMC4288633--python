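import warnings

import numpy as np
import pytest

from tempodose.empirical_bayes import (
    estimate_hyperparameters,
    update_gamma_prior,
    update_mixture,
)
from tempodose.pipeline import no_shrinkage_priors
from tempodose.spline_basis import build_basis, place_knots
from tempodose.synthetic_data import SimulationConfig, simulate_experiment


class TestUpdateMixture:
    def test_all_spike_gives_pi0_one(self):
        # slab evidence far below spike evidence for every gene
        ev = [(0.0, lambda t2: -1e3) for _ in range(10)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi0, tau2 = update_mixture(ev, (0.5, 1.0))
        assert pi0 > 0.999
        assert tau2 == 1.0  # kept at current value

    def test_mean_rule_for_inclusions(self):
        # one decisive slab gene, one decisive spike gene -> pi0 = 0.5
        ev = [(0.0, lambda t2: 1e3), (0.0, lambda t2: -1e3)]
        pi0, _ = update_mixture(ev, (0.5, 1.0))
        assert abs(pi0 - 0.5) < 1e-6

    def test_tau2_matches_dense_grid_search(self):
        """Closed-form slab evidence: optimizer vs brute 1-d grid."""
        rng = np.random.default_rng(0)
        mus = rng.normal(0, 1.2, 40)
        vls = np.full(40, 0.1)

        def make_fn(mu, vl):
            return lambda t2: -0.5 * (np.log(2 * np.pi * (t2 + vl)) + mu**2 / (t2 + vl))

        ev = [(-50.0, make_fn(m, v)) for m, v in zip(mus, vls)]
        _, tau2 = update_mixture(ev, (0.2, 1.0))
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e3), 4000))
        incl = np.ones(40)  # slab overwhelmingly favoured at these evidences
        obj = [sum(fn(t2) for _, fn in ev) for t2 in grid]
        tau2_grid = grid[int(np.argmax(obj))]
        assert abs(np.log(tau2) - np.log(tau2_grid)) < 1e-2


class TestUpdateGammaPrior:
    def test_moment_matching_arithmetic(self):
        # means 1 and 3: m=2, v=1 -> (shape, rate) = (4, 2)
        shape, rate = update_gamma_prior([(1.0, 0.1), (3.0, 0.1)])
        assert (shape, rate) == (4.0, 2.0)

    def test_near_constant_means_give_concentrated_prior(self):
        shape, rate = update_gamma_prior([(2.0, 0.0), (2.0, 0.0), (2.0, 0.0)])
        assert abs(shape / rate - 2.0) < 1e-6  # prior mean at the common value
        assert shape >= 100.0  # concentrated

    def test_single_gene_returns_current(self):
        assert update_gamma_prior([(1.0, 0.1)], current=(0.3, 0.7)) == (0.3, 0.7)

    def test_sampling_recovery_of_gamma_parameters(self, rng):
        """Precisions drawn from Gamma(3, 1.5): moment matching on the exact
        means recovers the parameters within 15%."""
        prec = rng.gamma(3.0, 1.0 / 1.5, size=2000)
        shape, rate = update_gamma_prior([(p, 0.0) for p in prec])
        assert abs(shape - 3.0) / 3.0 < 0.15
        assert abs(rate - 1.5) / 1.5 < 0.15


class TestEstimateHyperparameters:
    def test_single_iteration_returns_updated_init(self):
        cfg = SimulationConfig(n_genes=60, seed=3)
        exp, _ = simulate_experiment(cfg)
        basis = build_basis(exp.times, place_knots(exp.times, 2))
        init = no_shrinkage_priors()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = estimate_hyperparameters(exp, basis, init=init, max_iter=1, grid_size=5)
            s2 = estimate_hyperparameters(exp, basis, init=init, max_iter=1, grid_size=5)
        assert not s1.converged and s1.iteration == 1
        # deterministic: same inputs give identical updated hyperparameters
        assert s1.priors.shared() == s2.priors.shared()
        assert s1.priors.shared() != init.shared()

    def test_small_recovery_run(self):
        """200 genes, 10% true dosage effects: pi0-hat in a sane band and the
        EB objective improves over the first iterations."""
        cfg = SimulationConfig(n_genes=200, frac_cn_effect=0.1, beta_slab_sd=1.0, seed=9)
        exp, _ = simulate_experiment(cfg)
        basis = build_basis(exp.times, place_knots(exp.times, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = estimate_hyperparameters(exp, basis, init=no_shrinkage_priors(),
                                             max_iter=8, grid_size=5)
        assert 0.75 <= state.priors.beta_pi0 <= 0.97
        objs = [h["log_total_marglik"] for h in state.history]
        assert objs[-1] > objs[0]

    def test_null_data_concentrates_spike_and_flat_splines(self):
        cfg = SimulationConfig(n_genes=150, frac_cn_effect=0.0, frac_temporal=0.0,
                               seed=13)
        exp, _ = simulate_experiment(cfg)
        basis = build_basis(exp.times, place_knots(exp.times, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = estimate_hyperparameters(exp, basis, init=no_shrinkage_priors(),
                                             max_iter=8, grid_size=5)
        assert state.priors.beta_pi0 >= 0.95
        # spline-precision prior concentrated at high precision (flat splines)
        assert state.priors.gamma_prec_shape / state.priors.gamma_prec_rate > 10.0

    def test_pi0_decreases_with_signal_fraction(self):
        pi0s = []
        for frac in (0.05, 0.2, 0.5):
            cfg = SimulationConfig(n_genes=150, frac_cn_effect=frac,
                                   beta_slab_sd=1.0, seed=17)
            exp, _ = simulate_experiment(cfg)
            basis = build_basis(exp.times, place_knots(exp.times, 2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                state = estimate_hyperparameters(exp, basis, init=no_shrinkage_priors(),
                                                 max_iter=6, grid_size=5)
            pi0s.append(state.priors.beta_pi0)
        assert pi0s[0] > pi0s[1] > pi0s[2]

    def test_few_genes_warns(self):
        cfg = SimulationConfig(n_genes=20, seed=1)
        exp, _ = simulate_experiment(cfg)
        basis = build_basis(exp.times, place_knots(exp.times, 2))
        with pytest.warns(UserWarning, match="fewer than 50"):
            estimate_hyperparameters(exp, basis, init=no_shrinkage_priors(),
                                     max_iter=1, grid_size=3)
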