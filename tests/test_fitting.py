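"""Maximum-likelihood triad fitting: likelihood, gradients, recovery."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

import ensdist.fitting as F
from ensdist import (
    EdgeProcess,
    FittedTriadModel,
    discrete_gamma_rates,
    fit_general,
    fit_gtr,
    fit_gtr_gamma,
    jc_rate_matrix,
    log_likelihood,
    pattern_counts,
    sequential_fit,
)
from ensdist.simulate import random_general_model, simulate_alignment, stationary_triad_model
from ensdist.triad import pattern_labels

from conftest import random_reversible_matrix


def counts_from_patterns(**patterns):
    labels = pattern_labels()
    counts = np.zeros(64)
    for label, n in patterns.items():
        counts[labels.index(label)] = n
    return counts.reshape(4, 4, 4)


def zero_length_model(tree):
    Q = jc_rate_matrix()
    edges = {n: EdgeProcess(Q, 0.0) for n in tree.leaf_order}
    return FittedTriadModel(
        family=F.GTR,
        tree=tree,
        root_distribution=np.full(4, 0.25),
        edges=edges,
        dof=11,
    )


def brute_force_loglik(model, counts):
    """Explicit sum over root states (and rate bins) — the enumeration oracle."""
    order = model.tree.leaf_order
    rates, weights = model.rate_bin_weights()
    total = 0.0
    for idx, count in np.ndenumerate(counts):
        if count == 0:
            continue
        p = 0.0
        for rate, wt in zip(rates, weights):
            Ps = [model.edges[n].transition_matrix(rate) for n in order]
            for r in range(4):
                term = model.root_distribution[r]
                for P, x in zip(Ps, idx):
                    term *= P[r, x]
                p += wt * term
        total += count * np.log(p)
    return total


def random_model(seed, tree, gamma=False):
    rng = np.random.default_rng(seed)
    if gamma:
        return stationary_triad_model(
            random_reversible_matrix(rng),
            rng.uniform(0.05, 0.6, 3),
            tree,
            gamma_shape=rng.uniform(0.3, 5.0),
        )
    if seed % 2:
        return stationary_triad_model(random_reversible_matrix(rng), rng.uniform(0.05, 0.6, 3), tree)
    return random_general_model(seed, tree)


class TestLogLikelihood:
    def test_zero_length_edges_uniform_root(self, tree):
        counts = counts_from_patterns(AAA=1)
        assert log_likelihood(zero_length_model(tree), counts) == pytest.approx(np.log(0.25))

    def test_impossible_pattern_is_explicit_failure(self, tree):
        counts = counts_from_patterns(AAC=1)
        assert log_likelihood(zero_length_model(tree), counts) == -np.inf

    @pytest.mark.parametrize("gamma", [False, True], ids=["homogeneous", "gamma"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed, gamma, tree):
        model = random_model(seed, tree, gamma=gamma)
        rng = np.random.default_rng(1000 + seed)
        counts = rng.integers(0, 30, size=(4, 4, 4))
        assert log_likelihood(model, counts) == pytest.approx(
            brute_force_loglik(model, counts), abs=1e-8
        )


class TestAnalyticGradients:
    """The closed-form gradients drive the optimizer; check them hard."""

    @pytest.mark.parametrize("seed", range(3))
    def test_free_gradient_matches_finite_differences(self, seed, tree):
        true = random_general_model(seed, tree)
        aln = simulate_alignment(true, 3000, seed)
        counts = pattern_counts(aln, tree)
        support = counts > 0
        N = float(counts.sum())
        theta = F._general_encode(true) + 0.1
        _, grad = F._general_value_grad(theta, counts, support, N)
        numeric = approx_fprime(
            theta, lambda th: F._general_value_grad(th, counts, support, N)[0], 1e-7
        )
        assert np.abs(grad - numeric).max() < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_clock_gradient_matches_finite_differences(self, seed, tree):
        true = random_general_model(seed, tree, clock=True)
        aln = simulate_alignment(true, 3000, seed)
        counts = pattern_counts(aln, tree)
        support = counts > 0
        N = float(counts.sum())
        theta = F._general_encode(true) + 0.05
        _, grad = F._general_clock_value_grad(theta, counts, support, N)
        numeric = approx_fprime(
            theta, lambda th: F._general_clock_value_grad(th, counts, support, N)[0], 1e-7
        )
        assert np.abs(grad - numeric).max() < 1e-6


class TestFitGtr:
    def test_recovers_jc_edge_lengths(self, tree):
        truth = (0.2, 0.3, 0.5)
        true = stationary_triad_model(jc_rate_matrix(), truth, tree)
        aln = simulate_alignment(true, 100_000, 42)
        fit = fit_gtr(pattern_counts(aln, tree), tree)
        for leaf, t in zip(tree.leaf_order, truth):
            assert fit.edge_ens(leaf) == pytest.approx(t, rel=0.03)

    def test_clock_constraint_is_exact(self, tree):
        true = stationary_triad_model(jc_rate_matrix(), (0.2, 0.3, 0.5), tree)
        aln = simulate_alignment(true, 5000, 7)
        counts = pattern_counts(aln, tree)
        clock = fit_gtr(counts, tree, clock=True)
        ens_a, ens_b = clock.ingroup_ens()
        assert ens_a == ens_b  # shared parameter
        free = fit_gtr(counts, tree, init=clock)
        assert free.log_likelihood >= clock.log_likelihood

    def test_empty_counts_rejected(self, tree):
        with pytest.raises(F.FitError):
            fit_gtr(np.zeros((4, 4, 4)), tree)


@pytest.fixture(scope="module")
def gamma_data(tree):
    rng = np.random.default_rng(11)
    true = stationary_triad_model(
        random_reversible_matrix(rng), (0.25, 0.35, 0.5), tree, gamma_shape=0.5
    )
    aln = simulate_alignment(true, 100_000, 13)
    return true, pattern_counts(aln, tree)


class TestFitGtrGamma:
    def test_large_shape_limit_recovers_gtr(self, tree, gamma_data):
        # as shape -> infinity the rate mixture degenerates to rate 1
        _, counts = gamma_data
        gtr = fit_gtr(counts, tree)
        limit = fit_gtr_gamma(counts, tree, init=gtr, fixed_shape=1e6)
        assert abs(limit.log_likelihood - gtr.log_likelihood) < 0.1

    def test_recovers_shape_within_factor_two(self, tree, gamma_data):
        true, counts = gamma_data
        fit = fit_gtr_gamma(counts, tree, init=fit_gtr(counts, tree))
        assert 0.25 <= fit.gamma_shape <= 1.0

    def test_fitted_shape_beats_fixed_probes(self, tree, gamma_data):
        _, counts = gamma_data
        gtr = fit_gtr(counts, tree)
        fit = fit_gtr_gamma(counts, tree, init=gtr)
        for probe in [0.2, 1.0, 5.0]:
            fixed = fit_gtr_gamma(counts, tree, init=gtr, fixed_shape=probe)
            assert fit.log_likelihood >= fixed.log_likelihood - 1e-6

    def test_bin_rates_average_one(self):
        for shape in [0.1, 0.5, 2.0, 50.0]:
            rates = discrete_gamma_rates(shape)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(rates) > 0)


class TestFitGeneral:
    def test_gtr_data_nests_and_agrees(self, tree):
        rng = np.random.default_rng(3)
        true = stationary_triad_model(random_reversible_matrix(rng), (0.2, 0.3, 0.45), tree)
        aln = simulate_alignment(true, 100_000, 5)
        counts = pattern_counts(aln, tree)
        gtr = fit_gtr(counts, tree)
        general = fit_general(counts, tree, init=gtr)
        assert general.log_likelihood >= gtr.log_likelihood
        for leaf in tree.leaf_order:
            assert general.edge_ens(leaf) == pytest.approx(gtr.edge_ens(leaf), rel=0.02)

    def test_nonstationary_recovery(self, tree):
        true = random_general_model(17, tree, jsd_floor=0.02)
        aln = simulate_alignment(true, 50_000, 19)
        counts = pattern_counts(aln, tree)
        fit = fit_general(counts, tree, init=fit_gtr(counts, tree))
        for leaf in tree.leaf_order:
            assert fit.edge_ens(leaf) == pytest.approx(true.edge_ens(leaf), rel=0.10)
        assert np.abs(fit.root_distribution - true.root_distribution).max() < 0.03

    def test_clock_constraint_matches_ens(self, tree):
        true = random_general_model(23, tree)
        aln = simulate_alignment(true, 4000, 29)
        counts = pattern_counts(aln, tree)
        clock = fit_general(counts, tree, clock=True)
        ens_a, ens_b = clock.ingroup_ens()
        assert abs(ens_a - ens_b) < 1e-8
        free = fit_general(counts, tree, init=clock)
        assert free.log_likelihood >= clock.log_likelihood


class TestSequentialFit:
    def test_nested_chain_monotone(self, tree):
        true = random_general_model(31, tree)
        aln = simulate_alignment(true, 3000, 37)
        fits = sequential_fit(pattern_counts(aln, tree), tree)
        assert fits["General"].log_likelihood >= fits["GTR"].log_likelihood

    def test_clock_suite_returns_both_variants(self, tree):
        true = random_general_model(41, tree, clock=True)
        aln = simulate_alignment(true, 3000, 43)
        fits = sequential_fit(
            pattern_counts(aln, tree), tree, families=("GTR", "General"), clock_suite=True
        )
        for family in ("GTR", "General"):
            free, clk = fits[family], fits[f"{family}-clock"]
            assert free.log_likelihood >= clk.log_likelihood
            assert free.dof - clk.dof == 1

    def test_degrees_of_freedom(self, tree):
        true = random_general_model(47, tree)
        aln = simulate_alignment(true, 2000, 53)
        fits = sequential_fit(pattern_counts(aln, tree), tree, clock_suite=True)
        expected = {
            "GTR": 11,
            "GTR+Gamma": 12,
            "General": 39,
            "GTR-clock": 10,
            "GTR+Gamma-clock": 11,
            "General-clock": 38,
        }
        for name, dof in expected.items():
            assert fits[name].dof == dof
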