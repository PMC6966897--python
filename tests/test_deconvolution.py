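import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from chromofold import (DeconvolutionModel, compare_to_naive,
                        gibbs_deconvolve, log_likelihood, log_posterior,
                        log_prior)
from chromofold.dependency import DependencyDAG


def _model(contacts, f, edges=(), forbidden=(), **kw):
    dag = DependencyDAG(nodes=list(contacts),
                        edges=[(a, b, 0.1, 0.01) for a, b in edges],
                        forbidden=list(forbidden))
    return DeconvolutionModel(list(contacts), np.asarray(f, float), dag, **kw)


CONTACTS3 = [(0, 10), (3, 20), (8, 25)]


class TestLogPrior:
    def test_all_zero_state_scores_zero(self):
        m = _model(CONTACTS3, [0.3, 0.5, 0.7], n_cells=4)
        assert log_prior(np.zeros(3), m) == 0.0

    def test_forbidden_activation_is_minus_infinity(self):
        m = _model(CONTACTS3, [0.3, 0.5, 0.7],
                   forbidden=[[CONTACTS3[0], CONTACTS3[1]]], n_cells=4)
        assert log_prior(np.array([1, 1, 0]), m) == -math.inf
        assert np.isfinite(log_prior(np.array([1, 0, 1]), m))

    def test_parent_supported_contact_difference_in_closed_form(self):
        """Two states differing by one parent-supported contact differ by
        base log-odds + log boost - sparsity."""
        m = _model(CONTACTS3, [0.3, 0.5, 0.7],
                   edges=[(CONTACTS3[0], CONTACTS3[1])],
                   prior_boost=2.0, sparsity_weight=0.25, n_cells=4)
        with_child = log_prior(np.array([1, 1, 0]), m)
        without = log_prior(np.array([1, 0, 0]), m)
        expect = math.log(0.5 / 0.5) + math.log(2.0) - 0.25
        assert with_child - without == pytest.approx(expect)


class TestLogLikelihood:
    def test_single_contact_half_frequency_closed_form(self):
        m = _model([(0, 10)], [0.5], n_cells=2)
        states = np.array([[1], [0]])
        # Binom(k=1; n=2, f=0.5) = 0.5
        assert log_likelihood(states, m) == pytest.approx(math.log(0.5))

    def test_likelihood_peaks_at_matched_counts_and_falls_with_deviation(self):
        m = _model([(0, 10)], [0.3], n_cells=10)
        def ll(k):
            states = np.zeros((10, 1), int)
            states[:k] = 1
            return log_likelihood(states, m)
        values = [ll(k) for k in range(11)]
        assert np.argmax(values) == 3
        assert ll(3) > ll(5) > ll(7) > ll(9)  # unimodal decay


class TestGibbs:
    def test_single_site_marginal_matches_binomial_target(self):
        m = _model([(0, 10)], [0.6], n_cells=100, sparsity_weight=0.0,
                   prior_boost=1.0)
        res = gibbs_deconvolve(m, n_sweeps=400, burn_in=100, seed=3)
        k = res.states.sum()
        sigma = math.sqrt(100 * 0.6 * 0.4)
        assert abs(k - 60) < 3.5 * sigma

    def test_forbidden_pair_never_jointly_active(self):
        m = _model(CONTACTS3, [0.9, 0.9, 0.9],
                   forbidden=[[CONTACTS3[0], CONTACTS3[1]]],
                   n_cells=50, sparsity_weight=0.0)
        res = gibbs_deconvolve(m, n_sweeps=300, burn_in=50, seed=8,
                               record_history=True)
        assert not np.any((res.states[:, 0] == 1) & (res.states[:, 1] == 1))
        joint = (res.history[:, :, 0] == 1) & (res.history[:, :, 1] == 1)
        assert not joint.any()

    def test_empirical_distribution_matches_enumerated_posterior(self):
        """M=2, n_cells=2: the 16 joint states are enumerable; long-run
        Gibbs visit frequencies must match the exact normalized posterior
        (chi-square goodness of fit)."""
        contacts = [(0, 10), (5, 20)]
        f = np.array([0.4, 0.7])
        boost, sparsity = 1.5, 0.2
        m = _model(contacts, f, edges=[(contacts[0], contacts[1])],
                   prior_boost=boost, sparsity_weight=sparsity, n_cells=2)
        # independent enumeration of the unnormalized posterior
        def cell_prior(s):
            total = 0.0
            if s[0]:
                total += math.log(f[0] / (1 - f[0]))
            if s[1]:
                total += math.log(f[1] / (1 - f[1]))
                if s[0]:
                    total += math.log(boost)
            return total - sparsity * sum(s)
        def binom(k, n, p):
            return math.comb(n, k) * p ** k * (1 - p) ** (n - k)
        weights = {}
        for joint in itertools.product([0, 1], repeat=4):
            c1, c2 = joint[:2], joint[2:]
            k = np.array(c1) + np.array(c2)
            lp = cell_prior(c1) + cell_prior(c2)
            lp += math.log(binom(k[0], 2, f[0])) + math.log(binom(k[1], 2, f[1]))
            weights[joint] = math.exp(lp)
        z = sum(weights.values())
        exact = {s: w / z for s, w in weights.items()}

        res = gibbs_deconvolve(m, n_sweeps=50_000, burn_in=2000, seed=17,
                               record_history=True)
        counts = {s: 0 for s in exact}
        for sweep in res.history:
            counts[tuple(sweep.ravel())] += 1
        n = len(res.history)
        observed = np.array([counts[s] for s in exact])
        expected = np.array([exact[s] * n for s in exact])
        keep = expected > 5
        stat, p = chisquare(observed[keep],
                            expected[keep] * observed[keep].sum()
                            / expected[keep].sum())
        assert p > 0.01

    def test_marginals_track_targets_with_flat_prior(self):
        rng = np.random.default_rng(0)
        contacts = [(i, i + 12) for i in range(8)]
        f = rng.uniform(0.2, 0.8, 8)
        m = _model(contacts, f, n_cells=200, sparsity_weight=0.0,
                   prior_boost=1.0)
        res = gibbs_deconvolve(m, n_sweeps=1500, burn_in=500, seed=5)
        assert np.max(np.abs(res.marginals - f)) <= 0.05 + 3 * np.sqrt(
            f.max() * (1 - f.min()) / 200)


class TestCompareToNaive:
    def test_edgeless_flat_model_reduces_to_prior_terms(self):
        """With no DAG edges and zero sparsity the difference equals
        log-posterior minus the naive Bernoulli log-likelihood, computable
        in closed form for a fixed state matrix."""
        m = _model([(0, 10)], [0.5], n_cells=2, sparsity_weight=0.0,
                   prior_boost=1.0)
        states = np.array([[1], [0]])
        # prior: active cell contributes logit(0.5)=0; likelihood log 0.5;
        # naive: log(0.5) + log(0.5)
        expect = math.log(0.5) - 2 * math.log(0.5)
        assert compare_to_naive(states, m) == pytest.approx(expect)

    def test_planted_dependency_raises_posterior_over_naive(self):
        """States generated with strong pairwise dependence score higher
        under the DAG-aware model than under independent Bernoulli."""
        rng = np.random.default_rng(42)
        contacts = [(0, 15), (4, 11)]
        parent = rng.random(400) < 0.5
        child = np.where(parent, rng.random(400) < 0.9,
                         rng.random(400) < 0.1)
        states = np.stack([parent, child], axis=1).astype(int)
        f = states.mean(0)
        m = _model(contacts, f, edges=[(contacts[0], contacts[1])],
                   prior_boost=math.e ** 2, sparsity_weight=0.0, n_cells=400)
        assert compare_to_naive(states, m) > 0

    def test_dependency_bonus_requires_real_dependence(self):
        """The DAG-aware score advantage over the naive model is larger for
        genuinely dependent states than for independent states with the
        same marginals: the prior's bonus only pays off when parent and
        child truly co-occur."""
        rng = np.random.default_rng(7)
        contacts = [(0, 15), (4, 11)]

        def score(states):
            f = np.clip(states.mean(0), 0.05, 0.95)
            m = _model(contacts, f, edges=[(contacts[0], contacts[1])],
                       prior_boost=4.0, sparsity_weight=0.0, n_cells=200)
            return compare_to_naive(states, m)

        parent = rng.random(200) < 0.5
        child_dep = np.where(parent, rng.random(200) < 0.9,
                             rng.random(200) < 0.1)
        dep = np.stack([parent, child_dep], axis=1).astype(int)
        indep = (rng.random((200, 2)) < dep.mean(0)).astype(int)
        assert score(dep) > score(indep)
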