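import numpy as np
import pytest
from scipy.special import gammaln

from metamorph import TraitSimConfig, TreeSimConfig, simulate_discrete_traits, simulate_yule_tree
from metamorph.phylo import PagelModel, TreeTable, bayes_factor, mcmc_sample, summarize_rates
from metamorph.phylo.data import dichotomize_egg_size
from metamorph.phylo.marginal import stepping_stone, stepping_stone_pagel
from metamorph.phylo.mcmc import ChainConfig, PagelPosterior, run_chain

import pandas as pd


class ExpGammaToy:
    """Exponential data with a conjugate Gamma prior on the rate; the
    evidence has a closed form, making this the stepping-stone oracle."""

    def __init__(self, y, a=2.0, b=1.0):
        self.y = np.asarray(y, dtype=float)
        self.a, self.b, self.n = a, b, len(y)

    def init_params(self, rng):
        return np.array([rng.gamma(self.a, 1.0 / self.b)])

    def log_prior(self, p):
        lam = p[0]
        if lam <= 0:
            return -np.inf
        return (self.a * np.log(self.b) - gammaln(self.a)
                + (self.a - 1) * np.log(lam) - self.b * lam)

    def log_likelihood(self, p):
        lam = p[0]
        return self.n * np.log(lam) - lam * self.y.sum()

    def propose(self, p, rng, scale):
        f = np.exp(scale * (rng.random() - 0.5))
        return p * f, np.log(f)

    def exact_log_evidence(self):
        return (self.a * np.log(self.b) - gammaln(self.a)
                + gammaln(self.a + self.n)
                - (self.a + self.n) * np.log(self.b + self.y.sum()))


@pytest.fixture(scope="module")
def small_dataset():
    tree = simulate_yule_tree(TreeSimConfig(n_tips=60, seed=21,
                                            target_root_age=300.0))
    table = TreeTable.from_dendropy(tree)
    data = simulate_discrete_traits(tree, TraitSimConfig(
        model=PagelModel("dependent", (0.004,) * 8), seed=22,
        missing_D=0.0, missing_E=0.0))
    return table, data


class TestSampler:
    def test_seed_reproducibility(self, small_dataset):
        table, data = small_dataset
        cfg = ChainConfig(generations=2000, thin=10)
        r1 = mcmc_sample("dependent", table, data, config=cfg, seed=5)
        r2 = mcmc_sample("dependent", table, data, config=cfg, seed=5)
        assert np.array_equal(r1.samples, r2.samples)

    def test_prior_only_moments(self, small_dataset):
        """With the likelihood off (beta = 0) the chain recovers the
        hierarchical prior: rates | m ~ Exp(m), m ~ U(0, 100), so
        E[rate] = E[m] = 50 and E[rate | m] = m."""
        table, data = small_dataset
        post = PagelPosterior("independent", table, data)
        cfg = ChainConfig(generations=120_000, thin=40, proposal_scale=6.0)
        res = run_chain(post, cfg, seed=3, beta=0.0)
        m = res.samples[:, -1]
        rates = res.samples[:, :-1]
        n_eff_guess = len(m) / 20  # heavy autocorrelation allowance
        se = 100 / np.sqrt(12) / np.sqrt(n_eff_guess)
        assert abs(m.mean() - 50.0) < 4 * se
        # conditional mean: rate/m is Exp(1) -> mean 1
        ratio = rates / m[:, None]
        assert abs(ratio.mean() - 1.0) < 0.15

    def test_posterior_concentrates_with_signal(self, small_dataset):
        table, data = small_dataset
        cfg = ChainConfig(generations=6000, thin=10)
        res = mcmc_sample("dependent", table, data, config=cfg, seed=8)
        med = np.median(res.samples, axis=0)
        assert np.all(med > 1e-5) and np.all(med < 0.5)
        assert 0.05 < res.acceptance < 0.9


class TestSummaries:
    def test_single_sample_is_its_own_median(self):
        s = np.array([[0.1, 0.2, 0.3, 0.4]])
        out = summarize_rates(s, "independent")
        assert np.allclose(out["median"], s[0])

    def test_symmetric_two_point_sample_gives_midpoint(self):
        s = np.array([[0.1] * 8, [0.3] * 8])
        out = summarize_rates(s, "dependent")
        assert np.allclose(out["median"], 0.2)

    def test_table_layout_uses_conditional_labels(self):
        s = np.ones((5, 8)) * 0.01
        out = summarize_rates(s, "dependent")
        assert "P(D=0->1 | E=0)" in list(out["transition_rate"])


class TestDichotomization:
    def test_threshold_inclusive(self):
        v = pd.Series([1.0, 2.0, 3.0])
        out = dichotomize_egg_size(v)  # mean 2.0
        assert list(out) == [0, 1, 1]

    def test_value_at_threshold_is_large(self):
        out = dichotomize_egg_size(pd.Series([2.45, 1.0]), threshold=2.45)
        assert list(out) == [1, 0]

    def test_all_below_threshold(self):
        out = dichotomize_egg_size(pd.Series([0.1, 0.2]), threshold=5.0)
        assert list(out) == [0, 0]

    def test_missing_stays_missing(self):
        out = dichotomize_egg_size(pd.Series([np.nan, 3.0, 1.0]))
        assert out.iloc[0] == -1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_egg_size(pd.Series([np.nan, np.nan]))


class TestSteppingStone:
    def test_no_free_parameter_returns_the_log_likelihood(self):
        """A model whose prior is a point mass: the marginal likelihood is
        exactly the likelihood at that point."""
        class Fixed:
            def init_params(self, rng):
                return np.array([1.0])

            def log_prior(self, p):
                return 0.0  # degenerate: proposals never move (see propose)

            def log_likelihood(self, p):
                return -12.5

            def propose(self, p, rng, scale):
                return p.copy(), 0.0

        est = stepping_stone(Fixed(), stones=5,
                             config=ChainConfig(generations=500, thin=5), seed=1)
        assert est.log_marginal == pytest.approx(-12.5, abs=1e-12)

    def test_conjugate_toy_matches_closed_form(self):
        """Stepping stone within 0.1 nats of the analytic evidence at
        K = 30 stones."""
        rng = np.random.default_rng(17)
        toy = ExpGammaToy(rng.exponential(0.5, size=40))
        est = stepping_stone(toy, stones=30,
                             config=ChainConfig(generations=8000, thin=5),
                             seed=2)
        assert est.log_marginal == pytest.approx(toy.exact_log_evidence(),
                                                 abs=0.1)

    def test_stone_count_validated(self, small_dataset):
        table, data = small_dataset
        with pytest.raises(ValueError):
            stepping_stone_pagel("independent", table, data, stones=1)


class TestBayesFactor:
    @pytest.mark.parametrize("dep, indep, lbf, cat", [
        (-100.0, -110.0, 20.0, "very strong"),
        (-100.0, -100.0, 0.0, "none"),
        (-100.0, -101.5, 3.0, "support"),
    ])
    def test_arithmetic_and_categories(self, dep, indep, lbf, cat):
        got, category = bayes_factor(dep, indep)
        assert got == pytest.approx(lbf)
        assert category == cat

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(np.nan, -3.0)
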