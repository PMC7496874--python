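import dendropy
import numpy as np
import pytest

from metamorph import TraitSimConfig, TreeSimConfig, simulate_discrete_traits, simulate_yule_tree
from metamorph.phylo import (
    PagelModel,
    TreeTable,
    build_rate_matrix,
    log_likelihood,
    log_likelihood_single_trait,
    transition_probabilities,
)
from metamorph.phylo.data import MISSING, BinaryTraitMatrix

from oracles import enumeration_log_likelihood


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestTwoTipHandComputation:
    def test_matches_hand_calculation(self):
        """2-tip tree, branch lengths 3 and 5: likelihood assembled by hand
        from the transition matrices and the uniform root prior."""
        tree = _tree("(A:3,B:5);")
        model = PagelModel("dependent", (0.02, 0.03, 0.04, 0.05,
                                         0.06, 0.07, 0.08, 0.09))
        data = BinaryTraitMatrix.from_dicts({"A": 1, "B": 0}, {"A": 1, "B": 0})
        Q = build_rate_matrix(model)
        PA = transition_probabilities(Q, 3.0)
        PB = transition_probabilities(Q, 5.0)
        # tip states: A = (1,1) -> index 3, B = (0,0) -> index 0
        hand = 0.25 * sum(PA[s, 3] * PB[s, 0] for s in range(4))
        assert log_likelihood(tree, data, model) == pytest.approx(
            np.log(hand), abs=1e-12)


class TestEnumerationOracle:
    @pytest.mark.parametrize("n_tips", [3, 4, 5])
    def test_matches_brute_force_over_random_rates(self, n_tips):
        """Pruning equals summation over all internal-state assignments on
        small trees, across random rate draws, to 1e-10."""
        rng = np.random.default_rng(n_tips)
        tree = simulate_yule_tree(TreeSimConfig(n_tips=n_tips, seed=n_tips,
                                                target_root_age=80.0))
        data = simulate_discrete_traits(tree, TraitSimConfig(
            seed=n_tips + 1, missing_D=0.2, missing_E=0.3))
        for _ in range(10):
            model = PagelModel("dependent", tuple(rng.uniform(0.0, 0.05, 8)))
            assert log_likelihood(tree, data, model) == pytest.approx(
                enumeration_log_likelihood(tree, data, model), abs=1e-10)


class TestFactorization:
    def test_independent_model_factorizes(self):
        """With a factorizing root prior, the independent joint likelihood
        equals the product of the two single-trait likelihoods."""
        rng = np.random.default_rng(77)
        for rep in range(8):
            tree = simulate_yule_tree(TreeSimConfig(
                n_tips=int(rng.integers(5, 40)), seed=100 + rep,
                target_root_age=150.0))
            data = simulate_discrete_traits(tree, TraitSimConfig(
                seed=200 + rep, missing_D=0.15, missing_E=0.4))
            rates = tuple(rng.uniform(0.001, 0.02, 4))
            joint = log_likelihood(tree, data, PagelModel("independent", rates))
            D = {sp: data.states(sp)[0] for sp in data.species}
            E = {sp: data.states(sp)[1] for sp in data.species}
            split = (log_likelihood_single_trait(tree, D, rates[0], rates[1])
                     + log_likelihood_single_trait(tree, E, rates[2], rates[3]))
            assert joint == pytest.approx(split, abs=1e-10)


class TestInvariances:
    def test_tip_order_and_rotation_invariance(self):
        model = PagelModel("dependent", (0.01, 0.02, 0.03, 0.04,
                                         0.02, 0.01, 0.04, 0.03))
        data = BinaryTraitMatrix.from_dicts(
            {"A": 0, "B": 1, "C": 1, "D": MISSING},
            {"A": 1, "B": 0, "C": MISSING, "D": 0})
        t1 = _tree("((A:2,B:2):3,(C:4,D:4):1);")
        t2 = _tree("((D:4,C:4):1,(B:2,A:2):3);")
        assert log_likelihood(t1, data, model) == pytest.approx(
            log_likelihood(t2, data, model), abs=1e-12)

    def test_polytomy_equals_zero_length_resolution(self):
        model = PagelModel("dependent", (0.01,) * 8)
        data = BinaryTraitMatrix.from_dicts(
            {"A": 0, "B": 1, "C": 1}, {"A": 1, "B": 0, "C": 1})
        poly = _tree("(A:2,B:2,C:2);")
        resolved = _tree("((A:2,B:2):0,C:2);")
        assert log_likelihood(poly, data, model) == pytest.approx(
            log_likelihood(resolved, data, model), abs=1e-12)

    def test_fully_missing_tip_is_neutral(self):
        """A tip with both traits missing contributes no information: the
        likelihood equals the same tree with that tip's partials all-one."""
        model = PagelModel("dependent", (0.02,) * 8)
        with_missing = BinaryTraitMatrix.from_dicts(
            {"A": 0, "B": 1, "C": MISSING}, {"A": 1, "B": 0, "C": MISSING})
        tree = _tree("((A:2,B:2):3,C:5);")
        # marginalizing C by hand: sum over its states of P(c|root-side)
        # equals 1, so the 2-tip tree on (A,B) with the C edge pruned off
        # gives the same value
        two = _tree("(A:5,B:5);")
        # NB: not the same tree shape; instead compare against enumeration
        assert log_likelihood(tree, with_missing, model) == pytest.approx(
            enumeration_log_likelihood(tree, with_missing, model), abs=1e-10)

    def test_mismatched_labels_rejected(self):
        model = PagelModel("independent", (0.01,) * 4)
        data = BinaryTraitMatrix.from_dicts({"A": 0}, {"A": 1})
        with pytest.raises(ValueError):
            log_likelihood(_tree("(A:1,B:1);"), data, model)

    def test_stationary_root_prior_available(self):
        model = PagelModel("dependent", (0.01, 0.02, 0.03, 0.04,
                                         0.02, 0.01, 0.04, 0.03))
        data = BinaryTraitMatrix.from_dicts({"A": 0, "B": 1}, {"A": 1, "B": 0})
        tree = _tree("(A:3,B:5);")
        l_u = log_likelihood(tree, data, model, root_prior="uniform")
        l_s = log_likelihood(tree, data, model, root_prior="stationary")
        assert np.isfinite(l_s) and l_s != l_u
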