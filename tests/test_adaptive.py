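import numpy as np
import pytest

from metamorph import (
    TraitVector,
    find_singular,
    invasion_fitness,
    selection_gradient,
    solve_equilibrium,
)
from metamorph.adaptive import EcoEvoModel, _classification_label


class TestInvasionFitness:
    def test_resident_neutrality(self, fat, meta_traits, meta_equilibrium):
        s = invasion_fitness(meta_traits, meta_equilibrium, fat)
        assert abs(s) < 1e-8

    def test_resident_neutrality_random_strategies(self, fat):
        """|log R0| at a strategy's own equilibrium vanishes across random
        viable strategies (scaled-down sweep; the acceptance suite runs
        the full one)."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 12:
            tr = TraitVector(
                psi_L=float(rng.uniform(0, 0.3)),
                theta=float(rng.uniform(0.5, 1.0)),
                w_J=float(rng.uniform(0.015, 0.08)),
                w_b=float(rng.uniform(0.001, 0.009)),
            )
            try:
                eq = solve_equilibrium(tr, fat)
            except Exception:
                continue
            if not eq.viable:
                continue
            assert abs(invasion_fitness(tr, eq, fat)) < 1e-8
            checked += 1

    def test_nonviable_environment_rejected(self, fat, meta_traits):
        poor = fat.replace(X1_max=0.001, X2_max=0.001)
        eq = solve_equilibrium(meta_traits, poor)
        with pytest.raises(ValueError):
            invasion_fitness(meta_traits, eq, poor)

    def test_invalid_mutant_rejected(self, fat, meta_equilibrium):
        with pytest.raises(ValueError):
            invasion_fitness(TraitVector(0.0, 1.0, 0.02, 0.00009),
                             meta_equilibrium, fat)

    def test_selection_for_larger_offspring_at_low_primary_supply(self, fat):
        """Near the low-supply end of the metamorphosing branch, a mutant
        with larger offspring has positive invasion fitness."""
        p = fat.replace(X1_max=0.018)
        tr = TraitVector(0.0, 1.0, 0.0207, 0.0134)
        eq = solve_equilibrium(tr, p)
        up = invasion_fitness(tr.with_(w_b=tr.w_b * 1.05), eq, p)
        down = invasion_fitness(tr.with_(w_b=tr.w_b * 0.95), eq, p)
        assert up > 0 > down


class TestSelectionGradient:
    def test_vanishes_at_singular_strategy(self, fat):
        s = find_singular(TraitVector(0.0, 1.0, 0.025, 0.006), fat,
                          active=(False, True, True, True), classify=False)
        free = ~s.pinned & np.array([False, True, True, True])
        assert np.max(np.abs(s.gradient[free])) < 1e-6

    def test_central_difference_order(self, fat, meta_traits, meta_equilibrium):
        """Halving the step changes components at O(h^2)."""
        g1 = selection_gradient(meta_traits, fat, h=2e-3, env=meta_equilibrium)
        g2 = selection_gradient(meta_traits, fat, h=1e-3, env=meta_equilibrium)
        g3 = selection_gradient(meta_traits, fat, h=2e-4, env=meta_equilibrium)
        # the h=2e-3 error should be ~4x the h=1e-3 error
        err1 = np.abs(g1 - g3)
        err2 = np.abs(g2 - g3)
        assert np.all(err2 <= 0.5 * err1 + 1e-4)

    def test_gradient_sign_changes_across_toy_optimum(self, toy):
        """Symmetric two-food configuration: selection pushes psi toward
        0.5 from both sides."""
        lo = TraitVector(0.3, 0.0, 0.0002, 0.005)
        hi = TraitVector(0.7, 0.0, 0.0002, 0.005)
        g_lo = selection_gradient(lo, toy, active=(True, False, False, False))
        g_hi = selection_gradient(hi, toy, active=(True, False, False, False))
        assert g_lo[0] > 0 > g_hi[0]


class TestSingularStrategies:
    def test_symmetric_toy_singular_at_half(self, toy):
        """By the resource-exchange symmetry the singular specialization
        is exactly 1/2 (closed-form oracle)."""
        s = find_singular(TraitVector(0.35, 0.0, 0.0002, 0.005), toy,
                          active=(True, False, False, False), classify=False)
        assert s.traits.psi_L == pytest.approx(0.5, abs=1e-4)

    def test_restart_at_singular_stays(self, toy):
        s = find_singular(TraitVector(0.5, 0.0, 0.0002, 0.005), toy,
                          active=(True, False, False, False), classify=False)
        assert s.traits.psi_L == pytest.approx(0.5, abs=1e-4)

    def test_metamorphosing_css_structure(self, fat):
        """High-supply singular strategy: larvae fully specialized on the
        primary food (psi_L pinned at 0), thresholds ordered
        w_b < w_min < w_J < w_A."""
        s = find_singular(TraitVector(0.0, 1.0, 0.025, 0.006), fat,
                          active=(True, True, True, True), classify=False)
        tr = s.traits
        assert tr.psi_L == 0.0 and s.pinned[0]
        assert tr.w_b < fat.w_min < tr.w_J < fat.w_A
        g = selection_gradient(tr, fat, env=s.environment)
        assert g[0] < 0  # outward at the psi_L = 0 boundary

    def test_direct_development_boundary_css(self, fat):
        """The direct-development endpoint (psi_L=1, theta=0) is a boundary
        singular strategy with outward gradients at the default supplies."""
        s = find_singular(TraitVector(1.0, 0.0, 0.0102, 0.03), fat,
                          active=(True, True, False, True), classify=False)
        tr = s.traits
        assert tr.psi_L == 1.0 and tr.theta == 0.0
        assert tr.w_b > fat.w_min
        g = selection_gradient(tr, fat, env=s.environment)
        assert g[0] > 0      # outward at psi_L = 1
        assert g[1] < 0      # outward at theta = 0

    def test_classification_attached(self, fat):
        s = find_singular(TraitVector(0.0, 1.0, 0.025, 0.006), fat,
                          active=(False, True, True, True))
        assert s.classification in ("CSS", "boundary-CSS")
        assert np.max(s.hessian_eigs) < 0
        assert np.max(s.jacobian_eigs.real) < 0


class TestClassificationLogic:
    """The eigenvalue-combination rule against textbook 1-D cases."""

    @pytest.mark.parametrize(
        "hess, jac, expected",
        [
            (-1.0, -1.0, "CSS"),                      # uninvadable, converging
            (+1.0, -1.0, "branching"),                # invadable, converging
            (-1.0, +1.0, "repeller"),                 # uninvadable, diverging
            (+1.0, +1.0, "evolutionarily-unstable"),
        ],
    )
    def test_quadratic_fitness_cases(self, hess, jac, expected):
        label, indet = _classification_label(
            np.array([hess]), np.array([jac + 0j]), eig_tol=1e-4)
        assert label == expected and not indet

    def test_indeterminate_flagged_not_guessed(self):
        label, indet = _classification_label(
            np.array([1e-9]), np.array([-1.0 + 0j]), eig_tol=1e-4)
        assert indet and label == "indeterminate"

    def test_matches_analytic_second_derivatives(self):
        """1-D toy fitness s(y; x) = a*y^2 + b*x*y - (a+b)*x^2 has
        mutant curvature 2a at the singular point x*=0 and gradient slope
        d/dx [ds/dy|_{y=x}] = 2a + b; classification follows their signs."""
        for a, b in ((-1.0, 0.5), (1.0, -3.5), (-1.0, 3.0), (0.5, 0.1)):
            hess = 2 * a
            jac = 2 * a + b
            label, _ = _classification_label(
                np.array([hess]), np.array([jac + 0j]), eig_tol=1e-6)
            expected = {
                (True, True): "CSS",
                (False, True): "branching",
                (True, False): "repeller",
                (False, False): "evolutionarily-unstable",
            }[(hess < 0, jac < 0)]
            assert label == expected
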