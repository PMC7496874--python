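import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamorph import TraitVector, bioenergetics as be
from metamorph.bioenergetics import IndividualState, Stage
from metamorph.lifehistory import _scalar_rates, _vector_rates

from oracles import best_effort_split_intake


class TestAttackRate:
    def test_secondary_food_locked_below_threshold(self, fat):
        assert be.attack_rate(fat.w_min * 0.999, 0.7, 2, fat) == 0.0
        assert be.attack_rate(fat.w_min * 1.001, 0.7, 2, fat) > 0.0

    def test_full_specialist_has_no_primary_attack(self, fat):
        assert be.attack_rate(0.1, 1.0, 1, fat) == 0.0

    def test_invalid_resource_index(self, fat):
        with pytest.raises(ValueError):
            be.attack_rate(0.1, 0.5, 3, fat)

    def test_hump_peaks_at_configured_optimum(self, fat):
        """Grid-search maximizer of the primary attack equals w_opt1."""
        ws = np.geomspace(fat.w_opt1 / 50, fat.w_opt1 * 50, 4001)
        a = be.attack_rate(ws, 0.0, 1, fat)
        w_peak = ws[np.argmax(a)]
        assert w_peak == pytest.approx(fat.w_opt1, rel=0.01)
        # rises before the peak, falls after: a single interior maximum
        k = int(np.argmax(a))
        assert np.all(np.diff(a[:k]) > 0) and np.all(np.diff(a[k + 1:]) < 0)

    @given(w=st.floats(1e-4, 2.0), psi=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_specialization_monotonicity(self, fat, w, psi):
        assert be.attack_rate(w, 0.0, 1, fat) >= be.attack_rate(w, 1.0, 1, fat)
        assert be.attack_rate(w, 1.0, 2, fat) >= be.attack_rate(w, 0.0, 2, fat)
        assert be.attack_rate(w, psi, 1, fat) >= 0
        assert be.attack_rate(w, psi, 2, fat) >= 0


class TestDietAndIntake:
    def test_preference_all_primary_when_secondary_absent(self, fat):
        assert be.diet_preference(0.2, 0.5, 0.03, 0.0, fat) == 1.0
        # below the access threshold the secondary encounter rate is zero
        assert be.diet_preference(fat.w_min / 2, 0.5, 0.03, 0.5, fat) == 1.0

    def test_preference_fallback_when_nothing_encountered(self, fat):
        assert be.diet_preference(0.2, 0.5, 0.0, 0.0, fat) == 1.0

    def test_preference_half_at_equal_encounter_rates(self, fat):
        w, psi = 0.2, 0.5
        a1 = float(be.attack_rate(w, psi, 1, fat))
        a2 = float(be.attack_rate(w, psi, 2, fat))
        X2 = 0.05
        X1 = a2 * X2 / a1
        assert be.diet_preference(w, psi, X1, X2, fat) == pytest.approx(0.5)

    def test_preference_shares_sum_to_one(self, fat):
        phi1 = float(be.diet_preference(0.2, 0.5, 0.01, 0.08, fat))
        i1, i2 = be.intake_rates(0.2, 0.5, 0.01, 0.08, fat)
        assert 0.0 <= phi1 <= 1.0
        assert i1 / (i1 + i2) == pytest.approx(phi1)

    def test_zero_food_zero_intake(self, fat):
        assert be.intake_rates(0.2, 0.5, 0.0, 0.0, fat) == (0.0, 0.0)

    def test_saturation_limit(self, fat):
        """As X1 -> inf with X2 = 0 the intake approaches 1/H(w)."""
        w = 0.2
        i1, i2 = be.intake_rates(w, 0.0, 1e9, 0.0, fat)
        assert i2 == 0.0
        assert i1 == pytest.approx(1.0 / float(be.handling_time(w, fat)), rel=1e-4)

    def test_closed_form_evaluation(self, fat):
        w, psi, X1, X2 = 0.15, 0.4, 0.02, 0.09
        e1 = float(be.attack_rate(w, psi, 1, fat)) * X1
        e2 = float(be.attack_rate(w, psi, 2, fat)) * X2
        H = float(be.handling_time(w, fat))
        i1, i2 = be.intake_rates(w, psi, X1, X2, fat)
        assert i1 == pytest.approx(e1 / (1 + H * (e1 + e2)), rel=1e-12)
        assert i2 == pytest.approx(e2 / (1 + H * (e1 + e2)), rel=1e-12)

    @pytest.mark.parametrize("X1", [0.005, 0.02, 0.05])
    @pytest.mark.parametrize("X2", [0.01, 0.08, 0.16])
    def test_intake_dominates_any_effort_split(self, fat, X1, X2):
        """Optimal foraging: the realized total intake is at least the best
        achievable under any effort split between the two foods."""
        for w, psi in ((0.05, 0.3), (0.3, 0.8)):
            i1, i2 = be.intake_rates(w, psi, X1, X2, fat)
            assert i1 + i2 >= best_effort_split_intake(w, psi, X1, X2, fat) - 1e-12

    def test_intake_nondecreasing_in_density_and_bounded(self, fat):
        w, psi = 0.2, 0.5
        X2 = 0.05
        totals = [sum(be.intake_rates(w, psi, x1, X2, fat)) for x1 in np.linspace(0, 0.2, 30)]
        assert np.all(np.diff(totals) >= -1e-12)
        assert totals[-1] <= 1.0 / float(be.handling_time(w, fat))


class TestEnergetics:
    def test_net_production_boundary_and_sign(self, fat):
        w, psi = 0.2, 0.5
        # zero intake -> minus maintenance
        assert be.net_production(w, psi, 0.0, 0.0, fat) == pytest.approx(
            -float(be.maintenance(w, fat)))
        # doubling kappa_e doubles the assimilated term but not maintenance
        i1, i2 = be.intake_rates(w, psi, 0.02, 0.08, fat)
        e1 = float(be.net_production(w, psi, 0.02, 0.08, fat))
        e2 = float(be.net_production(w, psi, 0.02, 0.08, fat.replace(kappa_e=1.0)))
        assimilated = fat.kappa_e * fat.food_to_mass * (i1 + i2)
        assert e2 - e1 == pytest.approx(assimilated, rel=1e-10)

    def test_allocate_contracts(self, fat):
        larva = IndividualState(x=0.01, y=0.0074, stage=Stage.LARVA, psi=0.0)
        assert be.allocate(larva, 0.0, fat) == (0.0, 0.0, 0.0)
        # starvation: only reversible mass drains
        dx, dy, er = be.allocate(larva, -0.001, fat)
        assert (dx, er) == (0.0, 0.0) and dy == -0.001
        adult = IndividualState(x=0.3, y=0.22, stage=Stage.ADULT, psi=1.0)
        dx, dy, er = be.allocate(adult, 0.01, fat)
        assert er > 0 and dx >= 0 and dy >= 0
        assert dx + dy + er == pytest.approx(0.01)

    def test_fecundity_contracts(self, fat):
        meta = TraitVector(0.0, 0.8, 0.1, 0.002)
        assert be.fecundity_rate(0.0, meta, fat) == 0.0
        # metamorphosing offspring: the cost does not depend on theta
        assert be.offspring_cost(meta, fat) == be.offspring_cost(
            meta.with_(theta=0.1), fat)
        # direct development internalizes a theta-linear cost factor
        dd = TraitVector(0.5, 0.5, 0.01, 0.02)
        assert be.offspring_cost(dd, fat) > be.offspring_cost(
            dd.with_(theta=0.0), fat)
        # proportional part: without overhead, doubling w_b halves fecundity
        p0 = fat.replace(egg_overhead=0.0)
        f1 = be.fecundity_rate(0.01, meta, p0)
        f2 = be.fecundity_rate(0.01, meta.with_(w_b=0.004), p0)
        assert f1 == pytest.approx(2.0 * f2, rel=1e-12)

    def test_metamorphosis(self, fat):
        larva = IndividualState(x=0.013, y=0.0099, stage=Stage.LARVA, psi=0.0)
        tr = TraitVector(0.0, 0.0, larva.w, 0.002)
        new, surv = be.apply_metamorphosis(larva, tr, fat)
        assert surv == 1.0 and new.stage is Stage.JUVENILE
        assert new.w == pytest.approx(larva.w)  # theta = 0: no mass loss
        tr1 = tr.with_(theta=1.0)
        new1, surv1 = be.apply_metamorphosis(larva, tr1, fat)
        assert surv1 == pytest.approx(1.0 - fat.rho)
        assert new1.y == pytest.approx(larva.y * (1.0 - fat.meta_loss))
        assert new1.x == larva.x
        # composed specialization after the event
        assert new1.psi == tr1.psi_post

    @given(theta=st.floats(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_metamorphosis_survival_is_probability(self, fat, theta):
        s = be.metamorphosis_survival(theta, fat)
        assert 0.0 <= s <= 1.0

    def test_overcostly_metamorphosis_rejected(self, fat):
        # a mortality coefficient above 1 is an invalid configuration
        with pytest.raises(ValueError):
            fat.replace(rho=1.5)


def test_scalar_and_vector_rates_match_public_functions(fat):
    """The integrator's fused hot paths agree with the public API."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        w = float(rng.uniform(2e-4, 1.5 * fat.w_A))
        psi = float(rng.uniform(0, 1))
        X1 = float(rng.uniform(0, fat.X1_max))
        X2 = float(rng.uniform(0, fat.X2_max))
        i1_ref, i2_ref = be.intake_rates(w, psi, X1, X2, fat)
        e_ref = float(be.net_production(w, psi, X1, X2, fat))
        i1, i2, e = _scalar_rates(w, psi, X1, X2, fat)
        assert i1 == pytest.approx(float(i1_ref), abs=1e-14)
        assert i2 == pytest.approx(float(i2_ref), abs=1e-14)
        assert e == pytest.approx(e_ref, abs=1e-16)
        v1, v2, ve = _vector_rates(np.array([w]), psi, X1, X2, fat)
        assert v1[0] == pytest.approx(float(i1_ref), abs=1e-14)
        assert ve[0] == pytest.approx(e_ref, abs=1e-16)
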