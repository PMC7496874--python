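"""Individual-level bioenergetics: feeding, energetics, allocation,
reproduction and metamorphosis.

All functions accept scalar or numpy-array body masses so the same code
drives the deterministic life-history integrator and the individual-based
simulator.  Body mass w = x + y is the sum of irreversible mass x (bones,
organs) and reversible mass y (fat, gonads); feeding and maintenance depend
on w only, so the deterministic life history can be followed in total mass.

The attack rate on each food source is a hump-shaped function of body mass

    a_i(w) = s_i(psi) * A_i,max * (w / w_opt,i * exp(1 - w / w_opt,i))**alpha_i

whose height is scaled by the degree of specialization psi on the secondary
food source: s_1 = (1 - psi)**k, s_2 = psi**k (k = ``spec_exponent``,
default 1).  The secondary food is inaccessible below the mass threshold
w_min.  Both foods share a Holling type-II functional response with a
common handling time H(w) = xi1 * w**(-xi2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import BioenergeticParams
from .traits import TraitVector


class Stage(str, Enum):
    LARVA = "larva"
    JUVENILE = "juvenile"
    ADULT = "adult"


@dataclass
class IndividualState:
    """State of one consumer: masses, stage and expressed specialization."""

    x: float                  # irreversible mass (g)
    y: float                  # reversible mass (g)
    stage: Stage
    psi: float                # expressed specialization on the secondary food

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("irreversible mass x must be positive")
        if self.y < 0:
            raise ValueError("reversible mass y must be nonnegative")
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError("psi must lie in [0, 1]")

    @property
    def w(self) -> float:
        return self.x + self.y


def _hump(w, w_opt, alpha):
    z = w / w_opt
    return np.where(w > 0, (z * np.exp(1.0 - z)) ** alpha, 0.0)


def attack_rate(w, psi, resource: int, params: BioenergeticParams):
    """Clearance rate (L day^-1) on resource 1 or 2 at mass w, specialization psi.

    Zero on resource 2 below the access threshold w_min.
    """
    if resource == 1:
        scale = (1.0 - np.asarray(psi, dtype=float)) ** params.spec_exponent
        return scale * params.A1_max * _hump(w, params.w_opt1, params.alpha1)
    if resource == 2:
        scale = np.asarray(psi, dtype=float) ** params.spec_exponent
        base = scale * params.A2_max * _hump(w, params.w_opt2, params.alpha2)
        return np.where(np.asarray(w) >= params.w_min, base, 0.0)
    raise ValueError(f"resource must be 1 or 2, got {resource!r}")


def handling_time(w, params: BioenergeticParams):
    """Digestion/handling time per mg of food (day mg^-1), shared by both foods."""
    return params.xi1 * np.asarray(w, dtype=float) ** (-params.xi2)


def diet_preference(w, psi, X1, X2, params: BioenergeticParams):
    """Realized diet share phi1 of the primary food.

    With equal handling times for both foods the optimal diet never
    excludes either food, and the realized share simply follows the
    encounter rates: phi1 = a1*X1 / (a1*X1 + a2*X2).  When both encounter
    rates vanish the fallback is phi1 = 1.
    """
    e1 = attack_rate(w, psi, 1, params) * X1
    e2 = attack_rate(w, psi, 2, params) * X2
    tot = e1 + e2
    with np.errstate(invalid="ignore", divide="ignore"):
        phi1 = np.where(tot > 0, e1 / np.where(tot > 0, tot, 1.0), 1.0)
    return phi1


def intake_rates(w, psi, X1, X2, params: BioenergeticParams):
    """Multi-prey Holling type-II intake (mg day^-1) of each food source.

    I_i = a_i X_i / (1 + H(w) * (a_1 X_1 + a_2 X_2)), the standard disc
    equation with a handling time shared by both foods.  Total intake is
    bounded by 1/H(w) and dominates every effort-split alternative, so no
    partial preference could raise it (the optimal-foraging benchmark).
    """
    e1 = attack_rate(w, psi, 1, params) * X1
    e2 = attack_rate(w, psi, 2, params) * X2
    denom = 1.0 + handling_time(w, params) * (e1 + e2)
    return e1 / denom, e2 / denom


def maintenance(w, params: BioenergeticParams):
    """Maintenance costs (g day^-1), proportional to total body mass."""
    return params.maint_coef * np.asarray(w, dtype=float)


def net_production(w, psi, X1, X2, params: BioenergeticParams):
    """Net biomass production (g day^-1): assimilated intake minus maintenance.

    May be negative (starvation regime; the deficit drains reversible mass).
    """
    I1, I2 = intake_rates(w, psi, X1, X2, params)
    return params.kappa_e * params.food_to_mass * (I1 + I2) - maintenance(w, params)


def net_production_from_intake(state: IndividualState, I1, I2, params: BioenergeticParams):
    """Net production for an explicit individual state and given intakes."""
    return params.kappa_e * params.food_to_mass * (I1 + I2) - maintenance(state.w, params)


def allocate(state: IndividualState, E_net: float, params: BioenergeticParams):
    """Split net production into growth of x, growth of y, and reproduction.

    Positive net production of larvae and juveniles is split between
    irreversible and reversible mass so that y/x tracks the target ratio
    ``q_ratio`` (all surplus goes to y while the individual is below it).
    Adults keep a fraction ``kappa_adult`` for growth (default 0:
    determinate growth) and route the rest to reproduction.  Negative net
    production drains reversible mass only; x never shrinks.
    """
    if E_net < 0:
        return 0.0, float(E_net), 0.0
    if state.stage is Stage.ADULT:
        growth = params.kappa_adult * E_net
        E_repro = E_net - growth
    else:
        growth = E_net
        E_repro = 0.0
    q = params.q_ratio
    if state.y < q * state.x:
        dx, dy = 0.0, growth
    else:
        dx = growth / (1.0 + q)
        dy = growth * q / (1.0 + q)
    return dx, dy, E_repro


def offspring_cost(traits: TraitVector, params: BioenergeticParams) -> float:
    """Energetic cost (g) the mother pays per single offspring.

    A fixed overhead plus a term proportional to offspring mass encodes the
    size-number trade-off.  Under direct development (w_b >= w_J) the
    mother also internalizes the metamorphic mass loss of her offspring:
    the cost is multiplied by a factor linear in theta.
    """
    base = params.egg_overhead + params.egg_cost_per_gram * traits.w_b
    if traits.direct_development:
        frac_reversible = params.q_ratio / (1.0 + params.q_ratio)
        base *= 1.0 + params.meta_loss * traits.theta * frac_reversible
    return base


def fecundity_rate(E_repro: float, traits: TraitVector, params: BioenergeticParams) -> float:
    """Offspring production rate (day^-1) from the reproductive energy flux."""
    if E_repro < 0:
        raise ValueError("E_repro must be nonnegative")
    return E_repro / offspring_cost(traits, params)


def metamorphosis_survival(theta: float, params: BioenergeticParams) -> float:
    """Probability 1 - rho*theta of surviving metamorphosis."""
    s = 1.0 - params.rho * theta
    if s < 0:
        raise ValueError(f"rho*theta = {params.rho * theta} exceeds 1: invalid configuration")
    return s


def apply_metamorphosis(
    state: IndividualState, traits: TraitVector, params: BioenergeticParams
) -> tuple[IndividualState, float]:
    """Transform a larva at the metamorphosis threshold into a juvenile.

    Reversible mass shrinks by the configured loss fraction scaled by
    theta; the expressed specialization becomes min(1, psi_L + theta);
    survival is 1 - rho*theta.
    """
    if state.stage is not Stage.LARVA:
        raise ValueError("only larvae metamorphose")
    survival = metamorphosis_survival(traits.theta, params)
    new = IndividualState(
        x=state.x,
        y=state.y * (1.0 - params.meta_loss * traits.theta),
        stage=Stage.JUVENILE,
        psi=traits.psi_post,
    )
    return new, survival


def mass_after_metamorphosis(w_J: float, theta: float, params: BioenergeticParams) -> float:
    """Total mass directly after metamorphosis at threshold mass w_J.

    Assumes the larva is at the target condition y/x = q_ratio when it
    reaches w_J, so the reversible fraction is q/(1+q).
    """
    frac_reversible = params.q_ratio / (1.0 + params.q_ratio)
    return w_J * (1.0 - params.meta_loss * theta * frac_reversible)


def background_mortality(stage: Stage, params: BioenergeticParams) -> float:
    """Background per-day mortality; larvae also pay the larval-habitat addend."""
    if stage is Stage.LARVA:
        return params.mu_larva + params.mu_larval_habitat
    if stage is Stage.JUVENILE:
        return params.mu_juvenile
    return params.mu_adult
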