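"""Deterministic life-history integration at fixed resource densities.

Because feeding and maintenance depend only on total body mass w, the
deterministic life history can be followed in the mass domain: within a
life stage, growth is dw/da = g(w) with g the (stage-specific share of)
net biomass production, and age, survival, lifetime ingestion and
residence-time abundances are 1-D integrals over mass.  Metamorphosis is a
discrete event at w = w_J (survival factor 1 - rho*theta, reversible-mass
loss); maturation occurs at w = w_A.  Under direct development
(w_b >= w_J) there is no larval stage: the prenatal survival factor
1 - rho*theta applies at birth and the mother internalizes the metamorphic
cost in her per-offspring expenditure.

The central output is the expected lifetime offspring production R0 and
the lifetime per-capita ingestion of each food source (Gamma_1, Gamma_2),
which together define the resident equilibrium (R0 = 1, semichemostat
balance) in :mod:`metamorph.equilibrium`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _cheb
from . import bioenergetics as be
from .bioenergetics import Stage
from .params import BioenergeticParams
from .traits import TraitVector

#: survival below which remaining lifetime contributions are truncated
SURVIVAL_FLOOR = 1e-14

from math import exp as _exp  # noqa: E402  (scalar hot path below)


def _scalar_rates(w: float, psi: float, X1: float, X2: float, p: BioenergeticParams):
    """Scalar intake and net production; hot path of the integrator.

    Mirrors :func:`metamorph.bioenergetics.intake_rates` and
    :func:`metamorph.bioenergetics.net_production` without array overhead
    (the agreement is pinned by a unit test).
    """
    k = p.spec_exponent
    z1 = w / p.w_opt1
    a1 = (1.0 - psi) ** k * p.A1_max * (z1 * _exp(1.0 - z1)) ** p.alpha1
    if w >= p.w_min and psi > 0.0:
        z2 = w / p.w_opt2
        a2 = psi ** k * p.A2_max * (z2 * _exp(1.0 - z2)) ** p.alpha2
    else:
        a2 = 0.0
    e1 = a1 * X1
    e2 = a2 * X2
    den = 1.0 + p.xi1 * w ** (-p.xi2) * (e1 + e2)
    i1 = e1 / den
    i2 = e2 / den
    e_net = p.kappa_e * p.food_to_mass * (i1 + i2) - p.maint_coef * w
    return i1, i2, e_net


@dataclass
class Segment:
    """One smooth piece of the mass trajectory."""

    stage: Stage
    psi: float
    w0: float
    w1: float            # actual end mass (stall mass if stalled)
    age0: float
    age1: float
    surv0: float
    surv1: float
    abundance: float     # per-newborn residence integral of survival
    stalled: bool = False


@dataclass
class LifeHistory:
    """Summary of one deterministic life history at fixed (X1, X2)."""

    traits: TraitVector
    X1: float
    X2: float
    R0: float
    gamma1: float        # lifetime ingestion of food 1 per newborn (mg)
    gamma2: float        # lifetime ingestion of food 2 per newborn (mg)
    age_at_metamorphosis: float | None
    age_at_maturation: float | None
    survival_to_maturation: float
    segments: list[Segment] = field(default_factory=list)
    stalled: bool = False

    def abundance_between(self, lo: float, hi: float, stage: Stage | None = None) -> float:
        """Per-newborn expected residence abundance with mass in [lo, hi)."""
        tot = 0.0
        for s in self.segments:
            if stage is not None and s.stage is not stage:
                continue
            if s.w1 > s.w0:  # growing segment: clip mass window
                a, b = max(s.w0, lo), min(s.w1, hi)
                if b <= a:
                    continue
                if a == s.w0 and b == s.w1:
                    tot += s.abundance
                else:
                    tot += self._partial(s, a, b)
            else:  # stationary tail segment at mass w0
                if lo <= s.w0 < hi:
                    tot += s.abundance
        return tot

    def _partial(self, seg: Segment, a: float, b: float) -> float:
        raise NotImplementedError(
            "segments are split at all class boundaries; partial windows unused"
        )


def _growth(w, psi, stage, X1, X2, params):
    """Stage share of net production routed to total-mass growth."""
    _, _, e = _scalar_rates(w, psi, X1, X2, params)
    if stage is Stage.ADULT:
        return params.kappa_adult * e if e > 0 else e
    return e


def _vector_rates(w: np.ndarray, psi: float, X1: float, X2: float, p: BioenergeticParams):
    """Vectorized counterpart of :func:`_scalar_rates` for panel nodes."""
    k = p.spec_exponent
    z1 = w / p.w_opt1
    a1 = (1.0 - psi) ** k * p.A1_max * (z1 * np.exp(1.0 - z1)) ** p.alpha1
    if psi > 0.0:
        z2 = w / p.w_opt2
        a2 = np.where(
            w >= p.w_min, psi ** k * p.A2_max * (z2 * np.exp(1.0 - z2)) ** p.alpha2, 0.0
        )
    else:
        a2 = np.zeros_like(w)
    e1 = a1 * X1
    e2 = a2 * X2
    den = 1.0 + p.xi1 * w ** (-p.xi2) * (e1 + e2)
    i1 = e1 / den
    i2 = e2 / den
    e_net = p.kappa_e * p.food_to_mass * (i1 + i2) - p.maint_coef * w
    return i1, i2, e_net


#: spectral tolerance per quadrature panel and maximum bisection depth
_PANEL_TOL = 1e-12
_PANEL_DEPTH = 22


def _segment_integrate(stage, psi, w0, w1, age0, surv0, X1, X2, params, rtol, atol):
    """Integrate one smooth mass segment; returns (Segment, gamma1, gamma2).

    Survival within a stage is exp(-mu * age) with constant mu, so age,
    survival, lifetime ingestion and residence abundance are all smooth
    1-D mass integrals, evaluated by adaptive Clenshaw-Curtis panels.
    Growth stalls (g -> 0 inside the segment) cut the trajectory just
    before the stall mass; the caller appends a stationary tail there.
    """
    mu = be.background_mortality(stage, params)
    acc = {"age": age0, "surv": surv0, "g1": 0.0, "g2": 0.0, "n": 0.0, "w": w0}
    stalled = False

    def g_scalar(w):
        return _scalar_rates(w, psi, X1, X2, params)[2]

    # pending panels, processed strictly left to right so that survival
    # accumulates in order; a global budget bounds pathological refinement
    pending: list[tuple[float, float, int]] = [(w0, w1, 0)]
    budget = 3000
    stall_ahead = False  # a stall lies just past the last pending panel
    while pending:
        a, b, depth = pending.pop()
        budget -= 1
        w = 0.5 * (a + b) + 0.5 * (b - a) * _cheb.NODES
        i1, i2, g = _vector_rates(w, psi, X1, X2, params)
        if g[0] <= 0.0:
            stalled = True
            break
        if np.any(g <= 0.0):
            m = int(np.argmax(g <= 0.0))
            wc = brentq(g_scalar, w[m - 1], w[m], xtol=1e-15, rtol=1e-14)
            cut = wc - 1e-7 * max(wc - a, 1e-30)
            if cut > a:
                pending = [(a, cut, depth)]  # discard everything past the stall
                stall_ahead = True
                continue
            stalled = True
            break
        scale = 0.5 * (b - a)
        finv = 1.0 / g
        dage = scale * (_cheb.CUMINT @ finv)
        # clipping only affects panels that fail the spectral check below
        s_rel = np.exp(np.clip(-mu * dage, -745.0, 50.0))
        q1 = s_rel * i1 * finv
        q2 = s_rel * i2 * finv
        err = max(_cheb.coef_tail(finv), _cheb.coef_tail(q1), _cheb.coef_tail(q2))
        if err > _PANEL_TOL and depth < _PANEL_DEPTH and budget > 0:
            mid = 0.5 * (a + b)
            pending.append((mid, b, depth + 1))
            pending.append((a, mid, depth + 1))
            continue
        surv = acc["surv"]
        acc["g1"] += surv * scale * float(_cheb.CUMINT[-1] @ q1)
        acc["g2"] += surv * scale * float(_cheb.CUMINT[-1] @ q2)
        acc["n"] += surv * scale * float(_cheb.CUMINT[-1] @ (s_rel * finv))
        acc["age"] += float(dage[-1])
        acc["surv"] = surv * float(s_rel[-1])
        acc["w"] = b
        if acc["surv"] < SURVIVAL_FLOOR:
            stalled = True  # effectively dead before the stage boundary
            break

    stalled = stalled or stall_ahead
    seg = Segment(stage, psi, w0, acc["w"], age0, acc["age"], surv0, acc["surv"],
                  acc["n"], stalled=stalled)
    return seg, acc["g1"], acc["g2"]


def _stationary_tail(stage, psi, w, age, surv, X1, X2, params):
    """Contributions of an individual parked at mass w until death."""
    mu = be.background_mortality(stage, params)
    i1, i2, _ = _scalar_rates(w, psi, X1, X2, params)
    expected_time = surv / mu
    seg = Segment(stage, psi, w, w, age, np.inf, surv, 0.0, expected_time, stalled=True)
    return seg, float(i1 * expected_time), float(i2 * expected_time)


def _split_points(w0, w1, params):
    """Interior breakpoints (the w_min access threshold) of a mass interval."""
    pts = []
    if w0 < params.w_min < w1:
        pts.append(params.w_min)
    return pts


def integrate_life_history(
    traits: TraitVector,
    X1: float,
    X2: float,
    params: BioenergeticParams,
    *,
    rtol: float = 1e-11,
    atol: float = 1e-14,
) -> LifeHistory:
    """Expected life history of a newborn with the given strategy at fixed food.

    Returns R0, lifetime per-capita ingestion of both foods, stage timing
    and the per-newborn residence abundances used to reconstruct the
    equilibrium size distribution.
    """
    if X1 < 0 or X2 < 0:
        raise ValueError("resource densities must be nonnegative")
    if traits.w_b >= params.w_A:
        raise ValueError("body mass at birth must lie below the maturation mass")

    segments: list[Segment] = []
    gamma1 = gamma2 = 0.0
    age = 0.0
    age_meta: float | None = None

    if traits.direct_development:
        surv = be.metamorphosis_survival(traits.theta, params)
        stage, psi, w = Stage.JUVENILE, traits.psi_post, traits.w_b
        age_meta = 0.0
    else:
        surv = 1.0
        stage, psi, w = Stage.LARVA, traits.psi_L, traits.w_b
        if not traits.w_J < params.w_A:
            raise ValueError("w_J must lie below w_A for a metamorphosing strategy")

    stalled = False
    # --- pre-adult stages ---
    while stage is not Stage.ADULT and not stalled and surv > SURVIVAL_FLOOR:
        w_end = traits.w_J if stage is Stage.LARVA else params.w_A
        pieces = [w] + _split_points(w, w_end, params) + [w_end]
        for a_, b_ in zip(pieces[:-1], pieces[1:]):
            seg, g1, g2 = _segment_integrate(
                stage, psi, a_, b_, age, surv, X1, X2, params, rtol, atol
            )
            gamma1 += g1
            gamma2 += g2
            segments.append(seg)
            age, surv = seg.age1, seg.surv1
            if seg.stalled:
                stalled = True
                w = seg.w1
                break
        else:
            w = w_end
        if stalled:
            break
        if stage is Stage.LARVA:
            # metamorphosis event at w_J
            surv *= be.metamorphosis_survival(traits.theta, params)
            w = be.mass_after_metamorphosis(traits.w_J, traits.theta, params)
            psi = traits.psi_post
            stage = Stage.JUVENILE
            age_meta = age
            if w >= params.w_A:
                stage = Stage.ADULT
        else:
            stage = Stage.ADULT

    R0 = 0.0
    age_mat: float | None = None
    surv_mat = 0.0

    if stalled:
        if surv > SURVIVAL_FLOOR:
            seg, g1, g2 = _stationary_tail(stage, psi, w, age, surv, X1, X2, params)
            segments.append(seg)
            gamma1 += g1
            gamma2 += g2
    elif surv > SURVIVAL_FLOOR:
        # --- adult stage ---
        age_mat, surv_mat = age, surv
        mu_A = be.background_mortality(Stage.ADULT, params)
        cost = be.offspring_cost(traits, params)
        if params.kappa_adult == 0.0:
            i1, i2, e_net = _scalar_rates(w, psi, X1, X2, params)
            expected_time = surv / mu_A
            if e_net > 0:
                R0 = surv * (e_net / cost) / mu_A
            gamma1 += float(i1) * expected_time
            gamma2 += float(i2) * expected_time
            segments.append(
                Segment(Stage.ADULT, psi, w, w, age, np.inf, surv, 0.0, expected_time)
            )
        else:
            R0, g1, g2 = _adult_growth_integrate(
                traits, psi, w, age, surv, X1, X2, params, rtol, atol, segments
            )
            gamma1 += g1
            gamma2 += g2

    return LifeHistory(
        traits=traits,
        X1=X1,
        X2=X2,
        R0=float(R0),
        gamma1=float(gamma1),
        gamma2=float(gamma2),
        age_at_metamorphosis=age_meta,
        age_at_maturation=age_mat,
        survival_to_maturation=float(surv_mat),
        segments=segments,
        stalled=stalled,
    )


def _adult_growth_integrate(traits, psi, w_A, age, surv, X1, X2, params, rtol, atol, segments):
    """Indeterminate adult growth (kappa_adult > 0): mass-domain integration
    of reproduction until growth stalls, then a stationary reproductive tail."""
    mu = be.background_mortality(Stage.ADULT, params)
    cost = be.offspring_cost(traits, params)

    def e_of(w):
        return _scalar_rates(w, psi, X1, X2, params)[2]

    e0 = e_of(w_A)
    if e0 <= 0:
        seg, g1, g2 = _stationary_tail(Stage.ADULT, psi, w_A, age, surv, X1, X2, params)
        segments.append(seg)
        return 0.0, g1, g2

    # find the stall mass where net production vanishes
    w_hi = w_A
    while e_of(w_hi * 2) > 0:
        w_hi *= 2
        if w_hi > 1e6 * w_A:
            raise RuntimeError("adult growth does not stall; check maintenance scaling")
    w_stall = brentq(e_of, w_hi, w_hi * 2, xtol=1e-15, rtol=1e-14)

    def rhs(w, u):
        i1, i2, e = _scalar_rates(w, psi, X1, X2, params)
        g = params.kappa_adult * e
        s = _exp(u[1])
        inv = 1.0 / g
        fec = (1.0 - params.kappa_adult) * e / cost
        return (inv, -mu * inv, s * i1 * inv, s * i2 * inv, s * inv, s * fec * inv)

    w_end = w_stall * (1.0 - 1e-9)
    sol = solve_ivp(rhs, (w_A, w_end), [age, np.log(surv), 0.0, 0.0, 0.0, 0.0],
                    method="DOP853", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"adult integration failed: {sol.message}")
    age1, logs1, g1, g2, abundance, R0 = sol.y[:, -1]
    surv1 = float(np.exp(logs1))
    segments.append(
        Segment(Stage.ADULT, psi, w_A, w_end, age, float(age1), surv, surv1,
                float(abundance))
    )
    seg, t1, t2 = _stationary_tail(Stage.ADULT, psi, w_end, float(age1), surv1,
                                   X1, X2, params)
    segments.append(seg)
    # at the stall mass net production is ~0, so the stationary tail adds no R0
    return float(R0), float(g1) + t1, float(g2) + t2
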