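"""Resident-population equilibrium of the size-structured model.

A nontrivial equilibrium is a triple (X1*, X2*, b*) satisfying

    R0(X1*, X2*) = 1                       (lifetime reproduction balance)
    delta * (Xi,max - Xi*) = b* * Gamma_i  (semichemostat supply balance)

where b* is the population birth rate (newborns L^-1 day^-1) and Gamma_i
the lifetime per-capita ingestion of food i.  If even the consumer-free
resource densities cannot sustain the population (R0(X1,max, X2,max) < 1)
the trivial equilibrium (X1,max, X2,max, 0) is returned with the viability
flag unset.

The solver brackets the population birth rate b from the consumer-free
state upward; for each b the two resource balances are solved by a damped
fixed point polished with a quasi-Newton root, and the outer scalar
equation log R0 = 0 is closed with Brent's method.  A warm-started direct
3-D quasi-Newton path is tried first when a nearby solution is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .bioenergetics import Stage
from .lifehistory import LifeHistory, integrate_life_history
from .params import BioenergeticParams
from .traits import TraitVector


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium root finder fails to converge."""


@dataclass
class EquilibriumState:
    """Resident environment: resource densities, birth rate, stage structure."""

    X1: float
    X2: float
    b: float
    viable: bool
    life_history: LifeHistory | None = None

    @property
    def stage_abundances(self) -> dict[str, float]:
        """Number densities (individuals L^-1) per stage class.

        Larvae are split at the access threshold w_min into those that can
        (large) and cannot (small) use the secondary food source.
        """
        if not self.viable or self.life_history is None:
            return {"small_larvae": 0.0, "large_larvae": 0.0, "juveniles": 0.0, "adults": 0.0}
        lh = self.life_history
        w_min = self._w_min
        return {
            "small_larvae": self.b * lh.abundance_between(0.0, w_min, Stage.LARVA),
            "large_larvae": self.b * lh.abundance_between(w_min, np.inf, Stage.LARVA),
            "juveniles": self.b * lh.abundance_between(0.0, np.inf, Stage.JUVENILE),
            "adults": self.b * lh.abundance_between(0.0, np.inf, Stage.ADULT),
        }

    _w_min: float = 0.0

    @property
    def total_density(self) -> float:
        """Total consumer number density (individuals L^-1)."""
        return float(sum(self.stage_abundances.values()))


def _lh(traits, X1, X2, params, rtol):
    return integrate_life_history(traits, X1, X2, params, rtol=rtol)


def _resource_balance(traits, b, params, rtol, x_init):
    """Solve the two semichemostat balances at fixed birth rate b.

    Returns (X1, X2, LifeHistory) or None when no balance exists.
    """
    X1m, X2m = params.X1_max, params.X2_max

    def residual(xv):
        x1 = min(max(xv[0], 0.0), X1m)
        x2 = min(max(xv[1], 0.0), X2m)
        lh = _lh(traits, x1, x2, params, rtol)
        r1 = params.delta * (X1m - xv[0]) - b * lh.gamma1
        r2 = params.delta * (X2m - xv[1]) - b * lh.gamma2
        return [r1 / (params.delta * X1m), r2 / (params.delta * X2m)]

    sol = optimize.root(residual, np.asarray(x_init, dtype=float), method="hybr",
                        options={"xtol": 1e-13})
    xv = sol.x
    converged = np.max(np.abs(sol.fun)) < 1e-9  # scaled residuals
    if not converged or xv[0] < -1e-9 or xv[1] < -1e-9:
        return None
    x1, x2 = float(min(max(xv[0], 0.0), X1m)), float(min(max(xv[1], 0.0), X2m))
    lh = _lh(traits, x1, x2, params, rtol)
    return x1, x2, lh


def solve_equilibrium(
    traits: TraitVector,
    params: BioenergeticParams,
    *,
    rtol: float = 1e-11,
    warm: EquilibriumState | None = None,
) -> EquilibriumState:
    """Resident equilibrium for the given strategy.

    Returns the trivial consumer-free equilibrium (viable=False) when
    R0 at the maximum resource densities is below one.
    """
    X1m, X2m = params.X1_max, params.X2_max
    lh_free = _lh(traits, X1m, X2m, params, rtol)
    if lh_free.R0 <= 1.0:
        eq = EquilibriumState(X1=X1m, X2=X2m, b=0.0, viable=False, life_history=lh_free)
        eq._w_min = params.w_min
        return eq

    if warm is not None and warm.viable and warm.b > 0:
        eq = _solve_direct(traits, params, rtol, warm)
        if eq is not None:
            return eq

    # --- robust path: ramp the birth rate up from the consumer-free state ---
    # so the inner resource balance is always warm-started from a nearby
    # solution (the balance can be multivalued; continuation keeps us on
    # the branch connected to the consumer-free state).
    state = {"x": (X1m, X2m)}

    def h(b):
        res = _resource_balance(traits, b, params, rtol, state["x"])
        if res is None:
            return None
        x1, x2, lh = res
        state["x"] = (x1, x2)
        if lh.R0 <= 0:
            return -np.inf
        return float(np.log(lh.R0))

    # initial scale: a small fraction of full supply consumption per lifetime
    b_lo, x_lo = 0.0, (X1m, X2m)
    b_hi = 1e-3 * params.delta * X1m / max(lh_free.gamma1 + lh_free.gamma2, 1e-300)
    h_first = h(b_hi)
    if h_first is not None and h_first > 0:
        b_lo, x_lo = b_hi, state["x"]
        for _ in range(200):
            b_hi *= 2.0
            h_hi = h(b_hi)
            if h_hi is None or h_hi < 0:
                break  # bracketed (inner-solve loss counts as overexploitation)
            b_lo, x_lo = b_hi, state["x"]
        else:
            raise EquilibriumError("failed to bracket the equilibrium birth rate")
    else:
        # even the seed overshoots: ramp down until the population grows
        for _ in range(200):
            b_hi /= 4.0
            state["x"] = (X1m, X2m)
            h_lo = h(b_hi)
            if h_lo is not None and h_lo > 0:
                b_lo, x_lo = b_hi, state["x"]
                b_hi *= 4.0
                break
        else:
            raise EquilibriumError("failed to bracket the equilibrium birth rate")

    # bisect until the Newton polish has a reliable starting point
    # (robust to the inner solve failing on the upper side)
    for _ in range(60):
        if b_hi - b_lo <= 1e-3 * b_hi:
            break
        b_mid = 0.5 * (b_lo + b_hi)
        state["x"] = x_lo
        h_mid = h(b_mid)
        if h_mid is not None and h_mid > 0:
            b_lo, h_lo, x_lo = b_mid, h_mid, state["x"]
        else:
            b_hi = b_mid
    state["x"] = x_lo
    guess = EquilibriumState(X1=x_lo[0], X2=x_lo[1], b=b_lo, viable=True)
    eq = _solve_direct(traits, params, rtol, guess)
    if eq is None:
        raise EquilibriumError(
            f"equilibrium polish failed near b={b_lo:.6g}, X=({x_lo[0]:.6g}, {x_lo[1]:.6g})"
        )
    return eq


def _solve_direct(traits, params, rtol, warm):
    """Warm-started 3-D quasi-Newton on (X1, X2, log b); verified before use."""
    X1m, X2m = params.X1_max, params.X2_max
    cache = {}

    def residual(v):
        x1 = min(max(v[0], 1e-12), X1m)
        x2 = min(max(v[1], 1e-12), X2m)
        b = float(np.exp(np.clip(v[2], -700.0, 700.0)))
        lh = _lh(traits, x1, x2, params, rtol)
        cache["lh"] = lh
        r0 = lh.R0 if lh.R0 > 0 else 1e-300
        return [
            np.log(r0),
            (params.delta * (X1m - x1) - b * lh.gamma1) / (params.delta * X1m),
            (params.delta * (X2m - x2) - b * lh.gamma2) / (params.delta * X2m),
        ]

    if not warm.b > 0:
        return None
    v0 = [warm.X1, warm.X2, np.log(warm.b)]
    sol = optimize.root(residual, v0, method="hybr", options={"xtol": 1e-13})
    r = residual(sol.x)
    if max(abs(np.array(r))) > 1e-10:
        return None
    x1 = float(min(max(sol.x[0], 1e-12), X1m))
    x2 = float(min(max(sol.x[1], 1e-12), X2m))
    eq = EquilibriumState(
        X1=x1, X2=x2, b=float(np.exp(sol.x[2])), viable=True, life_history=cache["lh"]
    )
    eq._w_min = params.w_min
    return eq


def large_larvae_fraction(
    eq: EquilibriumState, traits: TraitVector, params: BioenergeticParams
) -> float:
    """Fraction of larvae with access to the secondary food source.

    Numerical abundance of larvae with w_min < w < w_J over all larvae.
    Defined as 1 for a direct-developing population (no larvae) and 0 when
    w_J <= w_min (no larva ever gains access).
    """
    if not eq.viable:
        raise ValueError("large_larvae_fraction requires a viable equilibrium")
    if traits.direct_development:
        return 1.0
    ab = eq.stage_abundances
    tot = ab["small_larvae"] + ab["large_larvae"]
    if tot <= 0.0:
        return 1.0
    return ab["large_larvae"] / tot
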