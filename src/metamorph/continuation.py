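"""Continuation of singular strategies in a model parameter, canonical-
equation trait trajectories, and the direct-development boundary scan.

The central experiment tracks the metamorphosing CSS while the supply
rate of the primary food source (delta * X1_max) decreases.  Three
terminal events matter:

``internalization``
    The body mass at birth reaches the body mass at metamorphosis
    (w_b -> w_J): metamorphosis happens before birth and the population
    continues as a direct developer.  This is how the CSS branch ends
    when the secondary food source is in high supply (in adaptive-
    dynamics terms, the CSS meets a repeller and metamorphosis
    disappears).
``extinction``
    The equilibrium birth rate collapses to zero before any
    internalization; the metamorphosing population is trapped and dies.
``fold``
    The Newton iteration loses its root while the resident population
    would still be viable and w_b is still well below w_J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive import (
    EcoEvoModel,
    SingularSearchError,
    SingularStrategy,
    _gradient_scaled,
    find_singular,
)
from .equilibrium import EquilibriumError, solve_equilibrium
from .params import BioenergeticParams
from .traits import TraitVector

#: birth rates below this (newborns per liter per day) count as extinct
B_EXTINCT = 1e-9


@dataclass
class ContinuationPoint:
    value: float
    strategy: SingularStrategy


@dataclass
class ContinuationCurve:
    parameter: str
    points: list[ContinuationPoint] = field(default_factory=list)
    terminal_event: str = "range-end"
    terminal_bracket: tuple[float, float] | None = None

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            t, env = p.strategy.traits, p.strategy.environment
            rows.append({
                self.parameter: p.value,
                "supply_rate_1": None,
                "psi_L": t.psi_L, "theta": t.theta, "w_J": t.w_J, "w_b": t.w_b,
                "X1": env.X1, "X2": env.X2, "b": env.b,
                "age_at_metamorphosis": env.life_history.age_at_metamorphosis
                if env.life_history else None,
                "classification": p.strategy.classification,
            })
        return pd.DataFrame(rows)


def continue_in_parameter(
    start: TraitVector | SingularStrategy,
    params: BioenergeticParams,
    parameter: str = "X1_max",
    *,
    stop: float,
    step: float | None = None,
    min_step: float | None = None,
    active: tuple[bool, bool, bool, bool] = (False, True, True, True),
    classify_points: bool = False,
    rtol: float = 1e-11,
    max_points: int = 200,
) -> ContinuationCurve:
    """Track a singular strategy while one parameter moves toward ``stop``.

    Steps adapt: a failed singular-strategy search halves the step; when
    the step underflows, the terminal event is classified and bracketed
    between the last converged and first failed parameter values.
    """
    v0 = getattr(params, parameter)
    direction = -1.0 if stop < v0 else 1.0
    span = abs(stop - v0)
    if step is None:
        step = span / 25.0
    if min_step is None:
        min_step = span * 1e-4

    curve = ContinuationCurve(parameter=parameter)
    if isinstance(start, SingularStrategy):
        sing = start
    else:
        sing = find_singular(start, params, active=active,
                             classify=classify_points, rtol=rtol)
    curve.points.append(ContinuationPoint(v0, sing))

    prev_u: np.ndarray | None = None
    v = v0
    h = step
    fail_hi: float | None = None  # closest failed value
    from .bioenergetics import mass_after_metamorphosis

    while len(curve.points) < max_points:
        # internalization: newborns at least as large as fresh metamorphs
        w_meta = mass_after_metamorphosis(sing.traits.w_J, sing.traits.theta, params)
        if sing.traits.w_b >= min(w_meta, 0.98 * sing.traits.w_J):
            curve.terminal_event = "internalization"
            if len(curve.points) >= 2:
                curve.terminal_bracket = _refine_internalization(
                    curve.points[-2], curve.points[-1], params, parameter,
                    active, rtol)
            else:
                curve.terminal_bracket = (v, fail_hi if fail_hi is not None else v)
            break
        v_next = v + direction * h
        if direction * (v_next - stop) > 0:
            v_next = stop
        p_next = params.replace(**{parameter: v_next})
        model = EcoEvoModel(p_next, active=active, rtol=rtol)
        u_last = model.to_scaled(sing.traits)
        guess = u_last if prev_u is None else np.clip(
            u_last + (u_last - prev_u), model.lower_full, model.upper_full
        )
        try:
            s_next = find_singular(
                model.to_traits(guess), p_next, active=active,
                classify=classify_points, rtol=rtol, warm=sing.environment,
            )
        except (SingularSearchError, EquilibriumError):
            fail_hi = v_next
            h *= 0.5
            if h < min_step:
                curve.terminal_event = _classify_terminal(sing, params, parameter,
                                                          v_next, rtol)
                curve.terminal_bracket = (v, v_next)
                break
            continue
        prev_u = u_last
        sing, v = s_next, v_next
        curve.points.append(ContinuationPoint(v, sing))
        h = min(h * 1.6, step)
        if v == stop:
            curve.terminal_event = "range-end"
            curve.terminal_bracket = (v, v)
            break
    return curve


def _refine_internalization(pt_before, pt_at, params, parameter, active, rtol,
                            n_bisect=7):
    """Bisect the parameter value where w_b first reaches the
    post-metamorphic mass along the branch."""
    from .bioenergetics import mass_after_metamorphosis

    def internalized(s):
        wm = mass_after_metamorphosis(s.traits.w_J, s.traits.theta, params)
        return s.traits.w_b >= min(wm, 0.98 * s.traits.w_J)

    v_lo, v_hi = pt_at.value, pt_before.value  # lo: internalized side
    sing = pt_before.strategy
    for _ in range(n_bisect):
        v_mid = 0.5 * (v_lo + v_hi)
        p_mid = params.replace(**{parameter: v_mid})
        try:
            s_mid = find_singular(sing.traits, p_mid, active=active,
                                  classify=False, rtol=rtol,
                                  warm=sing.environment)
        except (SingularSearchError, EquilibriumError):
            v_lo = v_mid  # treat failures as past the transition
            continue
        if internalized(s_mid):
            v_lo = v_mid
        else:
            v_hi, sing = v_mid, s_mid
    return (v_lo, v_hi)


def _classify_terminal(sing, params, parameter, v_fail, rtol) -> str:
    """Distinguish extinction from a fold at a continuation failure."""
    p_fail = params.replace(**{parameter: v_fail})
    try:
        eq = solve_equilibrium(sing.traits, p_fail, rtol=rtol, warm=sing.environment)
    except EquilibriumError:
        return "extinction"
    if not eq.viable or eq.b < B_EXTINCT:
        return "extinction"
    if sing.environment.b < 10 * B_EXTINCT:
        return "extinction"
    return "fold"


@dataclass
class CanonicalTrajectory:
    """Trait trajectory of the canonical equation (scaled evolutionary time)."""

    times: np.ndarray
    traits: list[TraitVector]
    population: np.ndarray
    truncated: bool = False          # extinction during the trajectory
    internalization_time: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, tr, n in zip(self.times, self.traits, self.population):
            rows.append({"time": t, "psi_L": tr.psi_L, "theta": tr.theta,
                         "w_J": tr.w_J, "w_b": tr.w_b, "population": n})
        return pd.DataFrame(rows)


def integrate_canonical(
    initial: TraitVector,
    params: BioenergeticParams,
    *,
    rate: float = 1.0,
    horizon: float = 100.0,
    active: tuple[bool, bool, bool, bool] = (True, True, True, True),
    max_trait_step: float = 0.01,
    h: float = 3e-4,
    rtol: float = 1e-11,
    record_every: int = 1,
) -> CanonicalTrajectory:
    """Integrate d(traits)/dt = rate * N* * gradient (identity covariance).

    The mutational covariance is the identity in the scaled trait space,
    so all traits evolve independently at speeds set by the selection
    gradient; the prefactor (mutation rate x variance / 2) is folded into
    ``rate`` and time is reported in scaled evolutionary units.  Traits
    are clipped at their boxes; the trajectory is truncated (flagged) if
    the population goes extinct.
    """
    model = EcoEvoModel(params, active=active, rtol=rtol)
    u = model.clip(model.to_scaled(initial))
    times, traits, pops = [0.0], [model.to_traits(u)], []
    t = 0.0
    env = model.equilibrium(model.to_traits(u))
    if not env.viable:
        raise ValueError("initial strategy is not viable")
    pops.append(env.total_density)
    truncated = False
    internal_t = None
    step_count = 0
    step_cap = max_trait_step
    grad_prev = None
    while t < horizon:
        grad = np.nan_to_num(_gradient_scaled(model, u, env, h))
        speed = rate * env.total_density * grad
        # the post-metamorphic specialization cap min(1, psi_L + theta) is a
        # non-smooth ridge: when it binds, the joint direction
        # (+psi_L, -theta) keeps feeding unchanged while shedding the theta
        # costs; follow the Filippov sliding motion along the cap
        if (model.active[0] and model.active[1]
                and u[0] + u[1] >= 1.0 and u[1] > 0.0 and u[0] < 1.0):
            v = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2.0)
            hp = min(h, 1.0 - u[0], u[1])
            if hp > 0:
                f0 = model.fitness(model.to_traits(u), env)
                f1 = model.fitness(model.to_traits(model.clip(u + hp * v)), env)
                g_v = (f1 - f0) / hp
                if g_v > 0:
                    speed = speed + rate * env.total_density * g_v * v
        smax = np.max(np.abs(speed))
        if smax == 0.0:
            break
        # damp the step while the gradient direction keeps reversing
        if grad_prev is not None:
            if float(np.dot(speed, grad_prev)) < 0.0:
                step_cap = max(step_cap * 0.5, 1e-4 * max_trait_step)
            else:
                step_cap = min(step_cap * 1.2, max_trait_step)
        grad_prev = speed.copy()
        dt = min(step_cap / smax, horizon - t)
        u_new = model.clip(u + dt * speed)
        tr_new = model.to_traits(u_new)
        try:
            env_new = model.equilibrium(tr_new, warm=env)
        except EquilibriumError:
            truncated = True
            break
        if not env_new.viable:
            truncated = True
            break
        if internal_t is None and tr_new.w_b >= tr_new.w_J:
            internal_t = t + dt
        u, env, t = u_new, env_new, t + dt
        step_count += 1
        if step_count % record_every == 0:
            times.append(t)
            traits.append(tr_new)
            pops.append(env.total_density)
        if np.max(np.abs(grad[model.active])) < 1e-6:
            break
    if len(pops) == len(times) + 1:
        pops = pops[:-1]
    return CanonicalTrajectory(
        times=np.array(times), traits=traits, population=np.array(pops),
        truncated=truncated, internalization_time=internal_t,
    )


def direct_development_boundary(
    params: BioenergeticParams,
    w_min_grid,
    x2_supply_grid,
    *,
    x1_supply_start: float = 0.005,
    x1_supply_stop: float = 0.0002,
    start_traits: TraitVector | None = None,
    active: tuple[bool, bool, bool, bool] = (False, True, True, True),
    rtol: float = 1e-11,
    coarse: bool = True,
) -> pd.DataFrame:
    """Outcome of habitat deterioration per (w_min, secondary supply) cell.

    For each grid cell the metamorphosing singular strategy is continued
    toward vanishing primary supply; the cell is classified by the
    terminal event: ``direct_development`` (internalization, or a fold
    with a viable direct-development strategy) or ``extinction``.
    Individual cell failures are recorded as ``failed``, not fatal.
    """
    rows = []
    for wmin in w_min_grid:
        for s2 in x2_supply_grid:
            p = params.replace(w_min=wmin, X2_max=s2 / params.delta,
                               X1_max=x1_supply_start / params.delta)
            tr0 = start_traits or TraitVector(0.0, 1.0, max(5 * wmin, 0.02), 0.003)
            # a population that is not even viable at the starting supply
            # goes extinct trivially under any further deterioration
            viable_start = False
            for cand in (tr0, tr0.with_(theta=0.7), tr0.with_(theta=0.5)):
                try:
                    if solve_equilibrium(cand, p, rtol=rtol).viable:
                        viable_start, tr0 = True, cand
                        break
                except EquilibriumError:
                    continue
            if not viable_start:
                rows.append({"w_min": wmin, "supply_rate_2": s2,
                             "outcome": "extinction",
                             "terminal_supply_rate_1_low": x1_supply_start,
                             "terminal_supply_rate_1_high": x1_supply_start})
                continue
            try:
                curve = continue_in_parameter(
                    tr0, p, "X1_max", stop=x1_supply_stop / params.delta,
                    active=active, rtol=rtol,
                    step=None if not coarse else None,
                    min_step=1e-3 * (x1_supply_start - x1_supply_stop) / params.delta,
                )
                ev = curve.terminal_event
                if ev == "fold":
                    outcome = ("direct_development"
                               if _dd_viable(p, curve, rtol) else "extinction")
                elif ev == "internalization":
                    outcome = "direct_development"
                elif ev == "extinction":
                    outcome = "extinction"
                else:
                    outcome = ev
                lo, hi = curve.terminal_bracket or (np.nan, np.nan)
                rows.append({"w_min": wmin, "supply_rate_2": s2, "outcome": outcome,
                             "terminal_supply_rate_1_low": params.delta * min(lo, hi),
                             "terminal_supply_rate_1_high": params.delta * max(lo, hi)})
            except (SingularSearchError, EquilibriumError) as err:
                rows.append({"w_min": wmin, "supply_rate_2": s2, "outcome": "failed",
                             "terminal_supply_rate_1_low": np.nan,
                             "terminal_supply_rate_1_high": np.nan,
                             "error": str(err)[:100]})
    return pd.DataFrame(rows)


def _dd_viable(params, curve, rtol) -> bool:
    """Is a direct-development strategy viable at the terminal parameter?"""
    lo, hi = curve.terminal_bracket
    p = params.replace(X1_max=min(lo, hi))
    wb = max(2.0 * params.w_min, 0.02 * params.w_A)
    tr = TraitVector(1.0, 0.0, wb * 0.5, wb)
    try:
        eq = solve_equilibrium(tr, p, rtol=rtol)
    except EquilibriumError:
        return False
    return eq.viable
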