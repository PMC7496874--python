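"""Adaptive dynamics on the size-structured consumer-resource model.

Invasion fitness of a rare mutant is the log of its lifetime reproduction
R0 in the resident's equilibrium environment (sign-equivalent to the
instantaneous invasion exponent at an ecological equilibrium, and far
cheaper).  Selection gradients are central finite differences in a scaled
trait space where all four traits are O(1): (psi_L, theta, w_J/w_A,
w_b/w_A).  Singular strategies are located by a damped finite-difference
Newton iteration with projection onto the trait boxes; traits that pin to
a box edge with an outward-pointing gradient are treated as boundary
components (the direct-development endpoint psi_L = 1, theta = 0 is such
a boundary singular strategy).

Classification combines evolutionary stability (definiteness of the
mutant-fitness Hessian at fixed environment) with convergence stability
(eigenvalues of the Jacobian of the selection gradient under an identity
mutational covariance):

    convergence-stable & uninvadable  -> CSS
    convergence-stable & invadable    -> branching
    convergence-unstable & uninvadable-> repeller
    convergence-unstable & invadable  -> evolutionarily-unstable
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .equilibrium import EquilibriumError, EquilibriumState, solve_equilibrium
from .lifehistory import integrate_life_history
from .params import BioenergeticParams
from .traits import MASS_FLOOR, TraitVector

TRAIT_NAMES = ("psi_L", "theta", "w_J", "w_b")


class SingularSearchError(RuntimeError):
    """Raised when the singular-strategy Newton iteration fails."""


def invasion_fitness(
    mutant: TraitVector,
    resident_env: EquilibriumState,
    params: BioenergeticParams,
    *,
    rtol: float = 1e-11,
) -> float:
    """log R0 of a rare mutant in the resident's equilibrium environment."""
    if not resident_env.viable:
        raise ValueError("invasion fitness requires a viable resident environment")
    lh = integrate_life_history(mutant, resident_env.X1, resident_env.X2, params, rtol=rtol)
    if lh.R0 <= 0.0:
        return -np.inf
    return float(np.log(lh.R0))


class EcoEvoModel:
    """Binds parameters, trait scaling, boxes and frozen traits.

    ``active`` masks which of (psi_L, theta, w_J, w_b) evolve; frozen
    traits keep the values of the reference strategy.  All adaptive-
    dynamics operations work in the scaled coordinates of the active
    subset.
    """

    def __init__(
        self,
        params: BioenergeticParams,
        *,
        active: tuple[bool, bool, bool, bool] = (True, True, True, True),
        rtol: float = 1e-11,
    ) -> None:
        self.params = params
        self.active = np.asarray(active, dtype=bool)
        self.rtol = rtol
        self.mass_scale = params.w_A
        lo_mass = MASS_FLOOR * 1.01 / self.mass_scale
        self.lower_full = np.array([0.0, 0.0, lo_mass, lo_mass])
        self.upper_full = np.array([1.0, 1.0, 0.99, 0.99])

    # --- coordinate maps -------------------------------------------------
    def to_scaled(self, traits: TraitVector) -> np.ndarray:
        v = traits.as_array()
        v[2] /= self.mass_scale
        v[3] /= self.mass_scale
        return v

    def to_traits(self, u_full: np.ndarray) -> TraitVector:
        v = np.array(u_full, dtype=float)
        v[2] *= self.mass_scale
        v[3] *= self.mass_scale
        return TraitVector.from_array(v)

    def embed(self, u_active: np.ndarray, reference: np.ndarray) -> np.ndarray:
        full = reference.copy()
        full[self.active] = u_active
        return full

    # --- model interface -------------------------------------------------
    def equilibrium(self, traits: TraitVector, warm=None) -> EquilibriumState:
        return solve_equilibrium(traits, self.params, rtol=self.rtol, warm=warm)

    def fitness(self, mutant: TraitVector, env: EquilibriumState) -> float:
        return invasion_fitness(mutant, env, self.params, rtol=self.rtol)

    def clip(self, u_full: np.ndarray) -> np.ndarray:
        return np.clip(u_full, self.lower_full, self.upper_full)


def _gradient_scaled(
    model: EcoEvoModel,
    u_full: np.ndarray,
    env: EquilibriumState,
    h: float,
) -> np.ndarray:
    """Central-difference gradient of mutant fitness at the resident.

    One-sided at trait-box edges.  Components of frozen traits are NaN.
    """
    n = 4
    grad = np.full(n, np.nan)
    for i in range(n):
        if not model.active[i]:
            continue
        lo, hi = model.lower_full[i], model.upper_full[i]
        x = u_full[i]
        hp = min(h, hi - x)
        hm = min(h, x - lo)
        if hp <= 0 and hm <= 0:
            grad[i] = 0.0
            continue
        up, um = u_full.copy(), u_full.copy()
        up[i] = x + hp
        um[i] = x - hm
        fp = model.fitness(model.to_traits(up), env)
        fm = model.fitness(model.to_traits(um), env)
        grad[i] = (fp - fm) / (hp + hm)
    return grad


def selection_gradient(
    resident: TraitVector,
    params: BioenergeticParams,
    *,
    h: float = 3e-4,
    active: tuple[bool, bool, bool, bool] = (True, True, True, True),
    env: EquilibriumState | None = None,
    rtol: float = 1e-11,
) -> np.ndarray:
    """Selection gradient (d fitness / d scaled trait) at the resident.

    Scaled traits are (psi_L, theta, w_J/w_A, w_b/w_A); frozen components
    are returned as NaN.
    """
    model = EcoEvoModel(params, active=active, rtol=rtol)
    if env is None:
        env = model.equilibrium(resident)
    if not env.viable:
        raise ValueError("selection gradient requires a viable resident")
    return _gradient_scaled(model, model.to_scaled(resident), env, h)


def _gradient_at(model, u_full, h, warm):
    """Gradient at a (possibly perturbed) resident; None when nonviable."""
    try:
        env = model.equilibrium(model.to_traits(u_full), warm=warm)
    except EquilibriumError:
        return None
    if not env.viable:
        return None
    return _gradient_scaled(model, u_full, env, h)


def _jacobian_column(model, u, grad, i, idx, h, h_jac, env):
    """FD column of the gradient Jacobian, one-sided when a perturbed
    resident loses viability."""
    up, um = u.copy(), u.copy()
    up[i] = min(u[i] + h_jac, model.upper_full[i])
    um[i] = max(u[i] - h_jac, model.lower_full[i])
    gp = _gradient_at(model, up, h, env) if up[i] > u[i] else None
    gm = _gradient_at(model, um, h, env) if um[i] < u[i] else None
    if gp is not None and gm is not None:
        return (gp[idx] - gm[idx]) / (up[i] - um[i])
    if gp is not None:
        return (gp[idx] - grad[idx]) / (up[i] - u[i])
    if gm is not None:
        return (grad[idx] - gm[idx]) / (u[i] - um[i])
    raise SingularSearchError(
        f"resident loses viability under perturbation of trait {TRAIT_NAMES[i]}"
    )


@dataclass
class SingularStrategy:
    """A strategy with vanishing (interior) selection gradient."""

    traits: TraitVector
    environment: EquilibriumState
    classification: str = "unclassified"
    gradient: np.ndarray | None = None
    gradient_norm: float = np.nan
    pinned: np.ndarray | None = None      # active traits pinned at a box edge
    hessian_eigs: np.ndarray | None = None
    jacobian_eigs: np.ndarray | None = None
    indeterminate: bool = False

    @property
    def boundary(self) -> bool:
        return self.pinned is not None and bool(np.any(self.pinned))


def find_singular(
    initial: TraitVector,
    params: BioenergeticParams,
    *,
    active: tuple[bool, bool, bool, bool] = (True, True, True, True),
    h: float = 3e-4,
    gtol: float = 1e-6,
    max_iter: int = 60,
    rtol: float = 1e-11,
    classify: bool = True,
    warm: EquilibriumState | None = None,
) -> SingularStrategy:
    """Locate a singular strategy by damped Newton iteration on the gradient.

    Traits that hit a box edge with an outward gradient are pinned there
    (boundary singular strategy); the Newton step continues in the
    remaining directions.
    """
    model = EcoEvoModel(params, active=active, rtol=rtol)
    u = model.clip(model.to_scaled(initial))
    env = model.equilibrium(model.to_traits(u), warm=warm)
    if not env.viable:
        raise SingularSearchError("initial strategy is not viable")
    act_idx = np.flatnonzero(model.active)
    grad = _gradient_scaled(model, u, env, h)

    def free_mask(u_, grad_):
        """Active components not pinned at an edge by an outward gradient."""
        free = np.zeros(4, dtype=bool)
        for i in act_idx:
            at_lo = u_[i] <= model.lower_full[i] + 1e-12
            at_hi = u_[i] >= model.upper_full[i] - 1e-12
            if (at_lo and grad_[i] < 0) or (at_hi and grad_[i] > 0):
                continue
            free[i] = True
        return free

    h_jac = max(3.0 * h, 1e-3)
    for _ in range(max_iter):
        free = free_mask(u, grad)
        gnorm = np.max(np.abs(grad[free])) if np.any(free) else 0.0
        if gnorm < gtol:
            break
        idx = np.flatnonzero(free)
        # FD Jacobian of the gradient restricted to free directions
        J = np.empty((idx.size, idx.size))
        for k, i in enumerate(idx):
            J[:, k] = _jacobian_column(model, u, grad, i, idx, h, h_jac, env)
        try:
            step = np.linalg.solve(J, -grad[idx])
        except np.linalg.LinAlgError:
            raise SingularSearchError("singular Jacobian in Newton iteration")
        step = np.clip(step, -0.2, 0.2)  # trust region in scaled units
        lam = 1.0
        for _try in range(8):
            u_new = u.copy()
            u_new[idx] = u[idx] + lam * step
            u_new = model.clip(u_new)
            try:
                env_new = model.equilibrium(model.to_traits(u_new), warm=env)
            except EquilibriumError:
                lam *= 0.5
                continue
            if not env_new.viable:
                lam *= 0.5
                continue
            grad_new = _gradient_scaled(model, u_new, env_new, h)
            free_new = free_mask(u_new, grad_new)
            gn = np.max(np.abs(grad_new[free_new])) if np.any(free_new) else 0.0
            if gn < gnorm or np.any(free_new != free):
                u, env, grad = u_new, env_new, grad_new
                break
            lam *= 0.5
        else:
            # Newton direction not productive (near-singular Jacobian, e.g.
            # close to a fold): follow the selection-gradient flow instead
            u, env, grad, ok = _flow_steps(model, u, env, grad, free_mask, h, gnorm)
            if not ok:
                raise SingularSearchError(
                    f"Newton line search stalled at |grad|={gnorm:.3g}"
                )
    else:
        raise SingularSearchError(f"no convergence in {max_iter} iterations")

    free = free_mask(u, grad)
    pinned = model.active & ~free
    sing = SingularStrategy(
        traits=model.to_traits(u),
        environment=env,
        gradient=grad,
        gradient_norm=float(np.max(np.abs(grad[free]))) if np.any(free) else 0.0,
        pinned=pinned,
    )
    if classify:
        classify_singular(sing, params, active=active, rtol=rtol, h=h)
    return sing


def _classification_label(hess_eigs, jac_eigs, eig_tol) -> tuple[str, bool]:
    """Combine Hessian / gradient-Jacobian eigenvalues into the singular-
    strategy label.  Eigenvalues within ``eig_tol`` of zero make the
    verdict indeterminate (flagged, never guessed)."""
    hess_eigs = np.asarray(hess_eigs, dtype=float)
    jac_re = np.asarray(jac_eigs).real
    uninvadable = np.max(hess_eigs) < -eig_tol
    invadable = np.max(hess_eigs) > eig_tol
    converging = np.max(jac_re) < -eig_tol
    diverging = np.max(jac_re) > eig_tol
    indeterminate = not ((uninvadable or invadable) and (converging or diverging))
    if converging and uninvadable:
        return "CSS", indeterminate
    if converging and invadable:
        return "branching", indeterminate
    if diverging and uninvadable:
        return "repeller", indeterminate
    if diverging and invadable:
        return "evolutionarily-unstable", indeterminate
    return "indeterminate", indeterminate


def _flow_steps(model, u, env, grad, free_mask, h, gnorm0, n_steps=25):
    """Damped selection-gradient flow; rescue path when Newton stalls.

    Converges toward convergence-stable singular points; returns the best
    point found and whether the gradient norm improved.
    """
    dt = 0.02 / max(gnorm0, 1e-12)
    gnorm = gnorm0
    improved = False
    for _ in range(n_steps):
        step = np.nan_to_num(grad) * dt
        step = np.clip(step, -0.02, 0.02)
        u_new = model.clip(u + step)
        try:
            env_new = model.equilibrium(model.to_traits(u_new), warm=env)
        except EquilibriumError:
            dt *= 0.3
            if dt * gnorm < 1e-9:
                break
            continue
        if not env_new.viable:
            dt *= 0.3
            if dt * gnorm < 1e-9:
                break
            continue
        grad_new = _gradient_scaled(model, u_new, env_new, h)
        free = free_mask(u_new, grad_new)
        gn = np.max(np.abs(grad_new[free])) if np.any(free) else 0.0
        if gn < gnorm:
            u, env, grad, gnorm = u_new, env_new, grad_new, gn
            improved = True
            dt *= 1.3
        else:
            dt *= 0.5
            if dt * gnorm < 1e-9:
                break
    return u, env, grad, improved


def classify_singular(
    sing: SingularStrategy,
    params: BioenergeticParams,
    *,
    active: tuple[bool, bool, bool, bool] = (True, True, True, True),
    h: float = 3e-4,
    h2: float = 3e-3,
    eig_tol: float = 1e-4,
    rtol: float = 1e-11,
) -> str:
    """Attach the {CSS, branching, repeller, evolutionarily-unstable}
    classification, from the mutant Hessian and the gradient Jacobian in
    the non-pinned trait directions.

    Eigenvalues within ``eig_tol`` of zero leave the verdict flagged as
    indeterminate rather than guessed.
    """
    model = EcoEvoModel(params, active=active, rtol=rtol)
    u = model.to_scaled(sing.traits)
    env = sing.environment
    pinned = sing.pinned if sing.pinned is not None else np.zeros(4, bool)
    idx = np.flatnonzero(model.active & ~pinned)
    if idx.size == 0:
        sing.classification = "boundary"
        return sing.classification

    # mutant Hessian at fixed environment (invasibility)
    n = idx.size
    f0 = model.fitness(model.to_traits(u), env)
    H = np.empty((n, n))
    for a in range(n):
        i = idx[a]
        up, um = u.copy(), u.copy()
        up[i] += h2
        um[i] -= h2
        fp = model.fitness(model.to_traits(model.clip(up)), env)
        fm = model.fitness(model.to_traits(model.clip(um)), env)
        H[a, a] = (fp - 2.0 * f0 + fm) / h2**2
        for bq in range(a + 1, n):
            j = idx[bq]
            vals = []
            for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                uu = u.copy()
                uu[i] += sa * h2
                uu[j] += sb * h2
                vals.append(model.fitness(model.to_traits(model.clip(uu)), env))
            H[a, bq] = H[bq, a] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4.0 * h2**2)
    hess_eigs = np.linalg.eigvalsh(0.5 * (H + H.T))

    # Jacobian of the selection gradient (convergence, identity covariance)
    J = np.empty((n, n))
    h_jac = max(3.0 * h, 1e-3)
    grad0 = _gradient_scaled(model, u, env, h)
    for k, i in enumerate(idx):
        J[:, k] = _jacobian_column(model, u, grad0, i, idx, h, h_jac, env)
    jac_eigs = np.linalg.eigvals(J)

    label, indeterminate = _classification_label(hess_eigs, jac_eigs, eig_tol)
    if sing.boundary and label in ("CSS", "indeterminate"):
        label = "boundary-" + label

    sing.classification = label
    sing.hessian_eigs = hess_eigs
    sing.jacobian_eigs = jac_eigs
    sing.indeterminate = indeterminate
    return label
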