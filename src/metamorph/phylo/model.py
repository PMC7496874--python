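"""CTMC models for two binary traits: independent, dependent, constrained.

The joint chain lives on the four states (D, E) in the fixed order
((0,0), (0,1), (1,0), (1,1)).  Dual transitions (both traits changing in
the same instant) are structurally impossible, so each state exchanges
with exactly two neighbours.  The independent model has 4 free rates (a
gain and a loss rate per trait, shared across the other trait's states),
the dependent model 8 (every conditional rate free), and the constrained
model 7 (the two gains of direct development share one rate, encoding
"the transition to direct development does not depend on egg size").
Rates are in transitions per million years when branch lengths are Myr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

#: joint states (D, E)
STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

#: allowed single-trait moves as (from_state, to_state) index pairs, in the
#: canonical label order of the dependent model
_DEP_MOVES = (
    (0, 2),  # P(D=0->1 | E=0)
    (1, 3),  # P(D=0->1 | E=1)
    (2, 0),  # P(D=1->0 | E=0)
    (3, 1),  # P(D=1->0 | E=1)
    (0, 1),  # P(E=0->1 | D=0)
    (2, 3),  # P(E=0->1 | D=1)
    (1, 0),  # P(E=1->0 | D=0)
    (3, 2),  # P(E=1->0 | D=1)
)

_DEP_LABELS = (
    "P(D=0->1 | E=0)",
    "P(D=0->1 | E=1)",
    "P(D=1->0 | E=0)",
    "P(D=1->0 | E=1)",
    "P(E=0->1 | D=0)",
    "P(E=0->1 | D=1)",
    "P(E=1->0 | D=0)",
    "P(E=1->0 | D=1)",
)

_INDEP_LABELS = ("q(D:0->1)", "q(D:1->0)", "q(E:0->1)", "q(E:1->0)")

#: map from the 8 dependent slots to free-parameter indices per model kind
_SLOT_MAP = {
    "independent": (0, 0, 1, 1, 2, 2, 3, 3),
    "dependent": (0, 1, 2, 3, 4, 5, 6, 7),
    # slots 0 and 1 (gains of D under E=0 / E=1) share parameter 0
    "constrained_dependent": (0, 0, 1, 2, 3, 4, 5, 6),
}

N_FREE = {"independent": 4, "dependent": 8, "constrained_dependent": 7}


def rate_labels(kind: str) -> tuple[str, ...]:
    """Human-readable labels of the free rates of a model kind."""
    if kind == "independent":
        return _INDEP_LABELS
    if kind == "dependent":
        return _DEP_LABELS
    if kind == "constrained_dependent":
        return ("P(D=0->1)",) + _DEP_LABELS[2:]
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass(frozen=True)
class PagelModel:
    """A model kind plus its free rate vector (transitions / Myr)."""

    kind: str
    rates: tuple

    def __post_init__(self) -> None:
        if self.kind not in N_FREE:
            raise ValueError(f"unknown model kind {self.kind!r}")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.rates) != N_FREE[self.kind]:
            raise ValueError(
                f"{self.kind} model needs {N_FREE[self.kind]} rates, got {len(self.rates)}"
            )
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be nonnegative")

    @property
    def n_free(self) -> int:
        return N_FREE[self.kind]

    def expanded_rates(self) -> np.ndarray:
        """The 8 conditional rates in the canonical dependent-slot order."""
        return np.array([self.rates[j] for j in _SLOT_MAP[self.kind]])


def build_rate_matrix(model: PagelModel) -> np.ndarray:
    """4x4 generator of the joint chain; rows sum to zero."""
    Q = np.zeros((4, 4))
    for (i, j), r in zip(_DEP_MOVES, model.expanded_rates()):
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Matrix exponential expm(Q t); a stochastic matrix for t >= 0."""
    if t < 0:
        raise ValueError("elapsed time must be nonnegative")
    return expm(Q * t)


def branch_probabilities(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transition matrices for many branch lengths at once.

    Uses one eigendecomposition of Q (shape (n, 4, 4) result); falls back
    to per-branch expm when the eigenvector matrix is ill-conditioned.
    """
    lengths = np.asarray(lengths, dtype=float)
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        cond = np.linalg.cond(U)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        E = np.exp(np.multiply.outer(lengths, lam))      # (n, 4)
        P = np.einsum("ij,nj,jk->nik", U, E, Uinv)
        P = np.real(P)
    else:
        P = np.stack([expm(Q * t) for t in lengths])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P
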