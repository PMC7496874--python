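"""Evolving life-history strategy of a consumer.

Four traits evolve: the larval specialization ``psi_L`` on the secondary
food source, the extent of metamorphosis ``theta``, the body mass at
metamorphosis ``w_J`` and the body mass at birth ``w_b``.  The
post-metamorphic specialization is not free but composed as
``min(1, psi_L + theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: Lower bound on the two evolving masses (g).
MASS_FLOOR = 0.0001


@dataclass(frozen=True)
class TraitVector:
    """A consumer strategy: (psi_L, theta, w_J, w_b).

    psi_L : larval specialization on the secondary food source, in [0, 1].
    theta : extent of metamorphosis, in [0, 1].
    w_J   : body mass at metamorphosis (g), > 0.0001.
    w_b   : body mass at birth (g), > 0.0001.
    """

    psi_L: float
    theta: float
    w_J: float
    w_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi_L <= 1.0):
            raise ValueError(f"psi_L must lie in [0, 1], got {self.psi_L}")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if not self.w_J > MASS_FLOOR:
            raise ValueError(f"w_J must exceed {MASS_FLOOR} g, got {self.w_J}")
        if not self.w_b > MASS_FLOOR:
            raise ValueError(f"w_b must exceed {MASS_FLOOR} g, got {self.w_b}")

    @property
    def psi_post(self) -> float:
        """Specialization of post-metamorphic stages, min(1, psi_L + theta)."""
        return min(1.0, self.psi_L + self.theta)

    @property
    def direct_development(self) -> bool:
        """True when offspring are born past the metamorphosis mass."""
        return self.w_b >= self.w_J

    def as_array(self):
        import numpy as np

        return np.array([self.psi_L, self.theta, self.w_J, self.w_b])

    @staticmethod
    def from_array(arr) -> "TraitVector":
        return TraitVector(float(arr[0]), float(arr[1]), float(arr[2]), float(arr[3]))

    def with_(self, **kw) -> "TraitVector":
        return replace(self, **kw)


def specialization_profile(traits: TraitVector) -> tuple[float, float]:
    """Return (larval, post-metamorphic) specialization on the secondary food.

    Larvae express ``psi_L``; juveniles and adults express
    ``min(1, psi_L + theta)``.
    """
    return traits.psi_L, traits.psi_post
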