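"""Parameterization of the size-structured consumer-resource models.

Two packaged presets parameterize the two model variants: ``fat_reserves``
(roach-like consumer with an irreversible/reversible mass split) and
``generic_invertebrate`` (abstract size-structured variant).  A third,
``toy_symmetric``, is a deliberately symmetric two-resource configuration
whose single evolving specialization trait has its optimum at 0.5 by
symmetry; it anchors the adaptive-dynamics oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import yaml


@dataclass(frozen=True)
class BioenergeticParams:
    """Full parameter set of one model variant.

    Resources follow semichemostat dynamics ``dXi/dt = delta*(Xi_max - Xi)
    - consumption``.  Attack rates are hump-shaped in body mass, handling
    time is a power law, maintenance is proportional to total mass.
    Masses in g, densities in mg L^-1, rates per day.
    """

    # --- resources ---
    delta: float            # resource turnover rate (day^-1)
    X1_max: float           # maximum density of the primary food (mg L^-1)
    X2_max: float           # maximum density of the secondary food (mg L^-1)
    w_min: float            # body mass giving access to the secondary food (g)

    # --- life-history thresholds ---
    w_A: float              # maturation mass (g)

    # --- feeding ---
    A1_max: float           # peak clearance on the primary food (L day^-1)
    A2_max: float           # peak clearance on the secondary food (L day^-1)
    w_opt1: float           # mass at the attack-rate peak, primary food (g)
    w_opt2: float           # mass at the attack-rate peak, secondary food (g)
    alpha1: float           # hump width exponent, primary food
    alpha2: float           # hump width exponent, secondary food
    spec_exponent: float    # exponent on the (1-psi)/psi specialization scaling
    xi1: float              # handling-time coefficient (day mg^-1 g^xi2)
    xi2: float              # handling-time mass exponent

    # --- energetics ---
    kappa_e: float          # assimilation efficiency (dimensionless)
    food_to_mass: float     # conversion of ingested food to body mass (g mg^-1)
    maint_coef: float       # maintenance rate per unit body mass (day^-1)
    q_ratio: float          # target reversible:irreversible mass ratio y/x
    q_starv: float          # starvation death threshold on y/x (IBM only)
    kappa_adult: float      # fraction of adult net production kept for growth

    # --- reproduction ---
    egg_overhead: float     # fixed energetic overhead per offspring (g)
    egg_cost_per_gram: float  # marginal cost per gram of offspring mass

    # --- metamorphosis ---
    rho: float              # mortality coefficient: die with probability rho*theta
    meta_loss: float        # fraction of reversible mass lost, scaled by theta

    # --- mortality ---
    mu_larva: float         # background mortality of larvae (day^-1)
    mu_juvenile: float      # background mortality of juveniles (day^-1)
    mu_adult: float         # background mortality of adults (day^-1)
    mu_larval_habitat: float = 0.0  # extra larval-habitat mortality (day^-1)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"{f.name} must be numeric, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")
        if not (0.0 < self.kappa_e <= 1.0):
            raise ValueError(f"kappa_e must lie in (0, 1], got {self.kappa_e}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not (0.0 <= self.meta_loss <= 1.0):
            raise ValueError(f"meta_loss must lie in [0, 1], got {self.meta_loss}")
        if not self.w_min < self.w_A:
            raise ValueError(
                f"w_min ({self.w_min}) must be below the maturation mass w_A ({self.w_A})"
            )

    def replace(self, **kw) -> "BioenergeticParams":
        return dataclasses.replace(self, **kw)

    @property
    def supply_rate_1(self) -> float:
        """Supply rate delta*X1_max of the primary food (mg L^-1 day^-1)."""
        return self.delta * self.X1_max

    @property
    def supply_rate_2(self) -> float:
        """Supply rate delta*X2_max of the secondary food (mg L^-1 day^-1)."""
        return self.delta * self.X2_max

    @classmethod
    def from_dict(cls, d: dict) -> "BioenergeticParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(d) - {"mu_larval_habitat"}
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


PRESET_NAMES = ("fat_reserves", "generic_invertebrate", "toy_symmetric")


def load_preset(name: str) -> BioenergeticParams:
    """Load a packaged parameter preset by name."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("metamorph.presets").joinpath(f"{name}.yaml").read_text()
    return BioenergeticParams.from_dict(yaml.safe_load(text))


def load_params_file(path) -> BioenergeticParams:
    """Read a parameter configuration from a YAML file on disk."""
    with open(path) as fh:
        return BioenergeticParams.from_dict(yaml.safe_load(fh))
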