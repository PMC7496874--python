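"""Per-species binary trait data and rate summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import rate_labels

#: sentinel for an unobserved trait value
MISSING = -1


@dataclass
class BinaryTraitMatrix:
    """Per-tip states of direct development (D) and large eggs (E).

    Values are 0, 1 or MISSING (-1); a missing value enters the
    likelihood as full ambiguity over the matching joint states.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_dicts(cls, D: dict, E: dict) -> "BinaryTraitMatrix":
        species = sorted(set(D) | set(E))
        rows = [{"species": s,
                 "D": D.get(s, MISSING),
                 "E": E.get(s, MISSING)} for s in species]
        return cls(pd.DataFrame(rows).set_index("species"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryTraitMatrix":
        """Build from a frame with columns species, D and E (or egg_size_mm)."""
        df = df.copy()
        if "species" in df.columns:
            if df["species"].duplicated().any():
                dup = df["species"][df["species"].duplicated()].iloc[0]
                raise ValueError(f"duplicated species label: {dup!r}")
            df = df.set_index("species")
        for col in ("D", "E"):
            if col not in df.columns:
                raise ValueError(f"trait table lacks column {col!r}")
            df[col] = df[col].fillna(MISSING).astype(int)
            bad = ~df[col].isin((0, 1, MISSING))
            if bad.any():
                raise ValueError(f"column {col} contains non-binary values "
                                 f"at rows {list(df.index[bad])[:5]}")
        return cls(df[["D", "E"]])

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def states(self, sp: str) -> tuple[int, int]:
        row = self.data.loc[sp]
        return int(row["D"]), int(row["E"])

    def __len__(self) -> int:
        return len(self.data)


def dichotomize_egg_size(values: pd.Series, threshold: float | None = None) -> pd.Series:
    """Binary large-egg indicator: E = 1 iff size >= threshold.

    The default threshold is the mean over the non-missing sizes (for
    comprehensive amphibian compilations this grand mean is about
    2.45 mm).  Missing sizes stay missing.
    """
    v = pd.Series(values, dtype=float)
    observed = v.dropna()
    if observed.empty:
        raise ValueError("all egg sizes are missing")
    if (observed < 0).any():
        raise ValueError("egg sizes must be nonnegative")
    if threshold is None:
        threshold = float(observed.mean())
    out = pd.Series(MISSING, index=v.index, dtype=int)
    out[v.notna() & (v >= threshold)] = 1
    out[v.notna() & (v < threshold)] = 0
    return out


def summarize_rates(samples: np.ndarray, kind: str) -> pd.DataFrame:
    """Posterior medians per rate, in the conditional-rate table layout."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("no posterior samples")
    labels = rate_labels(kind)
    if samples.shape[1] != len(labels):
        raise ValueError("sample width does not match the model's free rates")
    med = np.median(samples, axis=0)
    lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
    return pd.DataFrame({"transition_rate": labels, "median": med,
                         "q2.5": lo, "q97.5": hi})
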