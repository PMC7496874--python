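"""Readers, writers and run manifests shared by all workflows.

Egg-size dichotomization deliberately does not happen in the reader: the
trait table keeps raw sizes so the threshold policy stays an explicit,
downstream choice (:func:`metamorph.phylo.dichotomize_egg_size`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo.data import MISSING, BinaryTraitMatrix


def read_tree(path, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree with branch lengths (newick or nexus)."""
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {schema!r}")
    tree = dendropy.Tree.get(path=str(path), schema=schema,
                             preserve_underscores=True)
    return tree


def write_tree(tree: dendropy.Tree, path, schema: str = "newick") -> None:
    tree.write(path=str(path), schema=schema, suppress_rooting=True,
               real_value_format_specifier=".12g")


def read_trait_table(path, sep: str = ","):
    """Read a delimited trait table.

    Expected columns: ``species``, ``D`` and either ``E`` or
    ``egg_size_mm``.  Returns ``(BinaryTraitMatrix, egg_sizes)`` where
    ``egg_sizes`` is a Series of raw sizes (or None when the table
    already carries a binary E).  Absent cells become missing values.
    When only egg sizes are present, E is left missing for every species
    and must be filled by dichotomization downstream.
    """
    df = pd.read_csv(path, sep=sep)
    if "species" not in df.columns or "D" not in df.columns:
        raise ValueError("trait table needs 'species' and 'D' columns")
    if df["species"].duplicated().any():
        dup = df["species"][df["species"].duplicated()].iloc[0]
        raise ValueError(f"duplicated species label: {dup!r}")
    bad = df["D"].notna() & ~df["D"].isin((0, 1, MISSING))
    if bad.any():
        rows = list(df.index[bad][:5])
        raise ValueError(f"unparseable D values at rows {rows}")
    egg = None
    if "egg_size_mm" in df.columns:
        egg = pd.Series(df["egg_size_mm"].values, index=df["species"].values,
                        dtype=float)
        if (egg.dropna() < 0).any():
            raise ValueError("egg sizes must be nonnegative")
    if "E" in df.columns:
        e_col = df["E"].fillna(MISSING).astype(int)
    else:
        e_col = pd.Series(MISSING, index=df.index, dtype=int)
    frame = pd.DataFrame({
        "species": df["species"].values,
        "D": df["D"].fillna(MISSING).astype(int).values,
        "E": e_col.values,
    })
    return BinaryTraitMatrix.from_frame(frame), egg


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: dict, manifest: dict, outdir) -> list[Path]:
    """Write result tables (CSV, deterministic column order) + manifest.

    ``manifest`` must include the resolved seed; the config hash is
    added.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "seed" not in manifest:
        raise ValueError("manifest must record the resolved seed")
    manifest = dict(manifest)
    manifest["config_hash"] = config_hash(
        {k: v for k, v in manifest.items() if k != "config_hash"})
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df = pd.DataFrame(df)
        df = df[sorted(df.columns)] if list(df.columns) else df
        df.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(mp)
    return written
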