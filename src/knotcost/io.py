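"""Readers/writers for the package's delimited-text interchange formats.

All tables are tab-separated text with a header row; readers tolerate
``#`` comment lines.  Coordinates export as XYZ for visual inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_table", "write_xyz", "write_manifest"]


def read_table(path) -> pd.DataFrame:
    """Read a TSV table, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_xyz(ensemble: np.ndarray, path, element: str = "C") -> Path:
    """Dump chain conformations as a multi-frame XYZ file (nm units)."""
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim == 2:
        ensemble = ensemble[None]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, chain in enumerate(ensemble):
            fh.write(f"{len(chain)}\nchain {i}\n")
            for v in chain:
                fh.write(f"{element} {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
    return path


def write_manifest(path, **entries) -> Path:
    """Record run parameters (seeds included) as a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
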