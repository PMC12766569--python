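"""On-disk formats: TSV character matrices, Newick trees, barcode tables,
YAML configs, and provenance sidecars.

State-code dialect: 0 = unedited, 1..S = lineage-mark index, -1 = missing.
Every writer can emit a sidecar JSON recording inputs, parameters, seed and
tool version so randomized runs are reproducible from their outputs alone.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from .matrix import CharacterMatrix
from .tree import LineageTree

__all__ = [
    "read_character_matrix",
    "write_character_matrix",
    "read_newick",
    "write_newick",
    "read_barcode_groups",
    "write_barcode_groups",
    "read_positions",
    "load_config",
    "write_sidecar",
]


def read_character_matrix(path, n_marks: int) -> CharacterMatrix:
    return CharacterMatrix.read_tsv(path, n_marks)


def write_character_matrix(cm: CharacterMatrix, path, sidecar: Optional[dict] = None) -> None:
    cm.to_tsv(path)
    if sidecar is not None:
        write_sidecar(path, sidecar)


def read_newick(path) -> LineageTree:
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"EMPTY_INPUT: {path}")
    return LineageTree.from_newick(text)


def write_newick(tree: LineageTree, path, sidecar: Optional[dict] = None) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
    if sidecar is not None:
        write_sidecar(path, sidecar)


def read_barcode_groups(path) -> pd.DataFrame:
    """Long-form (cell, round, label) barcode-group table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell", "round", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"barcode-group TSV needs columns {sorted(required)}")
    return df


def write_barcode_groups(groups: pd.DataFrame, path) -> None:
    groups.to_csv(path, sep="\t", index=False)


def read_positions(path) -> pd.DataFrame:
    """Spatial table: cell, section (optional), x_um, y_um, optional z_um."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell", "x_um", "y_um"}
    if not required <= set(df.columns):
        raise ValueError(f"positions TSV needs columns {sorted(required)}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_sidecar(output_path, payload: dict) -> None:
    """Provenance JSON next to an output file."""
    from . import __version__

    meta = {
        "tool": "editrace",
        "version": __version__,
        "python": sys.version.split()[0],
        "written": datetime.now(timezone.utc).isoformat(),
        **payload,
    }
    side = Path(str(output_path) + ".json")
    side.write_text(json.dumps(meta, indent=2, default=str) + "\n")
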