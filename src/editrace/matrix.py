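"""Character matrices of lineage-mark states.

Cells x edit-site table with integer codes: 0 = unedited, 1..S = lineage
mark (LM) index, -1 = missing (detection dropout).  Ground-truth matrices
from the simulator contain no missing entries; missing codes only arise as a
readout artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

UNEDITED = 0
MISSING = -1

__all__ = ["CharacterMatrix", "UNEDITED", "MISSING"]


@dataclass
class CharacterMatrix:
    """N cells x M edit sites of categorical LM states."""

    data: pd.DataFrame
    n_marks: int

    def __post_init__(self):
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            self.data = self.data.astype(int)
            arr = self.data.to_numpy()
        bad = (arr < MISSING) | (arr > self.n_marks)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid state code {arr[i, j]} for cell {self.data.index[i]!r} "
                f"site {self.data.columns[j]!r} (S={self.n_marks})"
            )
        if self.data.index.has_duplicates:
            raise ValueError("duplicate cell ids")

    @property
    def cells(self) -> List[str]:
        return list(self.data.index)

    @property
    def sites(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def edited_fraction(self) -> float:
        """Fraction of non-missing entries carrying an LM."""
        arr = self.values
        detected = arr != MISSING
        if not detected.any():
            return float("nan")
        return float((arr > 0).sum() / detected.sum())

    def missing_fraction(self) -> float:
        return float((self.values == MISSING).mean())

    def subset_cells(self, cells: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix(self.data.loc[list(cells)], self.n_marks)

    def subset_sites(self, sites: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix(self.data[list(sites)], self.n_marks)

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(self.data.copy(), self.n_marks)

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        n_marks: int,
        cells: Optional[Sequence[str]] = None,
        sites: Optional[Sequence[str]] = None,
    ) -> "CharacterMatrix":
        arr = np.asarray(arr, dtype=int)
        n, m = arr.shape
        cells = list(cells) if cells is not None else [f"cell{i}" for i in range(n)]
        sites = list(sites) if sites is not None else [f"site{j}" for j in range(m)]
        return cls(pd.DataFrame(arr, index=cells, columns=sites), n_marks)

    # ------------------------------------------------------------------
    # TSV interchange
    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell")

    @classmethod
    def read_tsv(cls, path, n_marks: int) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell")
        if df.empty:
            raise ValueError(f"EMPTY_INPUT: no rows in {path}")
        return cls(df, n_marks)
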