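"""Editing-kinetics estimation.

Edit-fraction time courses follow a saturating exponential
``f(t) = s * (1 - exp(-r t))`` with rate ``r`` (edits per site per day) and
plateau ``s`` (the fraction of cells that edit at all).  Fits are bounded
nonlinear least squares with ``s`` in [0.8, 1] and ``r`` in [1e-4, 0.6].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .matrix import MISSING, CharacterMatrix

__all__ = [
    "KineticsFit",
    "InsufficientTimepointsError",
    "per_cell_edit_fraction",
    "fit_saturating_exponential",
    "saturating_exponential",
    "R_BOUNDS",
    "S_BOUNDS",
]

R_BOUNDS = (1e-4, 0.6)
S_BOUNDS = (0.8, 1.0)


class InsufficientTimepointsError(ValueError):
    pass


def saturating_exponential(t: np.ndarray, rate: float, saturation: float) -> np.ndarray:
    return saturation * (1.0 - np.exp(-rate * np.asarray(t, dtype=float)))


@dataclass
class KineticsFit:
    rate: float
    saturation: float
    times: np.ndarray
    fractions: np.ndarray
    cell_counts: Optional[np.ndarray]
    rss: float

    def predict(self, t) -> np.ndarray:
        return saturating_exponential(t, self.rate, self.saturation)


def per_cell_edit_fraction(cm: CharacterMatrix) -> "np.ndarray":
    """Edited / detected sites per cell; all-missing cells become NaN."""
    arr = cm.values
    detected = (arr != MISSING).sum(axis=1)
    edited = (arr > 0).sum(axis=1)
    if (detected == 0).any():
        warnings.warn(f"{(detected == 0).sum()} cell(s) have no detected site; NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(detected > 0, edited / np.maximum(detected, 1), np.nan)


def fit_saturating_exponential(
    times: Sequence[float],
    fractions: Sequence[float],
    cell_counts: Optional[Sequence[int]] = None,
    min_cells: int = 20,
    weight_by_cells: bool = False,
    include_day_zero: bool = True,
) -> KineticsFit:
    """Bounded least-squares fit of the saturating-exponential curve.

    Timepoints with fewer than ``min_cells`` cells are dropped before
    fitting; a (0, 0) anchor is added when absent (editing starts at
    induction).  Three starts across the rate range guard against the flat
    small-``r`` corner.
    """
    from scipy.optimize import least_squares

    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    n = np.asarray(cell_counts, dtype=float) if cell_counts is not None else None
    if n is not None:
        keep = n >= min_cells
        t, f, n = t[keep], f[keep], n[keep]
    if include_day_zero and not np.any(t == 0):
        t = np.concatenate([[0.0], t])
        f = np.concatenate([[0.0], f])
        if n is not None:
            n = np.concatenate([[max(n.max(), min_cells)], n])
    if t.size < 2:
        raise InsufficientTimepointsError(
            f"only {t.size} timepoint(s) survive the min_cells filter"
        )
    w = np.sqrt(n / n.sum()) if (weight_by_cells and n is not None) else np.ones_like(t)

    def residuals(params):
        return w * (saturating_exponential(t, params[0], params[1]) - f)

    lo = (R_BOUNDS[0], S_BOUNDS[0])
    hi = (R_BOUNDS[1], S_BOUNDS[1])
    best = None
    for r0 in (0.01, 0.1, 0.4):
        res = least_squares(residuals, x0=(r0, 0.9), bounds=(lo, hi))
        rss = float((res.fun**2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res.x)
    rss, (rate, sat) = best
    return KineticsFit(
        rate=float(np.clip(rate, *R_BOUNDS)),
        saturation=float(np.clip(sat, *S_BOUNDS)),
        times=t,
        fractions=f,
        cell_counts=n,
        rss=rss,
    )
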