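"""Imaging-readout decoding of integration barcodes and lineage marks.

Integration barcodes are read as 21-bit constant-weight codewords (Hamming
weight 6, minimum pairwise distance 4).  Measured spot intensities mix true
per-spot brightness, per-bit hybridization efficiency, and background; an
expectation-maximization loop alternately normalizes the intensity matrix by
spot/bit factors (with a per-bit signal-to-noise correction) and re-assigns
each spot to the nearest codeword in Euclidean distance.  Lineage marks are
decoded per edit site from row-normalized 9-bit intensity vectors, either by
argmax or by a per-site multinomial logistic-regression classifier.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "DecodeResult",
    "build_codebook",
    "validate_codebook",
    "em_decode_intbc",
    "decode_lm",
    "train_lm_classifier",
    "imaging_lm_qc",
    "synth_spot_intensities",
]

MASKED = -1


@dataclass
class Codebook:
    """Constant-weight binary codewords mapped to integration barcodes."""

    words: np.ndarray  # (n_codes, n_bits) of 0/1
    ids: List[str]
    weight: int = 6
    min_distance: int = 4

    def __post_init__(self):
        self.words = np.asarray(self.words, dtype=int)
        if len(self.ids) != self.words.shape[0]:
            raise ValueError("ids do not match codeword count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate codeword ids")

    @property
    def n_bits(self) -> int:
        return self.words.shape[1]

    @property
    def n_codes(self) -> int:
        return self.words.shape[0]

    def subset(self, ids: Iterable[str]) -> "Codebook":
        wanted = set(ids)
        idx = [i for i, x in enumerate(self.ids) if x in wanted]
        if not idx:
            raise ValueError("whitelist shares no id with the codebook")
        return Codebook(self.words[idx], [self.ids[i] for i in idx], self.weight, self.min_distance)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "intbc_id": self.ids,
                "bitstring": ["".join(map(str, w)) for w in self.words],
            }
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, weight: int = 6, min_distance: int = 4) -> "Codebook":
        df = pd.read_csv(path, dtype={"bitstring": str})
        words = np.array([[int(ch) for ch in s] for s in df["bitstring"]])
        return cls(words, list(df["intbc_id"]), weight, min_distance)


def build_codebook(
    n_bits: int = 21,
    weight: int = 6,
    min_distance: int = 4,
    target_size: Optional[int] = None,
    seed: int = 0,
) -> Codebook:
    """Greedy lexicographic constant-weight code construction.

    All weight-``weight`` vectors are scanned in lexicographic order and a
    candidate is accepted iff its Hamming distance to every accepted word is
    at least ``min_distance``.  Deterministic for a given seed (the seed is
    reserved for future randomized orders; the lexicode itself is fixed).

    Raises if ``target_size`` cannot be reached, reporting the achieved size.
    """
    if not (n_bits >= weight >= min_distance / 2):
        raise ValueError("need n_bits >= weight >= min_distance/2")
    accepted: List[np.ndarray] = []
    acc_mat = np.empty((0, n_bits), dtype=int)
    for positions in itertools.combinations(range(n_bits), weight):
        word = np.zeros(n_bits, dtype=int)
        word[list(positions)] = 1
        if acc_mat.shape[0]:
            dists = np.abs(acc_mat - word).sum(axis=1)
            if (dists < min_distance).any():
                continue
        accepted.append(word)
        acc_mat = np.vstack([acc_mat, word])
        if target_size is not None and len(accepted) >= target_size:
            break
    if target_size is not None and len(accepted) < target_size:
        raise ValueError(
            f"target_size {target_size} unreachable; achieved {len(accepted)}"
        )
    words = np.array(accepted)
    ids = [f"intBC{i:04d}" for i in range(words.shape[0])]
    return Codebook(words, ids, weight, min_distance)


def validate_codebook(cb: Codebook) -> List[str]:
    """Return a list of constraint violations (empty means valid)."""
    problems: List[str] = []
    weights = cb.words.sum(axis=1)
    for i in np.flatnonzero(weights != cb.weight):
        problems.append(f"{cb.ids[i]}: weight {weights[i]} != {cb.weight}")
    if len(set(cb.ids)) != len(cb.ids):
        problems.append("duplicate ids")
    for i in range(cb.n_codes):
        d = np.abs(cb.words[i + 1 :] - cb.words[i]).sum(axis=1)
        for off in np.flatnonzero(d < cb.min_distance):
            j = i + 1 + off
            problems.append(
                f"pair ({cb.ids[i]}, {cb.ids[j]}): distance {d[off]} < {cb.min_distance}"
            )
    return problems


@dataclass
class DecodeResult:
    """Per-spot assignments from the EM decoder."""

    assignments: np.ndarray  # index into codebook.ids, or MASKED
    distances: np.ndarray
    codebook: Codebook
    spot_intensity: np.ndarray
    bit_intensity: np.ndarray
    bit_snr: np.ndarray
    mean_distance_trace: List[float] = field(default_factory=list)

    @property
    def assigned_ids(self) -> List[Optional[str]]:
        return [
            self.codebook.ids[a] if a != MASKED else None for a in self.assignments
        ]

    @property
    def unmasked(self) -> np.ndarray:
        return self.assignments != MASKED


def _color_scale(X: np.ndarray, channel_map: Optional[Sequence[int]]) -> np.ndarray:
    """Per-bit scale equalizing mean intensity across color channels.

    Without a channel map no equalization is applied: the per-bit intensity
    factor estimated by the EM loop already absorbs arbitrary per-bit scale,
    whereas blanket per-bit equalization would distort codeword subsets with
    uneven bit usage.
    """
    if channel_map is None:
        return np.ones(X.shape[1])
    channel_map = np.asarray(channel_map)
    if channel_map.shape != (X.shape[1],):
        raise ValueError("channel map must give one channel per bit")
    scale = np.ones(X.shape[1])
    overall = X.mean()
    for ch in np.unique(channel_map):
        cols = channel_map == ch
        m = X[:, cols].mean()
        if m > 0:
            scale[cols] = overall / m
    return scale


def em_decode_intbc(
    X: np.ndarray,
    codebook: Codebook,
    max_dist: float = 1.7,
    iterations: int = 10,
    whitelist: Optional[Iterable[str]] = None,
    channel_map: Optional[Sequence[int]] = None,
    snr_floor: float = 1.05,
) -> DecodeResult:
    """EM assignment of spot intensity vectors to integration barcodes.

    Each iteration normalizes ``X`` by the outer product of per-spot and
    per-bit intensity factors, applies the per-bit SNR correction
    ``(Xc - 1/snr) / (1 - 1/snr)`` clipped above at 1, assigns each spot to
    the Euclidean-nearest codeword (KD-tree), masks spots at distance >=
    ``max_dist``, and re-estimates the factors -- spot intensities from all
    rows, bit intensities and SNR from confidently assigned spots only.
    Near-ties in the nearest-codeword search break to the lower barcode id.
    """
    from scipy.spatial import cKDTree

    X = np.asarray(X, dtype=float)
    cb = codebook.subset(whitelist) if whitelist is not None else codebook
    if X.ndim != 2 or X.shape[1] != cb.n_bits:
        raise ValueError(f"X must be (spots, {cb.n_bits})")
    if (X < 0).any():
        raise ValueError("intensities must be nonnegative")
    n_spots = X.shape[0]
    words = cb.words.astype(float)
    zero_rows = ~(X > 0).any(axis=1)

    colscale = _color_scale(X, channel_map)
    Xc0 = X * colscale
    s = np.percentile(Xc0, 95, axis=1)
    s = np.where(s > 0, s, 1.0)
    b = np.percentile(Xc0 / s[:, None], 95, axis=0)
    b = np.where(b > 0, b, 1.0)
    snr: Optional[np.ndarray] = None
    tree = cKDTree(words)

    assignments = np.full(n_spots, MASKED, dtype=int)
    distances = np.full(n_spots, np.inf)
    trace: List[float] = []

    for _ in range(iterations):
        Xc = Xc0 / (s[:, None] * b[None, :])
        if snr is not None:
            corr = 1.0 / snr
            Xc = (Xc - corr) / (1.0 - corr)
        Xc = np.minimum(Xc, 1.0)
        # E-step: nearest codeword
        dist2, idx = tree.query(Xc, k=2)
        near_tie = np.isclose(dist2[:, 0], dist2[:, 1], rtol=0, atol=1e-12)
        idx0 = idx[:, 0].copy()
        idx0[near_tie] = np.minimum(idx[near_tie, 0], idx[near_tie, 1])
        d = dist2[:, 0]
        d = np.where(zero_rows, np.inf, d)
        assignments = np.where(d < max_dist, idx0, MASKED)
        distances = d
        good = assignments != MASKED
        if good.any():
            trace.append(float(d[good].mean()))
        # M-step
        assigned_words = words[np.where(good, assignments, 0)]
        on_counts = assigned_words.sum(axis=1)
        s_new = np.where(
            good,
            (Xc0 / b[None, :] * assigned_words).sum(axis=1) / np.maximum(on_counts, 1),
            np.percentile(Xc0, 95, axis=1),
        )
        s = np.where(s_new > 0, s_new, s)
        if good.any():
            Xs = Xc0[good] / s[good, None]
            W = assigned_words[good]
            on_mass = (Xs * W).sum(axis=0)
            on_n = W.sum(axis=0)
            b_new = np.where(on_n > 0, on_mass / np.maximum(on_n, 1), b)
            b = np.where(b_new > 0, b_new, b)
            off_mass = (Xs * (1 - W)).sum(axis=0)
            off_n = (1 - W).sum(axis=0)
            off_mean = np.where(off_n > 0, off_mass / np.maximum(off_n, 1), np.nan)
            with np.errstate(invalid="ignore", divide="ignore"):
                snr_new = np.where(
                    (off_mean > 0) & np.isfinite(off_mean), b / off_mean, np.inf
                )
            snr = np.maximum(snr_new, snr_floor)
    return DecodeResult(
        assignments,
        distances,
        cb,
        s,
        b / colscale,  # report per-bit intensities in raw X units
        snr if snr is not None else np.full(cb.n_bits, np.inf),
        trace,
    )


# ----------------------------------------------------------------------
# lineage-mark decoding (per edit site, 9 bits = 8 marks + unedited)
# ----------------------------------------------------------------------

def _row_normalize(X_site: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X_site = np.asarray(X_site, dtype=float)
    sums = X_site.sum(axis=1)
    ok = sums > 0
    out = np.zeros_like(X_site)
    out[ok] = X_site[ok] / sums[ok, None]
    return out, ok


def train_lm_classifier(X_site: np.ndarray, labels: Sequence[int], seed: int = 0):
    """Multinomial logistic regression on row-normalized 9-bit vectors."""
    from sklearn.linear_model import LogisticRegression

    Xn, ok = _row_normalize(X_site)
    clf = LogisticRegression(max_iter=1000, C=1.0, random_state=seed)
    clf.fit(Xn[ok], np.asarray(labels)[ok])
    return clf


def decode_lm(
    X_site: np.ndarray,
    classifier=None,
    min_probability: float = 0.7,
) -> pd.DataFrame:
    """Per-spot lineage-mark calls for one edit site.

    Rows are normalized to sum to 1; the argmax call is always computed and
    a calibrated classifier refines it when supplied.  Calls with assignment
    probability below ``min_probability`` (and zero-sum rows) are flagged
    low-confidence.  Bit convention: column 0..S-1 = LM 1..S, column S =
    unedited, mirroring state codes 1..S and 0.
    """
    Xn, ok = _row_normalize(X_site)
    n_bits = Xn.shape[1]
    argmax_bit = Xn.argmax(axis=1)
    argmax_call = np.where(argmax_bit == n_bits - 1, 0, argmax_bit + 1)
    argmax_p = Xn.max(axis=1)
    if classifier is not None:
        proba = classifier.predict_proba(Xn)
        best = proba.argmax(axis=1)
        call = classifier.classes_[best]
        p = proba[np.arange(len(best)), best]
    else:
        call, p = argmax_call, argmax_p
    call = np.where(ok, call, -1)
    p = np.where(ok, p, 0.0)
    return pd.DataFrame(
        {
            "call": call.astype(int),
            "probability": p,
            "argmax_call": np.where(ok, argmax_call, -1).astype(int),
            "low_confidence": (p < min_probability) | ~ok,
        }
    )


# ----------------------------------------------------------------------
# imaging LM quality control
# ----------------------------------------------------------------------

def imaging_lm_qc(
    amplicons: pd.DataFrame,
    clone_labels: Dict[str, str],
    min_mean_probability: float = 0.7,
    max_dup_cell_fraction: float = 0.4,
    max_conflict_fraction: float = 0.5,
) -> pd.DataFrame:
    """Reduce decoded amplicons to one allele per (cell, intBC).

    Rules, in order: (1) drop amplicons whose mean LM assignment probability
    across the edit sites is below 0.7; (2) deduplicate repeated detections
    (same cell, intBC and LM set) keeping the brightest; (3) drop intBCs
    seen with conflicting LM sets in more than 40% of a clone's cells;
    (4) drop cells with more than 50% conflicting amplicons (segmentation
    doublets); (5) resolve remaining conflicts preferring in-mask amplicons,
    then brightness.

    ``amplicons`` columns: cell, intbc, lm1..lmK, p1..pK, brightness,
    in_mask.
    """
    t = amplicons.copy()
    lm_cols = sorted(c for c in t.columns if c.startswith("lm"))
    p_cols = sorted(c for c in t.columns if c.startswith("p"))
    # 1: mean assignment probability
    t = t[t[p_cols].mean(axis=1) >= min_mean_probability]
    # 2: identical (cell, intbc, LM set) detections -> brightest
    t = (
        t.sort_values("brightness", ascending=False)
        .drop_duplicates(subset=["cell", "intbc"] + lm_cols, keep="first")
    )
    # 3: duplicate integrations, clone-wide
    t["clone"] = t["cell"].map(clone_labels)
    drop = set()
    for (clone, intbc), grp in t.groupby(["clone", "intbc"], sort=False):
        if pd.isna(clone):
            continue
        per_cell = grp.groupby("cell").size()
        frac = (per_cell > 1).mean()
        if frac > max_dup_cell_fraction:
            drop.add((clone, intbc))
    t = t[[(cl, ib) not in drop for cl, ib in zip(t["clone"], t["intbc"])]]
    # 4: segmentation doublets
    bad_cells = set()
    for cell, grp in t.groupby("cell", sort=False):
        per_intbc = grp.groupby("intbc").size()
        conflicted = set(per_intbc[per_intbc > 1].index)
        frac = grp["intbc"].isin(conflicted).mean()
        if frac > max_conflict_fraction:
            bad_cells.add(cell)
    t = t[~t["cell"].isin(bad_cells)]
    # 5: in-mask preference, then brightness
    t = t.sort_values(
        ["in_mask", "brightness"], ascending=[False, False]
    ).drop_duplicates(subset=["cell", "intbc"], keep="first")
    return t.drop(columns=["clone"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# synthetic spot-intensity generator
# ----------------------------------------------------------------------

def synth_spot_intensities(
    codebook: Codebook,
    n_spots: int = 5000,
    brightness_sigma: float = 0.5,
    bit_efficiency_range: Tuple[float, float] = (0.5, 1.5),
    snr: float = 8.0,
    noise_sigma: float = 0.05,
    n_marks: int = 8,
    n_sites: int = 3,
    lm_bleed: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, List[np.ndarray], pd.DataFrame]:
    """Spot intensities with the multiplicative structure the EM model assumes.

    ``X[i, b] = brightness_i * efficiency_b * on(i, b) + background_b *
    (1 - on(i, b)) + noise`` where ``background_b = efficiency_b / snr``.
    Per-site LM bit matrices use a one-hot layout (optionally with
    ``lm_bleed`` cross-hybridization into neighboring mark bits).  Returns
    (intBC intensity matrix, per-site LM matrices, ground-truth table).
    """
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, codebook.n_codes, size=n_spots)
    on = codebook.words[idx].astype(float)
    brightness = rng.lognormal(0.0, brightness_sigma, size=n_spots)
    eff = rng.uniform(*bit_efficiency_range, size=codebook.n_bits)
    background = eff / snr if np.isfinite(snr) else np.zeros_like(eff)
    X = brightness[:, None] * eff[None, :] * on + background[None, :] * (1 - on)
    if noise_sigma > 0:
        X = X + rng.normal(0, noise_sigma, size=X.shape) * brightness[:, None]
    X = np.clip(X, 0.0, None)

    lm_truth = rng.integers(0, n_marks + 1, size=(n_spots, n_sites))
    site_mats = []
    n_bits_site = n_marks + 1
    for site in range(n_sites):
        eff_s = rng.uniform(*bit_efficiency_range, size=n_bits_site)
        bg_s = eff_s / snr if np.isfinite(snr) else np.zeros_like(eff_s)
        onehot = np.zeros((n_spots, n_bits_site))
        # state code 0 (unedited) lights the last bit, code k lights bit k-1
        cols = np.where(lm_truth[:, site] == 0, n_bits_site - 1, lm_truth[:, site] - 1)
        onehot[np.arange(n_spots), cols] = 1.0
        if lm_bleed > 0:
            bleed = np.roll(onehot, 1, axis=1) * lm_bleed
            onehot = onehot + bleed
        Xs = brightness[:, None] * eff_s[None, :] * onehot + bg_s[None, :] * (1 - (onehot > 0))
        if noise_sigma > 0:
            Xs = Xs + rng.normal(0, noise_sigma, size=Xs.shape) * brightness[:, None]
        site_mats.append(np.clip(Xs, 0.0, None))

    truth = pd.DataFrame(
        {
            "spot": np.arange(n_spots),
            "intbc_index": idx,
            "intbc_id": [codebook.ids[i] for i in idx],
            **{f"lm{s + 1}": lm_truth[:, s] for s in range(n_sites)},
        }
    )
    truth.attrs["bit_efficiency"] = eff
    return X, site_mats, truth
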