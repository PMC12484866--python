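"""Mutual-information scoring of spatially variable features.

A feature (gene, cell type) is spatially informative if, inside a local
neighborhood, its expression level predicts which half of the neighborhood a
subregion falls in.  The score formalizes this: detections are rasterized
into a grid of sigma x sigma squares; per-feature counts are quantile-binned
into q levels; a neighborhood ("megasquare") is any contiguous 2K x 2K block
of squares, split either vertically or horizontally into two halves.  On the
uniform sample space Omega = megasquares x squares x {split directions}, the
score of a feature is the conditional mutual information I(X; M | C) between
the half-indicator X in {b, t, l, r} and the binned count M, given the
megasquare index C.  Constant (or spatially unstructured) features score
(near) zero; features organized along boundaries score high.  Features are
then ranked greedily by decreasing score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varifold import FeatureSpace

__all__ = [
    "GridCounts",
    "QuantileBinning",
    "MegasquareEnsemble",
    "MIScore",
    "rasterize_counts",
    "quantile_bin",
    "split_label",
    "mi_score",
    "rank_features",
    "aggregate_sections",
    "score_detections",
]


@dataclass
class GridCounts:
    """Per-square, per-feature integer detection counts on a regular grid."""

    origin: np.ndarray  # (2,) lower corner, mm
    sigma: float  # square edge, mm
    counts: np.ndarray  # (n_rows, n_cols, n_features) ints
    mask: np.ndarray  # (n_rows, n_cols) bool, squares inside tissue support
    feature_space: FeatureSpace

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.mask = np.asarray(self.mask, bool)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.mask.shape != self.counts.shape[:2]:
            raise ValueError("mask shape must match the grid")


@dataclass
class QuantileBinning:
    """Binning map phi(n) = sum_k 1{n >= t_k} from empirical q-quantiles."""

    q: int
    thresholds: np.ndarray  # (n_features, q)

    def apply(self, counts: np.ndarray) -> np.ndarray:
        """Binned grid, feature-wise; values in [0, q]."""
        t = self.thresholds  # (F, q)
        return (counts[..., None] >= t[None, None, :, :]).sum(axis=-1)


@dataclass(frozen=True)
class MegasquareEnsemble:
    """All 2K x 2K blocks fully inside a grid, with the two split directions."""

    k: int
    grid_shape: tuple[int, int]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("megasquare half-width K must be >= 1")

    @property
    def side(self) -> int:
        return 2 * self.k

    def corners(self) -> list[tuple[int, int]]:
        h, w = self.grid_shape
        s = self.side
        return [(r, c) for r in range(h - s + 1) for c in range(w - s + 1)]

    def __len__(self) -> int:
        h, w = self.grid_shape
        s = self.side
        return max(h - s + 1, 0) * max(w - s + 1, 0)


def rasterize_counts(detections: pd.DataFrame, sigma: float,
                     bbox: tuple | None = None,
                     feature_space: FeatureSpace | None = None,
                     mask: np.ndarray | None = None) -> GridCounts:
    """Histogram point detections (columns x, y, feature) into grid squares.

    Squares are half-open, [edge_k, edge_{k+1}); a detection exactly on the
    upper bbox edge joins the last square.  Totals per feature are conserved.
    """
    x = np.asarray(detections["x"], float)
    y = np.asarray(detections["y"], float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite detection coordinates")
    feats = detections["feature"].astype(str).to_numpy()
    if feature_space is None:
        feature_space = FeatureSpace(tuple(sorted(set(feats))))
    if bbox is None:
        bbox = ((x.min(), x.max()), (y.min(), y.max()))
    (x0, x1), (y0, y1) = bbox
    if np.any(x < x0) or np.any(x > x1) or np.any(y < y0) or np.any(y > y1):
        raise ValueError("detections outside the bounding box")
    n_cols = max(int(np.ceil((x1 - x0) / sigma - 1e-9)), 1)
    n_rows = max(int(np.ceil((y1 - y0) / sigma - 1e-9)), 1)
    col = np.minimum(np.floor((x - x0) / sigma).astype(int), n_cols - 1)
    row = np.minimum(np.floor((y - y0) / sigma).astype(int), n_rows - 1)
    nf = len(feature_space)
    fidx = np.array([feature_space.index(f) for f in feats])
    counts = np.zeros((n_rows, n_cols, nf), dtype=np.int64)
    np.add.at(counts, (row, col, fidx), 1)
    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    return GridCounts(np.array([x0, y0]), sigma, counts, mask, feature_space)


def quantile_bin(grid: GridCounts, q: int) -> tuple[np.ndarray, QuantileBinning]:
    """Quantile-bin each feature's counts over the occupied (masked) squares.

    Thresholds t_k = inf{t >= 0 | F(t) >= k/q} come from the empirical CDF of
    counts across masked squares; the binned value of a count n is
    phi(n) = sum_k 1{n >= t_k}.  A feature constant on the mask collapses to
    a single bin (and will score zero mutual information).
    """
    if q < 2:
        raise ValueError("need at least two quantiles")
    counts = grid.counts
    nf = counts.shape[2]
    thresholds = np.zeros((nf, q))
    masked = counts[grid.mask]  # (n_squares, F)
    n_sq = len(masked)
    for f in range(nf):
        vals = np.sort(masked[:, f])
        cdf_vals, first_idx = np.unique(vals, return_index=True)
        # F(v) for each distinct value v: fraction of squares with count <= v
        last_idx = np.concatenate([first_idx[1:], [n_sq]])
        cdf = last_idx / n_sq
        for k in range(1, q + 1):
            hit = np.searchsorted(cdf, k / q - 1e-12)
            thresholds[f, k - 1] = cdf_vals[min(hit, len(cdf_vals) - 1)]
    binning = QuantileBinning(q, thresholds)
    return binning.apply(counts), binning


def split_label(i: int, j: int, d: str, k: int) -> str:
    """Half-label of square (column i, row j) in a 2K x 2K megasquare.

    ``d`` is the split direction: "h" (left/right) gives l if i <= K else r;
    "v" (bottom/top) gives b if j <= K else t.
    """
    if not (1 <= i <= 2 * k and 1 <= j <= 2 * k):
        raise ValueError("square index outside the megasquare")
    if d in ("h", "<->", "lr"):
        return "l" if i <= k else "r"
    if d in ("v", "ud", "bt"):
        return "b" if j <= k else "t"
    raise ValueError(f"unknown split direction {d!r}")


def _half_hists(binned: np.ndarray, ens: MegasquareEnsemble, n_bins: int):
    """Histograms of binned values over each megasquare half, all corners.

    Returns array (n_corner_rows, n_corner_cols, 4, n_bins) ordered
    (l, r, b, t), computed with 2D summed-area tables per bin.
    """
    h, w = binned.shape
    k = ens.k
    s = ens.side
    onehot = (binned[:, :, None] == np.arange(n_bins)[None, None, :]).astype(np.int64)
    sat = np.zeros((h + 1, w + 1, n_bins), dtype=np.int64)
    sat[1:, 1:] = onehot.cumsum(axis=0).cumsum(axis=1)

    hr = h - s + 1
    wc = w - s + 1
    if hr <= 0 or wc <= 0:
        raise ValueError("grid too small for a single megasquare")

    def block_sum(dr0, dr1, dc0, dc1):
        # vectorized rectangle sums: rows [r+dr0, r+dr1), cols [c+dc0, c+dc1)
        return (sat[dr1: dr1 + hr, dc1: dc1 + wc]
                - sat[dr0: dr0 + hr, dc1: dc1 + wc]
                - sat[dr1: dr1 + hr, dc0: dc0 + wc]
                + sat[dr0: dr0 + hr, dc0: dc0 + wc])

    left = block_sum(0, s, 0, k)
    right = block_sum(0, s, k, s)
    bottom = block_sum(0, k, 0, s)
    top = block_sum(k, s, 0, s)
    return np.stack([left, right, bottom, top], axis=2)


@dataclass
class MIScore:
    """Per-feature conditional mutual information scores and ranking."""

    scores: dict[str, float]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


def mi_score(binned: np.ndarray, ens: MegasquareEnsemble) -> float:
    """I(X; M | C) for one feature's binned grid, natural log.

    Omega = all (megasquare, square, direction) triples with uniform
    probability; X is the half-label of the square under the direction, M the
    binned value, C the megasquare.  Nonnegative; exactly zero when M is
    constant within every megasquare half-pair.
    """
    n_bins = int(binned.max()) + 1
    k = ens.k
    hists = _half_hists(binned, ens, n_bins)  # (hr, wc, 4, n_bins)
    n_c = hists.shape[0] * hists.shape[1]
    n_half = 2 * k * k  # squares per half
    n_omega_c = 2 * (2 * k) ** 2  # |Omega| restricted to one megasquare

    p_xm = hists / n_omega_c  # P(X=x, M=m | C)
    p_m = hists.sum(axis=2, keepdims=True) / n_omega_c  # P(M=m | C)
    p_x = n_half / n_omega_c  # = 1/4 for every half-label
    ratio = np.divide(p_xm, p_x * p_m, out=np.ones_like(p_xm, dtype=float),
                      where=p_m > 0)
    terms = np.where(p_xm > 0, p_xm * np.log(np.where(ratio > 0, ratio, 1.0)),
                     0.0)
    return float(terms.sum() / n_c)


def score_detections(detections: pd.DataFrame, sigma: float = 0.05,
                     q: int = 10, k: int = 4,
                     bbox: tuple | None = None,
                     feature_space: FeatureSpace | None = None) -> MIScore:
    """Rasterize, bin, and score every feature of a detection table."""
    grid = rasterize_counts(detections, sigma, bbox, feature_space)
    binned, _ = quantile_bin(grid, q)
    ens = MegasquareEnsemble(k, grid.counts.shape[:2])
    scores = {
        label: mi_score(binned[:, :, f], ens)
        for f, label in enumerate(grid.feature_space.labels)
    }
    return MIScore(scores)


def rank_features(scores: MIScore | dict, n: int | None = None) -> list[str]:
    """Top-n feature labels by decreasing score; ties broken lexicographically."""
    d = scores.scores if isinstance(scores, MIScore) else dict(scores)
    if n is None:
        n = len(d)
    if n > len(d):
        raise ValueError("cannot select more features than are scored")
    ordered = sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
    return [label for label, _ in ordered[:n]]


def aggregate_sections(per_section: list[dict | MIScore]) -> dict[str, float]:
    """Tally per-section scores into a collective per-feature total."""
    total: dict[str, float] = {}
    for section in per_section:
        d = section.scores if isinstance(section, MIScore) else section
        for label, val in d.items():
            total[label] = total.get(label, 0.0) + float(val)
    return total
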