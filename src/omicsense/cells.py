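"""Putative-cell calling from the barcode read curve.

Barcodes are ranked by total molecule counts; the cutoff separating
cell-containing barcodes from ambient noise is the position where the
discrete second derivative of the cumulative count curve attains its
minimum.  The second derivative is evaluated on log10(cumulative) versus
log10(rank) after light moving-average smoothing, which stabilizes the knee
across library depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .matrix import CountMatrix

DEFAULT_WINDOW = 11


@dataclass
class ReadCurve:
    """Descending per-barcode totals and their cumulative sum."""

    barcodes: list[str]
    ranked_totals: np.ndarray
    cumulative: np.ndarray
    smoothing_window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.ranked_totals = np.asarray(self.ranked_totals)
        self.cumulative = np.asarray(self.cumulative)
        if np.any(np.diff(self.ranked_totals) > 0):
            raise ValueError("ranked_totals must be non-increasing")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")

    def __len__(self) -> int:
        return len(self.ranked_totals)


@dataclass
class CellCallReport:
    cutoff_rank: int
    total_at_knee: int
    n_input: int
    n_retained: int
    n_dropped: int


def rank_barcodes(
    matrix: CountMatrix,
    modality: str | Iterable[str] | None = None,
    smoothing_window: int = DEFAULT_WINDOW,
) -> ReadCurve:
    """Rank barcodes by total molecules (ties broken lexicographically)."""
    if matrix.n_barcodes < 3:
        raise ValueError("need at least 3 barcodes to build a read curve")
    totals = matrix.totals(modality)
    order = sorted(range(len(totals)), key=lambda i: (-totals[i], matrix.barcodes[i]))
    ranked = totals[order]
    return ReadCurve(
        barcodes=[matrix.barcodes[i] for i in order],
        ranked_totals=ranked,
        cumulative=np.cumsum(ranked),
        smoothing_window=smoothing_window,
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _effective_window(n: int, window: int) -> int:
    if n >= 3 * window:
        return window
    w = max(1, n // 3)
    return w if w % 2 == 1 else w - 1


def second_derivative_cutoff(curve: ReadCurve) -> int:
    """Rank k of the knee: barcodes with rank <= k are putative cells.

    The knee is the minimum of the discrete second derivative (divided
    differences on the non-uniform log10(rank) grid) of the smoothed
    log10(cumulative) curve.  Ties resolve to the smallest rank.
    """
    n = len(curve)
    if n < 2:
        raise ValueError("read curve too short")
    if n == 2:
        if curve.ranked_totals[0] == curve.ranked_totals[1]:
            raise ValueError("no knee detected: flat read curve")
        return 1
    window = _effective_window(n, curve.smoothing_window)
    if window >= n:
        raise ValueError("smoothing_window must be smaller than the number of barcodes")
    y = np.log10(np.maximum(curve.cumulative.astype(float), 1e-300))
    y = _moving_average(y, window)
    x = np.log10(np.arange(1, n + 1, dtype=float))

    left = (y[1:-1] - y[:-2]) / (x[1:-1] - x[:-2])
    right = (y[2:] - y[1:-1]) / (x[2:] - x[1:-1])
    d2 = 2.0 * (right - left) / (x[2:] - x[:-2])

    if np.allclose(d2, 0.0, atol=1e-12):
        raise ValueError("no knee detected: flat read curve")
    k = int(np.argmin(d2)) + 2  # d2[i] measures the bend at rank i+2
    return min(max(k, 1), n - 1)


def call_cells(
    matrix: CountMatrix,
    modality: str | Iterable[str] | None = None,
    smoothing_window: int = DEFAULT_WINDOW,
) -> tuple[CountMatrix, CellCallReport]:
    """Split the matrix at the knee of its read curve.

    Returns the putative-cell submatrix plus a report with the cutoff rank
    and retention bookkeeping.  Retained and dropped barcodes partition the
    input.
    """
    curve = rank_barcodes(matrix, modality, smoothing_window)
    k = second_derivative_cutoff(curve)
    keep = set(curve.barcodes[:k])
    mask = np.array([b in keep for b in matrix.barcodes])
    cells = matrix.subset_barcodes(mask)
    report = CellCallReport(
        cutoff_rank=k,
        total_at_knee=int(curve.ranked_totals[k - 1]),
        n_input=matrix.n_barcodes,
        n_retained=cells.n_barcodes,
        n_dropped=matrix.n_barcodes - cells.n_barcodes,
    )
    return cells, report
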