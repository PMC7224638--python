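"""Sample-tag demultiplexing: singlet / multiplet / undetermined calls.

A barcode is a singlet when exactly one tag reaches its minimum count
threshold and that tag holds strictly more than 75% of all tag reads; a
multiplet when two or more tags reach their thresholds; undetermined
otherwise.  Per-tag thresholds default to a background rule
(mean + 3 SD of the tag's counts in cells where it is not the top tag)
with an absolute floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

log = logging.getLogger(__name__)

SINGLET = "singlet"
MULTIPLET = "multiplet"
UNDETERMINED = "undetermined"

DEFAULT_FLOOR = 10
MAJORITY_FRACTION = 0.75


@dataclass
class DemuxCall:
    barcode: str
    call: str  # singlet | multiplet | undetermined
    assigned_tag: str | None  # defined iff singlet
    tag_fraction: float  # top tag reads / total tag reads (0 when no reads)


@dataclass
class DemuxSummary:
    """Partition bookkeeping: singlets per tag + multiplets + undetermined."""

    n_total: int
    n_multiplet: int
    n_undetermined: int
    n_singlet_per_tag: dict[str, int] = field(default_factory=dict)

    @property
    def n_singlet(self) -> int:
        return self.n_total - self.n_multiplet - self.n_undetermined

    def __post_init__(self) -> None:
        if self.n_singlet < 0:
            raise ValueError("multiplets + undetermined exceed total barcodes")
        if self.n_singlet_per_tag and sum(self.n_singlet_per_tag.values()) != self.n_singlet:
            raise ValueError("per-tag singlet counts do not sum to the singlet total")

    @classmethod
    def from_counts(cls, n_total: int, n_multiplet: int, n_undetermined: int) -> "DemuxSummary":
        return cls(n_total=n_total, n_multiplet=n_multiplet, n_undetermined=n_undetermined)

    @classmethod
    def from_per_tag(
        cls, n_singlet_per_tag: dict[str, int], n_multiplet: int = 0, n_undetermined: int = 0
    ) -> "DemuxSummary":
        n_singlet = sum(n_singlet_per_tag.values())
        return cls(
            n_total=n_singlet + n_multiplet + n_undetermined,
            n_multiplet=n_multiplet,
            n_undetermined=n_undetermined,
            n_singlet_per_tag=dict(n_singlet_per_tag),
        )


def estimate_tag_thresholds(
    tag_matrix: CountMatrix, floor: int = DEFAULT_FLOOR
) -> dict[str, int]:
    """Per-tag minimum count: max(floor(bg_mean + 3*bg_SD), floor).

    Background for a tag is its counts in cells where it is not the argmax
    tag.  A tag that tops every cell falls back to the absolute floor
    (logged).
    """
    if tag_matrix.n_features < 2:
        raise ValueError("need at least 2 sample tags")
    if tag_matrix.n_barcodes < 10:
        raise ValueError("need at least 10 cells to estimate tag background")
    counts = tag_matrix.counts
    top = np.argmax(counts, axis=1)
    thresholds: dict[str, int] = {}
    for j, name in enumerate(tag_matrix.feature_names):
        bg = counts[top != j, j]
        if bg.size == 0:
            log.warning("tag %r is the top tag in every cell; using floor %d", name, floor)
            thresholds[name] = floor
            continue
        thr = math.floor(bg.mean() + 3.0 * bg.std())
        thresholds[name] = max(thr, floor)
    return thresholds


def classify_cell(
    tag_counts: np.ndarray,
    thresholds: np.ndarray,
    tag_names: list[str],
    barcode: str = "",
) -> DemuxCall:
    """Apply the singlet/multiplet/undetermined rule to one barcode."""
    tag_counts = np.asarray(tag_counts)
    if np.any(tag_counts < 0):
        raise ValueError("tag counts must be non-negative")
    total = tag_counts.sum()
    above = np.flatnonzero(tag_counts >= np.asarray(thresholds))
    top = int(np.argmax(tag_counts))
    fraction = float(tag_counts[top] / total) if total > 0 else 0.0

    if len(above) >= 2:
        return DemuxCall(barcode, MULTIPLET, None, fraction)
    if len(above) == 1:
        j = int(above[0])
        frac_j = float(tag_counts[j] / total)
        if frac_j > MAJORITY_FRACTION:
            return DemuxCall(barcode, SINGLET, tag_names[j], frac_j)
    return DemuxCall(barcode, UNDETERMINED, None, fraction)


def demultiplex(
    matrix: CountMatrix,
    thresholds: dict[str, int] | None = None,
    floor: int = DEFAULT_FLOOR,
) -> tuple[pd.DataFrame, DemuxSummary]:
    """Classify every barcode from its sample-tag counts.

    Returns a per-barcode call table (columns ``barcode``, ``call``,
    ``assigned_tag``, ``tag_fraction``) and a :class:`DemuxSummary`.
    """
    if not np.any(matrix.modality_mask("sample_tag")):
        raise ValueError("matrix has no sample_tag features")
    tags = matrix.subset_modality("sample_tag")
    if thresholds is None:
        thresholds = estimate_tag_thresholds(tags, floor=floor)
    thr = np.array([thresholds[name] for name in tags.feature_names], dtype=float)

    counts = tags.counts
    calls = [
        classify_cell(counts[i], thr, tags.feature_names, barcode=tags.barcodes[i])
        for i in range(tags.n_barcodes)
    ]
    table = pd.DataFrame(
        {
            "barcode": [c.barcode for c in calls],
            "call": [c.call for c in calls],
            "assigned_tag": [c.assigned_tag for c in calls],
            "tag_fraction": [c.tag_fraction for c in calls],
        }
    )
    per_tag = {
        name: int(((table["call"] == SINGLET) & (table["assigned_tag"] == name)).sum())
        for name in tags.feature_names
    }
    summary = DemuxSummary(
        n_total=len(table),
        n_multiplet=int((table["call"] == MULTIPLET).sum()),
        n_undetermined=int((table["call"] == UNDETERMINED).sum()),
        n_singlet_per_tag=per_tag,
    )
    return table, summary


def singlet_matrix(matrix: CountMatrix, calls: pd.DataFrame) -> CountMatrix:
    """Matrix restricted to singlets (multiplets and undetermined excluded)."""
    singlets = set(calls.loc[calls["call"] == SINGLET, "barcode"])
    mask = np.array([b in singlets for b in matrix.barcodes])
    return matrix.subset_barcodes(mask)
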