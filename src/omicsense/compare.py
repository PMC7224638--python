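"""Targeted-panel vs whole-transcriptome detection comparison.

Detection efficiency per shared gene is the ratio of mean molecules per
cell in the targeted matrix to the whole-transcriptome (WTA) matrix.  Genes
fall into four ratio groups (boundaries configurable; only the <0.3 edge is
fixed by convention).  Also provides a simple bimodal summary for protein
markers: valley of the density on the arcsinh scale separates positive from
negative cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .matrix import CountMatrix

DEFAULT_GROUP_BOUNDARIES = (0.3, 1.0, 3.0)


@dataclass
class RatioTable:
    table: pd.DataFrame  # gene, mean_targeted, mean_wta, ratio, group
    unmatched_targeted: list[str] = field(default_factory=list)
    unmatched_wta: list[str] = field(default_factory=list)


@dataclass
class BimodalStats:
    bimodal: bool
    positive_fraction: float | None = None
    positive_mean: float | None = None  # mean raw count among positive cells
    valley: float | None = None  # valley location on the raw-count scale


def mean_molecules_per_cell(matrix: CountMatrix) -> pd.Series:
    """Arithmetic mean of molecule counts over cells, per feature."""
    if matrix.n_barcodes < 1:
        raise ValueError("need at least one cell")
    return pd.Series(
        matrix.counts.mean(axis=0), index=matrix.feature_names, name="mean_molecules"
    )


def detection_ratio(
    targeted: CountMatrix,
    wta: CountMatrix,
    gene_name_map: Mapping[str, str] | None = None,
    group_boundaries: tuple[float, float, float] = DEFAULT_GROUP_BOUNDARIES,
) -> RatioTable:
    """Per-gene targeted/WTA mean-molecule ratio with group assignment.

    Gene matching is exact after uppercasing; ``gene_name_map`` maps
    targeted names to WTA names (applied before uppercasing).  Ratios with
    zero WTA mean are flagged undefined (NaN ratio, group 0) and excluded
    from groups.  Groups: 1 = ratio < b0; 2 = [b0, b1); 3 = [b1, b2);
    4 = >= b2.
    """
    gene_name_map = dict(gene_name_map or {})
    b0, b1, b2 = group_boundaries
    if not b0 < b1 < b2:
        raise ValueError("group boundaries must be strictly increasing")

    t_rna = targeted.subset_modality("rna") if np.any(targeted.modality_mask("rna")) else targeted
    w_rna = wta.subset_modality("rna") if np.any(wta.modality_mask("rna")) else wta

    t_means = mean_molecules_per_cell(t_rna)
    w_means = mean_molecules_per_cell(w_rna)

    def canonical(name: str) -> str:
        return gene_name_map.get(name, name).upper()

    t_by_key = {canonical(n): n for n in t_means.index}
    w_by_key = {n.upper(): n for n in w_means.index}
    shared = sorted(set(t_by_key) & set(w_by_key))
    if not shared:
        raise ValueError(
            "no shared genes between targeted and WTA matrices; "
            "check gene_name_map / feature naming"
        )

    rows = []
    for key in shared:
        mt = float(t_means[t_by_key[key]])
        mw = float(w_means[w_by_key[key]])
        if mw == 0.0:
            ratio, group = np.nan, 0
        else:
            ratio = mt / mw
            if ratio < b0:
                group = 1
            elif ratio < b1:
                group = 2
            elif ratio < b2:
                group = 3
            else:
                group = 4
        rows.append({"gene": key, "mean_targeted": mt, "mean_wta": mw, "ratio": ratio, "group": group})

    table = pd.DataFrame(rows)
    return RatioTable(
        table=table,
        unmatched_targeted=sorted(set(t_by_key) - set(w_by_key)),
        unmatched_wta=sorted(set(w_by_key) - set(t_by_key)),
    )


def bimodal_positive_stats(
    counts,
    cofactor: float = 5.0,
    grid_size: int = 1024,
    min_cells: int = 50,
) -> BimodalStats:
    """Positive fraction / mean for a bimodal protein marker.

    A kernel density estimate is built on the ``asinh(count/cofactor)``
    scale; the valley is the deepest interior minimum between the two
    highest modes, and cells above it are positive.  Returns a not-bimodal
    flag when no interior minimum exists.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    if len(counts) < min_cells:
        raise ValueError(f"need at least {min_cells} cells")
    t = np.arcsinh(counts / cofactor)
    if np.ptp(t) == 0:
        return BimodalStats(bimodal=False)

    kde = gaussian_kde(t)
    grid = np.linspace(t.min(), t.max(), grid_size)
    density = kde(grid)

    maxima = argrelextrema(density, np.greater)[0]
    # include the boundary points as candidate modes
    if density[0] > density[1]:
        maxima = np.concatenate([[0], maxima])
    if density[-1] > density[-2]:
        maxima = np.concatenate([maxima, [grid_size - 1]])
    if len(maxima) < 2:
        return BimodalStats(bimodal=False)

    top2 = maxima[np.argsort(density[maxima])[-2:]]
    lo_mode, hi_mode = int(top2.min()), int(top2.max())
    if hi_mode - lo_mode < 2:
        return BimodalStats(bimodal=False)
    valley_idx = lo_mode + int(np.argmin(density[lo_mode : hi_mode + 1]))
    if valley_idx in (lo_mode, hi_mode):
        return BimodalStats(bimodal=False)

    valley_t = float(grid[valley_idx])
    positive = t > valley_t
    if not positive.any():
        return BimodalStats(bimodal=False)
    return BimodalStats(
        bimodal=True,
        positive_fraction=float(positive.mean()),
        positive_mean=float(counts[positive].mean()),
        valley=float(np.sinh(valley_t) * cofactor),
    )
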