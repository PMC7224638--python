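"""One-SENSE-style visualization for two modalities.

Each modality (protein, transcript) is reduced to a single dimension with
UMAP; cells are scattered at (protein coordinate, transcript coordinate) and
each axis is annotated with a 500-bin heatmap of per-bin median expression,
colored blue (low) -> green (mid) -> red (high), with empty bins black.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .preprocess import NormalizedMatrix

DEFAULT_N_BINS = 500

_CMAP = LinearSegmentedColormap.from_list("onesense", ["blue", "green", "red"])
_CMAP.set_bad(color="black")


@dataclass
class Embedding1D:
    coordinates: np.ndarray  # one finite value per cell
    barcodes: list[str]
    modality: str
    feature_names: list[str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).ravel()
        if len(self.coordinates) != len(self.barcodes):
            raise ValueError("one coordinate required per cell")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class BinAssignment:
    bin_index: np.ndarray  # 0-based bin per cell
    bin_edges: np.ndarray  # n_bins + 1 edges, equal widths
    counts: np.ndarray  # cells per bin

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class BinnedHeatmap:
    medians: np.ndarray  # (n_features, n_bins); NaN where empty
    empty_mask: np.ndarray  # (n_bins,) True iff bin holds zero cells
    feature_names: list[str]
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.empty_mask)


def embed_1d(
    normalized: NormalizedMatrix,
    modality: str = "",
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 42,
) -> Embedding1D:
    """One-dimensional UMAP embedding of the modality's full feature set.

    Cells are internally sorted by barcode before embedding so the result
    depends only on the barcode->values mapping, never on input row order;
    output order matches the input.
    """
    n_cells = normalized.shape[0]
    if n_cells < n_neighbors + 1:
        raise ValueError(
            f"{n_cells} cells < n_neighbors+1 ({n_neighbors + 1}); lower n_neighbors"
        )
    import umap  # deferred: heavy numba import

    order = np.argsort(np.asarray(normalized.barcodes, dtype=object))
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))

    reducer = umap.UMAP(
        n_components=1,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    coords_sorted = reducer.fit_transform(np.asarray(normalized.values)[order]).ravel()
    return Embedding1D(
        coordinates=coords_sorted[inverse],
        barcodes=list(normalized.barcodes),
        modality=modality or normalized.transform_tag,
        feature_names=list(normalized.feature_names),
        parameters={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "metric": metric,
            "seed": seed,
        },
    )


def bin_1d(embedding: Embedding1D, n_bins: int = DEFAULT_N_BINS) -> BinAssignment:
    """Assign each cell to one of ``n_bins`` equal-width bins.

    Bins are half-open ``[lo, hi)`` — a coordinate exactly on an interior
    edge belongs to the right-hand bin — and the last bin is closed.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    coords = embedding.coordinates
    lo, hi = coords.min(), coords.max()
    if hi == lo:
        raise ValueError("degenerate range: all embedding coordinates identical")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges, coords, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)  # closes the last bin
    counts = np.bincount(idx, minlength=n_bins)
    return BinAssignment(bin_index=idx, bin_edges=edges, counts=counts)


def bin_medians(
    normalized: NormalizedMatrix,
    assignment: BinAssignment,
    features: list[str] | None = None,
) -> BinnedHeatmap:
    """Per-bin, per-feature median expression; empty bins masked."""
    if features is None:
        features = list(normalized.feature_names)
    if len(features) == 0:
        raise ValueError("empty feature list")
    pos = {f: i for i, f in enumerate(normalized.feature_names)}
    missing = [f for f in features if f not in pos]
    if missing:
        raise KeyError(f"features not in matrix: {missing[:5]}")
    cols = [pos[f] for f in features]
    values = np.asarray(normalized.values)[:, cols]

    n_bins = assignment.n_bins
    medians = np.full((len(features), n_bins), np.nan)
    for b in range(n_bins):
        in_bin = assignment.bin_index == b
        if in_bin.any():
            medians[:, b] = np.median(values[in_bin], axis=0)
    empty = assignment.counts == 0
    return BinnedHeatmap(
        medians=medians,
        empty_mask=empty,
        feature_names=list(features),
        bin_edges=assignment.bin_edges,
    )


def heatmap_rgb(heatmap: BinnedHeatmap, percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """(n_features, n_bins, 4) RGBA array: blue->green->red, empty bins black.

    Each feature row is min-max scaled between its own robust percentiles
    across non-empty bins before the colormap is applied.
    """
    med = heatmap.medians
    scaled = np.full_like(med, np.nan)
    for i in range(med.shape[0]):
        row = med[i]
        finite = np.isfinite(row)
        if not finite.any():
            continue
        lo, hi = np.percentile(row[finite], percentiles)
        if hi == lo:
            scaled[i, finite] = 0.5
        else:
            scaled[i, finite] = np.clip((row[finite] - lo) / (hi - lo), 0.0, 1.0)
    masked = np.ma.masked_invalid(scaled)
    rgba = _CMAP(masked)
    rgba[np.broadcast_to(heatmap.empty_mask, med.shape)] = (0.0, 0.0, 0.0, 1.0)
    return rgba


def render_onesense(
    protein: tuple[Embedding1D, BinnedHeatmap],
    rna: tuple[Embedding1D, BinnedHeatmap],
    out_path,
    cluster_labels: dict[str, int] | None = None,
    figsize: tuple[float, float] = (12.0, 12.0),
    dpi: int = 150,
):
    """Render the combined plot: central scatter + axis-aligned heatmaps.

    Protein runs along x (heatmap below), transcript along y (heatmap on the
    left).  Both modalities must cover the identical cell set.  Returns the
    figure (also saved to ``out_path`` when given).
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    p_emb, p_heat = protein
    r_emb, r_heat = rna
    if set(p_emb.barcodes) != set(r_emb.barcodes):
        diff = set(p_emb.barcodes) ^ set(r_emb.barcodes)
        raise ValueError(f"modalities cover different cell sets ({len(diff)} cells differ)")

    # align transcript coordinates to the protein barcode order
    r_pos = {b: i for i, b in enumerate(r_emb.barcodes)}
    y = r_emb.coordinates[[r_pos[b] for b in p_emb.barcodes]]
    x = p_emb.coordinates

    fig = plt.figure(figsize=figsize)
    gs = fig.add_gridspec(
        2, 2, width_ratios=[1, 3], height_ratios=[3, 1], wspace=0.05, hspace=0.05
    )
    ax_scatter = fig.add_subplot(gs[0, 1])
    ax_bottom = fig.add_subplot(gs[1, 1], sharex=ax_scatter)
    ax_left = fig.add_subplot(gs[0, 0], sharey=ax_scatter)

    if cluster_labels is not None:
        colors = np.asarray([cluster_labels[b] for b in p_emb.barcodes])
        ax_scatter.scatter(x, y, c=colors, s=4, cmap="tab10", linewidths=0)
    else:
        ax_scatter.scatter(x, y, s=4, color="0.3", linewidths=0)
    ax_scatter.tick_params(labelbottom=False, labelleft=False)

    # protein heatmap under the x axis: features as rows, bins along x
    p_rgba = heatmap_rgb(p_heat)
    ax_bottom.imshow(
        p_rgba,
        aspect="auto",
        interpolation="nearest",
        extent=[p_heat.bin_edges[0], p_heat.bin_edges[-1], len(p_heat.feature_names), 0],
    )
    ax_bottom.set_yticks(np.arange(len(p_heat.feature_names)) + 0.5)
    ax_bottom.set_yticklabels(p_heat.feature_names, fontsize=6)
    ax_bottom.set_xlabel(f"{p_emb.modality} 1D embedding")

    # transcript heatmap left of the y axis: bins along y, features as columns
    r_rgba = heatmap_rgb(r_heat)
    ax_left.imshow(
        np.transpose(r_rgba, (1, 0, 2))[::-1],
        aspect="auto",
        interpolation="nearest",
        extent=[0, len(r_heat.feature_names), r_heat.bin_edges[0], r_heat.bin_edges[-1]],
    )
    ax_left.set_xticks(np.arange(len(r_heat.feature_names)) + 0.5)
    ax_left.set_xticklabels(r_heat.feature_names, fontsize=6, rotation=90)
    ax_left.set_ylabel(f"{r_emb.modality} 1D embedding")

    if out_path is not None:
        fig.savefig(out_path, dpi=dpi, bbox_inches="tight")
    return fig
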