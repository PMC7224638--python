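"""Synthetic multimodal datasets with known ground truth.

Everything downstream (cell calling, demultiplexing, normalization, the
One-SENSE pipeline) is exercised against data from this module, so its
distributions mirror the qualitative shape of real panel data:

* RNA: negative-binomial counts with cluster-specific means and
  per-gene Bernoulli zero-inflation (dropout),
* protein: low Poisson background for every cell plus an over-dispersed
  positive component for marker-positive cells (bimodal markers),
* sample tags: the assigned tag is strongly over-represented
  (NB, mean ~100) against a faint ambient background (Poisson, mean ~2),
* noise barcodes: totals 20-100x below true cells,
* doublets: sums of two cells from different donors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import CountMatrix

__all__ = ["SyntheticTruth", "generate_dataset", "generate_barcode_rank_curve"]


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated dataset."""

    true_cell_barcodes: set[str]
    donor_of_cell: dict[str, int]  # non-doublet true cells only
    doublet_barcodes: set[str]
    cluster_of_cell: dict[str, int]
    positive_protein_cells: set[tuple[str, str]] = field(default_factory=set)  # (feature, barcode)

    def __post_init__(self) -> None:
        if not self.doublet_barcodes <= self.true_cell_barcodes:
            raise ValueError("doublet barcodes must be true cells")
        non_doublets = self.true_cell_barcodes - self.doublet_barcodes
        if not non_doublets <= set(self.donor_of_cell):
            raise ValueError("donor must be defined for every non-doublet true cell")


def _nb(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_dataset(
    n_cells: int = 2000,
    n_noise_barcodes: int = 500,
    n_clusters: int = 4,
    n_genes: int = 60,
    n_proteins: int = 10,
    n_tags: int = 3,
    doublet_rate: float = 0.05,
    seed: int = 0,
    rna_dispersion: float = 0.5,
    protein_dispersion: float = 0.2,
    tag_mean: float = 100.0,
    tag_background_mean: float = 2.0,
    tag_dispersion: float = 0.05,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate a multimodal count matrix plus its :class:`SyntheticTruth`.

    All randomness flows from one :class:`numpy.random.Generator` seeded
    with ``seed``, so identical arguments reproduce identical matrices.
    """
    if min(n_cells, n_clusters, n_genes, n_proteins, n_tags) < 1:
        raise ValueError("all sizes must be >= 1")
    if not 0 <= doublet_rate < 1:
        raise ValueError("doublet_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    width = max(6, len(str(n_cells + n_noise_barcodes)))
    cell_bc = [f"C{i:0{width}d}" for i in range(1, n_cells + 1)]
    noise_bc = [f"N{i:0{width}d}" for i in range(1, n_noise_barcodes + 1)]

    # cluster labels: first n_clusters cells pin each cluster non-empty
    clusters = np.concatenate(
        [np.arange(1, n_clusters + 1), rng.integers(1, n_clusters + 1, size=max(0, n_cells - n_clusters))]
    )[:n_cells]

    donors = rng.integers(0, n_tags, size=n_cells)

    # --- RNA -----------------------------------------------------------
    base_mean = rng.lognormal(mean=0.7, sigma=0.8, size=n_genes)  # ~2 molecules
    fold = np.ones((n_clusters, n_genes))
    n_markers = max(1, n_genes // 5)
    for k in range(n_clusters):
        marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
        fold[k, marker_idx] = rng.uniform(3.0, 10.0, size=n_markers)
    dropout = rng.uniform(0.3, 0.8, size=n_genes)

    def draw_rna(cluster_idx: np.ndarray) -> np.ndarray:
        means = base_mean[None, :] * fold[cluster_idx - 1, :]
        counts = _nb(rng, means, rna_dispersion)
        keep = rng.random(counts.shape) >= dropout[None, :]
        return counts * keep

    # --- protein -------------------------------------------------------
    pos_clusters = [
        set(rng.choice(np.arange(1, n_clusters + 1), size=max(1, n_clusters // 2), replace=False))
        for _ in range(n_proteins)
    ]
    pos_mean = rng.lognormal(mean=np.log(200.0), sigma=0.4, size=n_proteins)
    protein_bg_mean = rng.uniform(1.0, 3.0, size=n_proteins)

    def draw_protein(cluster_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = len(cluster_idx)
        counts = rng.poisson(protein_bg_mean[None, :], size=(n, n_proteins))
        positive = np.zeros((n, n_proteins), dtype=bool)
        for j in range(n_proteins):
            mask = np.isin(cluster_idx, list(pos_clusters[j]))
            positive[:, j] = mask
            if mask.any():
                counts[mask, j] += _nb(rng, pos_mean[j], protein_dispersion, size=int(mask.sum()))
        return counts, positive

    # --- sample tags ---------------------------------------------------
    def draw_tags(donor_idx: np.ndarray) -> np.ndarray:
        n = len(donor_idx)
        counts = rng.poisson(tag_background_mean, size=(n, n_tags))
        counts[np.arange(n), donor_idx] = _nb(rng, tag_mean, tag_dispersion, size=n)
        return counts

    rna = draw_rna(clusters)
    protein, positive = draw_protein(clusters)
    tags = draw_tags(donors)

    # --- doublets: overwrite selected cells with a two-cell sum --------
    n_doublets = int(rng.binomial(n_cells, doublet_rate)) if doublet_rate > 0 else 0
    if doublet_rate > 0 and doublet_rate * n_cells < 1:
        warnings.warn("doublet_rate * n_cells < 1; generating zero doublets", stacklevel=2)
        n_doublets = 0
    doublet_idx = rng.choice(n_cells, size=n_doublets, replace=False) if n_doublets else np.array([], dtype=int)
    for i in doublet_idx:
        other_donors = [d for d in range(n_tags) if d != donors[i]]
        if not other_donors:  # single-tag run: cannot form a cross-donor doublet
            continue
        d2 = int(rng.choice(other_donors))
        c2 = int(rng.integers(1, n_clusters + 1))
        rna[i] += draw_rna(np.array([c2]))[0]
        p2, _ = draw_protein(np.array([c2]))
        protein[i] += p2[0]
        tags[i] += draw_tags(np.array([d2]))[0]

    # --- noise barcodes ------------------------------------------------
    n_features = n_genes + n_proteins + n_tags
    cell_block = np.hstack([rna, protein, tags])
    if n_noise_barcodes:
        profile = cell_block.mean(axis=0) + 1e-9
        profile = profile / profile.sum()
        cell_total = cell_block.sum(axis=1).mean()
        noise_totals = cell_total / rng.uniform(20.0, 100.0, size=n_noise_barcodes)
        noise_block = np.vstack(
            [rng.multinomial(max(1, int(round(t))), profile) for t in noise_totals]
        )
    else:
        noise_block = np.empty((0, n_features), dtype=np.int64)

    counts = np.vstack([cell_block, noise_block])
    barcodes = cell_bc + noise_bc
    gene_names = [f"G{j:03d}" for j in range(1, n_genes + 1)]
    protein_names = [f"P{j:02d}" for j in range(1, n_proteins + 1)]
    tag_names = [f"Tag{j}" for j in range(1, n_tags + 1)]
    feature_names = gene_names + protein_names + tag_names
    modalities = ["rna"] * n_genes + ["protein"] * n_proteins + ["sample_tag"] * n_tags

    matrix = CountMatrix(counts, barcodes, feature_names, modalities)

    doublet_set = {cell_bc[i] for i in doublet_idx}
    truth = SyntheticTruth(
        true_cell_barcodes=set(cell_bc),
        donor_of_cell={cell_bc[i]: int(donors[i]) for i in range(n_cells) if cell_bc[i] not in doublet_set},
        doublet_barcodes=doublet_set,
        cluster_of_cell={cell_bc[i]: int(clusters[i]) for i in range(n_cells)},
        positive_protein_cells={
            (protein_names[j], cell_bc[i])
            for i, j in zip(*np.nonzero(positive))
        },
    )
    return matrix, truth


def generate_barcode_rank_curve(
    n_cells: int,
    n_noise: int,
    cell_mean: float,
    noise_mean: float,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Per-barcode molecule totals for a curve with a knee at ``n_cells``.

    Cell totals are negative binomial around ``cell_mean`` (mild
    over-dispersion); noise totals are Poisson around ``noise_mean``.
    Returns unsorted totals plus the ground-truth cell count.
    """
    rng = np.random.default_rng(seed)
    cells = _nb(rng, cell_mean, 0.02, size=n_cells)
    noise = rng.poisson(noise_mean, size=n_noise) if n_noise else np.array([], dtype=int)
    return np.concatenate([cells, noise]), n_cells
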