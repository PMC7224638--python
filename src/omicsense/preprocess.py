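"""Modality-specific normalization, QC filtering, scaling and down-sampling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import CountMatrix

DEFAULT_SCALE_FACTOR = 10_000.0
DEFAULT_COFACTOR = 5.0
DEFAULT_CLIP = 10.0

QC_RULESETS = ("wta_inclusion", "wta_doublet_removal", "none")


@dataclass
class NormalizedMatrix:
    """Real-valued matrix produced by one of the deterministic transforms.

    ``transform_tag`` plus ``parameters`` (and ``seed`` for stochastic
    transforms) fully determine ``values`` given the input counts.
    """

    values: np.ndarray
    barcodes: list[str]
    feature_names: list[str]
    transform_tag: str  # lognorm10k | jittered_arcsinh | scaled_residual
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class QCReport:
    ruleset: str
    n_input: int
    n_kept: int
    drops_per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def log_normalize(
    matrix: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Library-size normalize then natural-log transform.

    Each value becomes ``ln(1 + count / cell_total * scale_factor)``, so a
    zero count maps to exactly zero and the per-cell pre-log sums equal the
    scale factor.  Cells with zero total counts are dropped with a warning.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = matrix.totals().astype(float)
    keep = totals > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} cells with zero total counts", stacklevel=2
        )
    counts = matrix.counts[keep].astype(float)
    totals = totals[keep]
    values = np.log1p(counts / totals[:, None] * scale_factor)
    return NormalizedMatrix(
        values=values,
        barcodes=[b for b, k in zip(matrix.barcodes, keep) if k],
        feature_names=list(matrix.feature_names),
        transform_tag="lognorm10k",
        parameters={"scale_factor": float(scale_factor)},
    )


def arcsinh_values(counts, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Plain ``asinh(count / cofactor)`` (the jitter term forced to zero)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(counts, dtype=float) / cofactor)


def jittered_arcsinh_values(
    counts, cofactor: float = DEFAULT_COFACTOR, seed: int | None = None
) -> np.ndarray:
    """``asinh((count + U(0,1)) / cofactor)`` with one uniform per entry.

    Jitter is drawn row-major from a single generator seeded with ``seed``,
    so output is order-stable and reproducible.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    counts = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(seed)
    u = rng.random(counts.shape)
    return np.arcsinh((counts + u) / cofactor)


def jittered_arcsinh(
    matrix: CountMatrix, cofactor: float = DEFAULT_COFACTOR, seed: int | None = None
) -> NormalizedMatrix:
    """Jittered arcsinh transform of a count matrix (cytometry-style)."""
    return NormalizedMatrix(
        values=jittered_arcsinh_values(matrix.counts, cofactor=cofactor, seed=seed),
        barcodes=list(matrix.barcodes),
        feature_names=list(matrix.feature_names),
        transform_tag="jittered_arcsinh",
        parameters={"cofactor": float(cofactor)},
        seed=seed,
    )


def qc_filter(
    matrix: CountMatrix,
    ruleset: str,
    mito_features: Sequence[str] = (),
    min_genes: int = 200,
    max_mito_fraction: float = 0.20,
    max_umis: int = 15_000,
    max_genes: int = 3_000,
) -> tuple[CountMatrix, QCReport]:
    """Cell-level QC filters.

    ``wta_inclusion`` keeps cells with >= ``min_genes`` detected genes and
    mito fraction <= ``max_mito_fraction``; ``wta_doublet_removal`` drops
    cells with > ``max_umis`` total UMIs, > ``max_genes`` detected genes or
    mito fraction > ``max_mito_fraction``; ``none`` passes everything
    through (targeted panels impose no per-cell gene cutoffs).
    """
    if ruleset not in QC_RULESETS:
        raise ValueError(f"unknown ruleset {ruleset!r}; expected one of {QC_RULESETS}")
    if ruleset == "none":
        return matrix, QCReport(ruleset, matrix.n_barcodes, matrix.n_barcodes, {})

    rna_mask = matrix.modality_mask("rna")
    if not rna_mask.any():  # fall back to all features if untagged
        rna_mask = np.ones(matrix.n_features, dtype=bool)
    counts = matrix.counts
    rna_counts = counts[:, rna_mask]
    rna_names = [f for f, m in zip(matrix.feature_names, rna_mask) if m]

    mito_set = set(mito_features)
    unknown = mito_set - set(rna_names)
    if unknown:
        raise ValueError(f"mito features not in matrix: {sorted(unknown)[:5]}")
    mito_cols = np.array([f in mito_set for f in rna_names])

    detected = (rna_counts > 0).sum(axis=1)
    umis = rna_counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, rna_counts[:, mito_cols].sum(axis=1) / np.maximum(umis, 1.0), 0.0)

    if ruleset == "wta_inclusion":
        rules = {
            "min_genes": detected < min_genes,
            "mito_fraction": mito_frac > max_mito_fraction,
        }
    else:  # wta_doublet_removal
        rules = {
            "max_umis": umis > max_umis,
            "max_genes": detected > max_genes,
            "mito_fraction": mito_frac > max_mito_fraction,
        }

    drop = np.zeros(matrix.n_barcodes, dtype=bool)
    drops_per_rule = {}
    for name, mask in rules.items():
        drops_per_rule[name] = int(mask.sum())
        drop |= mask

    kept = matrix.subset_barcodes(~drop)
    report = QCReport(ruleset, matrix.n_barcodes, kept.n_barcodes, drops_per_rule)
    return kept, report


def regress_and_scale(
    normalized: NormalizedMatrix,
    covariates: np.ndarray,
    clip: float = DEFAULT_CLIP,
) -> NormalizedMatrix:
    """Regress out covariates per feature, z-score the residuals, clip.

    Ordinary least squares with an intercept; residuals are standardized to
    mean 0 / SD 1 and clipped to ``±clip``.  Constant features scale to all
    zeros (SD guard).
    """
    values = np.asarray(normalized.values, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != values.shape[0]:
        raise ValueError(
            f"covariate length {cov.shape[0]} != number of cells {values.shape[0]}"
        )
    design = np.column_stack([np.ones(values.shape[0]), cov])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    sd = resid.std(axis=0)
    # residual SD at float rounding level means the feature is (numerically)
    # fully explained: scale it to zero rather than amplifying noise
    tol = 1e-10 * max(1.0, float(np.abs(values).max(initial=0.0)))
    ok = sd > tol
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(ok, (resid - resid.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
    scaled = np.clip(scaled, -clip, clip)
    return NormalizedMatrix(
        values=scaled,
        barcodes=list(normalized.barcodes),
        feature_names=list(normalized.feature_names),
        transform_tag="scaled_residual",
        parameters={"clip": float(clip), "n_covariates": cov.shape[1]},
    )


def downsample_counts(
    matrix: CountMatrix, fraction: float, seed: int | None = None
) -> CountMatrix:
    """Binomially thin every count: each molecule kept with prob ``fraction``.

    Approximates reduced sequencing depth at the molecule level.
    ``fraction=1`` is the identity.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return matrix
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(matrix.counts, fraction)
    return CountMatrix(thinned, matrix.barcodes, matrix.feature_names, matrix.modalities)
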