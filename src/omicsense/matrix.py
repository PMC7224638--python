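"""Core count-matrix container shared by every stage of the toolkit.

A :class:`CountMatrix` holds UMI-corrected molecule counts for a set of
barcodes (rows) by a set of features (columns), where each feature is tagged
with a modality: ``rna``, ``protein`` or ``sample_tag``.  Counts are always
non-negative integers; normalized/transformed values live in
:class:`omicsense.preprocess.NormalizedMatrix` instead.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

MODALITIES = ("rna", "protein", "sample_tag")

#: density below which counts are kept in CSR form internally
_SPARSE_DENSITY = 0.5


class CountMatrix:
    """Barcodes x features matrix of non-negative integer molecule counts.

    Parameters
    ----------
    counts
        ``(n_barcodes, n_features)`` array-like or scipy sparse matrix of
        non-negative integers.
    barcodes
        Unique barcode identifiers, one per row.
    feature_names
        Feature names, one per column.  Names must be unique within a
        modality.
    modalities
        Modality tag per feature, each one of ``rna`` / ``protein`` /
        ``sample_tag``.  A single string applies to all features.
    """

    def __init__(
        self,
        counts,
        barcodes: Sequence[str],
        feature_names: Sequence[str],
        modalities,
    ) -> None:
        barcodes = [str(b) for b in barcodes]
        feature_names = [str(f) for f in feature_names]
        if isinstance(modalities, str):
            modalities = [modalities] * len(feature_names)
        modalities = np.asarray([str(m) for m in modalities], dtype=object)

        if sp.issparse(counts):
            data = counts.tocsr()
            raw = data.data
        else:
            data = np.asarray(counts)
            raw = data

        if np.asarray(raw, dtype=float).size and (
            np.any(np.asarray(raw, dtype=float) < 0)
            or np.any(np.asarray(raw, dtype=float) != np.floor(np.asarray(raw, dtype=float)))
        ):
            raise ValueError("counts must be non-negative integers")

        if sp.issparse(data):
            data = data.astype(np.int64)
        else:
            data = data.astype(np.int64)
            if data.ndim != 2:
                raise ValueError("counts must be a 2-D matrix")
            # keep large sparse-ish matrices in CSR form
            if data.size > 0:
                density = np.count_nonzero(data) / data.size
                if density < _SPARSE_DENSITY and data.size > 10_000:
                    data = sp.csr_matrix(data)

        n_bc, n_ft = data.shape
        if len(barcodes) != n_bc:
            raise ValueError(f"{len(barcodes)} barcodes for {n_bc} rows")
        if len(feature_names) != n_ft:
            raise ValueError(f"{len(feature_names)} feature names for {n_ft} columns")
        if len(modalities) != n_ft:
            raise ValueError("one modality tag required per feature")

        if len(set(barcodes)) != len(barcodes):
            seen, dup = set(), None
            for b in barcodes:
                if b in seen:
                    dup = b
                    break
                seen.add(b)
            raise ValueError(f"duplicate barcode: {dup!r}")

        for m in set(modalities):
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}; expected one of {MODALITIES}")
            names_m = [f for f, mm in zip(feature_names, modalities) if mm == m]
            if len(set(names_m)) != len(names_m):
                raise ValueError(f"duplicate feature name within modality {m!r}")

        self.barcodes: list[str] = barcodes
        self.feature_names: list[str] = feature_names
        self.modalities: np.ndarray = modalities
        self._data = data

    # ------------------------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        """Dense ``(n_barcodes, n_features)`` int64 view of the counts."""
        if sp.issparse(self._data):
            return np.asarray(self._data.todense())
        return self._data

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def n_barcodes(self) -> int:
        return self._data.shape[0]

    @property
    def n_features(self) -> int:
        return self._data.shape[1]

    @property
    def features(self) -> list[tuple[str, str]]:
        """``(name, modality)`` pairs in column order."""
        return list(zip(self.feature_names, (str(m) for m in self.modalities)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        mods = {m: int(np.sum(self.modalities == m)) for m in MODALITIES if np.any(self.modalities == m)}
        return f"CountMatrix({self.n_barcodes} barcodes x {self.n_features} features, {mods})"

    # ------------------------------------------------------------------
    def modality_mask(self, modality: str | Iterable[str]) -> np.ndarray:
        if isinstance(modality, str):
            modality = (modality,)
        return np.isin(self.modalities.astype(str), list(modality))

    def subset_modality(self, modality: str | Iterable[str]) -> "CountMatrix":
        """Columns restricted to one or more modalities; barcodes unchanged."""
        mask = self.modality_mask(modality)
        idx = np.flatnonzero(mask)
        return CountMatrix(
            self._data[:, idx],
            self.barcodes,
            [self.feature_names[i] for i in idx],
            self.modalities[idx],
        )

    def subset_barcodes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Rows restricted to ``keep`` (names or boolean mask); order preserved."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(map(str, keep))
            missing = wanted - set(self.barcodes)
            if missing:
                raise KeyError(f"unknown barcodes: {sorted(missing)[:5]}")
            idx = [i for i, b in enumerate(self.barcodes) if b in wanted]
            idx = np.asarray(idx, dtype=int)
        return CountMatrix(
            self._data[idx, :],
            [self.barcodes[i] for i in idx],
            self.feature_names,
            self.modalities,
        )

    def subset_features(self, names: Sequence[str]) -> "CountMatrix":
        pos = {f: i for i, f in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        idx = np.asarray([pos[n] for n in names], dtype=int)
        return CountMatrix(
            self._data[:, idx],
            self.barcodes,
            [self.feature_names[i] for i in idx],
            self.modalities[idx],
        )

    def totals(self, modality: str | Iterable[str] | None = None) -> np.ndarray:
        """Per-barcode molecule totals, optionally over a modality subset."""
        data = self._data
        if modality is not None:
            idx = np.flatnonzero(self.modality_mask(modality))
            data = data[:, idx]
        if sp.issparse(data):
            return np.asarray(data.sum(axis=1)).ravel()
        return data.sum(axis=1)

    def total_molecules(self) -> int:
        return int(self._data.sum())


def concat_features(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Horizontally concatenate two matrices over identical barcodes."""
    if a.barcodes != b.barcodes:
        raise ValueError("matrices must share identical barcode order")
    if sp.issparse(a._data) or sp.issparse(b._data):
        data = sp.hstack([sp.csr_matrix(a._data), sp.csr_matrix(b._data)]).tocsr()
    else:
        data = np.hstack([a.counts, b.counts])
    return CountMatrix(
        data,
        a.barcodes,
        a.feature_names + b.feature_names,
        np.concatenate([a.modalities, b.modalities]),
    )
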