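"""Readers and writers for molecule-count tables, triplet matrices and FCS.

Tabular counts follow the vendor CSV convention: an optional leading block of
``#``-prefixed comment lines, a header row of feature names, then one row per
barcode with the barcode identifier in the first column.  Triplet matrices
use MatrixMarket coordinate format plus two plain-text label files.  Antibody
counts can be exported as FCS 3.1 (float32, list mode) for cytometry
software.
"""

from __future__ import annotations

import logging
import math
from io import StringIO
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import MODALITIES, CountMatrix

log = logging.getLogger(__name__)

_MODALITY_COMMENT = "#modality"


# ----------------------------------------------------------------------
# tabular counts
# ----------------------------------------------------------------------
def read_molecule_counts(
    source,
    modality_map: Mapping[str, str] | None = None,
    default_modality: str = "rna",
) -> CountMatrix:
    """Parse a molecule-count CSV into a :class:`CountMatrix`.

    ``source`` is a path or text file object.  Leading ``#`` comment lines
    are skipped; a ``#modality,...`` line written by
    :func:`write_molecule_counts` is honoured for features not covered by
    ``modality_map``.  Features with no modality information default to
    ``rna`` (logged).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()

    comment_modalities: list[str] | None = None
    body_lines = []
    in_header = True
    for line in text.splitlines():
        if in_header and line.startswith("#"):
            if line.startswith(_MODALITY_COMMENT + ","):
                comment_modalities = line.split(",")[1:]
            continue
        in_header = False
        if line.strip():
            body_lines.append(line)
    if not body_lines:
        raise ValueError("empty count table")

    df = pd.read_csv(StringIO("\n".join(body_lines)), index_col=0, dtype=str)
    feature_names = [str(c) for c in df.columns]
    barcodes = [str(b) for b in df.index]
    if len(set(barcodes)) != len(barcodes):
        dup = pd.Index(barcodes)[pd.Index(barcodes).duplicated()][0]
        raise ValueError(f"duplicate barcode: {dup!r}")

    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        try:
            vals = raw.astype(np.float64)
        except (TypeError, ValueError) as exc:
            bad = next(i for i, v in enumerate(raw) if not _is_number(v))
            raise ValueError(
                f"non-numeric count at row {barcodes[bad]!r}, column {col!r}"
            ) from exc
        bad = np.flatnonzero((vals < 0) | (vals != np.floor(vals)))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-integer or negative count {raw[i]!r} at row "
                f"{barcodes[i]!r}, column {col!r}"
            )
        counts[:, j] = vals.astype(np.int64)

    modalities = _resolve_modalities(
        feature_names, modality_map, comment_modalities, default_modality
    )
    return CountMatrix(counts, barcodes, feature_names, modalities)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _resolve_modalities(
    feature_names, modality_map, comment_modalities, default_modality
) -> list[str]:
    if comment_modalities is not None and len(comment_modalities) != len(feature_names):
        log.warning("modality comment length mismatch; ignoring it")
        comment_modalities = None
    out = []
    n_defaulted = 0
    for i, name in enumerate(feature_names):
        if modality_map is not None and name in modality_map:
            out.append(modality_map[name])
        elif comment_modalities is not None:
            out.append(comment_modalities[i])
        else:
            out.append(default_modality)
            n_defaulted += 1
    if n_defaulted:
        log.info(
            "%d features lacked a modality entry; defaulted to %r",
            n_defaulted,
            default_modality,
        )
    return out


def write_molecule_counts(matrix: CountMatrix, path, with_modality_comment: bool = True) -> None:
    """Write counts as CSV (barcode first column, feature header row)."""
    path = Path(path)
    with path.open("w") as fh:
        if with_modality_comment:
            fh.write(_MODALITY_COMMENT + "," + ",".join(map(str, matrix.modalities)) + "\n")
        df = pd.DataFrame(matrix.counts, index=matrix.barcodes, columns=matrix.feature_names)
        df.to_csv(fh, lineterminator="\n")


# ----------------------------------------------------------------------
# triplet (MatrixMarket) format
# ----------------------------------------------------------------------
def read_triplet_matrix(
    matrix_source,
    row_label_source,
    col_label_source,
    modality_map: Mapping[str, str] | None = None,
    default_modality: str = "rna",
) -> CountMatrix:
    """Read a MatrixMarket coordinate matrix plus row/column label files.

    Rows are barcodes, columns are features; omitted entries are zero and
    triplet order is irrelevant.  Indices outside the declared dimensions
    raise a :class:`ValueError`.
    """
    try:
        mat = scipy.io.mmread(str(matrix_source) if not hasattr(matrix_source, "read") else matrix_source)
    except ValueError as exc:
        raise ValueError(f"invalid triplet matrix (index out of declared dimensions?): {exc}") from exc
    barcodes = _read_labels(row_label_source)
    feature_names = _read_labels(col_label_source)
    mat = sp.coo_matrix(mat).tocsr()
    if mat.shape != (len(barcodes), len(feature_names)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match labels "
            f"({len(barcodes)} rows, {len(feature_names)} columns)"
        )
    modalities = _resolve_modalities(feature_names, modality_map, None, default_modality)
    return CountMatrix(mat, barcodes, feature_names, modalities)


def _read_labels(source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_triplet_matrix(matrix: CountMatrix, matrix_path, row_label_path, col_label_path) -> None:
    """Write counts as MatrixMarket coordinate format plus label files."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(matrix.counts))
    Path(row_label_path).write_text("\n".join(matrix.barcodes) + "\n")
    Path(col_label_path).write_text("\n".join(matrix.feature_names) + "\n")


# ----------------------------------------------------------------------
# FCS 3.1 export
# ----------------------------------------------------------------------
_FCS_NAME_LIMIT = 32


def write_fcs(
    matrix: CountMatrix,
    path,
    transform: str = "none",
    seed: int | None = None,
    cofactor: float = 5.0,
) -> None:
    """Export protein counts as an FCS 3.1 file (one event per barcode).

    ``transform`` is ``none`` (raw counts) or ``jittered_arcsinh``
    (``asinh((count + U(0,1)) / cofactor)``, reproducible under ``seed``).
    Only protein-modality features are allowed; the data segment is float32
    little-endian list mode.
    """
    if matrix.n_barcodes == 0:
        raise ValueError("FCS requires at least one event; matrix has zero barcodes")
    if not all(m == "protein" for m in matrix.modalities):
        bad = sorted({str(m) for m in matrix.modalities} - {"protein"})
        raise ValueError(f"write_fcs accepts only protein features; found modalities {bad}")
    if matrix.n_features == 0:
        raise ValueError("no protein features to export")

    if transform == "none":
        values = matrix.counts.astype(np.float32)
    elif transform == "jittered_arcsinh":
        from .preprocess import jittered_arcsinh_values

        values = jittered_arcsinh_values(matrix.counts, cofactor=cofactor, seed=seed).astype(np.float32)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    names = [_sanitize_channel_name(n) for n in matrix.feature_names]
    _write_fcs31(Path(path), values, names)


def _sanitize_channel_name(name: str) -> str:
    clean = name.replace("/", "_").replace(",", "_").strip()
    return clean[:_FCS_NAME_LIMIT] if clean else "P"


def _write_fcs31(path: Path, values: np.ndarray, channel_names: list[str]) -> None:
    n_events, n_par = values.shape
    data = values.astype("<f4").tobytes()

    keywords = {
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(channel_names, start=1):
        col_max = float(values[:, i - 1].max()) if n_events else 0.0
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(math.ceil(col_max)) + 1)

    # offsets appear inside TEXT, so pad them to fixed width and iterate once
    def build_text(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = f"{begin_data:>10d}"
        kw["$ENDDATA"] = f"{end_data:>10d}"
        parts = ["/"]
        for k, v in kw.items():
            parts.append(f"{k}/{v}/")
        return "".join(parts).encode("ascii")

    header_len = 58  # "FCS3.1    " + 6 x 8-char offsets
    text = build_text(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = build_text(data_begin, data_end)  # same length: fixed-width offsets

    def off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # beyond header capacity; TEXT carries the real offsets
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_begin) + off(text_end) + off(data_begin) + off(data_end) + off(0) + off(0)
    assert len(header) == header_len
    path.write_bytes(header + text + data)


def read_fcs(path):
    """Minimal FCS reader for round-trip verification of files we write.

    Returns ``(values, channel_names)`` with ``values`` float32 of shape
    ``(n_events, n_parameters)``.  Supports float32 list-mode files with
    little- or big-endian byte order.
    """
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.1", b"FCS3.0"):
        raise ValueError("not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    data_begin = int(kw.get("$BEGINDATA", raw[26:34]))
    data_end = int(kw.get("$ENDDATA", raw[34:42]))
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ValueError("only float32 list-mode FCS supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    payload = raw[data_begin : data_end + 1]
    values = np.frombuffer(payload, dtype=f"{order}f4", count=n_par * n_tot)
    values = values.reshape(n_tot, n_par).astype(np.float32)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return values, names
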