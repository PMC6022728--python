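"""Readers and writers for proximal spectroradiometer data and sidecar tables.

Three spectral input formats are supported:

* ASD FieldSpec binary files (``read_asd``) — the documented subset of the
  binary container: a 3-byte version magic, a little-endian header carrying
  the start wavelength, step, channel count, data-type code, payload format
  and reference flag, the spectrum block, and an optional white-reference
  block.  Raw target spectra are converted to reflectance by element-wise
  division with the reference block.
* SpectraWiz text exports (``read_spectrawiz``) — whitespace- or
  tab-delimited wavelength/value rows; leading header lines are skipped.
* Generic delimited tables (``read_generic_table``) — a matrix of merged
  spectra with wavelengths on one axis and samples on the other, orientation
  auto-detected.

Two sidecar tables accompany the spectra: a tab-delimited attribute table
keyed by filename (``read_attributes``) and a comma-delimited field-layout
matrix of filenames (``read_field_layout``).  ``export_table`` writes any
per-sample value table back out, optionally averaged over discrete
attributes.
"""

from __future__ import annotations

import io as _io
import logging
import math
import os
import struct
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CorruptFileError,
    DuplicationError,
    EmptyFileError,
    FormatError,
    KeyCollisionError,
    OrderingError,
    ParseError,
    SchemaError,
    ShapeError,
    UsageError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "AttributeTable",
    "FieldLayout",
    "read_asd",
    "read_spectrawiz",
    "read_generic_table",
    "read_attributes",
    "read_field_layout",
    "export_table",
    "write_generic_table",
    "CONTINUOUS",
    "DISCRETE",
]

CONTINUOUS = "continuous"
DISCRETE = "discrete"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One sample's reflectance trace on a wavelength grid.

    Parameters
    ----------
    sample_id : str
        Identity of the sample; defaults to the source file's basename.
    wavelengths : array-like of float
        Strictly increasing wavelengths in nm.
    reflectance : array-like of float
        Unitless reflectance, same length as ``wavelengths``.  NaN marks a
        per-channel missing value (e.g. a zero-valued reference channel).
    source_format : {"asd", "spectrawiz", "generic"}
    instrument_metadata : dict
        Free-form header information carried along from the source file.
    """

    sample_id: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    source_format: str = "generic"
    instrument_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if len(self.wavelengths) != len(self.reflectance):
            raise ValueError(
                f"length mismatch: {len(self.wavelengths)} wavelengths vs "
                f"{len(self.reflectance)} reflectance values"
            )
        if len(self.wavelengths) == 0:
            raise ValueError("spectrum must contain at least one channel")
        if np.any(np.diff(self.wavelengths) <= 0):
            bad = int(np.argmax(np.diff(self.wavelengths) <= 0)) + 1
            raise OrderingError(
                f"wavelengths not strictly increasing at position {bad} "
                f"({self.wavelengths[bad - 1]} -> {self.wavelengths[bad]})"
            )
        finite = self.reflectance[np.isfinite(self.reflectance)]
        if np.any(finite < 0):
            raise ValueError("reflectance values must be >= 0")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def equals(self, other: "Spectrum", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Grid and values equal (NaN == NaN); exact when tolerances are 0."""
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.allclose(
                self.reflectance, other.reflectance, rtol=rtol, atol=atol,
                equal_nan=True,
            )
        )


def _strip_extension(name: str) -> str:
    base = os.path.basename(name)
    stem, _ext = os.path.splitext(base)
    return stem


class AttributeTable:
    """Per-sample traits keyed by filename.

    Columns are tagged ``continuous`` when every non-missing entry parses as
    a number, ``discrete`` otherwise.  Lookup matches the exact filename
    first, then the basename without extension.
    """

    def __init__(self, data: pd.DataFrame, types: Mapping[str, str]):
        if data.index.name != "filename":
            raise SchemaError(
                f"attribute table key column must be 'filename', got "
                f"{data.index.name!r}"
            )
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise KeyCollisionError(f"duplicate filenames in attribute table: {dups}")
        unknown = set(types) - set(data.columns)
        if unknown:
            raise SchemaError(f"type tags for unknown columns: {sorted(unknown)}")
        self.data = data
        self.types = dict(types)
        # secondary index: basename without extension -> filename
        self._stem_index: dict[str, str] = {}
        for fn in data.index:
            self._stem_index.setdefault(_strip_extension(str(fn)), str(fn))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AttributeTable":
        """Build from a frame whose first column (or index) is 'filename'."""
        if df.index.name != "filename":
            if "filename" not in df.columns:
                raise SchemaError(
                    f"attribute table key column must be 'filename', got "
                    f"{df.columns[0]!r}"
                )
            df = df.set_index("filename")
        types = {}
        parsed = {}
        for col in df.columns:
            series = df[col]
            numeric = pd.to_numeric(series, errors="coerce")
            nonmissing = series.notna() & (series.astype(str).str.strip() != "")
            if (numeric.notna() | ~nonmissing).all():
                types[col] = CONTINUOUS
                parsed[col] = numeric
            else:
                types[col] = DISCRETE
                cleaned = series.where(nonmissing, other=pd.NA)
                parsed[col] = cleaned.astype("string") if cleaned.notna().any() else cleaned
        out = pd.DataFrame(parsed, index=df.index)
        return cls(out, types)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def type_of(self, column: str) -> str:
        if column not in self.types:
            from .errors import UnknownNameError

            raise UnknownNameError(f"unknown attribute {column!r}")
        return self.types[column]

    def resolve(self, sample_id: str) -> str | None:
        """Return the matching filename key for a sample id, or None."""
        if sample_id in self.data.index:
            return sample_id
        return self._stem_index.get(_strip_extension(sample_id))

    def values_for(self, sample_ids: Sequence[str], column: str) -> pd.Series:
        """Trait values aligned to ``sample_ids``; unmatched samples -> NA.

        Unmatched samples are logged and excluded from attribute-dependent
        operations only (they stay in the spectral collection).
        """
        self.type_of(column)
        out = []
        for sid in sample_ids:
            key = self.resolve(sid)
            if key is None:
                logger.warning(
                    "sample %r has no attribute-table entry; excluded from "
                    "attribute-dependent operations", sid,
                )
                out.append(pd.NA)
            else:
                out.append(self.data.at[key, column])
        return pd.Series(out, index=list(sample_ids), name=column)

    def to_file(self, path) -> str:
        df = self.data.copy()
        df.insert(0, "filename", df.index)
        df.to_csv(path, sep="\t", index=False, na_rep="")
        return str(path)


@dataclass
class FieldLayout:
    """Rectangular grid of sample filenames giving the field plan.

    ``grid`` is an ``n_rows x n_cols`` object array; empty cells hold None.
    Row 0 corresponds to the top field row (file order).
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=object)
        if grid.ndim != 2 or grid.size == 0:
            raise ShapeError("layout must be a non-empty 2-D matrix")
        grid = np.where(pd.isna(grid) | (grid == ""), None, grid)
        names = [c for c in grid.ravel() if c is not None]
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise DuplicationError(f"filename {name!r} occurs in more than one cell")
            seen.add(name)
        self.grid = grid

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def filenames(self) -> list[str]:
        return [c for c in self.grid.ravel() if c is not None]

    def to_file(self, path) -> str:
        with open(path, "w") as fh:
            for row in self.grid:
                fh.write(",".join("" if c is None else str(c) for c in row) + "\n")
        return str(path)


# --------------------------------------------------------------------------
# ASD FieldSpec binary subset
# --------------------------------------------------------------------------
#
# Layout (little-endian), shared with the fixture writer in .synthetic:
#   bytes 0-2   version magic, one of ASD_VERSIONS
#   f4          start wavelength (nm)
#   f4          wavelength step (nm)
#   i4          channel count
#   u1          data-type code: 1 = reflectance, 0 = raw target (needs ref)
#   u1          payload format: 0 = float32, 1 = float64
#   u1          reference flag: 1 = a white-reference block follows the data
#   payload     channels x (4 or 8 bytes)
#   [reference] channels x (4 or 8 bytes) if the flag is set

ASD_VERSIONS = (b"ASD", b"as6", b"as7", b"as8")
ASD_HEADER = struct.Struct("<ffiBBB")
ASD_DTYPE_RAW = 0
ASD_DTYPE_REFLECTANCE = 1


def read_asd(path) -> Spectrum:
    """Read an ASD FieldSpec binary spectrum file.

    The wavelength grid is reconstructed from the header's start wavelength,
    step and channel count.  Raw target spectra stored alongside a
    white-reference block are divided element-wise; zero-valued reference
    channels become per-channel missing values (NaN) with a logged warning.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    magic = blob[:3]
    if magic not in ASD_VERSIONS:
        raise FormatError(
            f"{path}: unrecognized ASD version magic {magic!r} "
            f"(supported: {', '.join(m.decode('latin-1') for m in ASD_VERSIONS)})"
        )
    header_end = 3 + ASD_HEADER.size
    if len(blob) < header_end:
        raise CorruptFileError(f"{path}: truncated ASD header")
    start_nm, step_nm, channels, dtype_code, fmt_code, ref_flag = ASD_HEADER.unpack(
        blob[3:header_end]
    )
    if channels <= 0:
        raise CorruptFileError(f"{path}: non-positive channel count {channels}")
    if fmt_code not in (0, 1):
        raise FormatError(f"{path}: unknown payload format code {fmt_code}")
    if dtype_code not in (ASD_DTYPE_RAW, ASD_DTYPE_REFLECTANCE):
        raise FormatError(f"{path}: unknown data-type code {dtype_code}")
    itemsize = 4 if fmt_code == 0 else 8
    np_dtype = np.dtype("<f4" if fmt_code == 0 else "<f8")
    need = channels * itemsize * (2 if ref_flag else 1)
    payload = blob[header_end:]
    if len(payload) < need:
        raise CorruptFileError(
            f"{path}: truncated data block (need {need} bytes, have {len(payload)})"
        )
    data = np.frombuffer(payload[: channels * itemsize], dtype=np_dtype).astype(float)
    wavelengths = start_nm + step_nm * np.arange(channels)
    if dtype_code == ASD_DTYPE_RAW:
        if not ref_flag:
            raise CorruptFileError(
                f"{path}: raw target spectrum without a white-reference block"
            )
        ref = np.frombuffer(
            payload[channels * itemsize: 2 * channels * itemsize], dtype=np_dtype
        ).astype(float)
        zero = ref == 0
        if zero.any():
            logger.warning(
                "%s: %d zero-valued reference channel(s); reported as missing",
                path, int(zero.sum()),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            reflectance = np.where(zero, np.nan, data / np.where(zero, 1.0, ref))
    else:
        reflectance = data
    return Spectrum(
        sample_id=os.path.basename(str(path)),
        wavelengths=wavelengths,
        reflectance=reflectance,
        source_format="asd",
        instrument_metadata={
            "version": magic.decode("latin-1"),
            "start_nm": start_nm,
            "step_nm": step_nm,
            "channels": channels,
            "data_type": "raw" if dtype_code == ASD_DTYPE_RAW else "reflectance",
        },
    )


# --------------------------------------------------------------------------
# SpectraWiz text
# --------------------------------------------------------------------------

def read_spectrawiz(path) -> Spectrum:
    """Read a SpectraWiz-style text export.

    Any leading line whose first token does not parse as a number is treated
    as a header and skipped.  The first numeric column is the wavelength,
    the second the reflectance; extra columns are ignored.
    """
    wavelengths: list[float] = []
    values: list[float] = []
    header: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.replace("\t", " ").split()
            try:
                wl = float(tokens[0])
            except ValueError:
                header.append(line)
                continue
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected two numeric columns")
            try:
                val = float(tokens[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: second column {tokens[1]!r} is not numeric"
                ) from None
            if wavelengths and wl <= wavelengths[-1]:
                raise OrderingError(
                    f"{path}:{lineno}: wavelength {wl} not greater than previous "
                    f"{wavelengths[-1]}"
                )
            wavelengths.append(wl)
            values.append(val)
    if not wavelengths:
        raise EmptyFileError(f"{path}: no numeric wavelength/value rows found")
    return Spectrum(
        sample_id=os.path.basename(str(path)),
        wavelengths=np.array(wavelengths),
        reflectance=np.array(values),
        source_format="spectrawiz",
        instrument_metadata={"header_lines": header},
    )


# --------------------------------------------------------------------------
# Generic delimited table
# --------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    # ties broken in this order
    counts = [(first_line.count(d), d) for d in ("\t", ",", ";")]
    best = max(counts, key=lambda t: t[0])
    return best[1] if best[0] > 0 else "\t"


def _all_numeric(labels: Iterable) -> bool:
    try:
        vals = [float(x) for x in labels]
    except (TypeError, ValueError):
        return False
    return all(math.isfinite(v) for v in vals)


def read_generic_table(path) -> list[Spectrum]:
    """Read a merged-spectra table; orientation is auto-detected.

    If the header row parses as numbers it is the wavelength axis (samples
    as rows); otherwise the first column is the wavelength axis (samples as
    columns, header = sample ids).  All returned spectra share one grid.
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise EmptyFileError(f"{path}: empty file")
    sep = _sniff_delimiter(first.rstrip("\n"))
    header_tokens = [t.strip() for t in first.rstrip("\n").split(sep)[1:]]
    if len(set(header_tokens)) != len(header_tokens):
        dups = sorted({t for t in header_tokens if header_tokens.count(t) > 1})
        raise KeyCollisionError(f"{path}: duplicate header entries {dups}")
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise EmptyFileError(f"{path}: no data rows")
    if _all_numeric(df.columns):
        # samples as rows, wavelengths in the header
        wl = np.array([float(c) for c in df.columns])
        sample_ids = [str(i) for i in df.index]
        matrix = df.to_numpy(dtype=float)
    elif _all_numeric(df.index):
        # wavelengths as rows, samples in the header
        wl = np.array([float(i) for i in df.index])
        sample_ids = [str(c) for c in df.columns]
        matrix = df.to_numpy(dtype=float).T
    else:
        raise ParseError(
            f"{path}: neither the header row nor the first column is numeric; "
            "cannot locate the wavelength axis"
        )
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise KeyCollisionError(f"{path}: duplicate sample ids {dups}")
    order = np.argsort(wl)
    wl = wl[order]
    matrix = matrix[:, order]
    return [
        Spectrum(sid, wl, row, source_format="generic")
        for sid, row in zip(sample_ids, matrix)
    ]


def write_generic_table(spectra: Sequence[Spectrum] | "object", path) -> str:
    """Write spectra (or a SpectralCollection) as a merged tab-delimited table.

    Layout: header ``wavelength<TAB>id1<TAB>id2...``, one row per wavelength.
    Numeric cells carry 6 significant digits.
    """
    if hasattr(spectra, "grid") and hasattr(spectra, "values"):
        grid = np.asarray(spectra.grid, dtype=float)
        ids = list(spectra.sample_ids)
        matrix = np.asarray(spectra.values, dtype=float)
    else:
        spectra = list(spectra)
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, grid):
                raise UsageError("write_generic_table requires a shared grid")
        ids = [s.sample_id for s in spectra]
        matrix = np.vstack([s.reflectance for s in spectra])
    with open(path, "w") as fh:
        fh.write("wavelength\t" + "\t".join(ids) + "\n")
        for j, wl in enumerate(grid):
            cells = [_fmt(wl)] + [_fmt(matrix[i, j]) for i in range(len(ids))]
            fh.write("\t".join(cells) + "\n")
    return str(path)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    xf = float(x)
    if xf == int(xf) and abs(xf) < 1e15:
        return str(int(xf))
    return format(xf, ".6g")


# --------------------------------------------------------------------------
# Sidecar tables
# --------------------------------------------------------------------------

def read_attributes(path) -> AttributeTable:
    """Read the tab-delimited attribute table (first column 'filename')."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty and len(df.columns) == 0:
        raise EmptyFileError(f"{path}: empty attribute table")
    if df.columns[0] != "filename":
        raise SchemaError(
            f"{path}: first column must be labelled 'filename', found "
            f"{df.columns[0]!r}"
        )
    if df["filename"].duplicated().any():
        dups = df["filename"][df["filename"].duplicated()].tolist()
        raise KeyCollisionError(f"{path}: duplicate filenames {dups}")
    return AttributeTable.from_dataframe(df)


def read_field_layout(path) -> FieldLayout:
    """Read the comma-delimited field-layout matrix (no header)."""
    rows: list[list[str | None]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if line.strip() == "" and not rows:
                continue
            cells = [c.strip() or None for c in line.split(",")]
            rows.append(cells)
    while rows and all(c is None for c in rows[-1]):
        rows.pop()
    if not rows:
        raise EmptyFileError(f"{path}: empty layout file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ShapeError(
            f"{path}: ragged layout matrix (row widths {sorted(widths)})"
        )
    return FieldLayout(np.array(rows, dtype=object))


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def export_table(
    table: pd.DataFrame,
    path,
    attributes: AttributeTable | None = None,
    aggregate_by: Sequence[str] = (),
    stat: str = "mean",
) -> str:
    """Write a samples x columns value table, optionally attribute-averaged.

    With ``aggregate_by`` non-empty, one output row is written per unique
    combination of the named discrete attributes; values are combined with
    ``stat`` (mean or median), ignoring missing entries.  Numeric cells are
    rendered with 6 significant digits.
    """
    if stat not in ("mean", "median"):
        raise UsageError(f"stat must be 'mean' or 'median', got {stat!r}")
    aggregate_by = list(aggregate_by)
    if aggregate_by:
        if attributes is None:
            raise UsageError("aggregate_by requires an attribute table")
        for name in aggregate_by:
            if attributes.type_of(name) != DISCRETE:
                raise UsageError(
                    f"attribute {name!r} is continuous; aggregation requires "
                    "discrete attributes"
                )
        keys = pd.DataFrame(
            {name: attributes.values_for(table.index, name) for name in aggregate_by}
        )
        matched = keys.notna().all(axis=1)
        grouped = (
            table[matched.to_numpy()]
            .groupby([keys[n][matched].astype(str) for n in aggregate_by])
            .agg(stat)
        )
        grouped = grouped.reset_index()
        out = grouped
    else:
        out = table.copy()
        out.insert(0, table.index.name or "sample_id", table.index)
    with open(path, "w") as fh:
        fh.write("\t".join(str(c) for c in out.columns) + "\n")
        for _, row in out.iterrows():
            fh.write(
                "\t".join(
                    str(v) if isinstance(v, str) else _fmt(v) for v in row
                )
                + "\n"
            )
    return str(path)
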