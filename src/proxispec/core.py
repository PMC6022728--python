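"""The shared spectral-collection model.

A :class:`SpectralCollection` is a samples x wavelengths reflectance matrix
on one strictly increasing integer-nm grid.  Building a collection from
spectra on different grids takes the *intersection* of the rounded grids —
no interpolation or resampling is ever performed; instruments with sub-nm
resolution must be resampled upstream.

The documented quality-control trim for the supported instruments keeps the
400–1,000 nm analysis range (:data:`ANALYSIS_RANGE_NM`); it is applied only
on request, never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyRangeError,
    IncompatibleGridsError,
    InsufficientSamplesError,
    KeyCollisionError,
    UnknownNameError,
    UsageError,
)
from .io import DISCRETE, AttributeTable, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["SpectralCollection", "build_collection", "ANALYSIS_RANGE_NM"]

#: Closed analysis interval retaining both endpoints; the edges outside it
#: have low signal-to-noise on the supported field instruments.
ANALYSIS_RANGE_NM = (400, 1000)


@dataclass
class SpectralCollection:
    """Samples x wavelengths reflectance matrix on a shared grid."""

    sample_ids: list[str]
    grid: np.ndarray
    values: np.ndarray
    attributes: AttributeTable | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            dups = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise KeyCollisionError(f"duplicate sample ids {dups}")
        if self.values.shape != (len(self.sample_ids), len(self.grid)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.grid)} wavelengths"
            )
        if len(self.grid) and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise ValueError("negative reflectance in collection")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return len(self.grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.grid)

    def to_spectra(self) -> list[Spectrum]:
        return [
            Spectrum(sid, self.grid.astype(float), row)
            for sid, row in zip(self.sample_ids, self.values)
        ]

    def band(self, wavelength_nm: int) -> np.ndarray | None:
        """Per-sample reflectance at one wavelength, or None if absent."""
        idx = np.searchsorted(self.grid, wavelength_nm)
        if idx < len(self.grid) and self.grid[idx] == wavelength_nm:
            return self.values[:, idx]
        return None

    # -- grid operations (never touch retained values) ---------------------

    def trim(self, keep_min_nm: float, keep_max_nm: float) -> "SpectralCollection":
        """Keep grid points in the closed interval [keep_min_nm, keep_max_nm]."""
        if keep_min_nm >= keep_max_nm:
            raise UsageError(
                f"trim requires keep_min_nm < keep_max_nm, got "
                f"[{keep_min_nm}, {keep_max_nm}]"
            )
        keep = (self.grid >= keep_min_nm) & (self.grid <= keep_max_nm)
        if not keep.any():
            raise EmptyRangeError(
                f"trim to [{keep_min_nm}, {keep_max_nm}] nm leaves no wavelengths "
                f"(grid spans {self.grid[0]}–{self.grid[-1]} nm)"
            )
        return replace(self, grid=self.grid[keep], values=self.values[:, keep])

    def mask(self, intervals: Sequence[Sequence[float]]) -> "SpectralCollection":
        """Remove grid points falling in any closed [lo, hi] interval."""
        remove = np.zeros(len(self.grid), dtype=bool)
        for iv in intervals:
            lo, hi = iv
            if lo >= hi:
                raise UsageError(f"mask interval [{lo}, {hi}] is not well-formed")
            remove |= (self.grid >= lo) & (self.grid <= hi)
        if remove.all():
            raise EmptyRangeError("masking removes every wavelength")
        keep = ~remove
        return replace(self, grid=self.grid[keep], values=self.values[:, keep])

    # -- summaries ---------------------------------------------------------

    def summarize(self, stat: str = "mean") -> Spectrum:
        """Per-wavelength mean, median or unbiased (n-1) variance trace."""
        if stat not in ("mean", "median", "variance"):
            raise UsageError(f"unknown summary statistic {stat!r}")
        if self.n_samples < 1:
            raise InsufficientSamplesError("summarize needs at least one sample")
        if stat == "variance":
            if self.n_samples < 2:
                raise InsufficientSamplesError(
                    "variance needs at least two samples"
                )
            trace = np.nanvar(self.values, axis=0, ddof=1)
        elif stat == "mean":
            trace = np.nanmean(self.values, axis=0)
        else:
            trace = np.nanmedian(self.values, axis=0)
        return Spectrum(stat, self.grid.astype(float), trace)

    # -- attribute-driven operations ---------------------------------------

    def group_by_attribute(self, attribute_name: str) -> dict[str, "SpectralCollection"]:
        """Partition samples by a discrete attribute's level.

        Samples with no (or missing) attribute entry form an ``"unassigned"``
        group.
        """
        if self.attributes is None:
            raise UsageError("collection has no attribute table")
        if self.attributes.type_of(attribute_name) != DISCRETE:
            raise UsageError(
                f"attribute {attribute_name!r} is continuous; grouping requires "
                "a discrete attribute"
            )
        levels = self.attributes.values_for(self.sample_ids, attribute_name)
        groups: dict[str, SpectralCollection] = {}
        order = list(dict.fromkeys(
            str(v) if not pd.isna(v) else "unassigned" for v in levels
        ))
        for level in order:
            members = [
                i for i, v in enumerate(levels)
                if (str(v) if not pd.isna(v) else "unassigned") == level
            ]
            groups[level] = replace(
                self,
                sample_ids=[self.sample_ids[i] for i in members],
                values=self.values[members],
            )
        return groups

    def remove_samples(self, sample_ids: Sequence[str]) -> "SpectralCollection":
        """Drop the named samples; attribute links for the rest are kept."""
        targets = set(sample_ids)
        unknown = targets - set(self.sample_ids)
        if unknown:
            raise UnknownNameError(f"unknown sample ids: {sorted(unknown)}")
        keep = [i for i, s in enumerate(self.sample_ids) if s not in targets]
        if not keep:
            raise InsufficientSamplesError("removing all samples leaves an empty collection")
        if targets:
            logger.info("removed %d sample(s): %s", len(targets), sorted(targets))
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in keep],
            values=self.values[keep],
        )


def build_collection(
    spectra: Sequence[Spectrum],
    attributes: AttributeTable | None = None,
) -> SpectralCollection:
    """Assemble spectra onto the intersection of their integer-nm grids.

    Grids are rounded to integer nm first (1-nm acquisition is the
    recommended resolution); each sample then contributes its measured value
    at every shared wavelength.  Nothing is interpolated: spectra with no
    common wavelength raise :class:`IncompatibleGridsError`.
    """
    spectra = list(spectra)
    if not spectra:
        raise InsufficientSamplesError("build_collection needs at least one spectrum")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise KeyCollisionError(f"duplicate sample ids {dups}")
    rounded = [np.rint(s.wavelengths).astype(int) for s in spectra]
    shared = reduce(np.intersect1d, rounded)
    if shared.size == 0:
        ranges = ", ".join(
            f"{s.sample_id}: {g[0]}–{g[-1]} nm" for s, g in zip(spectra, rounded)
        )
        raise IncompatibleGridsError(
            f"spectra share no common wavelength ({ranges}); proxispec never "
            "interpolates — harmonize grids upstream"
        )
    rows = []
    for spec, g in zip(spectra, rounded):
        pos = np.searchsorted(g, shared)
        rows.append(spec.reflectance[pos])
    return SpectralCollection(ids, shared, np.vstack(rows), attributes=attributes)
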