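"""Synthetic canopy spectra, field trials, and on-disk reader fixtures.

The generator emulates 1-nm canopy reflectance over 339–1,100 nm with the
classic shape of a healthy cereal canopy: a low visible baseline, a green
reflectance peak near 550 nm, the chlorophyll absorption dip near 670 nm,
the steep red-edge rise into a high NIR plateau, and the ~970 nm water
absorption dip.  A field trial composes one spectrum per breeding line x
fertilizer treatment x replicate, where the higher fertilizer level raises
the NIR plateau (denser canopy) and each line carries its own NIR offset.
A dry-leaf control — a smoothly rising brownish profile with no chlorophyll
dip and no red-edge step — can be planted as a known outlier.

The closed form on the integer grid is::

    R(l) = base + green * G(l; 550, 25) - chl * G(l; 670, 15)
         + plateau * logistic((l - center) / width)
         - water * G(l; 970, 20) + eps(l),   eps ~ N(0, noise_sd), clipped at 0

with G a unit-height Gaussian.  This is a pragmatic parametric model, not a
radiative-transfer simulation; it exists to exercise every pipeline stage
with realistic-looking data.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np

from .core import SpectralCollection, build_collection
from .io import (
    ASD_DTYPE_RAW,
    ASD_DTYPE_REFLECTANCE,
    ASD_HEADER,
    AttributeTable,
    DISCRETE,
    FieldLayout,
    Spectrum,
)

__all__ = [
    "GRID_NM",
    "CanopySpectrumParams",
    "TrialDesign",
    "generate_canopy_spectrum",
    "generate_dry_leaf_spectrum",
    "generate_trial",
    "write_fixture_asd",
    "write_fixture_spectrawiz",
]

#: Instrument wavelength range emulated by the generator, 1-nm step.
GRID_NM = np.arange(339, 1101)


@dataclass(frozen=True)
class CanopySpectrumParams:
    """Shape parameters of one synthetic canopy spectrum (units: nm, reflectance)."""

    base_reflectance: float = 0.04
    green_peak_amplitude: float = 0.06
    green_peak_sigma_nm: float = 25.0
    chlorophyll_dip_depth: float = 0.03
    chlorophyll_dip_sigma_nm: float = 15.0
    nir_plateau: float = 0.45
    red_edge_center_nm: float = 720.0
    red_edge_width_nm: float = 15.0
    water_dip_depth: float = 0.05
    water_dip_sigma_nm: float = 20.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "green_peak_amplitude", "chlorophyll_dip_depth", "nir_plateau",
            "water_dip_depth", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((lam - center) ** 2) / (2 * sigma**2))


def canopy_profile(params: CanopySpectrumParams, lam: np.ndarray | None = None) -> np.ndarray:
    """Noise-free closed-form canopy reflectance on the grid."""
    lam = GRID_NM.astype(float) if lam is None else np.asarray(lam, dtype=float)
    return (
        params.base_reflectance
        + params.green_peak_amplitude * _gauss(lam, 550.0, params.green_peak_sigma_nm)
        - params.chlorophyll_dip_depth * _gauss(lam, 670.0, params.chlorophyll_dip_sigma_nm)
        + params.nir_plateau
        / (1.0 + np.exp(-(lam - params.red_edge_center_nm) / params.red_edge_width_nm))
        - params.water_dip_depth * _gauss(lam, 970.0, params.water_dip_sigma_nm)
    )


def generate_canopy_spectrum(
    params: CanopySpectrumParams = CanopySpectrumParams(),
    sample_id: str = "canopy",
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One synthetic canopy spectrum; reproducible under a fixed seed."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    lam = GRID_NM.astype(float)
    r = canopy_profile(params, lam)
    if params.noise_sd > 0:
        r = r + rng.normal(0.0, params.noise_sd, lam.size)
    return Spectrum(sample_id, lam, np.clip(r, 0.0, None), source_format="generic")


def generate_dry_leaf_spectrum(
    seed: int = 0,
    sample_id: str = "dry_leaf_control",
    noise_sd: float = 0.005,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """A dry-leaf control profile: smooth brownish rise, no chlorophyll dip,
    no red-edge step — drastically different from any canopy trace."""
    rng = np.random.default_rng(seed) if rng is None else rng
    lam = GRID_NM.astype(float)
    r = 0.15 + 0.30 * (lam - lam[0]) / (lam[-1] - lam[0])
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, lam.size)
    return Spectrum(sample_id, lam, np.clip(r, 0.0, None), source_format="generic")


@dataclass(frozen=True)
class TrialDesign:
    """Design of a synthetic fertilizer trial.

    Treatments are ordered low to high; each step up adds
    ``nir_treatment_boost`` to the NIR plateau (denser canopy under more
    fertilizer).  Every line draws one NIR offset shared across treatments
    and replicates.
    """

    n_lines: int = 10
    treatments: tuple[str, ...] = ("140", "180")
    n_reps: int = 2
    nir_treatment_boost: float = 0.06
    line_effect_sd: float = 0.02
    canopy: CanopySpectrumParams = field(default_factory=CanopySpectrumParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_reps < 1 or len(self.treatments) < 1:
            raise ValueError("n_lines, n_reps >= 1 and at least one treatment required")


def generate_trial(
    design: TrialDesign = TrialDesign(),
    planted_outlier: bool = False,
) -> tuple[SpectralCollection, AttributeTable, FieldLayout]:
    """Generate a mutually consistent (collection, attributes, layout) triple.

    One spectrum per line x treatment x replicate; the attribute table has
    columns filename, line, treatment, rep; the layout has one row per
    treatment x replicate and one column per line.  With
    ``planted_outlier=True`` a dry-leaf control sample is appended to the
    collection and attribute table (it has no field plot, so it does not
    appear in the layout).
    """
    import pandas as pd

    rng = np.random.default_rng(design.seed)
    line_effects = rng.normal(0.0, design.line_effect_sd, design.n_lines)
    spectra = []
    rows = []
    layout_rows = []
    for t_idx, trt in enumerate(design.treatments):
        for rep in range(1, design.n_reps + 1):
            layout_row = []
            for line in range(1, design.n_lines + 1):
                sid = f"line{line:02d}_t{trt}_rep{rep}"
                plateau = (
                    design.canopy.nir_plateau
                    + t_idx * design.nir_treatment_boost
                    + line_effects[line - 1]
                )
                params = replace(design.canopy, nir_plateau=max(plateau, 0.0))
                spectra.append(generate_canopy_spectrum(params, sample_id=sid, rng=rng))
                rows.append(
                    {"filename": sid, "line": f"line{line:02d}",
                     "treatment": trt, "rep": f"rep{rep}"}
                )
                layout_row.append(sid)
            layout_rows.append(layout_row)
    if planted_outlier:
        sid = "dry_leaf_control"
        spectra.append(
            generate_dry_leaf_spectrum(
                sample_id=sid, noise_sd=design.canopy.noise_sd, rng=rng
            )
        )
        rows.append({"filename": sid, "line": pd.NA, "treatment": pd.NA, "rep": pd.NA})
    frame = pd.DataFrame(rows).set_index("filename")
    attributes = AttributeTable(
        frame, {"line": DISCRETE, "treatment": DISCRETE, "rep": DISCRETE}
    )
    layout = FieldLayout(np.array(layout_rows, dtype=object))
    collection = build_collection(spectra, attributes=attributes)
    return collection, attributes, layout


# --------------------------------------------------------------------------
# On-disk fixtures for the readers
# --------------------------------------------------------------------------

def write_fixture_asd(
    spectrum: Spectrum,
    path,
    raw_with_reference: np.ndarray | None = None,
    version: bytes = b"as7",
) -> str:
    """Write the canonical ASD binary fixture (float64 payload).

    By default the reflectance is stored directly (data-type code 1).  Pass
    ``raw_with_reference`` (a per-channel white-reference trace) to store a
    raw target block ``reflectance * reference`` plus the reference block,
    exercising the on-read target/reference division.
    """
    wl = spectrum.wavelengths
    step = float(wl[1] - wl[0]) if len(wl) > 1 else 1.0
    if len(wl) > 1 and not np.allclose(np.diff(wl), step):
        raise ValueError("ASD fixtures require a uniform wavelength step")
    with open(path, "wb") as fh:
        fh.write(version)
        if raw_with_reference is None:
            fh.write(ASD_HEADER.pack(float(wl[0]), step, len(wl),
                                     ASD_DTYPE_REFLECTANCE, 1, 0))
            fh.write(np.asarray(spectrum.reflectance, dtype="<f8").tobytes())
        else:
            ref = np.asarray(raw_with_reference, dtype="<f8")
            if ref.shape != spectrum.reflectance.shape:
                raise ValueError("reference trace length mismatch")
            fh.write(ASD_HEADER.pack(float(wl[0]), step, len(wl),
                                     ASD_DTYPE_RAW, 1, 1))
            fh.write((np.asarray(spectrum.reflectance, dtype="<f8") * ref).tobytes())
            fh.write(ref.tobytes())
    return str(path)


def write_fixture_spectrawiz(spectrum: Spectrum, path) -> str:
    """Write a SpectraWiz-style text fixture (6 significant digits)."""
    with open(path, "w") as fh:
        fh.write("SpectraWiz text export fixture\n")
        fh.write(f"sample: {spectrum.sample_id}\n")
        for wl, val in zip(spectrum.wavelengths, spectrum.reflectance):
            fh.write(f"{wl:.6g} {val:.6g}\n")
    return str(path)
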