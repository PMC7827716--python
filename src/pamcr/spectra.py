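"""Endmember spectra: parametric models, normalization, LSPR geometry.

Gold nanorods (GNRs) owe their photoacoustic contrast to the longitudinal
surface plasmon resonance (LSPR), a single NIR absorption band whose peak
wavelength is set by the rod aspect ratio and the refractive index of the
surrounding medium (Link's empirical relation).  This module provides:

* the aspect-ratio <-> LSPR-wavelength conversion,
* parametric single-peak endmembers (Lorentzian by default — plasmon
  bands are near-Lorentzian — or Gaussian) used by the phantom generator,
* analytic stand-ins for blood and tissue background spectra, and
* the max-to-1 normalization applied to initial spectra before MCR-ALS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypercube import WavelengthGrid

__all__ = [
    "LINK_INTERCEPT_NM",
    "LINK_SLOPE_NM",
    "LINK_OFFSET",
    "WATER_EPSILON_M",
    "EndmemberSpectrum",
    "LsprModel",
    "aspect_ratio",
    "lspr_wavelength",
    "lorentzian_endmember",
    "normalize_max",
    "blood_endmember",
    "tissue_background",
    "read_endmember_library",
    "write_endmember_library",
]

# Constants of Link's empirical LSPR relation:
#   AR = (lambda_max - 495.14) / (53.71 * eps_m) + 0.79
LINK_INTERCEPT_NM = 495.14
LINK_SLOPE_NM = 53.71
LINK_OFFSET = 0.79
#: refractive-index term of water used throughout.
WATER_EPSILON_M = 1.77


def aspect_ratio(lambda_max_nm: float, epsilon_m: float = WATER_EPSILON_M) -> float:
    """Nanorod aspect ratio from its LSPR peak wavelength.

    Parameters
    ----------
    lambda_max_nm : float
        LSPR peak wavelength in nm.
    epsilon_m : float
        Refractive-index term of the medium (1.77 for water).
    """
    if epsilon_m <= 0:
        raise ValueError("epsilon_m must be positive")
    return (lambda_max_nm - LINK_INTERCEPT_NM) / (LINK_SLOPE_NM * epsilon_m) + LINK_OFFSET


def lspr_wavelength(aspect_ratio_: float, epsilon_m: float = WATER_EPSILON_M) -> float:
    """LSPR peak wavelength (nm) from the aspect ratio; inverse of
    :func:`aspect_ratio`."""
    if epsilon_m <= 0:
        raise ValueError("epsilon_m must be positive")
    if aspect_ratio_ < LINK_OFFSET:
        raise ValueError(f"aspect ratio must be >= {LINK_OFFSET}")
    return LINK_INTERCEPT_NM + LINK_SLOPE_NM * epsilon_m * (aspect_ratio_ - LINK_OFFSET)


@dataclass
class EndmemberSpectrum:
    """A named pure-component spectrum on a wavelength grid."""

    name: str
    grid: WavelengthGrid
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (len(self.grid),):
            raise ValueError(
                f"amplitude length {self.amplitude.shape} does not match grid "
                f"({len(self.grid)} wavelengths)"
            )
        if (self.amplitude < 0).any():
            raise ValueError(f"endmember {self.name!r} has negative amplitude")

    def value_at(self, wavelength_nm: float) -> float:
        return float(self.amplitude[self.grid.index_of(wavelength_nm)])


@dataclass(frozen=True)
class LsprModel:
    """Single-band plasmon resonance: peak position, FWHM, amplitude.

    Default FWHM of 120 nm gives the partial overlap between neighbouring
    GNR bands (688/820/940 nm) that makes the unmixing problem non-trivial
    without destroying identifiability.
    """

    lambda_max_nm: float
    width_nm: float = 120.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm (FWHM) must be positive")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")


def lorentzian_endmember(
    model: LsprModel,
    grid: WavelengthGrid,
    name: str | None = None,
    shape: str = "lorentzian",
) -> EndmemberSpectrum:
    """Parametric single-peak endmember for a plasmon band.

    ``shape`` selects a Lorentzian (default) or Gaussian profile; both peak
    at ``lambda_max_nm`` with value ``peak_amplitude`` and have the stated
    full width at half maximum.
    """
    lam = grid.values
    half = model.width_nm / 2.0
    if shape == "lorentzian":
        amp = model.peak_amplitude / (1.0 + ((lam - model.lambda_max_nm) / half) ** 2)
    elif shape == "gaussian":
        sigma = model.width_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        amp = model.peak_amplitude * np.exp(
            -0.5 * ((lam - model.lambda_max_nm) / sigma) ** 2
        )
    else:
        raise ValueError(f"unknown peak shape {shape!r}")
    if name is None:
        name = f"gnr_{model.lambda_max_nm:.0f}nm"
    return EndmemberSpectrum(name, grid, amp)


def normalize_max(spectrum: EndmemberSpectrum) -> EndmemberSpectrum:
    """Scale a spectrum so its maximum is 1 (shape preserved).

    This is the normalization applied to initial spectra before the
    alternating least squares run; it resolves the bilinear scale
    ambiguity by putting all magnitude into the abundances.
    """
    peak = spectrum.amplitude.max()
    if peak <= 0:
        raise ValueError(f"cannot normalize all-zero spectrum {spectrum.name!r}")
    return EndmemberSpectrum(spectrum.name, spectrum.grid, spectrum.amplitude / peak)


# Blood template parameters: the deoxygenated-dominant profile peaks at
# 684 nm and decays through the NIR-I window; the decay constant puts its
# 862 nm value at 2% of peak, below the ~5% cross-signal level seen in
# blood-dominated tissue regions.
_BLOOD_PEAK_NM = 684.0
_BLOOD_862_FRACTION = 0.02
_BLOOD_DECAY_NM = (862.0 - _BLOOD_PEAK_NM) / np.log(1.0 / _BLOOD_862_FRACTION)
_BLOOD_RISE_NM = 20.0  # gentle roll-off below the 684 nm peak


def blood_endmember(kind: str, grid: WavelengthGrid) -> EndmemberSpectrum:
    """Analytic blood-like endmember.

    ``kind='deoxy'``: deoxygenated-dominant whole-blood template peaking at
    684 nm and decaying through the NIR-I window (liver lateral lobes).
    ``kind='oxy'``: oxygenated template rising gently towards longer
    wavelengths.  Both are smooth stand-ins, not measured spectra.
    """
    lam = grid.values
    if not (600 <= lam[0] and lam[-1] <= 1100):
        raise ValueError("blood template is defined for grids within 600-1100 nm")
    if kind == "deoxy":
        amp = np.where(
            lam >= _BLOOD_PEAK_NM,
            np.exp(-(lam - _BLOOD_PEAK_NM) / _BLOOD_DECAY_NM),
            np.exp(-0.5 * ((lam - _BLOOD_PEAK_NM) / _BLOOD_RISE_NM) ** 2),
        )
    elif kind == "oxy":
        span = lam[-1] - lam[0]
        amp = 0.3 + 0.7 * (lam - lam[0]) / span
    else:
        raise ValueError(f"unknown blood kind {kind!r}; use 'deoxy' or 'oxy'")
    return EndmemberSpectrum(f"blood_{kind}", grid, amp)


def tissue_background(grid: WavelengthGrid, level: float) -> EndmemberSpectrum:
    """Flat, wavelength-nonspecific tissue background at the given level."""
    if level < 0:
        raise ValueError("background level must be non-negative")
    return EndmemberSpectrum("tissue", grid, np.full(len(grid), float(level)))


def write_endmember_library(
    endmembers: list[EndmemberSpectrum], path
) -> None:
    """Write endmembers as CSV: wavelength_nm column + one column per name."""
    grid = endmembers[0].grid
    for e in endmembers[1:]:
        if e.grid != grid:
            raise ValueError("all endmembers must share one wavelength grid")
    df = pd.DataFrame({"wavelength_nm": grid.values})
    for e in endmembers:
        df[e.name] = e.amplitude
    df.to_csv(path, index=False)


def read_endmember_library(path) -> list[EndmemberSpectrum]:
    """Read an endmember CSV written by :func:`write_endmember_library`."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing wavelength_nm column")
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    if len(lam) < 2:
        raise ValueError(f"{path}: need at least two wavelengths")
    step = lam[1] - lam[0]
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), float(step))
    if not np.allclose(grid.values, lam):
        raise ValueError(f"{path}: wavelengths are not evenly spaced")
    return [
        EndmemberSpectrum(str(col), grid, df[col].to_numpy(dtype=float))
        for col in df.columns
        if col != "wavelength_nm"
    ]
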