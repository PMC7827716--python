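"""Synthetic hyperspectral PA scenes with known ground truth.

Three scene families mirror the experimental designs the pipeline is
meant for:

* ``tube_phantom`` — a net of parallel tubes, each filled with one gold
  nanorod (GNR) batch (LSPR peaks 688/820/940 nm by default), on a dark
  background: the controlled test object used to harvest pure spectra.
* ``bio_phantom`` — soft-edged boluses of each GNR batch injected into a
  tissue slab with a weak flat background everywhere.
* ``liver_phantom`` — three lobes: the central one dominated by a GNR
  endmember, the lateral ones by a deoxygenated-blood template, with a
  small calibrated cross-talk fraction of the minority component in each
  lobe (see :func:`calibrate_cross_talk`).

Every phantom stores its true abundances and endmembers, so the noiseless
cube equals the bilinear product exactly and the generator is bit-for-bit
reproducible from its seed.  Noise is additive i.i.d. Gaussian with a
standard deviation expressed relative to the noiseless scene maximum,
clipped at zero (PA amplitudes are non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import HyperCube, WavelengthGrid, make_grid
from .spectra import (
    EndmemberSpectrum,
    LsprModel,
    blood_endmember,
    lorentzian_endmember,
    tissue_background,
)

__all__ = [
    "DEFAULT_GRID",
    "PhantomScene",
    "tube_phantom",
    "bio_phantom",
    "liver_phantom",
    "calibrate_cross_talk",
    "photostability_series",
    "concentration_series",
]

#: the NIR-I acquisition grid: 680-970 nm in 2 nm steps (146 wavelengths)
DEFAULT_GRID = make_grid(680.0, 970.0, 2.0)

DEFAULT_LSPR_PEAKS_NM = (688.0, 820.0, 940.0)


@dataclass
class PhantomScene:
    """Ground truth for one synthetic scene.

    ``true_C`` is (height, width, components); the noiseless cube is the
    pixel-wise product ``true_C @ S`` with S the stacked endmember
    spectra.  ``noise_sigma`` is the additive Gaussian standard deviation
    relative to the noiseless scene maximum.
    """

    grid: WavelengthGrid
    shape: tuple[int, int]
    endmembers: list[EndmemberSpectrum]
    true_C: np.ndarray
    noise_sigma: float
    seed: int
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_C = np.asarray(self.true_C, dtype=float)
        h, w = self.shape
        if self.true_C.shape != (h, w, len(self.endmembers)):
            raise ValueError(
                f"true_C shape {self.true_C.shape} inconsistent with scene "
                f"{self.shape} x {len(self.endmembers)} components"
            )
        if (self.true_C < 0).any():
            raise ValueError("true concentrations must be non-negative")

    @property
    def spectra_matrix(self) -> np.ndarray:
        """(components x wavelengths) stacked endmember spectra."""
        return np.stack([e.amplitude for e in self.endmembers])

    def noiseless_cube(self, dataset_id: str = "phantom") -> HyperCube:
        values = self.true_C @ self.spectra_matrix
        return HyperCube(values, self.grid, dataset_id=dataset_id)

    def cube(self, dataset_id: str = "phantom") -> HyperCube:
        """Noisy realization, reproducible from the stored seed."""
        clean = self.true_C @ self.spectra_matrix
        if self.noise_sigma > 0:
            rng = np.random.default_rng(self.seed)
            sigma = self.noise_sigma * clean.max()
            clean = clean + rng.normal(0.0, sigma, size=clean.shape)
            np.clip(clean, 0.0, None, out=clean)
        return HyperCube(clean, self.grid, dataset_id=dataset_id)

    def true_maps(self) -> np.ndarray:
        """(components, height, width) ground-truth abundance images."""
        return np.moveaxis(self.true_C, 2, 0)


def _default_tube_geometry(
    shape: tuple[int, int], n_tubes: int
) -> list[tuple[int, int, int, int]]:
    """Evenly spaced horizontal bands: (row0, col0, height, width)."""
    h, w = shape
    band = max(2, h // (2 * n_tubes + 1))
    gap = (h - n_tubes * band) // (n_tubes + 1)
    margin = max(1, w // 10)
    return [
        (gap + i * (band + gap), margin, band, w - 2 * margin)
        for i in range(n_tubes)
    ]


def _check_no_overlap(masks: list[np.ndarray]) -> None:
    total = np.zeros_like(masks[0], dtype=int)
    for m in masks:
        total += m.astype(int)
    if (total > 1).any():
        raise ValueError("tube regions overlap; pass allow_overlap=True to permit")


def tube_phantom(
    shape: tuple[int, int] = (64, 64),
    grid: WavelengthGrid = DEFAULT_GRID,
    lspr_peaks_nm: tuple[float, ...] = DEFAULT_LSPR_PEAKS_NM,
    tube_geometry: list[tuple[int, int, int, int]] | None = None,
    concentrations: tuple[float, ...] | None = None,
    noise_sigma: float = 0.01,
    seed: int = 0,
    allow_overlap: bool = False,
    peak_shape: str = "lorentzian",
) -> tuple[PhantomScene, HyperCube]:
    """Tube test object: one GNR batch per tube, near-zero background."""
    n = len(lspr_peaks_nm)
    if tube_geometry is None:
        tube_geometry = _default_tube_geometry(shape, n)
    if len(tube_geometry) != n:
        raise ValueError("need one tube region per LSPR peak")
    if concentrations is None:
        concentrations = tuple(1.0 for _ in lspr_peaks_nm)
    h, w = shape
    masks = []
    for r0, c0, th, tw in tube_geometry:
        if r0 < 0 or c0 < 0 or r0 + th > h or c0 + tw > w:
            raise ValueError(f"tube ({r0},{c0},{th},{tw}) outside frame {shape}")
        m = np.zeros(shape, dtype=bool)
        m[r0 : r0 + th, c0 : c0 + tw] = True
        masks.append(m)
    if not allow_overlap:
        _check_no_overlap(masks)
    endmembers = [
        lorentzian_endmember(LsprModel(p), grid, shape=peak_shape)
        for p in lspr_peaks_nm
    ]
    true_C = np.zeros((h, w, n))
    for i, (m, conc) in enumerate(zip(masks, concentrations)):
        true_C[m, i] = conc
    scene = PhantomScene(
        grid, shape, endmembers, true_C, noise_sigma, seed,
        labels={e.name: m for e, m in zip(endmembers, masks)},
    )
    return scene, scene.cube(dataset_id="tube")


def bio_phantom(
    shape: tuple[int, int] = (64, 64),
    grid: WavelengthGrid = DEFAULT_GRID,
    bolus_specs: list[tuple[float, float, float, float]] | None = None,
    lspr_peaks_nm: tuple[float, ...] = DEFAULT_LSPR_PEAKS_NM,
    tissue_level: float = 0.02,
    noise_sigma: float = 0.01,
    seed: int = 1,
    edge_softness: float = 0.25,
    peak_shape: str = "lorentzian",
) -> tuple[PhantomScene, HyperCube]:
    """Tissue slab with soft-edged GNR boluses over a flat background.

    ``bolus_specs`` entries are (row_center, col_center, radius,
    concentration), one per LSPR peak; defaults place the boluses on a
    diagonal.  Bolus profiles fall off as a Gaussian of width
    ``edge_softness * radius`` beyond the disk edge.
    """
    h, w = shape
    n = len(lspr_peaks_nm)
    if bolus_specs is None:
        r = min(h, w) / 8
        bolus_specs = [
            ((i + 1) * h / (n + 1), (i + 1) * w / (n + 1), r, 1.0)
            for i in range(n)
        ]
    if len(bolus_specs) != n:
        raise ValueError("need one bolus spec per LSPR peak")
    rows, cols = np.mgrid[0:h, 0:w]
    endmembers = [
        lorentzian_endmember(LsprModel(p), grid, shape=peak_shape)
        for p in lspr_peaks_nm
    ]
    endmembers.append(tissue_background(grid, 1.0))
    true_C = np.zeros((h, w, n + 1))
    for i, (rc, cc, radius, conc) in enumerate(bolus_specs):
        if not (0 <= rc < h and 0 <= cc < w):
            raise ValueError(f"bolus centre ({rc},{cc}) outside frame {shape}")
        dist = np.hypot(rows - rc, cols - cc)
        soft = max(edge_softness * radius, 1e-9)
        profile = np.where(
            dist <= radius,
            1.0,
            np.exp(-0.5 * ((dist - radius) / soft) ** 2),
        )
        true_C[:, :, i] = conc * profile
    true_C[:, :, n] = tissue_level
    scene = PhantomScene(grid, shape, endmembers, true_C, noise_sigma, seed)
    return scene, scene.cube(dataset_id="bio")


def calibrate_cross_talk(
    gnr: EndmemberSpectrum,
    blood: EndmemberSpectrum,
    central_ratio: float = 0.013,
    lateral_ratio: float = 0.05,
    low_nm: float = 684.0,
    high_nm: float = 862.0,
) -> tuple[float, float]:
    """Solve the lobe mixing fractions from two cross-signal ratio targets.

    The central (GNR-dominated) lobe spectrum is ``g + cb * b`` and the
    lateral (blood-dominated) lobes are ``b + cg * g``.  The fractions are
    chosen so that, on the noiseless scene,

    * the central lobe's signal at ``low_nm`` is ``central_ratio`` of its
      signal at ``high_nm`` (default 1.3%), and
    * the lateral lobes' signal at ``high_nm`` is ``lateral_ratio`` of
      their signal at ``low_nm`` (default 5%).

    Returns ``(blood_in_central, gnr_in_lateral)``.  Raises if the
    endmember shapes make a target unreachable with non-negative
    fractions (e.g. a GNR band so broad that its own ``low_nm`` tail
    already exceeds the central target).
    """
    g_lo, g_hi = gnr.value_at(low_nm), gnr.value_at(high_nm)
    b_lo, b_hi = blood.value_at(low_nm), blood.value_at(high_nm)
    cb = (central_ratio * g_hi - g_lo) / (b_lo - central_ratio * b_hi)
    cg = (lateral_ratio * b_lo - b_hi) / (g_hi - lateral_ratio * g_lo)
    if cb < 0 or cg < 0:
        raise ValueError(
            "cross-talk calibration infeasible: endmember values at "
            f"{low_nm}/{high_nm} nm (gnr {g_lo:.3g}/{g_hi:.3g}, blood "
            f"{b_lo:.3g}/{b_hi:.3g}) cannot reach ratios "
            f"{central_ratio}/{lateral_ratio} with non-negative fractions"
        )
    return cb, cg


def _default_lobe_geometry(
    shape: tuple[int, int]
) -> list[tuple[float, float, float, float]]:
    """Three side-by-side half-ellipses: (row_center, col_center, a, b)."""
    h, w = shape
    b = w / 8.0
    a = h / 3.0
    row_c = 0.65 * h
    return [(row_c, (2 * i + 1) * w / 6.0, a, b) for i in range(3)]


def liver_phantom(
    shape: tuple[int, int] = (64, 64),
    grid: WavelengthGrid = DEFAULT_GRID,
    lobe_geometry: list[tuple[float, float, float, float]] | None = None,
    gnr_peak_nm: float = 820.0,
    gnr_fwhm_nm: float = 90.0,
    blood_kind: str = "deoxy",
    cross_talk: tuple[float, float] | None = None,
    noise_sigma: float = 0.01,
    seed: int = 2,
) -> tuple[PhantomScene, HyperCube]:
    """Liver-like scene: GNR-dominated central lobe, blood-dominated
    lateral lobes.

    The GNR endmember is a Gaussian band (narrower than the tube-phantom
    Lorentzians: in-tissue PA spectra are dominated by the resonance
    core) and the blood endmember the deoxygenated template peaking at
    684 nm.  ``cross_talk = (blood_in_central, gnr_in_lateral)`` defaults
    to the exact solution of :func:`calibrate_cross_talk`, which makes
    the noiseless lobe-mean spectra reproduce the 1.3% / 5% cross-signal
    ratios at 684 vs 862 nm.  If either calibration wavelength is absent
    from the grid the calibration is skipped with a warning and zero
    cross-talk is used.
    """
    import warnings

    h, w = shape
    if lobe_geometry is None:
        lobe_geometry = _default_lobe_geometry(shape)
    if len(lobe_geometry) != 3:
        raise ValueError("liver phantom needs exactly three lobes")
    gnr = lorentzian_endmember(
        LsprModel(gnr_peak_nm, width_nm=gnr_fwhm_nm), grid,
        name="gnr", shape="gaussian",
    )
    blood = blood_endmember(blood_kind, grid)
    if cross_talk is None:
        try:
            grid.index_of(684.0)
            grid.index_of(862.0)
        except ValueError:
            warnings.warn(
                "684/862 nm not on the grid; skipping cross-talk calibration "
                "(using zero cross-talk)",
                stacklevel=2,
            )
            cross_talk = (0.0, 0.0)
        else:
            cross_talk = calibrate_cross_talk(gnr, blood)
    blood_in_central, gnr_in_lateral = cross_talk
    rows, cols = np.mgrid[0:h, 0:w]
    masks = []
    for rc, cc, a, b in lobe_geometry:
        inside = ((rows - rc) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0
        inside &= rows <= rc  # upper half-ellipse
        masks.append(inside)
    true_C = np.zeros((h, w, 2))  # component 0 = gnr, 1 = blood
    for i, m in enumerate(masks):
        if i == 1:  # central lobe
            true_C[m, 0] += 1.0
            true_C[m, 1] += blood_in_central
        else:
            true_C[m, 1] += 1.0
            true_C[m, 0] += gnr_in_lateral
    scene = PhantomScene(
        grid, shape, [gnr, blood], true_C, noise_sigma, seed,
        labels={"central_lobe": masks[1], "lateral_lobes": masks[0] | masks[2]},
    )
    return scene, scene.cube(dataset_id="liver")


def photostability_series(
    endmember: EndmemberSpectrum | None,
    n_shots: int,
    cv_target_percent: float,
    snr_target: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary PA signal series under repeated laser shots.

    The signal series has mean equal to the endmember's peak amplitude
    (1.0 when ``endmember`` is None) and standard deviation set by the
    target coefficient of variation; the background noise series is
    zero-mean with standard deviation ``mean / snr_target``, so the
    expected CV and SNR of the pair equal the targets.
    """
    if n_shots < 2:
        raise ValueError("need at least two shots")
    if cv_target_percent < 0 or snr_target <= 0:
        raise ValueError("targets must be positive (cv may be zero)")
    mean = float(endmember.amplitude.max()) if endmember is not None else 1.0
    rng = np.random.default_rng(seed)
    signal = mean + rng.normal(0.0, mean * cv_target_percent / 100.0, n_shots)
    noise = rng.normal(0.0, mean / snr_target, n_shots)
    return signal, noise


def concentration_series(
    endmember: EndmemberSpectrum,
    concentrations,
    noise_sigma: float = 0.01,
    seed: int = 0,
    n_repeats: int = 100,
) -> np.ndarray:
    """Mean PA signal per concentration level (signal linear in
    concentration, additive Gaussian noise relative to the largest
    expected signal)."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least three concentration levels")
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    peak = endmember.amplitude.max()
    expected = conc * peak
    rng = np.random.default_rng(seed)
    sigma = noise_sigma * expected.max()
    samples = expected[:, None] + rng.normal(0.0, sigma, (conc.size, n_repeats))
    if noise_sigma == 0:
        return expected
    return samples.mean(axis=1)
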