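"""Hyperspectral photoacoustic image cubes and their matrix form.

A photoacoustic (PA) acquisition sweeps a pulsed laser over a wavelength
grid (typically 680-970 nm in 2 nm steps) and records one image per
wavelength, giving a height x width x wavelength cube of PA amplitudes.
Multivariate curve resolution operates on the *unfolded* form: a
(pixels x wavelengths) matrix where every row is one pixel's spectrum.
Several acquisitions sharing a wavelength grid can be stacked row-wise
into a single augmented ("multiset") matrix and factored simultaneously;
a :class:`MultisetIndex` keeps the bookkeeping needed to fold abundance
columns back into per-acquisition images.

Cubes are stored on disk as multi-page 32-bit float TIFF stacks (one page
per wavelength) with a JSON sidecar carrying the wavelength grid and a
dataset label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "MultisetIndex",
    "UnfoldedMatrix",
    "ROI",
    "make_grid",
    "unfold",
    "refold",
    "augment_rowwise",
    "read_cube",
    "write_cube",
    "extract_roi_mean_spectrum",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced, endpoint-inclusive wavelength axis in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.stop_nm <= self.start_nm:
            raise ValueError(
                f"stop_nm ({self.stop_nm}) must exceed start_nm ({self.start_nm})"
            )
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = self.stop_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"wavelength range {self.start_nm}-{self.stop_nm} nm is not "
                f"divisible by step {self.step_nm} nm"
            )

    @property
    def values(self) -> np.ndarray:
        n = len(self)
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def index_of(self, wavelength_nm: float) -> int:
        """Position of an on-grid wavelength; raises if it is off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        if pos < 0 or pos > len(self) - 1 or abs(pos - round(pos)) > 1e-9:
            raise ValueError(f"{wavelength_nm} nm is not on the grid {self}")
        return int(round(pos))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start_nm}-{self.stop_nm} nm @ {self.step_nm} nm"


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build the acquisition wavelength grid (endpoints inclusive)."""
    return WavelengthGrid(start_nm, stop_nm, step_nm)


@dataclass
class HyperCube:
    """A stack of PA images over a wavelength grid.

    ``values`` is indexed ``[row, col, wavelength]`` and holds PA amplitude
    in arbitrary units; amplitudes are non-negative by convention.  Vendor
    pre-processing can leave small negative values; pass ``clip_negative``
    to zero them instead of rejecting the cube.
    """

    values: np.ndarray
    grid: WavelengthGrid
    dataset_id: str = "cube"
    clip_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.values.shape}")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.values.shape[2]} planes but the grid has "
                f"{len(self.grid)} wavelengths"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")
        if self.clip_negative:
            np.clip(self.values, 0.0, None, out=self.values)
        elif (self.values < 0).any():
            raise ValueError(
                "cube contains negative PA amplitudes; pass clip_negative=True "
                "to zero them"
            )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class MultisetIndex:
    """Maps rows of an augmented matrix back to (dataset, row, col) pixels.

    ``entries`` is an ordered list of ``(dataset_id, height, width,
    row_offset)`` with cumulative, non-overlapping offsets partitioning
    ``[0, total_rows)``.
    """

    entries: tuple[tuple[str, int, int, int], ...]

    @classmethod
    def from_cubes(cls, cubes: Sequence[HyperCube]) -> "MultisetIndex":
        entries = []
        offset = 0
        for cube in cubes:
            entries.append((cube.dataset_id, cube.height, cube.width, offset))
            offset += cube.n_pixels
        return cls(tuple(entries))

    @property
    def total_rows(self) -> int:
        if not self.entries:
            return 0
        ds, h, w, off = self.entries[-1]
        return off + h * w

    @property
    def dataset_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def lookup(self, row: int) -> tuple[str, int, int]:
        """(dataset_id, row, col) for a global row index."""
        if not 0 <= row < self.total_rows:
            raise IndexError(f"row {row} outside [0, {self.total_rows})")
        for ds, h, w, off in reversed(self.entries):
            if row >= off:
                local = row - off
                return ds, local // w, local % w
        raise AssertionError("unreachable")

    def concat(self, other: "MultisetIndex") -> "MultisetIndex":
        shift = self.total_rows
        shifted = tuple(
            (ds, h, w, off + shift) for ds, h, w, off in other.entries
        )
        return MultisetIndex(self.entries + shifted)


@dataclass
class UnfoldedMatrix:
    """A (pixels x wavelengths) PA data matrix with provenance index."""

    values: np.ndarray
    grid: WavelengthGrid
    index: MultisetIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("unfolded matrix must be 2-D")
        if self.values.shape[0] != self.index.total_rows:
            raise ValueError(
                f"matrix has {self.values.shape[0]} rows but index covers "
                f"{self.index.total_rows}"
            )
        if self.values.shape[1] != len(self.grid):
            raise ValueError("matrix columns do not match grid length")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; 0-based, half-open extents."""

    dataset_id: str
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI extents must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_in(self, cube: HyperCube) -> None:
        if (
            self.row0 + self.height > cube.height
            or self.col0 + self.width > cube.width
        ):
            raise ValueError(
                f"ROI {self} does not fit inside cube "
                f"{cube.dataset_id} ({cube.height}x{cube.width})"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


def unfold(cube: HyperCube) -> UnfoldedMatrix:
    """Reshape a cube to (pixels x wavelengths), row-major pixel order.

    The pixel row index varies slowest: matrix row ``r*width + c`` holds
    the spectrum of pixel ``(r, c)``.
    """
    mat = cube.values.reshape(cube.n_pixels, len(cube.grid))
    return UnfoldedMatrix(mat, cube.grid, MultisetIndex.from_cubes([cube]))


def refold(columns: np.ndarray, index: MultisetIndex) -> dict[str, np.ndarray]:
    """Fold per-pixel column vectors back into per-dataset images.

    ``columns`` is (rows,) or (rows, k); the result maps each dataset_id to
    an (height, width) image, or (k, height, width) for multi-column input.
    """
    columns = np.asarray(columns, dtype=float)
    squeeze = columns.ndim == 1
    if squeeze:
        columns = columns[:, None]
    if columns.shape[0] != index.total_rows:
        raise ValueError(
            f"vector length {columns.shape[0]} does not match index rows "
            f"{index.total_rows}"
        )
    out: dict[str, np.ndarray] = {}
    for ds, h, w, off in index.entries:
        block = columns[off : off + h * w]  # (h*w, k)
        imgs = block.T.reshape(columns.shape[1], h, w)
        out[ds] = imgs[0] if squeeze else imgs
    return out


def augment_rowwise(matrices: Sequence[UnfoldedMatrix]) -> UnfoldedMatrix:
    """Stack unfolded matrices row-wise into one multiset matrix.

    All members must share an identical wavelength grid; rows keep their
    input order and the multiset index is concatenated with updated
    offsets.
    """
    if not matrices:
        raise ValueError("need at least one matrix to augment")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.grid != ref.grid:
            bad = m.index.dataset_ids
            raise ValueError(
                f"wavelength grid of dataset(s) {bad} ({m.grid}) does not "
                f"match {ref.grid}"
            )
    if len(matrices) == 1:
        return ref
    index = matrices[0].index
    for m in matrices[1:]:
        index = index.concat(m.index)
    values = np.vstack([m.values for m in matrices])
    return UnfoldedMatrix(values, ref.grid, index)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(cube: HyperCube, path: str | Path) -> None:
    """Write a cube as a multi-page float32 TIFF + JSON wavelength sidecar."""
    path = Path(path)
    planes = np.ascontiguousarray(
        np.moveaxis(cube.values, 2, 0).astype(np.float32)
    )
    tifffile.imwrite(path, planes, photometric="minisblack")
    meta = {
        "start_nm": cube.grid.start_nm,
        "stop_nm": cube.grid.stop_nm,
        "step_nm": cube.grid.step_nm,
        "dataset_id": cube.dataset_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube container written by :func:`write_cube`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"missing wavelength metadata sidecar {sidecar.name} for {path.name}"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("start_nm", "stop_nm", "step_nm"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar.name} lacks required key {key!r}")
    grid = WavelengthGrid(meta["start_nm"], meta["stop_nm"], meta["step_nm"])
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.shape[0] != len(grid):
        raise ValueError(
            f"{path.name} holds {planes.shape[0]} image planes but the grid "
            f"has {len(grid)} wavelengths"
        )
    values = np.moveaxis(planes.astype(float), 0, 2)
    return HyperCube(values, grid, dataset_id=meta.get("dataset_id", path.stem))


def extract_roi_mean_spectrum(cube: HyperCube, roi: ROI) -> np.ndarray:
    """Average PA spectrum over a rectangular ROI (one value per wavelength)."""
    roi.validate_in(cube)
    rs, cs = roi.slices()
    return cube.values[rs, cs, :].mean(axis=(0, 1))
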