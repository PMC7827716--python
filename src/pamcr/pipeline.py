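"""End-to-end unmixing runs and the diagnostic surfaces built on them.

An :class:`UnmixingRun` ties together: unfolding one or more cubes,
row-wise multiset augmentation, initial-spectrum extraction from ROIs (or
a spectral library), the constrained MCR-ALS fit, and refolding the
abundance columns into per-acquisition component maps.  On top of the fit
it computes the standard diagnostics:

* per-pixel maximum-residual maps, in percent of each acquisition's
  maximum PA amplitude;
* winner-take-all dominance maps with a top-to-second abundance ratio
  (pixels below a 10x ratio are flagged ambiguous but still displayed by
  their argmax component);
* ROI-based relative contribution tables (largest mean contribution
  scaled to 100%) and their cell-wise comparison between two unmixing
  methods;
* photostability (CV%, SNR) and concentration-linearity checks used to
  qualify contrast agents before unmixing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from .hypercube import (
    ROI,
    HyperCube,
    MultisetIndex,
    UnfoldedMatrix,
    augment_rowwise,
    extract_roi_mean_spectrum,
    refold,
    unfold,
)
from .mcr import MCRALS, MCRALSResults, McrOptions
from .spectra import EndmemberSpectrum

__all__ = [
    "UnmixingRun",
    "DominanceMap",
    "run_unmixing",
    "residual_percent_map",
    "dominance_map",
    "roi_relative_contributions",
    "compare_unmixings",
    "photostability_stats",
    "linearity_check",
]


@dataclass
class DominanceMap:
    """Winner-take-all display of component abundances.

    ``winner`` holds the 0-based argmax component per pixel, or -1 where
    all abundances are zero; ``ratio`` the top-to-second abundance ratio
    (inf where the runner-up is zero); ``ambiguous`` flags pixels whose
    ratio falls below the threshold (default 10).
    """

    winner: np.ndarray
    ratio: np.ndarray
    ambiguous: np.ndarray
    threshold_ratio: float


def dominance_map(maps: np.ndarray, threshold_ratio: float = 10.0) -> DominanceMap:
    """Winner-take-all map from stacked (components, ...) abundance images."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim < 2:
        raise ValueError("maps must be (components, ...) with >= 1 component")
    k = maps.shape[0]
    flat = maps.reshape(k, -1)
    order = np.argsort(flat, axis=0)
    top_idx = order[-1]
    top = np.take_along_axis(flat, top_idx[None], axis=0)[0]
    second = (
        np.take_along_axis(flat, order[-2][None], axis=0)[0]
        if k > 1
        else np.zeros_like(top)
    )
    winner = top_idx.astype(int)
    winner[top == 0] = -1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, top / second, np.inf)
    ratio[top == 0] = np.nan
    ambiguous = (ratio < threshold_ratio) & (top > 0)
    shape = maps.shape[1:]
    return DominanceMap(
        winner.reshape(shape),
        ratio.reshape(shape),
        ambiguous.reshape(shape),
        threshold_ratio,
    )


def residual_percent_map(
    result: MCRALSResults,
    D: UnfoldedMatrix | np.ndarray,
    index: MultisetIndex | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel maximum residual in percent of each dataset's max signal.

    For each pixel: ``100 * max_over_wavelengths |e| / max(D_dataset)``,
    the dataset maximum being the global maximum PA amplitude of the raw
    data, computed before unmixing.
    """
    if isinstance(D, UnfoldedMatrix):
        values, index = D.values, D.index
    else:
        values = np.asarray(D, dtype=float)
        if index is None:
            raise ValueError("index required when D is a bare array")
    E = result.E
    if E.shape != values.shape:
        raise ValueError("result residuals do not match D")
    max_abs_e = np.abs(E).max(axis=1)
    out: dict[str, np.ndarray] = {}
    for ds, h, w, off in index.entries:
        block = values[off : off + h * w]
        d_max = block.max()
        if d_max <= 0:
            raise ValueError(f"dataset {ds!r} has zero maximum PA amplitude")
        pix = 100.0 * max_abs_e[off : off + h * w] / d_max
        out[ds] = pix.reshape(h, w)
    return out


@dataclass
class UnmixingRun:
    """A complete provenance-carrying unmixing of one or more cubes."""

    cubes: list[HyperCube]
    init_spectra: np.ndarray
    init_names: list[str]
    options: McrOptions
    matrix: UnfoldedMatrix
    result: MCRALSResults
    maps: dict[str, np.ndarray]  # dataset_id -> (components, h, w)

    @property
    def n_components(self) -> int:
        return self.init_spectra.shape[0]

    def residual_maps(self) -> dict[str, np.ndarray]:
        return residual_percent_map(self.result, self.matrix)

    def dominance_maps(self, threshold_ratio: float = 10.0) -> dict[str, DominanceMap]:
        return {
            ds: dominance_map(m, threshold_ratio) for ds, m in self.maps.items()
        }

    def save(self, out_dir: str | Path) -> None:
        """Write the results bundle: abundance/residual TIFFs, spectra CSV,
        dominance map + legend, and a JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        res = self.result
        for ds, comp_maps in self.maps.items():
            for i in range(comp_maps.shape[0]):
                tifffile.imwrite(
                    out / f"abundance_{ds}_{self.init_names[i]}.tif",
                    comp_maps[i].astype(np.float32),
                )
        df = pd.DataFrame(
            {"wavelength_nm": self.matrix.grid.values}
            | {
                name: res.S_T[i]
                for i, name in enumerate(self.init_names)
            }
        )
        df.to_csv(out / "spectra.csv", index=False)
        for ds, rmap in self.residual_maps().items():
            tifffile.imwrite(
                out / f"residual_percent_{ds}.tif", rmap.astype(np.float32)
            )
        for ds, dom in self.dominance_maps().items():
            tifffile.imwrite(
                out / f"dominance_{ds}.tif", dom.winner.astype(np.int16)
            )
        legend = {
            "components": {str(i): n for i, n in enumerate(self.init_names)},
            "none_label": -1,
            "threshold_ratio": 10.0,
        }
        (out / "dominance_legend.json").write_text(json.dumps(legend, indent=2))
        report = {
            "iterations": res.iterations,
            "converged": res.converged,
            "lof_trace": [float(x) for x in res.lof_trace],
            "lack_of_fit_percent": res.lof_percent,
            "explained_variance_percent": res.explained_variance_percent,
            "n_components": self.n_components,
            "component_names": self.init_names,
            "datasets": {
                ds: {"height": int(m.shape[1]), "width": int(m.shape[2])}
                for ds, m in self.maps.items()
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))


def run_unmixing(
    cubes: Sequence[HyperCube],
    init: Sequence[ROI] | Sequence[EndmemberSpectrum] | np.ndarray,
    options: McrOptions | None = None,
    component_names: Sequence[str] | None = None,
) -> UnmixingRun:
    """Unfold, augment, initialize, fit, and refold.

    ``init`` may be ROIs (one per component; mean spectra are extracted
    from the named cube, mirroring pure-region initialization), a list of
    endmember spectra from a library, or a raw (components x wavelengths)
    array.  Initial spectra are max-normalized inside the solver.
    """
    cubes = list(cubes)
    if not cubes:
        raise ValueError("run_unmixing: empty cube list")
    matrix = augment_rowwise([unfold(c) for c in cubes])
    by_id = {c.dataset_id: c for c in cubes}
    names: list[str]
    if isinstance(init, np.ndarray):
        s0 = np.asarray(init, dtype=float)
        names = [f"component_{i}" for i in range(s0.shape[0])]
    elif init and isinstance(init[0], ROI):
        rows = []
        names = []
        for roi in init:  # type: ignore[union-attr]
            if roi.dataset_id not in by_id:
                raise ValueError(
                    f"ROI references unknown dataset {roi.dataset_id!r}"
                )
            rows.append(extract_roi_mean_spectrum(by_id[roi.dataset_id], roi))
            names.append(f"roi_{roi.dataset_id}_{roi.row0}_{roi.col0}")
        s0 = np.stack(rows)
    elif init and isinstance(init[0], EndmemberSpectrum):
        for e in init:  # type: ignore[union-attr]
            if e.grid != cubes[0].grid:
                raise ValueError(
                    f"endmember {e.name!r} grid does not match the cubes"
                )
        s0 = np.stack([e.amplitude for e in init])  # type: ignore[union-attr]
        names = [e.name for e in init]  # type: ignore[union-attr]
    else:
        raise ValueError("init must be ROIs, endmember spectra, or an array")
    if component_names is not None:
        if len(component_names) != s0.shape[0]:
            raise ValueError("component_names length does not match components")
        names = list(component_names)
    result = MCRALS(matrix, s0, options=options).fit()
    maps = refold(result.C, matrix.index)
    return UnmixingRun(
        cubes=cubes,
        init_spectra=s0,
        init_names=names,
        options=result.model.options,
        matrix=matrix,
        result=result,
        maps=maps,
    )


def roi_relative_contributions(
    maps: np.ndarray | dict[str, np.ndarray],
    rois: Sequence[ROI],
    component_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative component contributions per ROI, largest scaled to 100%.

    ``maps`` is a (components, h, w) stack, or a dict of such stacks
    keyed by dataset_id when ROIs span several acquisitions.  Each ROI's
    component means are divided by their maximum and expressed in
    percent, so any common abundance scale cancels.
    """
    def stack_for(roi: ROI) -> np.ndarray:
        if isinstance(maps, dict):
            if roi.dataset_id not in maps:
                raise ValueError(f"no maps for dataset {roi.dataset_id!r}")
            return maps[roi.dataset_id]
        return maps

    table: dict[str, np.ndarray] = {}
    k = None
    for roi in rois:
        m = np.asarray(stack_for(roi), dtype=float)
        k = m.shape[0] if k is None else k
        if m.shape[0] != k:
            raise ValueError("inconsistent component counts across maps")
        rs, cs = roi.slices()
        if roi.row0 + roi.height > m.shape[1] or roi.col0 + roi.width > m.shape[2]:
            raise ValueError(f"ROI {roi} outside maps of shape {m.shape[1:]}")
        means = m[:, rs, cs].mean(axis=(1, 2))
        top = means.max()
        if top <= 0:
            raise ValueError(f"ROI {roi} has all-zero mean abundance")
        table[f"{roi.dataset_id}[{roi.row0},{roi.col0}]"] = 100.0 * means / top
    index = (
        list(component_names)
        if component_names is not None
        else [f"component_{i}" for i in range(k or 0)]
    )
    return pd.DataFrame(table, index=index)


def compare_unmixings(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Cell-wise absolute mismatch between two relative-contribution
    tables, plus a per-ROI maximum row (``max_mismatch``).

    Symmetric in its arguments; both tables must share component and ROI
    labels.
    """
    if list(table_a.index) != list(table_b.index) or list(table_a.columns) != list(
        table_b.columns
    ):
        raise ValueError("tables have different component or ROI labels")
    diff = (table_a - table_b).abs()
    diff.loc["max_mismatch"] = diff.max(axis=0)
    return diff


def photostability_stats(
    signal_series, noise_series
) -> tuple[float, float]:
    """Coefficient of variation (%) of the signal and its SNR.

    CV uses the sample (n-1) standard deviation of the signal series;
    SNR is the signal mean over the sample standard deviation of the
    background noise series.
    """
    signal = np.asarray(signal_series, dtype=float)
    noise = np.asarray(noise_series, dtype=float)
    if signal.size < 2 or noise.size < 2:
        raise ValueError("both series need at least two samples")
    mean = signal.mean()
    if mean == 0:
        raise ValueError("zero-mean signal: CV undefined")
    cv = 100.0 * signal.std(ddof=1) / mean
    snr = mean / noise.std(ddof=1)
    return float(cv), float(snr)


def linearity_check(
    concentrations, mean_signals
) -> tuple[float, float, float]:
    """Ordinary least-squares line through (concentration, signal) and R².

    Returns (slope, intercept, r_squared); needs at least three levels.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(mean_signals, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 matched concentration/signal pairs")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
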