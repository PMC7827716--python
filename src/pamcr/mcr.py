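"""Constrained alternating least squares for multivariate curve resolution.

The bilinear model is

    D = C @ S_T + E

where D is the (pixels x wavelengths) photoacoustic data matrix, C holds
per-pixel component abundances, S_T the component spectra and E the
residuals.  Both factors are constrained non-negative; no closure or
unimodality constraints are applied (neither is physically meaningful for
multispectral PA imaging, where components diffuse through the imaged
section and noisy spectra may carry spurious local maxima).

The alternating scheme solves each factor exactly by non-negative least
squares (Lawson-Hanson active set, one small problem per pixel row or
wavelength column) given the other, so the lack of fit is non-increasing
across iterations.  Convergence is declared when the relative change of
the lack of fit between successive cycles stays below a tolerance
(default 0.05%) for two consecutive cycles.

After every spectral half-step each spectrum is rescaled to maximum 1 and
the matching abundance column multiplied by the reciprocal, leaving the
product C @ S_T unchanged: all magnitude lives in the abundances, which
fixes the bilinear scale ambiguity and makes spectra comparable across
runs.

The public surface follows the Model/Results convention: build
:class:`MCRALS` from a data matrix and initial spectra, call
:meth:`MCRALS.fit`, and read estimates and diagnostics off the returned
:class:`MCRALSResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .hypercube import UnfoldedMatrix

__all__ = [
    "McrOptions",
    "MCRALS",
    "MCRALSResults",
    "DegenerateComponentError",
    "DegenerateComponentWarning",
    "solve_abundances",
    "solve_spectra",
    "normalize_factors",
    "lack_of_fit",
    "explained_variance",
    "run_mcr_als",
]


@dataclass
class McrOptions:
    """Solver options.

    convergence_tol_percent is the relative lack-of-fit change (in %)
    below which a cycle counts toward convergence; two consecutive such
    cycles terminate the run.
    """

    n_components: int = 0  # 0 = infer from the initial spectra
    max_iterations: int = 50
    convergence_tol_percent: float = 0.05
    constraints: frozenset[str] = frozenset({"nonneg_C", "nonneg_S"})

    def __post_init__(self) -> None:
        if self.convergence_tol_percent <= 0:
            raise ValueError("convergence_tol_percent must be positive")
        if self.n_components < 0:
            raise ValueError("n_components must be >= 1 (or 0 to infer)")
        unknown = self.constraints - {"nonneg_C", "nonneg_S"}
        if unknown:
            raise ValueError(f"unsupported constraints: {sorted(unknown)}")


def _as_array(D) -> np.ndarray:
    if isinstance(D, UnfoldedMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def solve_abundances(D, S_T: np.ndarray) -> np.ndarray:
    """Non-negative least-squares abundances for every pixel row of D.

    Each row of the result minimizes ``||d - c @ S_T||`` subject to
    ``c >= 0``.  S_T must have full row rank on the grid.
    """
    D = _as_array(D)
    S_T = np.asarray(S_T, dtype=float)
    k = S_T.shape[0]
    if np.linalg.matrix_rank(S_T) < k:
        # name the components involved in the deficiency
        norms = np.linalg.norm(S_T, axis=1)
        suspects = [int(i) for i in np.where(norms < 1e-12)[0]] or list(range(k))
        raise ValueError(
            f"spectra matrix is rank-deficient (rank < {k}); "
            f"check components {suspects}"
        )
    A = S_T.T  # (wavelengths x components)
    C = np.zeros((D.shape[0], k))
    for i, d in enumerate(D):
        if not d.any():
            continue  # all-zero pixel -> all-zero abundances
        C[i], _ = nnls(A, d)
    return C


def solve_spectra(D, C: np.ndarray) -> np.ndarray:
    """Non-negative least-squares spectra given abundances.

    Each wavelength column of S_T minimizes ``||D[:, j] - C @ s_j||``
    subject to ``s_j >= 0``.  Components whose abundance column is all
    zero are degenerate (their spectrum is unidentifiable) and raise.
    Use :func:`normalize_factors` afterwards to restore the max-1 spectrum
    convention.
    """
    D = _as_array(D)
    C = np.asarray(C, dtype=float)
    dead = np.where(~C.any(axis=0))[0]
    if dead.size:
        raise DegenerateComponentError(
            f"component(s) {dead.tolist()} have all-zero abundance; "
            "their spectra are unidentifiable"
        )
    k = C.shape[1]
    S_T = np.zeros((k, D.shape[1]))
    for j in range(D.shape[1]):
        S_T[:, j], _ = nnls(C, D[:, j])
    return S_T


class DegenerateComponentError(RuntimeError):
    """A component lost all abundance (or all spectral weight) mid-run."""


class DegenerateComponentWarning(UserWarning):
    """A component carries no abundance; the model may be over-specified."""


def normalize_factors(
    C: np.ndarray, S_T: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so every spectrum has maximum 1, compensating in C.

    The product ``C @ S_T`` is unchanged.  All-zero spectra raise.
    """
    peaks = S_T.max(axis=1)
    if (peaks <= 0).any():
        dead = np.where(peaks <= 0)[0]
        raise DegenerateComponentError(
            f"component(s) {dead.tolist()} have an all-zero spectrum"
        )
    return C * peaks, S_T / peaks[:, None]


def lack_of_fit(D, E: np.ndarray) -> float:
    """Percent lack of fit: 100 * sqrt(sum(E^2) / sum(D^2))."""
    D = _as_array(D)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape:
        raise ValueError(f"shape mismatch: D {D.shape} vs E {E.shape}")
    ss_d = float(np.sum(D * D))
    if ss_d == 0:
        raise ValueError("lack of fit undefined for an all-zero data matrix")
    return 100.0 * float(np.sqrt(np.sum(E * E) / ss_d))


def explained_variance(D, E: np.ndarray) -> float:
    """Percent of total variance captured: 100 * (1 - sum(E^2)/sum(D^2))."""
    D = _as_array(D)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape:
        raise ValueError(f"shape mismatch: D {D.shape} vs E {E.shape}")
    ss_d = float(np.sum(D * D))
    if ss_d == 0:
        raise ValueError("explained variance undefined for an all-zero data matrix")
    return 100.0 * (1.0 - float(np.sum(E * E)) / ss_d)


class MCRALS:
    """Multivariate curve resolution by alternating least squares.

    Parameters
    ----------
    D : array-like or UnfoldedMatrix
        (pixels x wavelengths) data matrix; rows may come from several
        row-wise augmented acquisitions.
    s_init : array-like
        (components x wavelengths) initial spectra, e.g. ROI-averaged
        pure-component estimates.  Normalized to max 1 internally.
    options : McrOptions, optional
    """

    def __init__(self, D, s_init, options: McrOptions | None = None):
        self.data = D
        self._D = _as_array(D)
        if self._D.ndim != 2:
            raise ValueError("D must be a 2-D matrix (pixels x wavelengths)")
        s_init = np.asarray(s_init, dtype=float)
        if s_init.ndim != 2:
            raise ValueError("s_init must be 2-D (components x wavelengths)")
        if s_init.shape[1] != self._D.shape[1]:
            raise ValueError(
                f"initial spectra have {s_init.shape[1]} wavelengths but D "
                f"has {self._D.shape[1]}"
            )
        if (s_init < 0).any():
            raise ValueError("initial spectra must be non-negative")
        self.options = options or McrOptions()
        if self.options.n_components and self.options.n_components != s_init.shape[0]:
            raise ValueError(
                f"options.n_components={self.options.n_components} but s_init "
                f"has {s_init.shape[0]} rows"
            )
        peaks = s_init.max(axis=1)
        if (peaks <= 0).any():
            raise ValueError("initial spectra must each have a positive maximum")
        self.s_init = s_init / peaks[:, None]

    @classmethod
    def from_unfolded(cls, matrix: UnfoldedMatrix, s_init, **kw) -> "MCRALS":
        return cls(matrix, s_init, **kw)

    @property
    def n_components(self) -> int:
        return self.s_init.shape[0]

    def fit(self) -> "MCRALSResults":
        """Run the constrained alternating least squares to convergence."""
        D = self._D
        opts = self.options
        S_T = self.s_init.copy()
        lof_trace: list[float] = []
        converged = False
        streak = 0  # consecutive cycles under tolerance
        C = np.zeros((D.shape[0], self.n_components))
        for it in range(1, opts.max_iterations + 1):
            C = solve_abundances(D, S_T)
            live = C.any(axis=0)
            if not live.all():
                # over-specified model: a component lost all abundance; keep
                # its (max-1) spectrum frozen so the product is unaffected
                warnings.warn(
                    f"component(s) {np.where(~live)[0].tolist()} have zero "
                    "abundance everywhere; model may be over-specified",
                    DegenerateComponentWarning,
                    stacklevel=2,
                )
                if not live.any():
                    raise DegenerateComponentError(
                        f"all components degenerate at iteration {it}"
                    )
                S_live = solve_spectra(D, C[:, live])
                C_live, S_live = normalize_factors(C[:, live], S_live)
                C[:, live] = C_live
                S_T[live] = S_live
            else:
                S_T = solve_spectra(D, C)
                C, S_T = normalize_factors(C, S_T)
            if not (np.isfinite(C).all() and np.isfinite(S_T).all()):
                raise RuntimeError(
                    f"non-finite values in the factors at iteration {it}"
                )
            lof = lack_of_fit(D, D - C @ S_T)
            lof_trace.append(lof)
            if lof < 1e-10:
                # residuals at machine noise: nothing left to fit
                converged = True
                break
            if len(lof_trace) >= 2:
                prev = lof_trace[-2]
                rel_change = abs(prev - lof) / prev * 100.0 if prev > 0 else 0.0
                streak = streak + 1 if rel_change < opts.convergence_tol_percent else 0
                if streak >= 2:
                    converged = True
                    break
        return MCRALSResults(self, C, S_T, np.asarray(lof_trace), converged)


class MCRALSResults:
    """Fitted MCR-ALS factors and diagnostics.

    Attributes
    ----------
    C : (pixels x components) non-negative abundances (all magnitude).
    S_T : (components x wavelengths) non-negative spectra, each max 1.
    lof_trace : per-cycle lack of fit (%), non-increasing.
    converged : whether the stopping rule fired before max_iterations.
    """

    def __init__(self, model: MCRALS, C, S_T, lof_trace, converged: bool):
        self.model = model
        self.C = C
        self.S_T = S_T
        self.lof_trace = lof_trace
        self.converged = bool(converged)

    @property
    def iterations(self) -> int:
        return len(self.lof_trace)

    @property
    def E(self) -> np.ndarray:
        """Residual matrix D - C @ S_T (computed on demand)."""
        return self.model._D - self.C @ self.S_T

    @property
    def lof_percent(self) -> float:
        return float(self.lof_trace[-1]) if self.iterations else float("nan")

    @property
    def explained_variance_percent(self) -> float:
        return explained_variance(self.model._D, self.E)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        D = self.model._D
        lines = [
            "MCR-ALS Results",
            "=" * 46,
            f"{'Data matrix':<28}{D.shape[0]} x {D.shape[1]}",
            f"{'Components':<28}{self.model.n_components}",
            f"{'Constraints':<28}{', '.join(sorted(self.model.options.constraints))}",
            f"{'Iterations':<28}{self.iterations}",
            f"{'Converged':<28}{self.converged}",
            f"{'Lack of fit (%)':<28}{self.lof_percent:.6g}",
            f"{'Explained variance (%)':<28}{self.explained_variance_percent:.4f}",
            "=" * 46,
        ]
        for i, row in enumerate(self.S_T):
            peak_idx = int(np.argmax(row))
            lines.append(
                f"  component {i}: abundance total {self.C[:, i].sum():.4g}, "
                f"spectrum peak at column {peak_idx}"
            )
        return "\n".join(lines)

    def plot_spectra(self, grid=None, ax=None, labels=None):
        """Plot the resolved spectra against wavelength (or column index)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = grid.values if grid is not None else np.arange(self.S_T.shape[1])
        for i, row in enumerate(self.S_T):
            label = labels[i] if labels else f"component {i}"
            ax.plot(x, row, label=label)
        ax.set_xlabel("wavelength (nm)" if grid is not None else "column")
        ax.set_ylabel("normalized PA amplitude")
        ax.legend()
        return ax


def run_mcr_als(D, s_init, options: McrOptions | None = None) -> MCRALSResults:
    """Functional entry point: fit MCR-ALS and return the results object."""
    return MCRALS(D, s_init, options=options).fit()
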