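# Methods

## The bilinear model and its assumptions

A hyperspectral PA cube is unfolded into a matrix `D` (pixels ×
wavelengths) and modelled as `D = C·Sᵀ + E`: every pixel spectrum is a
non-negative linear combination of a small number of component spectra.
This presumes the PA signal is additive across absorbers and that each
component's spectral shape is spatially invariant — a reasonable
first-order description at a fixed depth and fluence, but one that
ignores wavelength-dependent fluence decay with depth and any
laser-induced reshaping of the contrast agents. Pixel order is
immaterial to the factorization (it is row-permutation invariant), so
several acquisitions sharing a wavelength grid can be concatenated
row-wise and modelled simultaneously ("multiset" analysis); a multiset
index records how to fold abundance columns back into per-acquisition
images.

## The alternating least squares scheme

Given initial spectra (ROI-averaged pure-region estimates or a library),
each cycle solves two exact constrained sub-problems with the
Lawson–Hanson active-set NNLS solver (`scipy.optimize.nnls`):

1. abundances: for each pixel row `d`, `min ‖d − c·Sᵀ‖` s.t. `c ≥ 0`;
2. spectra: for each wavelength column, `min ‖D[:,j] − C·s_j‖` s.t.
   `s_j ≥ 0`.

Because each half-step minimizes the same residual sum of squares
exactly over its block, the lack of fit `LOF = 100·√(ΣE²/ΣD²)` is
non-increasing by construction. After every spectral step each spectrum
is rescaled to maximum 1 with the reciprocal factor absorbed into its
abundance column, which leaves `C·Sᵀ` unchanged, resolves the bilinear
scale ambiguity, and makes spectra comparable across runs (all signal
magnitude lives in `C`). Only non-negativity constraints ship: closure
(a mass balance) is wrong for an imaged section that components diffuse
in and out of, and unimodality misbehaves on noisy spectra.

**Convergence.** The run stops when the *relative change* of the LOF
between successive cycles is below `convergence_tol_percent`
(default 0.05 %) for two consecutive cycles, when the LOF itself falls
below machine noise (1e-10 %), or at `max_iterations` (default 50). The
stopping statistic is stated as a design choice: the relative-LOF-change
convention of the standard MCR-ALS toolboxes makes "two consecutive
cycles" well defined.

**Degenerate components.** If a component's abundance column becomes
identically zero (typically an over-specified model), its spectrum is
frozen and a `DegenerateComponentWarning` is emitted rather than
aborting: the remaining components continue to be refined and the run is
reported, not crashed. A rank-deficient spectra matrix is rejected with
the offending component indices. Non-finite values mid-iteration abort
with the iteration number.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `convergence_tol_percent` | 0.05 | % relative LOF change | stabilization criterion for two consecutive cycles |
| `max_iterations` | 50 | cycles | customary toolbox cap; runs on well-initialized phantoms converge in ≤ 5 |
| dominance `threshold_ratio` | 10 | top/second abundance | pixels below 10× are flagged ambiguous but still displayed by their argmax component |
| Lorentzian `width_nm` | 120 | nm FWHM | gives partial overlap between the 688/820/940 nm bands without destroying identifiability |
| liver `gnr_fwhm_nm` | 90 | nm FWHM (Gaussian) | see calibration below |
| phantom `noise_sigma` | 0.01 | fraction of scene max | additive Gaussian noise, clipped at 0 |

## Synthetic phantoms: what they emulate, and what they do not

Three generators provide ground-truth scenes on the 680–970 nm / 2 nm
grid (146 wavelengths):

* **tube**: three non-overlapping tube bands, one GNR batch each
  (Lorentzian bands at 688/820/940 nm), near-zero background — the
  controlled geometry used to harvest pure initial spectra;
* **bio**: soft-edged GNR boluses over a flat low tissue background;
* **liver**: three half-elliptical lobes, the central one dominated by a
  GNR endmember, the lateral ones by a deoxygenated-blood template, with
  a small cross-talk fraction of the minority component in each lobe.

Every scene stores its true abundances and endmembers; the noiseless
cube equals the bilinear product exactly and the noisy cube is bit-for-bit
reproducible from the seed. Geometry is deliberately simple (rectangles,
disks, half-ellipses): the phantoms are built for *identifiability
structure*, not visual realism. They do not model acoustic propagation,
fluence decay with depth, spatially varying spectra, speckle, or nanorod
reshaping under illumination — so passing recovery tests demonstrates the
solver and pipeline are correct on data obeying the bilinear model, not
that any instrument's data obey it.

**Liver cross-talk calibration.** The two lobe mixing fractions are the
exact solution of two cross-signal ratio equations evaluated on the
endmembers at 684 and 862 nm: the central (GNR) lobe's 684 nm signal is
1.3 % of its 862 nm signal, and the lateral (blood) lobes' 862 nm signal
is 5 % of their 684 nm signal. Feasibility with non-negative fractions
requires the GNR band's own 684 nm tail to sit below 1.3 % of its 862 nm
value; a Lorentzian at 820 nm with the 120 nm default width fails this
(its ratio is ≈ 24 %), so the liver generator uses a Gaussian band at
820 nm with 90 nm FWHM — consistent with an in-tissue spectrum dominated
by the resonance core — and a blood template whose 862 nm value is 2 % of
its 684 nm peak. Infeasible shape combinations raise rather than
silently miscalibrate; grids lacking 684/862 nm skip calibration with a
warning.

The blood templates are smooth analytic stand-ins (a 684 nm-peaked
exponential decay for deoxygenated-dominant blood; a rising ramp for
oxygenated), not measured hemoglobin spectra.

## Numerical and interface choices

* Unfolding is row-major (pixel row varies slowest); coordinates are
  0-based with half-open extents.
* Cube container: multi-page float32 TIFF (one page per wavelength,
  `photometric=minisblack`) + JSON sidecar `{start_nm, stop_nm, step_nm,
  dataset_id}` — portable and inspectable; no vendor DICOM dialect.
* Negative input amplitudes (possible after vendor pre-processing) are
  rejected by default, with an explicit `clip_negative` opt-in.
* Residual maps divide each pixel's maximum absolute residual across
  wavelengths by that acquisition's *global* maximum raw amplitude,
  computed before unmixing.
* ROI contribution tables use raw abundance values; because each ROI is
  scaled so its largest mean contribution is 100 %, any common abundance
  scale cancels.
* CV/SNR use the sample (n−1) standard deviation.
* The solver is fully deterministic given `D` and the initial spectra;
  the only randomness in the package is phantom noise, always drawn from
  an explicit seed.

## Problem sizes

The test suite factorizes scenes between 16×16 and 64×64 pixels on the
full 146-wavelength grid (a 64×64 liver fit takes well under a second);
the acquisition-scale shapes (503×647 and 505×648 frames, 650,882-row
multiset matrix) are exercised as shape/compression arithmetic on zero
cubes, since the factorization result at that scale is data-dependent
and no public acquisition exists to compare against.

## Known limitations

* No rotational-ambiguity (feasible band) analysis: a single factor pair
  is returned, conditioned on the initialization.
* No equality constraints for components with known spectra, and no
  hard-soft hybrid modelling.
* The liver frame-size discrepancy in the source material (327,240
  spectra × 145 vs 146 columns) is resolved in favour of 146, the count
  forced by the 680–970/2 nm grid.
* Physical pixel size is not modelled; ROIs are specified in pixels.
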