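# pamcr

Spectral unmixing of hyperspectral **photoacoustic (PA)** image cubes by
**multivariate curve resolution — alternating least squares (MCR-ALS)**,
aimed at discriminating exogenous contrast agents (gold nanorods, GNRs)
from endogenous absorbers such as blood.

A hyperspectral PA acquisition records one image per laser wavelength
(typically 680–970 nm in 2 nm steps, i.e. 146 images) and every pixel
carries a PA spectrum that mixes the absorbers present at that location.
`pamcr` unfolds such cubes into a pixels × wavelengths matrix **D** and
factors it under the bilinear model

```
D = C · Sᵀ + E
```

where the rows of **Sᵀ** are the component spectra (endmembers), the
columns of **C** are per-pixel abundances refoldable into distribution
maps, and **E** is the residual. Both factors are constrained
non-negative; no closure or unimodality constraints are applied (neither
is physically meaningful for PA imaging). The alternating scheme solves
each factor exactly by non-negative least squares given the other, so the
lack of fit `LOF = 100·√(ΣE²/ΣD²)` never increases; convergence is
declared when its relative change stays below 0.05 % for two consecutive
cycles. Several acquisitions sharing a wavelength grid can be stacked
row-wise ("multiset" analysis) and factored simultaneously.

The package also ships:

* parametric endmember models (Lorentzian/Gaussian plasmon bands, blood
  and tissue templates) and the Link relation between a nanorod's aspect
  ratio and its plasmon peak, `AR = (λmax − 495.14)/(53.71·εm) + 0.79`;
* synthetic ground-truth phantoms (tube net, tissue boluses, liver lobes)
  so the whole pipeline is testable without any instrument data;
* diagnostics: per-pixel maximum-residual maps in percent of the scene
  maximum, winner-take-all dominance maps with a 10× ambiguity threshold,
  ROI-based relative-contribution tables and their comparison between two
  unmixing methods, photostability (CV/SNR) and concentration-linearity
  checks;
* a CLI (`pamcr simulate | unmix | compare | diagnose`) for reproducible
  file-based runs.

## Worked example

Unmix a synthetic liver-like scene (GNR-dominated central lobe,
blood-dominated lateral lobes, 1 % additive noise), initializing from
in-image regions rather than the ground truth:

```python
import numpy as np
from pamcr import ROI, extract_roi_mean_spectrum, refold, run_mcr_als, unfold
from pamcr.phantoms import liver_phantom

scene, cube = liver_phantom((64, 64), noise_sigma=0.01, seed=1)
rois = [ROI("liver", 32, 28, 8, 8),   # central lobe -> GNR-like spectrum
        ROI("liver", 32, 7, 8, 8)]    # lateral lobe -> blood-like spectrum
s0 = np.stack([extract_roi_mean_spectrum(cube, r) for r in rois])
mat = unfold(cube)
res = run_mcr_als(mat, s0)
print(res.summary())
```

```
MCR-ALS Results
==============================================
Data matrix                 4096 x 146
Components                  2
Constraints                 nonneg_C, nonneg_S
Iterations                  3
Converged                   True
Lack of fit (%)             4.1671
Explained variance (%)      99.8264
==============================================
  component 0: abundance total 279.6, spectrum peak at column 70
  component 1: abundance total 554.1, spectrum peak at column 2
```

The fit converged in 3 cycles; the 4.2 % lack of fit is the injected
noise floor, and the model keeps 99.8 % of the data variance. Component 0
peaks at column 70 (820 nm, the GNR plasmon band) and component 1 at
column 2 (684 nm, the deoxygenated-blood peak). Refolding the abundance
columns gives the distribution maps, which correlate with the generating
truth at r = 0.997 (GNR) and r = 1.000 (blood):

```python
maps = refold(res.C, mat.index)["liver"]   # (2, 64, 64) images
```

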