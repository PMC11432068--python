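# Methods

This note documents the physical model behind the simulator, the estimators
in the processing chain, the parameter defaults and why they were chosen,
and what the synthetic phantoms do and do not establish about real data.

## Signal model

**Spectral sampling.**  The swept source is described by its center
wavelength λ0, Gaussian FWHM bandwidth Δλ, and a monotone polynomial sweep
map g(s) from normalized sample index s ∈ [0, 1] to normalized wavenumber.
The sampled wavenumber span is `sweep_span_factor` (default 2) times the
FWHM span Δk = 2πΔλ/λ0², so the Gaussian envelope falls to ≈ 6% amplitude at
the sweep edges.  Unbalanced dispersion enters as the spectral phase
a2·κ² + a3·κ³ with κ the centered normalized wavenumber in [−1, 1].

**Scatterers.**  Each phantom layer draws a Poisson number of discrete
scatterers per A-scan (mean `scatterer_density`), uniform in depth within
the layer, each with a uniform random phase and a fixed field amplitude
(`reflectivity`).  A scatterer at depth z contributes the interference term
Re{a_c S(k) exp(i(2kz + φ + a2κ² + a3κ³))} to channel c, where S(k) is the
envelope and a_c the scatterer's Jones amplitude.  Speckle arises naturally
from the coherent sum of scatterers within the axial point-spread function.

**Polarization.**  The illumination Jones state is 45° linear by default
(equal H/V amplitude, zero relative phase) so both channels carry signal for
preserving tissue; it is configurable, and the incoherent intensity is
invariant to it.  Depolarization is per-scatterer Bernoulli(p): with
probability `depolarization_p` the scatterer's returned state is replaced by
an independent Haar-uniform pure state (uniform on the Poincaré sphere).
Every scatterer draws its Bernoulli variate and candidate random state
regardless of p, so realizations at different p values from the same seed
are monotonically coupled — raising p only converts additional scatterers
from preserving to randomized, which makes the DOPU-vs-p monotonicity
property exact rather than statistical.  This binary mechanism reproduces
the phenomenology that matters for DOPU contrast (kernel-level state
variance increasing with melanin-like pigmentation); it does not model
continuous partial depolarization, multiple scattering, or birefringence.

**Noise.**  Additive white Gaussian noise of standard deviation
`noise_sigma_h` / `noise_sigma_v` per spectral sample, independent between
channels, models the balanced-detector noise floor.

## Reconstruction

Per channel: (1) DC subtraction using the mean spectrum over each B-scan's
A-lines (skippable via `dc='none'` for single-A-line inputs, where the mean
*is* the signal); (2) analytic signal by Hilbert transform; (3) resampling
to a uniform wavenumber grid with cubic splines; (4) multiplication by the
conjugate dispersion phase exp(−i(a2κ² + a3κ³)) on the linearized grid;
(5) FFT along the spectral axis, keeping the positive-delay half.  Both
channels receive identical processing, preserving their relative phase.
Depth spacing is π(N−1)/(Δk_total·N) with N spectral samples; an optional
`pad_factor` zero-pads the spectrum for finer PSF sampling.

**Calibration.**  The k-linearization map is estimated from a noise-free
single-reflector fringe: the unwrapped analytic phase is proportional to
wavenumber, so resample positions that render it affine in the target index
linearize the sweep.  The unwrapped phase is denoised by a degree-7
polynomial fitted to the central 90% of samples before inversion, because
the analytic phase is unreliable near the sweep edges (envelope roll-off
plus Hilbert endpoint artifacts); without this the endpoint errors bias the
whole map by ≈ 0.3 samples, with it the identity map is recovered to
≈ 0.001 samples and a nonlinear generating map to ≈ 3×10⁻⁶ relative RMS.
The calibration fringe is generated dispersion-free (the calibration
separates sweep nonlinearity from dispersion, which is compensated
downstream); a map estimated at one mirror depth linearizes fringes from
any other depth (verified to < 0.01% residual nonlinearity).

**Dispersion estimation.**  When coefficients are not known, (a2, a3) are
estimated by sharpness maximization: Shannon entropy of the normalized
intensity image is minimized over a2 (coarse 33-point grid on ±200 rad,
then bounded scalar refinement), then a3, then a2 again.  On a noise-free
reflector the generating a2 = 40 rad is recovered within 0.5%.

## DOPU estimator

The estimator is the ratio of kernel sums (intensity-weighted), not the
mean of per-voxel-normalized Stokes vectors: the additive-noise correction
is defined on sums, and intensity weighting is better conditioned at low
SNR.  The per-voxel-normalized variant is available via
`estimator='normalized'` for comparison; the two coincide when voxel
intensities are equal.

Noise correction subtracts the mean noise energy of each channel, estimated
from the deepest 10% of depth samples (beyond the tissue): I′ = I − n_H −
n_V and Q′ = Q − (n_H − n_V); U and V are unbiased because the channel
noises are independent and zero-mean.  The residual effect of noise is a
variance inflation of the numerator, which kernel averaging suppresses by
the kernel size; the dominant low-SNR bias (inflated denominator) is
removed, which is why the corrected estimator is strictly closer to 1 on
preserving tissue at every tested SNR (5/10/15 dB).

Defaults, all configurable:

| parameter | default | rationale |
|---|---|---|
| averaging kernel (lateral × axial) | 3 × 5 | standard DOPU contrast kernel; axial dimension larger because the depth pixel (≈ 2.8 µm) undersamples the PSF less than the lateral pitch |
| DOPU threshold | 0.8 | separates preserving tissue (≈ 1) from melanin-bearing voxels in the phantom family; applied as "set supra-threshold values to the preserving background 1" |
| median filter (lateral × axial × frames) | 3 × 5 × 3 | removes isolated speckle misclassifications while retaining slabs ≥ 5 voxels thick |
| SNR floor | 3 × (n_H + n_V) | voxels with kernel-mean corrected intensity below it are masked NaN; a display choice, set it to 0 to evaluate the estimator itself |
| noise region | deepest 10% of depth | signal-free in all bundled phantoms; a warning fires if its energy exceeds 10× the volume median |

Thresholding semantics (saturate to 1, rather than zeroing or masking) was
a genuinely open choice; saturating keeps the preserving background visually
uniform while leaving depolarizing structure quantitative, and it is
isolated behind the `dopu_threshold` parameter.

The Stokes V sign convention is V = −2 Im(E_H E_V*); DOPU is invariant to
it.

## Presentation products

Scattering OCT defaults to the incoherent channel sum |E_H|² + |E_V|²,
which is invariant under unitary rotations of the channel pair and shows no
polarization dropout.  The literal complex channel average
|(E_H + E_V)/2|² is retained as `coherent_mean` because the two readings of
"averaging the complex data" differ physically; the incoherent sum is the
artifact-free default.  Display windows span 40 dB below the volume's
99.9th-percentile intensity.  En face maps project min/mean/max over the
depth voxels of one mask label (NaN where the label is absent); DOPU maps
use minimum projection.  Composites tint voxels with DOPU below the
threshold using a perceptually uniform colormap evaluated reversed, so low
DOPU (melanin) renders warm.

## Desk-scale study conditions

The clinical protocol (2304 samples × 2000 A-lines × 1000 B-scans, 400 kHz,
5 s/volume, 105° FOV) is carried as configuration and used for protocol
arithmetic.  Simulated volumes run at reduced sizes chosen once for the
test suite: 512 spectral samples (≈ 2.8 µm depth pixel, ≈ 0.72 mm range)
and lateral grids between 48×8 and 128×64 depending on the experiment; the
phantom family (uniform slab, three-layer retina with p = 0 / 0.85 / 0.3,
and a preserving host with a p = 1 melanotic disc of radius 16 A-lines)
is fixed in `pdoct.presets`.  SNR for the noise-correction experiments is
defined as mean in-layer signal intensity divided by the mean per-voxel
noise energy measured from a unit-noise pilot reconstruction.

## Limitations

- Per-scatterer binary depolarization ignores continuous depolarization,
  multiple scattering and birefringence; passing tests show estimator
  correctness under the stated model, not instrument-level realism.
- No eye motion, vignetting, roll-off, or scanner geometry; `fov_degrees`
  is metadata.  No complex-conjugate-artifact removal (standard
  positive-delay processing).
- The axial resolution tested is the Gaussian transform-limited closed form
  (2 ln2/π)·λ0²/Δλ, measured as the FWHM of the linear amplitude A-scan
  envelope (the coherence-length convention).
- The noise energy estimated from the deepest depth bins slightly
  underestimates the noise at shallower depths because resampling shapes
  the noise spectrum; the correction therefore remains conservative at very
  low SNR.
- Melanin *concentration* is not quantified; DOPU is a contrast, not a
  calibrated measure.
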