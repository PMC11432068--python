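# pdoct — polarization-diversity OCT post-processing

`pdoct` implements the post-processing chain of a polarization-diversity
swept-source OCT (PD-OCT) retinal imaging system, from raw dual-channel
spectral interferograms to melanin-specific depolarization contrast.  It is
aimed at researchers building or studying PD-OCT pipelines: every stage of
the chain is an ordinary Python function over plain containers, and a
built-in swept-source phantom simulator makes the whole pipeline exercisable
— and testable against ground truth — without instrument data.

## What it computes

A PD-OCT system detects the horizontal (H) and vertical (V) polarization
components of the backscattered light on separate balanced detectors.  After
conventional reconstruction per channel — DC subtraction, Hilbert transform,
wavenumber (k-)linearization, numerical dispersion compensation, FFT — each
voxel carries a complex Jones pair (E_H, E_V), from which the Stokes
parameters follow:

    I = |E_H|² + |E_V|²,   Q = |E_H|² − |E_V|²,
    U = 2 Re(E_H E_V*),    V = −2 Im(E_H E_V*).

The **degree of polarization uniformity (DOPU)** is the magnitude of the
kernel-summed Stokes vector normalized by the kernel-summed intensity,
computed in a sliding 3×5 (lateral × axial) window within each B-scan:

    DOPU = √((ΣQ′)² + (ΣU)² + (ΣV)²) / Σ I′

where I′ = I − n_H − n_V and Q′ = Q − (n_H − n_V) remove the additive-noise
bias of each detection channel (n_H, n_V are mean noise energies estimated
from a signal-free region).  DOPU = 1 means the polarization state is
uniform across the kernel (fully preserved); low DOPU marks depolarizing
tissue — melanin in the retinal pigment epithelium (RPE), pigmented lesions
such as choroidal nevi.  DOPU volumes are thresholded (values above the
threshold set to the preserving background 1) and smoothed with a 3×5×3
median filter; minimum projection over a segmented layer yields the en face
melanin map, and low-DOPU voxels are overlaid in color on the grayscale
log-intensity B-scan to form composite images.

The simulator generates the raw fringes this chain consumes: a layered
retina phantom with discrete scatterers, per-scatterer polarization behavior
(preserving, or randomized with a tunable melanin-like probability *p*), a
Gaussian-spectrum swept source with a nonlinear sweep map and unbalanced
dispersion, and independent Gaussian detection noise per channel.

## Worked example

Run the bundled desk-scale configuration (a 512×96×16 volume with inner
retina / RPE / choroid layers at depolarization p = 0 / 0.85 / 0.3, mild
sweep nonlinearity, matched dispersion, and detection noise):

```
pdoct run-all --config examples/desk_config.yaml --out-dir out
```

This writes the raw fringes, calibration map, complex volume, layer masks,
filtered DOPU volume, scattering OCT volume, en face maps and a composite
B-scan PNG, plus `manifest.json` with per-stage timings and SHA-256
checksums (a rerun with the same config reproduces identical checksums).
Summarizing the DOPU volume over the truth masks:

```python
import numpy as np
from pdoct import io as pio

d = pio.read_dopu("out/dopu_volume.tif")
mask = pio.read_mask("out/layer_mask.tif")
for name in ("inner_retina", "rpe", "choroid"):
    vals = d.dopu[mask.labels == mask.label_of(name)]
    vals = vals[np.isfinite(vals)]
    print(name, round(float(vals.mean()), 3))
```

prints

```
inner_retina 0.987
rpe 0.464
choroid 0.848
```

— the polarization-preserving inner retina stays near 1, the melanin-rich
RPE drops to ≈ 0.46, and the moderately pigmented choroid sits in between:
the depth-resolved melanin contrast the method exists for.  With the
clinical raster (2000 A-lines × 1000 B-scans at a 400 kHz A-scan rate) the
manifest reports the volume acquisition time, 5 s.

The same stages are available individually (`pdoct simulate`, `calibrate`,
`reconstruct`, `dopu`, `enface`, `render`) and as library calls
(`pdoct.synthesize_volume`, `pdoct.reconstruct`, `pdoct.dopu`, …).

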