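"""Stokes parameters and noise-error-corrected degree of polarization uniformity.

DOPU measures how uniform the polarization state is across a small spatial
neighborhood: 1 means every voxel in the kernel carries the same state
(polarization preserved), values near 0 mean the states are scrambled — the
signature of melanin in the RPE and pigmented lesions.

The estimator is the intensity-weighted ratio of kernel sums

    DOPU = sqrt((ΣQ')² + (ΣU)² + (ΣV)²) / Σ I'

with the additive-noise bias of each channel removed before the ratio:
``E[|E_H|²] = S_H + n_H`` for additive complex noise of mean energy ``n_H``,
so ``I' = I − n_H − n_V`` and ``Q' = Q − (n_H − n_V)`` are unbiased while U
and V need no correction (channel noises are independent and zero-mean).
Without the correction the denominator is inflated and DOPU is biased low at
low SNR; the corrected form restores values near 1 for preserving tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, uniform_filter

from .recon import ComplexVolume

__all__ = [
    "NoiseEstimate",
    "StokesVolume",
    "DopuVolume",
    "stokes_from_jones",
    "estimate_noise",
    "dopu",
    "postfilter",
]


@dataclass(frozen=True)
class NoiseEstimate:
    """Mean additive-noise energy per voxel for each polarization channel."""

    n_h: float = 0.0
    n_v: float = 0.0
    region_spec: str = "none"

    def __post_init__(self) -> None:
        if self.n_h < 0 or self.n_v < 0:
            raise ValueError("noise energies must be >= 0")

    @property
    def total(self) -> float:
        return self.n_h + self.n_v


@dataclass
class StokesVolume:
    """Per-voxel Stokes parameters with the channel noise estimate attached."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    noise: NoiseEstimate = field(default_factory=NoiseEstimate)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.i, self.q, self.u, self.v)}
        if len(shapes) != 1:
            raise ValueError("Stokes component arrays must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.i.shape

    def with_noise(self, noise: NoiseEstimate) -> "StokesVolume":
        return StokesVolume(self.i, self.q, self.u, self.v, noise)


@dataclass
class DopuVolume:
    """DOPU in [0, 1] per voxel (NaN where masked)."""

    dopu: np.ndarray
    kernel: tuple[int, int]
    filtered: bool = False
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        d = self.dopu
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("DOPU values must lie in [0, 1]")


def stokes_from_jones(vol: ComplexVolume, noise: NoiseEstimate | None = None) -> StokesVolume:
    """Voxelwise Stokes parameters from the two complex field components.

    I = |E_H|² + |E_V|², Q = |E_H|² − |E_V|², U = 2 Re(E_H E_V*),
    V = −2 Im(E_H E_V*).  (The V sign convention is cosmetic; DOPU does not
    depend on it.)
    """
    eh, ev = vol.e_h, vol.e_v
    if not (np.all(np.isfinite(eh.real)) and np.all(np.isfinite(ev.real))):
        raise ValueError("NaN/Inf in complex volume")
    ah2 = np.abs(eh) ** 2
    av2 = np.abs(ev) ** 2
    cross = eh * np.conj(ev)
    return StokesVolume(
        i=ah2 + av2,
        q=ah2 - av2,
        u=2.0 * cross.real,
        v=-2.0 * cross.imag,
        noise=noise if noise is not None else NoiseEstimate(),
    )


def estimate_noise(
    vol: ComplexVolume,
    region: tuple[slice, slice, slice] | None = None,
    depth_fraction: float = 0.1,
    structure_factor: float = 10.0,
) -> NoiseEstimate:
    """Estimate per-channel noise energy from a signal-free region.

    By default the deepest ``depth_fraction`` of depth samples is used — in a
    retinal volume this lies beyond the tissue, so it contains detection
    noise only.  A warning is issued if the region's energy is suspiciously
    high relative to the volume (bright structure leaking into the region).
    """
    n_depth = vol.shape[0]
    if region is None:
        z0 = int(round(n_depth * (1.0 - depth_fraction)))
        z0 = min(max(z0, 0), n_depth - 1)
        region = (slice(z0, n_depth), slice(None), slice(None))
        spec = f"deepest {depth_fraction:.0%} of depth samples"
    else:
        spec = f"slices {region!r}"
    eh = vol.e_h[region]
    ev = vol.e_v[region]
    if eh.size == 0:
        raise ValueError("noise region is empty")
    n_h = float(np.mean(np.abs(eh) ** 2))
    n_v = float(np.mean(np.abs(ev) ** 2))
    global_median = float(np.median(np.abs(vol.e_h) ** 2 + np.abs(vol.e_v) ** 2))
    if global_median > 0 and (n_h + n_v) > structure_factor * global_median:
        warnings.warn(
            f"noise region energy ({n_h + n_v:.3g}) exceeds {structure_factor}x the volume median "
            f"({global_median:.3g}); the region may overlap bright structure",
            stacklevel=2,
        )
    return NoiseEstimate(n_h=n_h, n_v=n_v, region_spec=spec)


def _kernel_mean(a: np.ndarray, axial: int, lateral: int) -> np.ndarray:
    # sliding mean over (depth, aline) within each B-scan; ratio of means
    # equals ratio of sums for a shared kernel
    return uniform_filter(a, size=(axial, lateral, 1), mode="nearest")


def dopu(
    stokes: StokesVolume,
    kernel: tuple[int, int] = (3, 5),
    noise_correct: bool = True,
    snr_floor_factor: float = 3.0,
    estimator: str = "sum-ratio",
) -> DopuVolume:
    """Kernel-averaged DOPU, optionally noise-error corrected.

    Parameters
    ----------
    stokes : StokesVolume
        Stokes volume with its noise estimate attached (zero estimate for
        noise-free data or when correction is off).
    kernel : (lateral, axial)
        Averaging window, A-lines × depth samples within a B-scan; both odd.
        The default (3, 5) is the standard DOPU contrast kernel.
    noise_correct : bool
        Apply the additive-noise bias correction (see module docstring).
    snr_floor_factor : float
        Voxels whose kernel-mean corrected intensity falls below
        ``snr_floor_factor × (n_H + n_V)`` are masked NaN (too noisy to
        carry a meaningful state).  Set 0 to disable display masking.
    estimator : {'sum-ratio', 'normalized'}
        'sum-ratio' (default) is the intensity-weighted ratio of kernel sums;
        'normalized' averages per-voxel unit Stokes vectors instead (no noise
        correction is defined for it) — provided for comparison.
    """
    lateral, axial = kernel
    if lateral < 1 or axial < 1 or lateral % 2 == 0 or axial % 2 == 0:
        raise ValueError("kernel dimensions must be odd and >= 1")
    if estimator not in ("sum-ratio", "normalized"):
        raise ValueError(f"unknown estimator {estimator!r}")

    noise = stokes.noise
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "normalized":
            inten = stokes.i
            valid = inten > 0
            q = np.where(valid, stokes.q / np.where(valid, inten, 1.0), np.nan)
            u = np.where(valid, stokes.u / np.where(valid, inten, 1.0), np.nan)
            v = np.where(valid, stokes.v / np.where(valid, inten, 1.0), np.nan)
            mq = _kernel_mean(np.nan_to_num(q), axial, lateral)
            mu = _kernel_mean(np.nan_to_num(u), axial, lateral)
            mv = _kernel_mean(np.nan_to_num(v), axial, lateral)
            frac = _kernel_mean(valid.astype(float), axial, lateral)
            d = np.sqrt(mq**2 + mu**2 + mv**2) / np.where(frac > 0, frac, np.nan)
        else:
            if noise_correct:
                ic = stokes.i - noise.total
                qc = stokes.q - (noise.n_h - noise.n_v)
            else:
                ic = stokes.i
                qc = stokes.q
            m_i = _kernel_mean(ic, axial, lateral)
            m_q = _kernel_mean(qc, axial, lateral)
            m_u = _kernel_mean(stokes.u, axial, lateral)
            m_v = _kernel_mean(stokes.v, axial, lateral)
            d = np.sqrt(m_q**2 + m_u**2 + m_v**2) / np.where(m_i > 0, m_i, np.nan)
            if noise_correct and snr_floor_factor > 0 and noise.total > 0:
                d[m_i < snr_floor_factor * noise.total] = np.nan

    d = np.clip(d, 0.0, 1.0)
    return DopuVolume(dopu=d, kernel=(lateral, axial), filtered=False)


def _nan_median_filter(a: np.ndarray, size: tuple[int, int, int], chunk: int = 32) -> np.ndarray:
    """3-D median filter that ignores NaNs (edge handling: nearest)."""
    pads = tuple(s // 2 for s in size)
    padded = np.pad(a, [(p, p) for p in pads], mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, size)
    out = np.empty_like(a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN windows
        for lo in range(0, a.shape[0], chunk):  # chunked along depth to bound memory
            hi = min(lo + chunk, a.shape[0])
            out[lo:hi] = np.nanmedian(win[lo:hi], axis=(-3, -2, -1))
    return out


def postfilter(
    d: DopuVolume,
    dopu_threshold: float = 0.8,
    median_kernel: tuple[int, int, int] = (3, 5, 3),
) -> DopuVolume:
    """Threshold and 3-D median filter a DOPU volume for display.

    Values above ``dopu_threshold`` are set to the polarization-preserving
    background value 1, retaining only the low-DOPU depolarizing structures
    as contrast; the result is then smoothed by a 3-D median filter
    (lateral × axial × B-scans, default 3×5×3) to remove residual speckle.
    NaNs are ignored within each median window.
    """
    if d.filtered:
        raise ValueError("input DopuVolume is already filtered")
    lateral, axial, frames = median_kernel
    if any(k < 1 or k % 2 == 0 for k in median_kernel):
        raise ValueError("median kernel dimensions must be odd and >= 1")
    vol = d.dopu.copy()
    finite = np.isfinite(vol)
    vol[finite & (vol > dopu_threshold)] = 1.0
    size = (axial, lateral, frames)  # array axes: depth, aline, bscan
    if np.all(finite):
        out = median_filter(vol, size=size, mode="nearest")
    else:
        out = _nan_median_filter(vol, size)
    out = np.clip(out, 0.0, 1.0)
    return DopuVolume(dopu=out, kernel=d.kernel, filtered=True, threshold_used=float(dopu_threshold))
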