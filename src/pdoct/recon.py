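"""Complex volume reconstruction from raw dual-channel fringes.

The processing chain per channel is the conventional swept-source one:
B-scan-mean DC subtraction, analytic signal (Hilbert transform), resampling
to a wavenumber-linear grid (cubic spline), numerical dispersion compensation
by conjugate spectral phase, and FFT along the spectral axis keeping the
positive-delay half.  Both channels go through identical processing so their
relative phase — the quantity polarimetry depends on — is preserved.

Sweep calibration follows the time-frequency route: the unwrapped analytic
phase of a single-reflector fringe is, up to dispersion, proportional to
wavenumber, so resampling positions that render it affine in the target index
linearize the sweep.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.optimize import minimize_scalar
from scipy.signal import hilbert

from .simulator import RawFringeVolume, SweptSourceSpec

__all__ = [
    "CalibrationMap",
    "DispersionCoeffs",
    "ComplexVolume",
    "estimate_calibration",
    "reconstruct",
    "optimize_dispersion",
    "profile_fwhm",
    "CalibrationError",
    "ReconError",
]


class CalibrationError(RuntimeError):
    """Sweep calibration failed (non-monotone phase, degenerate fringe)."""


class ReconError(RuntimeError):
    """Reconstruction or dispersion optimization failed."""


def _source_hash(source: SweptSourceSpec) -> str:
    blob = json.dumps(source.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CalibrationMap:
    """Fractional source-sample positions that linearize the sweep.

    ``resample_positions[m]`` is the (fractional) index into the raw spectral
    samples at which target linear-wavenumber sample ``m`` should be read.
    """

    resample_positions: np.ndarray
    source_spec_hash: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.resample_positions, dtype=float)
        if pos.ndim != 1 or pos.size < 4:
            raise CalibrationError("resample_positions must be a 1-D vector of length >= 4")
        if not np.all(np.diff(pos) > 0):
            raise CalibrationError("resample_positions must be strictly increasing")
        if pos[0] < -1e-9 or pos[-1] > pos.size - 1 + 1e-9:
            raise CalibrationError("resample_positions out of [0, n-1]")
        self.resample_positions = pos

    @classmethod
    def identity(cls, n: int) -> "CalibrationMap":
        return cls(np.arange(n, dtype=float), "identity")

    @classmethod
    def from_source(cls, source: SweptSourceSpec) -> "CalibrationMap":
        """Analytic map from a source's known sweep polynomial.

        This is the 'predefined rescaling parameter' of a calibrated
        instrument; :func:`estimate_calibration` recovers it from data.
        """
        n = source.samples_per_ascan
        targets = np.arange(n) / (n - 1)
        pos = source.sweep_map_inverse(targets) * (n - 1)
        pos[0], pos[-1] = 0.0, float(n - 1)
        return cls(pos, _source_hash(source))


@dataclass(frozen=True)
class DispersionCoeffs:
    """Compensating quadratic/cubic spectral-phase coefficients (rad)."""

    a2: float = 0.0
    a3: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a2) and math.isfinite(self.a3)):
            raise ReconError("dispersion coefficients must be finite")


@dataclass
class ComplexVolume:
    """Depth-resolved complex reflectivity per polarization channel.

    Arrays are indexed ``[depth, aline, bscan]``; depth index 0 is zero delay
    and physical depth is ``index * depth_spacing_um``.
    """

    e_h: np.ndarray
    e_v: np.ndarray
    depth_spacing_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.e_h = np.asarray(self.e_h)
        self.e_v = np.asarray(self.e_v)
        if self.e_h.shape != self.e_v.shape:
            raise ReconError("e_h and e_v must share one shape")
        if self.depth_spacing_um <= 0:
            raise ReconError("depth_spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.e_h.shape

    @property
    def depth_axis(self) -> tuple[int, float]:
        """(n_depth, spacing_um) — the grid truth masks must match."""
        return (self.e_h.shape[0], self.depth_spacing_um)

    def intensity(self) -> np.ndarray:
        """Polarization-diversity intensity |E_H|² + |E_V|²."""
        return np.abs(self.e_h) ** 2 + np.abs(self.e_v) ** 2


def estimate_calibration(calib: RawFringeVolume, fit_degree: int = 7) -> CalibrationMap:
    """Estimate the k-linearization map from a single-reflector fringe.

    Takes the channel with more energy, forms the analytic signal, unwraps
    its phase, denoises it with a degree-``fit_degree`` polynomial fitted to
    the central 90% of samples (the analytic phase is unreliable near the
    sweep edges, where the spectral envelope rolls off and the Hilbert
    transform has endpoint artifacts), and returns resampling positions that
    make the phase affine in the target sample index.

    Raises
    ------
    CalibrationError
        If the unwrapped phase is not strictly monotone (phase-wrap failure,
        e.g. a mirror beyond the unambiguous range, or no fringe at all).
    """
    if calib.shape[1] != 1 or calib.shape[2] != 1:
        raise CalibrationError("calibration volume must contain exactly one A-line")
    fr_h = calib.fringes_h[:, 0, 0]
    fr_v = calib.fringes_v[:, 0, 0]
    fr = fr_h if np.sum(fr_h**2) >= np.sum(fr_v**2) else fr_v
    if np.sum(fr**2) == 0:
        raise CalibrationError("calibration fringe is identically zero")
    phase = np.unwrap(np.angle(hilbert(fr)))
    if phase[-1] < phase[0]:
        phase = -phase
    if not np.all(np.diff(phase) > 0):
        raise CalibrationError("unwrapped calibration phase is not strictly monotone")
    n = fr.size
    x = np.arange(n, dtype=float)
    lo, hi = int(round(0.05 * n)), int(round(0.95 * n))
    coeffs = np.polynomial.Polynomial.fit(x[lo:hi], phase[lo:hi], deg=min(fit_degree, hi - lo - 1))
    smooth = coeffs(x)
    if not np.all(np.diff(smooth) > 0):
        raise CalibrationError("fitted calibration phase is not strictly monotone")
    pnorm = (smooth - smooth[0]) / (smooth[-1] - smooth[0])
    targets = np.arange(n) / (n - 1)
    positions = np.interp(targets, pnorm, x)
    positions[0], positions[-1] = 0.0, float(n - 1)
    return CalibrationMap(positions, _source_hash(calib.source))


def _preprocess(raw: RawFringeVolume, cal: CalibrationMap, dc: str) -> tuple[np.ndarray, np.ndarray]:
    """DC-subtract, analytic signal, and k-linear resampling for both channels."""
    n = raw.shape[0]
    if cal.resample_positions.size != n:
        raise ReconError(
            f"calibration length {cal.resample_positions.size} does not match {n} spectral samples"
        )
    if dc not in ("bscan-mean", "none"):
        raise ReconError(f"unknown dc mode {dc!r}")
    out = []
    grid = np.arange(n, dtype=float)
    for fr in (raw.fringes_h, raw.fringes_v):
        if not np.all(np.isfinite(fr)):
            raise ReconError("NaN/Inf in input fringes")
        x = fr.astype(np.float64, copy=True)
        if dc == "bscan-mean":
            x -= x.mean(axis=1, keepdims=True)  # mean spectrum over A-lines, per B-scan
        a = hilbert(x, axis=0)
        re = make_interp_spline(grid, a.real, k=3, axis=0)(cal.resample_positions)
        im = make_interp_spline(grid, a.imag, k=3, axis=0)(cal.resample_positions)
        out.append(re + 1j * im)
    return out[0], out[1]


def _disp_fft(resampled: np.ndarray, disp: DispersionCoeffs, pad_factor: int) -> np.ndarray:
    n = resampled.shape[0]
    kappa = 2.0 * (np.arange(n) / (n - 1)) - 1.0
    comp = np.exp(-1j * (disp.a2 * kappa**2 + disp.a3 * kappa**3))
    spec = resampled * comp[:, None, None]
    n_fft = n * pad_factor
    depth = np.fft.fft(spec, n=n_fft, axis=0) / math.sqrt(n)
    return depth[: n_fft // 2]


def reconstruct(
    raw: RawFringeVolume,
    cal: CalibrationMap,
    disp: DispersionCoeffs = DispersionCoeffs(),
    dc: str = "bscan-mean",
    pad_factor: int = 1,
) -> ComplexVolume:
    """Reconstruct the depth-resolved complex volume from raw fringes.

    Parameters
    ----------
    raw : RawFringeVolume
    cal : CalibrationMap
        k-linearization map (length must match the spectral sample count).
    disp : DispersionCoeffs
        Compensating phase; the conjugate of ``exp(i(a2 κ² + a3 κ³))`` is
        applied on the *linearized* wavenumber grid.
    dc : {'bscan-mean', 'none'}
        DC estimate subtracted per channel.  'bscan-mean' (default) uses the
        mean spectrum over each B-scan's A-lines; 'none' skips subtraction
        (use for single-A-line or few-A-line inputs, where the mean spectrum
        is not a DC estimate but the signal itself).
    pad_factor : int
        Spectral zero-padding multiple; > 1 samples the axial PSF more finely
        (depth spacing divides accordingly) without changing its physics.
    """
    if pad_factor < 1:
        raise ReconError("pad_factor must be >= 1")
    e_h_res, e_v_res = _preprocess(raw, cal, dc)
    e_h = _disp_fft(e_h_res, disp, pad_factor)
    e_v = _disp_fft(e_v_res, disp, pad_factor)
    n = raw.shape[0]
    spacing = math.pi * (n - 1) / (raw.source.dk_total_um * n * pad_factor)
    meta = {
        "source": raw.source.to_dict(),
        "dispersion": {"a2": disp.a2, "a3": disp.a3},
        "dc": dc,
        "pad_factor": pad_factor,
        "calibration_hash": cal.source_spec_hash,
        "provenance": dict(raw.provenance),
    }
    return ComplexVolume(e_h, e_v, spacing, meta)


def _entropy(intensity: np.ndarray) -> float:
    """Shannon entropy of the normalized intensity image (sharpness metric)."""
    total = intensity.sum()
    if total <= 0:
        raise ReconError("flat metric: no signal energy in dispersion-optimization subset")
    p = intensity / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def optimize_dispersion(
    raw: RawFringeVolume,
    cal: CalibrationMap,
    a2_range: tuple[float, float] = (-200.0, 200.0),
    a3_range: tuple[float, float] = (-200.0, 200.0),
    n_grid: int = 33,
    dc: str = "bscan-mean",
) -> DispersionCoeffs:
    """Estimate dispersion coefficients by image-sharpness maximization.

    Minimizes the Shannon entropy of the normalized intensity image (sharp
    images concentrate energy, lowering entropy) over ``a2`` then ``a3``,
    each by a coarse grid followed by bounded local refinement, with a final
    ``a2`` refinement pass.  Deterministic given inputs.
    """
    e_h_res, e_v_res = _preprocess(raw, cal, dc)

    def metric(a2: float, a3: float) -> float:
        d = DispersionCoeffs(a2, a3)
        ih = np.abs(_disp_fft(e_h_res, d, 1)) ** 2
        iv = np.abs(_disp_fft(e_v_res, d, 1)) ** 2
        return _entropy(ih + iv)

    def refine(f, lo: float, hi: float, grid_n: int) -> float:
        grid = np.linspace(lo, hi, grid_n)
        vals = [f(g) for g in grid]
        i = int(np.argmin(vals))
        step = grid[1] - grid[0]
        b_lo, b_hi = grid[i] - step, grid[i] + step
        res = minimize_scalar(f, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-4})
        return float(res.x) if res.fun <= vals[i] else float(grid[i])

    a2 = refine(lambda x: metric(x, 0.0), a2_range[0], a2_range[1], n_grid)
    a3 = refine(lambda x: metric(a2, x), a3_range[0], a3_range[1], n_grid)
    a2 = refine(lambda x: metric(x, a3), max(a2 - 25.0, a2_range[0]), min(a2 + 25.0, a2_range[1]), 11)
    return DispersionCoeffs(a2, a3)


def profile_fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """FWHM of a single-peaked 1-D profile via linear half-max crossing interpolation.

    Used on the |A(z)| amplitude envelope to measure the axial PSF width.
    """
    y = np.asarray(profile, dtype=float)
    i_pk = int(np.argmax(y))
    half = y[i_pk] / 2.0
    if y[i_pk] <= 0:
        raise ReconError("profile has no positive peak")
    left = np.nonzero(y[:i_pk] < half)[0]
    right = np.nonzero(y[i_pk:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ReconError("half-max crossings not found within the profile")
    i0 = left[-1]
    x_left = i0 + (half - y[i0]) / (y[i0 + 1] - y[i0])
    i1 = i_pk + right[0]
    x_right = i1 - 1 + (y[i1 - 1] - half) / (y[i1 - 1] - y[i1])
    return float((x_right - x_left) * spacing)
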