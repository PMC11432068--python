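"""Swept-source fringe simulation for a layered eye phantom.

This module generates the raw dual-polarization spectral interferograms that a
polarization-diversity OCT (PD-OCT) system would digitize: two real-valued
fringe channels (horizontal H and vertical V) per A-scan, sampled on a
(possibly nonlinear) wavelength sweep, with unbalanced-dispersion spectral
phase and independent additive detection noise per channel.

Physical model
--------------
The source sweeps a Gaussian power spectrum of FWHM ``fwhm_bandwidth_nm``
centered at ``center_wavelength_nm``.  Sample index ``j`` maps to normalized
wavenumber ``u = g(j/(N-1))`` through a monotone polynomial sweep map ``g``
(identity for a perfectly linearized source).  The sampled wavenumber span is
``sweep_span_factor`` times the FWHM wavenumber span, so the spectral envelope
rolls off toward the sweep edges.

Each phantom layer is populated with discrete scatterers (Poisson count per
A-scan, uniform depth within the layer, uniform random phase).  A scatterer at
depth ``z`` contributes the interference term ``Re{ a_c S(k) exp(i(2 k z + φ +
a2 κ² + a3 κ³)) }`` to channel ``c``, where ``S(k)`` is the spectral envelope,
``κ`` the centered normalized wavenumber and ``a_c`` the scatterer's Jones
amplitude in that channel.  Polarization-preserving scatterers keep the input
Jones state; with probability ``depolarization_p`` a scatterer instead returns
an independent uniformly random pure state (uniform on the Poincaré sphere),
which is the melanin-like depolarization mechanism that lowers DOPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SweptSourceSpec",
    "ScanProtocol",
    "LayerSpec",
    "LesionSpec",
    "PhantomModel",
    "NoiseSpec",
    "RawFringeVolume",
    "synthesize_volume",
    "calibration_fringe",
    "truth_masks",
    "DEFAULT_INPUT_STATE",
]

# Illumination Jones state reaching the sample: 45° linear (equal H/V
# amplitude, zero relative phase) so both detection channels carry signal for
# a polarization-preserving sample.
DEFAULT_INPUT_STATE = (1.0 / math.sqrt(2.0), 1.0 / math.sqrt(2.0))

_LN2 = math.log(2.0)


class SimulationError(ValueError):
    """Raised for invalid phantom/source/protocol combinations."""


@dataclass(frozen=True)
class SweptSourceSpec:
    """Swept laser source and the spectral sampling it produces.

    Parameters
    ----------
    center_wavelength_nm : float
        Sweep center wavelength λ0.
    fwhm_bandwidth_nm : float
        FWHM of the Gaussian power spectrum Δλ; must be < λ0.
    ascan_rate_hz : float
        Sweep repetition (A-scan) rate.
    samples_per_ascan : int
        Digitizer samples per sweep (≥ 16).
    sweep_nonlinearity : tuple of float
        Coefficients ``(c1, c2, ...)`` of the monotone polynomial
        ``raw(s) = c1 s + c2 s² + ...`` mapping normalized sample index to
        (unnormalized) wavenumber progress; the map used is
        ``g(s) = raw(s)/raw(1)``.  ``(1.0,)`` is a linear-in-k sweep.
    dispersion_a2, dispersion_a3 : float
        Quadratic/cubic spectral-phase coefficients (rad) applied as
        ``exp(i(a2 κ² + a3 κ³))`` with κ the centered normalized wavenumber
        in [-1, 1]; models unbalanced dispersion between the arms.
    sweep_span_factor : float
        Total sampled wavenumber span as a multiple of the FWHM span.
    """

    center_wavelength_nm: float = 1060.0
    fwhm_bandwidth_nm: float = 100.0
    ascan_rate_hz: float = 400e3
    samples_per_ascan: int = 2304
    sweep_nonlinearity: tuple[float, ...] = (1.0,)
    dispersion_a2: float = 0.0
    dispersion_a3: float = 0.0
    sweep_span_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.center_wavelength_nm <= 0 or self.fwhm_bandwidth_nm <= 0:
            raise SimulationError("wavelength and bandwidth must be positive")
        if self.fwhm_bandwidth_nm >= self.center_wavelength_nm:
            raise SimulationError("fwhm_bandwidth_nm must be < center_wavelength_nm")
        if self.ascan_rate_hz <= 0:
            raise SimulationError("ascan_rate_hz must be positive")
        if self.samples_per_ascan < 16:
            raise SimulationError("samples_per_ascan must be >= 16")
        if self.sweep_span_factor <= 0:
            raise SimulationError("sweep_span_factor must be positive")
        if not np.all(np.isfinite([self.dispersion_a2, self.dispersion_a3])):
            raise SimulationError("dispersion coefficients must be finite")
        # strict monotonicity of the sweep map over [0, 1]
        s = np.linspace(0.0, 1.0, 2049)
        g = self._raw_sweep(s)
        if not np.all(np.diff(g) > 0):
            raise SimulationError("sweep map must be strictly monotone over [0, 1]")
        object.__setattr__(self, "sweep_nonlinearity", tuple(float(c) for c in self.sweep_nonlinearity))

    # -- derived spectral geometry (lengths in µm, wavenumbers in rad/µm) ----

    def _raw_sweep(self, s: np.ndarray) -> np.ndarray:
        out = np.zeros_like(s, dtype=float)
        for i, c in enumerate(self.sweep_nonlinearity, start=1):
            out += c * s**i
        return out

    def sweep_map(self, s: np.ndarray | float) -> np.ndarray:
        """Normalized wavenumber u = g(s) ∈ [0, 1] for s ∈ [0, 1]."""
        s = np.asarray(s, dtype=float)
        return self._raw_sweep(s) / self._raw_sweep(np.asarray(1.0))

    def sweep_map_inverse(self, u: np.ndarray | float) -> np.ndarray:
        """Numerical inverse of the sweep map on [0, 1]."""
        s = np.linspace(0.0, 1.0, 8193)
        return np.interp(np.asarray(u, dtype=float), self.sweep_map(s), s)

    @property
    def k0_um(self) -> float:
        """Center wavenumber, rad/µm."""
        return 2.0 * math.pi / (self.center_wavelength_nm * 1e-3)

    @property
    def dk_fwhm_um(self) -> float:
        """FWHM wavenumber span, rad/µm."""
        lam = self.center_wavelength_nm * 1e-3
        return 2.0 * math.pi * (self.fwhm_bandwidth_nm * 1e-3) / lam**2

    @property
    def dk_total_um(self) -> float:
        """Total sampled wavenumber span, rad/µm."""
        return self.sweep_span_factor * self.dk_fwhm_um

    @property
    def depth_spacing_um(self) -> float:
        """Depth-pixel spacing of the reconstructed A-scan (no zero padding)."""
        n = self.samples_per_ascan
        return math.pi * (n - 1) / (self.dk_total_um * n)

    @property
    def max_depth_um(self) -> float:
        """Unambiguous (Nyquist) depth range."""
        return self.depth_spacing_um * (self.samples_per_ascan // 2)

    def sample_wavenumbers(self) -> np.ndarray:
        """Wavenumber of each digitizer sample on the (nonlinear) sweep grid."""
        n = self.samples_per_ascan
        s = np.arange(n) / (n - 1)
        u = self.sweep_map(s)
        return self.k0_um + (u - 0.5) * self.dk_total_um

    def spectral_envelope(self, k: np.ndarray) -> np.ndarray:
        """Gaussian power-spectrum envelope evaluated at wavenumbers ``k``."""
        return np.exp(-4.0 * _LN2 * ((k - self.k0_um) / self.dk_fwhm_um) ** 2)

    def dispersion_phase(self, k: np.ndarray) -> np.ndarray:
        """Unbalanced-dispersion spectral phase a2·κ² + a3·κ³ at ``k``."""
        kappa = 2.0 * (k - self.k0_um) / self.dk_total_um
        return self.dispersion_a2 * kappa**2 + self.dispersion_a3 * kappa**3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ScanProtocol:
    """Raster-scan geometry: samples × A-lines × B-scans (+ FOV metadata)."""

    samples_per_ascan: int = 2304
    alines_per_bscan: int = 2000
    bscans_per_volume: int = 1000
    fov_degrees: float = 105.0

    def __post_init__(self) -> None:
        if min(self.samples_per_ascan, self.alines_per_bscan, self.bscans_per_volume) < 1:
            raise SimulationError("all protocol dimensions must be >= 1")
        if self.fov_degrees <= 0:
            raise SimulationError("fov_degrees must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.samples_per_ascan, self.alines_per_bscan, self.bscans_per_volume)

    def acquisition_time_s(self, ascan_rate_hz: float) -> float:
        """Volume acquisition time at the given sweep rate."""
        if ascan_rate_hz <= 0:
            raise SimulationError("ascan_rate_hz must be positive")
        return self.alines_per_bscan * self.bscans_per_volume / ascan_rate_hz

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LayerSpec:
    """One phantom layer: depth extent, scatterer statistics, depolarization.

    ``depolarization_p`` is the probability that a scatterer scrambles the
    polarization state (0 = fully preserving, 1 = every scatterer returns a
    random state).  Melanin-rich layers such as the RPE get high values.
    """

    name: str
    top_depth_um: float
    bottom_depth_um: float
    scatterer_density: float  # expected scatterers per A-scan in this layer
    reflectivity: float  # mean field amplitude per scatterer
    depolarization_p: float = 0.0

    def __post_init__(self) -> None:
        if self.top_depth_um >= self.bottom_depth_um:
            raise SimulationError(f"layer {self.name!r}: top_depth_um must be < bottom_depth_um")
        if not 0.0 <= self.depolarization_p <= 1.0:
            raise SimulationError(f"layer {self.name!r}: depolarization_p must be in [0, 1]")
        if self.scatterer_density < 0 or self.reflectivity < 0:
            raise SimulationError(f"layer {self.name!r}: density and reflectivity must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """Disc-shaped override of a host layer's polarization/reflectivity.

    The disc lives in (A-line, B-scan) index space; scatterers of the host
    layer inside the disc take the override values.  Emulates focal pathology
    (a melanotic nevus as a high-``p`` disc, RPE dropout as a low-``p`` disc).
    """

    center_aline: int
    center_bscan: int
    radius_alines: float
    layer_name: str
    depolarization_p_override: float | None = None
    reflectivity_override: float | None = None

    def __post_init__(self) -> None:
        if self.radius_alines <= 0:
            raise SimulationError("lesion radius must be positive")
        if self.depolarization_p_override is not None and not 0.0 <= self.depolarization_p_override <= 1.0:
            raise SimulationError("lesion depolarization_p_override must be in [0, 1]")


@dataclass(frozen=True)
class PhantomModel:
    """Layered retina phantom (ground truth for simulation and testing)."""

    layers: tuple[LayerSpec, ...]
    lesions: tuple[LesionSpec, ...] = ()
    axial_extent_um: float = 700.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if self.axial_extent_um <= 0:
            raise SimulationError("axial_extent_um must be positive")
        ordered = sorted(layers, key=lambda ly: ly.top_depth_um)
        if list(ordered) != list(layers):
            raise SimulationError("layers must be sorted by top_depth_um")
        for a, b in zip(layers, layers[1:]):
            if a.bottom_depth_um > b.top_depth_um:
                raise SimulationError(f"layers {a.name!r} and {b.name!r} overlap in depth")
        names = {ly.name for ly in layers}
        if len(names) != len(layers):
            raise SimulationError("layer names must be unique")
        for les in self.lesions:
            if les.layer_name not in names:
                raise SimulationError(f"lesion references unknown layer {les.layer_name!r}")

    def layer(self, name: str) -> LayerSpec:
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise KeyError(name)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian detection noise, independent per polarization channel."""

    noise_sigma_h: float = 0.0
    noise_sigma_v: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma_h < 0 or self.noise_sigma_v < 0:
            raise SimulationError("noise sigmas must be >= 0")


@dataclass
class RawFringeVolume:
    """Two-channel real-valued spectral interferogram volume.

    Arrays are indexed ``[sample, aline, bscan]``.
    """

    fringes_h: np.ndarray
    fringes_v: np.ndarray
    source: SweptSourceSpec
    protocol: ScanProtocol
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fringes_h = np.asarray(self.fringes_h, dtype=np.float64)
        self.fringes_v = np.asarray(self.fringes_v, dtype=np.float64)
        if self.fringes_h.shape != self.fringes_v.shape:
            raise SimulationError("H and V fringe arrays must share one shape")
        if self.fringes_h.shape != self.protocol.shape:
            raise SimulationError(
                f"fringe shape {self.fringes_h.shape} does not match protocol {self.protocol.shape}"
            )
        if not (np.all(np.isfinite(self.fringes_h)) and np.all(np.isfinite(self.fringes_v))):
            raise SimulationError("fringe values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fringes_h.shape


def _random_jones(rng_normals: np.ndarray) -> np.ndarray:
    """Map (M, 4) standard normals to M Haar-uniform pure Jones states (M, 2)."""
    z = rng_normals[:, 0::2] + 1j * rng_normals[:, 1::2]
    norm = np.linalg.norm(z, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return z / norm


def _lesion_overrides(
    phantom: PhantomModel,
    layer: LayerSpec,
    aline_idx: np.ndarray,
    bscan_idx: np.ndarray,
    p: np.ndarray,
    amp: np.ndarray,
) -> None:
    """Apply disc lesion overrides in place for scatterers of one layer."""
    for les in phantom.lesions:
        if les.layer_name != layer.name:
            continue
        inside = (aline_idx - les.center_aline) ** 2 + (bscan_idx - les.center_bscan) ** 2 <= les.radius_alines**2
        if les.depolarization_p_override is not None:
            p[inside] = les.depolarization_p_override
        if les.reflectivity_override is not None:
            amp[inside] = les.reflectivity_override


def synthesize_volume(
    phantom: PhantomModel,
    source: SweptSourceSpec,
    protocol: ScanProtocol,
    noise: NoiseSpec,
    seed: int,
    input_state: tuple[complex, complex] = DEFAULT_INPUT_STATE,
    _scatterer_chunk: int = 8192,
) -> RawFringeVolume:
    """Simulate a raw dual-polarization fringe volume from a layered phantom.

    Deterministic for fixed arguments.  Random draws come from a single
    ``numpy.random.default_rng(seed)`` in this documented order, per layer in
    phantom order: (1) Poisson scatterer count per A-scan, (2) scatterer
    depths, (3) scatterer phases, (4) depolarization uniforms, (5) candidate
    random Jones states (drawn for *every* scatterer and used only when the
    uniform falls below the local depolarization probability, so realizations
    are monotonically coupled across ``p``); then (6) H-channel noise and
    (7) V-channel noise, each drawn only when its sigma is nonzero.

    Raises
    ------
    SimulationError
        If a layer extends beyond the unambiguous depth range, the phantom
        exceeds the axial extent, or protocol/source sample counts disagree.
    """
    if protocol.samples_per_ascan != source.samples_per_ascan:
        raise SimulationError("protocol and source samples_per_ascan must agree")
    z_max = source.max_depth_um
    for ly in phantom.layers:
        if ly.bottom_depth_um > phantom.axial_extent_um:
            raise SimulationError(f"layer {ly.name!r} exceeds phantom axial extent")
        if ly.bottom_depth_um >= z_max:
            raise SimulationError(
                f"layer {ly.name!r} extends beyond the unambiguous depth range ({z_max:.1f} um)"
            )
        if ly.top_depth_um < 0:
            raise SimulationError(f"layer {ly.name!r} has negative depth")

    n_samp, n_alines, n_bscans = protocol.shape
    k = source.sample_wavenumbers()
    env = source.spectral_envelope(k)
    disp = source.dispersion_phase(k)
    carrier = env * np.exp(1j * disp)  # (n_samp,) complex; multiplied by exp(i(2kz+phi))

    rng = np.random.default_rng(seed)
    jh0, jv0 = complex(input_state[0]), complex(input_state[1])
    jnorm = math.hypot(abs(jh0), abs(jv0))
    if jnorm == 0:
        raise SimulationError("input_state must be nonzero")
    jh0, jv0 = jh0 / jnorm, jv0 / jnorm

    fr_h = np.zeros((n_samp, n_alines * n_bscans))
    fr_v = np.zeros_like(fr_h)

    for layer in phantom.layers:
        counts = rng.poisson(layer.scatterer_density, size=n_alines * n_bscans)
        m = int(counts.sum())
        if m == 0:
            continue
        col = np.repeat(np.arange(n_alines * n_bscans), counts)
        z = rng.uniform(layer.top_depth_um, layer.bottom_depth_um, size=m)
        phi = rng.uniform(0.0, 2.0 * math.pi, size=m)
        u_dep = rng.uniform(size=m)
        jones_rand = _random_jones(rng.standard_normal((m, 4)))

        p = np.full(m, layer.depolarization_p)
        amp = np.full(m, layer.reflectivity)
        aline_idx = col % n_alines
        bscan_idx = col // n_alines
        _lesion_overrides(phantom, layer, aline_idx, bscan_idx, p, amp)

        depol = u_dep < p
        jones_h = np.where(depol, jones_rand[:, 0], jh0)
        jones_v = np.where(depol, jones_rand[:, 1], jv0)
        w_h = amp * jones_h * np.exp(1j * phi)
        w_v = amp * jones_v * np.exp(1j * phi)

        for lo in range(0, m, _scatterer_chunk):
            hi = min(lo + _scatterer_chunk, m)
            osc = np.exp(2j * np.outer(k, z[lo:hi]))  # (n_samp, chunk)
            osc *= carrier[:, None]
            np.add.at(fr_h, (slice(None), col[lo:hi]), (osc * w_h[lo:hi]).real)
            np.add.at(fr_v, (slice(None), col[lo:hi]), (osc * w_v[lo:hi]).real)

    # flat column index = bscan * n_alines + aline (see aline_idx/bscan_idx above)
    fringes_h = np.ascontiguousarray(np.moveaxis(fr_h.reshape(n_samp, n_bscans, n_alines), 1, 2))
    fringes_v = np.ascontiguousarray(np.moveaxis(fr_v.reshape(n_samp, n_bscans, n_alines), 1, 2))

    if noise.noise_sigma_h > 0:
        fringes_h += rng.normal(0.0, noise.noise_sigma_h, size=fringes_h.shape)
    if noise.noise_sigma_v > 0:
        fringes_v += rng.normal(0.0, noise.noise_sigma_v, size=fringes_v.shape)

    prov = {
        "generator": "pdoct.simulator.synthesize_volume",
        "seed": int(seed),
        "phantom_seed": int(phantom.rng_seed),
        "input_state": [repr(jh0), repr(jv0)],
    }
    return RawFringeVolume(fringes_h, fringes_v, source, protocol, prov)


def calibration_fringe(
    source: SweptSourceSpec,
    mirror_depth_um: float,
    input_state: tuple[complex, complex] = DEFAULT_INPUT_STATE,
) -> RawFringeVolume:
    """Noise-free single-reflector fringe (1 A-line) for sweep calibration.

    The mirror preserves polarization; the fringe carries the source's sweep
    nonlinearity and dispersion phase, exactly as a calibration measurement
    on the instrument would.
    """
    if mirror_depth_um <= 0:
        raise SimulationError("mirror_depth_um must be positive (calibration needs a nonzero fringe frequency)")
    if mirror_depth_um >= source.max_depth_um:
        raise SimulationError("mirror_depth_um beyond the unambiguous depth range")
    k = source.sample_wavenumbers()
    env = source.spectral_envelope(k)
    phase = 2.0 * k * mirror_depth_um + source.dispersion_phase(k)
    jh, jv = complex(input_state[0]), complex(input_state[1])
    jnorm = math.hypot(abs(jh), abs(jv))
    jh, jv = jh / jnorm, jv / jnorm
    field_ = env * np.exp(1j * phase)
    protocol = ScanProtocol(source.samples_per_ascan, 1, 1, fov_degrees=1.0)
    fr_h = (field_ * jh).real[:, None, None]
    fr_v = (field_ * jv).real[:, None, None]
    prov = {"generator": "pdoct.simulator.calibration_fringe", "mirror_depth_um": float(mirror_depth_um)}
    return RawFringeVolume(fr_h, fr_v, source, protocol, prov)


def truth_masks(
    phantom: PhantomModel,
    protocol: ScanProtocol,
    depth_axis: tuple[int, float],
) -> "LabelMaskVolume":
    """Ground-truth layer label volume on the reconstructed depth grid.

    ``depth_axis`` is ``(n_depth, spacing_um)`` matching the reconstruction
    (depth index 0 = zero delay).  Layers get labels 1..L in phantom order;
    lesion voxels keep their host layer's label; background is 0.
    """
    from .contrast import LabelMaskVolume  # local import to avoid a cycle

    n_depth, spacing = depth_axis
    n_depth = int(n_depth)
    spacing = float(spacing)
    if n_depth < 1 or spacing <= 0 or not math.isfinite(spacing):
        raise SimulationError("depth_axis must be (n_depth >= 1, spacing_um > 0)")
    z = np.arange(n_depth) * spacing
    labels = np.zeros((n_depth, protocol.alines_per_bscan, protocol.bscans_per_volume), dtype=np.uint8)
    names: dict[int, str] = {}
    for i, layer in enumerate(phantom.layers, start=1):
        in_layer = (z >= layer.top_depth_um) & (z < layer.bottom_depth_um)
        labels[in_layer, :, :] = i
        names[i] = layer.name
    return LabelMaskVolume(labels=labels, label_names=names)
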