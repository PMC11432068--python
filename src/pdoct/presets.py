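"""Canonical sources, protocols, and phantoms.

``clinical_source``/``clinical_protocol`` carry the acquisition parameters of
the ultra-widefield instrument this package models (1060 nm center, 100 nm
FWHM, 400 kHz sweep; 2304 × 2000 × 1000 raster at 105°).  The desk-scale
presets are reduced volumes with the same spectral geometry, sized so the
full simulate→reconstruct→DOPU chain runs in seconds; layer depths,
densities, reflectivities and depolarization levels are fixed here once and
shared by the test suite so every result refers to the same phantom family.
"""

from __future__ import annotations

from .simulator import (
    LayerSpec,
    LesionSpec,
    NoiseSpec,
    PhantomModel,
    ScanProtocol,
    SweptSourceSpec,
)

__all__ = [
    "clinical_source",
    "clinical_protocol",
    "desk_source",
    "desk_protocol",
    "slab_phantom",
    "retina_phantom",
    "nevus_phantom",
    "quiet_detector",
]


def clinical_source() -> SweptSourceSpec:
    """The instrument's swept source: 1060 nm / 100 nm FWHM / 400 kHz / 2304 samples."""
    return SweptSourceSpec(
        center_wavelength_nm=1060.0,
        fwhm_bandwidth_nm=100.0,
        ascan_rate_hz=400e3,
        samples_per_ascan=2304,
    )


def clinical_protocol() -> ScanProtocol:
    """The instrument's raster: 2304 points × 2000 A-lines × 1000 B-scans, 105° FOV."""
    return ScanProtocol(
        samples_per_ascan=2304,
        alines_per_bscan=2000,
        bscans_per_volume=1000,
        fov_degrees=105.0,
    )


def desk_source(
    samples: int = 512,
    sweep: tuple[float, ...] = (1.0, 0.05),
    a2: float = 0.0,
    a3: float = 0.0,
) -> SweptSourceSpec:
    """Desk-scale source: clinical spectral geometry, reduced sample count.

    Depth pixel ≈ 2.8 µm, unambiguous range ≈ 0.72 mm at 512 samples.  The
    default sweep map s + 0.05 s² is a mild, realistic nonlinearity.
    """
    return SweptSourceSpec(
        center_wavelength_nm=1060.0,
        fwhm_bandwidth_nm=100.0,
        ascan_rate_hz=400e3,
        samples_per_ascan=samples,
        sweep_nonlinearity=sweep,
        dispersion_a2=a2,
        dispersion_a3=a3,
    )


def desk_protocol(samples: int = 512, alines: int = 128, bscans: int = 16) -> ScanProtocol:
    return ScanProtocol(
        samples_per_ascan=samples,
        alines_per_bscan=alines,
        bscans_per_volume=bscans,
        fov_degrees=55.0,
    )


def slab_phantom(
    depolarization_p: float = 0.0,
    top_um: float = 100.0,
    bottom_um: float = 240.0,
    density: float = 25.0,
    reflectivity: float = 1.0,
    seed: int = 0,
) -> PhantomModel:
    """Single uniform slab — the work-horse for estimator characterization."""
    return PhantomModel(
        layers=(
            LayerSpec(
                name="slab",
                top_depth_um=top_um,
                bottom_depth_um=bottom_um,
                scatterer_density=density,
                reflectivity=reflectivity,
                depolarization_p=depolarization_p,
            ),
        ),
        axial_extent_um=bottom_um + 60.0,
        rng_seed=seed,
    )


def retina_phantom(seed: int = 0) -> PhantomModel:
    """Three-layer retina: preserving inner retina, melanin-rich RPE, choroid.

    Depolarization levels follow the physiology the DOPU contrast exploits:
    the inner retina preserves polarization, the RPE (melanin) scrambles it
    strongly, the choroid is intermediate.
    """
    return PhantomModel(
        layers=(
            LayerSpec("inner_retina", 60.0, 250.0, 20.0, 0.3, 0.0),
            LayerSpec("rpe", 250.0, 285.0, 10.0, 1.0, 0.85),
            LayerSpec("choroid", 285.0, 500.0, 25.0, 0.5, 0.3),
        ),
        axial_extent_um=560.0,
        rng_seed=seed,
    )


def nevus_phantom(
    center_aline: int = 64,
    center_bscan: int = 32,
    radius_alines: float = 16.0,
    lesion_p: float = 1.0,
    host_p: float = 0.0,
    seed: int = 0,
) -> PhantomModel:
    """Polarization-preserving host layer with a strongly depolarizing disc.

    Desk-scale analogue of a flat melanotic choroidal nevus: the lesion's
    scrambled polarization makes it a well-circumscribed low-DOPU footprint
    in the minimum-projection en face map even where scattering contrast is
    poor.  The host preserves polarization so the lesion is the only
    low-DOPU structure in the projection.
    """
    return PhantomModel(
        layers=(
            LayerSpec("inner_retina", 60.0, 230.0, 15.0, 0.3, 0.0),
            LayerSpec("host", 250.0, 460.0, 25.0, 0.7, host_p),
        ),
        lesions=(
            LesionSpec(
                center_aline=center_aline,
                center_bscan=center_bscan,
                radius_alines=radius_alines,
                layer_name="host",
                depolarization_p_override=lesion_p,
            ),
        ),
        axial_extent_um=520.0,
        rng_seed=seed,
    )


def quiet_detector() -> NoiseSpec:
    """Noise-free detection (ideal balanced detectors)."""
    return NoiseSpec(0.0, 0.0)
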