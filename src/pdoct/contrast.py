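"""Presentation products: scattering OCT, en face projections, composites.

The scattering OCT image combines the two polarization channels so that the
displayed intensity does not depend on the (arbitrary) polarization state of
the returning light — the polarization-diversity property.  En face maps
project a volume statistic over the depth voxels of one segmented layer;
the minimum projection of filtered DOPU over the RPE/choroid is the melanin
map.  Composite B-scans overlay low-DOPU (depolarizing) voxels in color on
the grayscale log-intensity B-scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps

from .polarimetry import DopuVolume
from .recon import ComplexVolume

__all__ = [
    "IntensityVolume",
    "LabelMaskVolume",
    "EnFaceMap",
    "CompositeImage",
    "scattering_oct",
    "enface",
    "composite",
    "dopu_tint",
]

#: Colormap for the depolarization overlay; evaluated reversed so low DOPU
#: (strong depolarization, melanin) renders warm/bright.
DOPU_CMAP = "inferno"


@dataclass
class IntensityVolume:
    """Linear scattering intensity with a display dB window."""

    linear_intensity: np.ndarray
    db_floor: float
    db_ceiling: float

    def __post_init__(self) -> None:
        if self.db_floor >= self.db_ceiling:
            raise ValueError("db_floor must be < db_ceiling")
        if np.any(self.linear_intensity < 0):
            raise ValueError("linear intensity must be >= 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.linear_intensity.shape

    def to_db(self, clip: bool = True) -> np.ndarray:
        """10·log10 intensity, optionally clipped to the display window."""
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(self.linear_intensity)
        if clip:
            db = np.clip(db, self.db_floor, self.db_ceiling)
        return db


@dataclass
class LabelMaskVolume:
    """Unsigned-integer layer label volume (0 = background)."""

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.unsignedinteger):
            raise ValueError("labels must be an unsigned-integer array")
        present = set(np.unique(self.labels).tolist()) - {0}
        unnamed = present - set(self.label_names)
        if unnamed:
            raise ValueError(f"labels without names: {sorted(unnamed)}")

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return int(lab)
        raise KeyError(f"no layer named {name!r}")


@dataclass
class EnFaceMap:
    """2-D depth projection of one layer: values[aline, bscan]."""

    values: np.ndarray
    mode: str
    source: str
    layer: str


@dataclass
class CompositeImage:
    """RGB composite of grayscale intensity and a DOPU color overlay."""

    rgb: np.ndarray
    overlay_threshold: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")


def scattering_oct(
    vol: ComplexVolume,
    mode: str = "incoherent_sum",
    db_range: float = 40.0,
    percentile: float = 99.9,
) -> IntensityVolume:
    """Polarization-combined scattering intensity volume.

    'incoherent_sum' (default) is |E_H|² + |E_V|²: free of polarization
    artifacts and invariant under any unitary rotation of the channel pair.
    'coherent_mean' is |(E_H + E_V)/2|², the literal complex average of the
    channels, kept as an option (it fades where the two channels are out of
    phase).  The display window spans ``db_range`` dB below the volume's
    ``percentile`` intensity.
    """
    if not (np.all(np.isfinite(vol.e_h.real)) and np.all(np.isfinite(vol.e_v.real))):
        raise ValueError("NaN/Inf in complex volume")
    if mode == "incoherent_sum":
        lin = np.abs(vol.e_h) ** 2 + np.abs(vol.e_v) ** 2
    elif mode == "coherent_mean":
        lin = np.abs((vol.e_h + vol.e_v) / 2.0) ** 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ref = float(np.percentile(lin[lin > 0], percentile)) if np.any(lin > 0) else 1.0
    ceiling = 10.0 * np.log10(ref) if ref > 0 else 0.0
    return IntensityVolume(linear_intensity=lin, db_floor=ceiling - db_range, db_ceiling=ceiling)


def _volume_array(volume) -> tuple[np.ndarray, str]:
    if isinstance(volume, DopuVolume):
        return volume.dopu, "dopu"
    if isinstance(volume, IntensityVolume):
        return volume.linear_intensity, "intensity"
    arr = np.asarray(volume)
    if arr.ndim == 3:
        return arr, "array"
    raise TypeError("volume must be a DopuVolume, IntensityVolume, or 3-D array")


def enface(volume, mask: LabelMaskVolume, layer: str, mode: str = "min") -> EnFaceMap:
    """Depth projection of one segmented layer.

    For each (A-line, B-scan) position the stated statistic (min/mean/max,
    NaN-aware) is taken over the depth voxels carrying the layer's label;
    positions with no labeled voxel project to NaN.
    """
    arr, source = _volume_array(volume)
    if arr.shape != mask.labels.shape:
        raise ValueError(f"volume shape {arr.shape} does not match mask {mask.labels.shape}")
    if mode not in ("min", "mean", "max"):
        raise ValueError(f"unknown projection mode {mode!r}")
    lab = mask.label_of(layer)
    sel = mask.labels == lab
    if not sel.any():
        raise ValueError(f"layer {layer!r} is empty everywhere in the mask")
    masked = np.where(sel, arr, np.nan)
    func = {"min": np.nanmin, "mean": np.nanmean, "max": np.nanmax}[mode]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN columns
        values = func(masked, axis=0)
    return EnFaceMap(values=values, mode=mode, source=source, layer=layer)


def dopu_tint(d: np.ndarray, threshold: float) -> np.ndarray:
    """RGB tint for DOPU values below the overlay threshold.

    Maps DOPU 0 → warm/bright end of the colormap and DOPU = threshold → its
    dark end, so stronger depolarization draws more attention.
    """
    cmap = colormaps[DOPU_CMAP]
    frac = np.clip(1.0 - np.nan_to_num(d, nan=threshold) / threshold, 0.0, 1.0)
    return cmap(frac)[..., :3]


def composite(
    intensity_bscan_db: np.ndarray,
    dopu_bscan: np.ndarray,
    overlay_threshold: float = 0.8,
    alpha: float = 0.6,
    db_window: tuple[float, float] | None = None,
) -> CompositeImage:
    """OCT + DOPU composite B-scan.

    Grayscale dB intensity is the base; voxels with DOPU < overlay_threshold
    are tinted by the DOPU colormap, alpha-blended with weight ``alpha``.
    Deterministic rendering.
    """
    base = np.asarray(intensity_bscan_db, dtype=float)
    d = np.asarray(dopu_bscan, dtype=float)
    if base.shape != d.shape:
        raise ValueError("intensity and DOPU B-scans must share one shape")
    lo, hi = db_window if db_window is not None else (float(np.min(base)), float(np.max(base)))
    if hi <= lo:
        hi = lo + 1.0
    gray = np.clip((base - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    overlay = np.isfinite(d) & (d < overlay_threshold)
    tint = dopu_tint(d, overlay_threshold)
    rgb[overlay] = (1.0 - alpha) * rgb[overlay] + alpha * tint[overlay]
    return CompositeImage(rgb=rgb, overlay_threshold=float(overlay_threshold), alpha=float(alpha))
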