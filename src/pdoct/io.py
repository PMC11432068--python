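"""File codecs: raw fringe volumes, complex volumes, masks, DOPU, renders.

Every binary artifact travels with a JSON sidecar (``<stem>.json``) holding
shape, axis order, dtype and provenance; reads fail hard when the sidecar is
missing rather than guessing dimensions.  Volumes are float32 little-endian;
masks are unsigned 8-bit multi-page TIFF; en face maps are written both as
float32 TIFF (quantitative) and 16-bit PNG (display); composites as 8-bit PNG.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .contrast import CompositeImage, EnFaceMap, LabelMaskVolume
from .polarimetry import DopuVolume
from .recon import ComplexVolume
from .simulator import RawFringeVolume, ScanProtocol, SweptSourceSpec

__all__ = [
    "write_raw",
    "read_raw",
    "write_complex",
    "read_complex",
    "write_mask",
    "read_mask",
    "write_dopu",
    "read_dopu",
    "write_enface",
    "write_composite",
    "write_calibration",
    "read_calibration",
    "sha256_file",
    "SidecarError",
]

_CANON_AXES = ("sample", "aline", "bscan")


class SidecarError(RuntimeError):
    """Missing or inconsistent JSON sidecar."""


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise SidecarError(f"sidecar {sc} not found; refusing to guess dimensions")
    with open(sc) as f:
        return json.load(f)


def _dump_sidecar(path: Path, meta: dict) -> Path:
    sc = _sidecar_path(path)
    with open(sc, "w") as f:
        json.dump(meta, f, indent=1, sort_keys=True, default=str)
        f.write("\n")
    return sc


def _axis_perm(axis_order: str) -> tuple[int, ...]:
    axes = tuple(axis_order.split(","))
    if sorted(axes) != sorted(_CANON_AXES):
        raise SidecarError(f"unknown axis order {axis_order!r}")
    return tuple(axes.index(a) for a in _CANON_AXES)


# ---------------------------------------------------------------- raw fringes


def write_raw(path: str | Path, raw: RawFringeVolume, axis_order: str = "sample,aline,bscan") -> list[Path]:
    """Write a RawFringeVolume as float32 raw binary + JSON sidecar.

    Layout: for each B-scan, the H spectral plane then the V plane
    (channel-interleaved by plane), planes stored in the given axis order.
    """
    path = Path(path)
    perm = _axis_perm(axis_order)
    inv = np.argsort(perm)
    h = np.transpose(raw.fringes_h, inv).astype("<f4")
    v = np.transpose(raw.fringes_v, inv).astype("<f4")
    # interleave on the axis that holds B-scans in the stored order
    b_axis = axis_order.split(",").index("bscan")
    stacked = np.stack([np.moveaxis(h, b_axis, 0), np.moveaxis(v, b_axis, 0)], axis=1)
    with open(path, "wb") as f:
        stacked.tofile(f)
    meta = {
        "format": "pdoct-raw-fringes",
        "version": 1,
        "dtype": "float32",
        "byte_order": "little",
        "shape": list(raw.shape),
        "axis_order": axis_order,
        "channels": ["H", "V"],
        "channel_interleave": "per-bscan-plane",
        "units": "ADC-arbitrary",
        "source": raw.source.to_dict(),
        "protocol": raw.protocol.to_dict(),
        "provenance": raw.provenance,
    }
    return [path, _dump_sidecar(path, meta)]


def read_raw(path: str | Path) -> RawFringeVolume:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("format") != "pdoct-raw-fringes":
        raise SidecarError(f"{path} is not a raw fringe volume (format={meta.get('format')!r})")
    shape = tuple(meta["shape"])  # canonical (sample, aline, bscan)
    axis_order = meta["axis_order"]
    perm = _axis_perm(axis_order)
    stored_shape = tuple(shape[p] for p in np.argsort(perm))
    b_axis = axis_order.split(",").index("bscan")
    n_b = stored_shape[b_axis]
    plane_shape = tuple(s for i, s in enumerate(stored_shape) if i != b_axis)
    data = np.fromfile(path, dtype="<f4")
    expected = n_b * 2 * int(np.prod(plane_shape))
    if data.size != expected:
        raise SidecarError(f"{path}: {data.size} samples on disk, sidecar implies {expected}")
    data = data.reshape((n_b, 2) + plane_shape)
    h = np.moveaxis(data[:, 0], 0, b_axis)
    v = np.moveaxis(data[:, 1], 0, b_axis)
    h = np.transpose(h, perm)
    v = np.transpose(v, perm)
    source = SweptSourceSpec(**{**meta["source"], "sweep_nonlinearity": tuple(meta["source"]["sweep_nonlinearity"])})
    protocol = ScanProtocol(**meta["protocol"])
    return RawFringeVolume(h, v, source, protocol, meta.get("provenance", {}))


# ------------------------------------------------------------- complex volume


def write_complex(path: str | Path, vol: ComplexVolume) -> list[Path]:
    """Write a ComplexVolume as four float32 blocks (Hre, Him, Vre, Vim) + sidecar."""
    path = Path(path)
    blocks = [vol.e_h.real, vol.e_h.imag, vol.e_v.real, vol.e_v.imag]
    with open(path, "wb") as f:
        for b in blocks:
            np.ascontiguousarray(b, dtype="<f4").tofile(f)
    meta = {
        "format": "pdoct-complex-volume",
        "version": 1,
        "dtype": "float32",
        "byte_order": "little",
        "shape": list(vol.shape),
        "axis_order": "depth,aline,bscan",
        "blocks": ["h_real", "h_imag", "v_real", "v_imag"],
        "depth_spacing_um": vol.depth_spacing_um,
        "meta": vol.meta,
    }
    return [path, _dump_sidecar(path, meta)]


def read_complex(path: str | Path) -> ComplexVolume:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("format") != "pdoct-complex-volume":
        raise SidecarError(f"{path} is not a complex volume")
    shape = tuple(meta["shape"])
    data = np.fromfile(path, dtype="<f4")
    n = int(np.prod(shape))
    if data.size != 4 * n:
        raise SidecarError(f"{path}: size mismatch with sidecar shape")
    blocks = data.reshape(4, *shape)
    e_h = blocks[0] + 1j * blocks[1]
    e_v = blocks[2] + 1j * blocks[3]
    return ComplexVolume(e_h, e_v, float(meta["depth_spacing_um"]), meta.get("meta", {}))


# -------------------------------------------------------------------- masks


def write_mask(path: str | Path, mask: LabelMaskVolume) -> list[Path]:
    """Write a label volume as multi-page uint8 TIFF (pages = depth) + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.uint8), photometric="minisblack")
    meta = {
        "format": "pdoct-label-mask",
        "version": 1,
        "shape": list(mask.labels.shape),
        "axis_order": "depth,aline,bscan",
        "label_names": {str(k): v for k, v in mask.label_names.items()},
    }
    return [path, _dump_sidecar(path, meta)]


def read_mask(path: str | Path) -> LabelMaskVolume:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("format") != "pdoct-label-mask":
        raise SidecarError(f"{path} is not a label mask")
    labels = tifffile.imread(path)
    if list(labels.shape) != meta["shape"]:
        raise SidecarError(f"{path}: TIFF shape {labels.shape} != sidecar {meta['shape']}")
    names = {int(k): v for k, v in meta["label_names"].items()}
    return LabelMaskVolume(labels=labels.astype(np.uint8), label_names=names)


# --------------------------------------------------------------------- DOPU


def write_dopu(path: str | Path, d: DopuVolume) -> list[Path]:
    path = Path(path)
    tifffile.imwrite(path, d.dopu.astype(np.float32), photometric="minisblack")
    meta = {
        "format": "pdoct-dopu-volume",
        "version": 1,
        "shape": list(d.dopu.shape),
        "axis_order": "depth,aline,bscan",
        "kernel": list(d.kernel),
        "filtered": d.filtered,
        "threshold_used": d.threshold_used,
    }
    return [path, _dump_sidecar(path, meta)]


def read_dopu(path: str | Path) -> DopuVolume:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("format") != "pdoct-dopu-volume":
        raise SidecarError(f"{path} is not a DOPU volume")
    arr = tifffile.imread(path).astype(np.float64)
    return DopuVolume(
        dopu=arr,
        kernel=tuple(meta["kernel"]),
        filtered=bool(meta["filtered"]),
        threshold_used=float(meta["threshold_used"]),
    )


# ------------------------------------------------------------------ renders


def write_enface(stem: str | Path, emap: EnFaceMap, display_range: tuple[float, float] | None = None) -> list[Path]:
    """Write an en face map as float32 TIFF + 16-bit PNG + sidecar."""
    stem = Path(stem)
    tif = stem.with_suffix(".tif")
    png = stem.with_suffix(".png")
    tifffile.imwrite(tif, emap.values.astype(np.float32), photometric="minisblack")
    finite = emap.values[np.isfinite(emap.values)]
    if display_range is None:
        lo, hi = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
    else:
        lo, hi = display_range
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((np.nan_to_num(emap.values, nan=lo) - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(png, (scaled * 65535).astype(np.uint16))
    meta = {
        "format": "pdoct-enface",
        "version": 1,
        "shape": list(emap.values.shape),
        "axis_order": "aline,bscan",
        "mode": emap.mode,
        "source": emap.source,
        "layer": emap.layer,
        "png_display_range": [lo, hi],
    }
    return [tif, png, _dump_sidecar(tif, meta)]


def write_composite(path: str | Path, img: CompositeImage) -> list[Path]:
    """Write a composite B-scan as 8-bit RGB PNG + sidecar."""
    path = Path(path)
    rgb8 = np.clip(img.rgb * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(path, rgb8)
    meta = {
        "format": "pdoct-composite",
        "version": 1,
        "shape": list(img.rgb.shape[:2]),
        "overlay_threshold": img.overlay_threshold,
        "alpha": img.alpha,
    }
    return [path, _dump_sidecar(path, meta)]


# -------------------------------------------------------------- calibration


def write_calibration(path: str | Path, cal) -> list[Path]:
    from .recon import CalibrationMap  # noqa: F401  (type only)

    path = Path(path)
    payload = {
        "format": "pdoct-calibration",
        "version": 1,
        "source_spec_hash": cal.source_spec_hash,
        "resample_positions": [float(x) for x in cal.resample_positions],
    }
    with open(path, "w") as f:
        json.dump(payload, f)
        f.write("\n")
    return [path]


def read_calibration(path: str | Path):
    from .recon import CalibrationMap

    with open(path) as f:
        payload = json.load(f)
    if payload.get("format") != "pdoct-calibration":
        raise SidecarError(f"{path} is not a calibration file")
    return CalibrationMap(np.array(payload["resample_positions"]), payload.get("source_spec_hash", ""))
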