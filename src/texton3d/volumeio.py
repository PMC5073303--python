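"""Volume I/O: read/write 3D stacks, isotropic resampling, depth cropping, normalization.

A :class:`Volume` is a 3D nonnegative intensity grid in ``(z, y, x)`` index
order (0-based, voxel centers at integer coordinates) together with the
per-axis voxel pitch in micrometres.  SHG stacks are typically acquired with
anisotropic pitch (e.g. 1.0 um axial, 0.37 um lateral); every downstream
texture operation assumes equal pitch, and :func:`interpolate_isotropic` is
the only producer of such volumes.

Spacing source of truth: an explicit override (config/manifest) wins over
TIFF metadata, which is unreliable on many microscope exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, ParameterError, SizeError

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "LabeledStackManifest",
    "load_stack",
    "write_stack",
    "interpolate_isotropic",
    "crop_depth",
    "normalize_intensity",
    "read_manifest",
    "write_manifest",
]


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Intensity grid, ``(z, y, x)`` order.
    spacing : tuple of float
        Voxel pitch in micrometres per axis, ``(dz, dy, dx)``; strictly positive.
    provenance : list of str
        Source path and a log of transforms applied.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be three positive pitches, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.spacing
        ref = min(self.spacing)
        return all(abs(s - ref) <= 1e-9 * ref for s in (dz, dy, dx))

    def with_values(self, values: np.ndarray, note: str) -> "Volume":
        return replace(self, values=values, provenance=self.provenance + [note])


@dataclass
class LabeledStackManifest:
    """Class-labeled list of stacks used for training/evaluation.

    ``entries`` are ``(path, class_label, patient_id)`` triples; every label
    must be in ``classes`` and paths must be unique.
    """

    entries: list[tuple[str, str, str]]
    classes: list[str]

    def __post_init__(self) -> None:
        paths = [e[0] for e in self.entries]
        if len(set(paths)) != len(paths):
            raise FormatError("manifest paths are not unique")
        bad = {e[1] for e in self.entries} - set(self.classes)
        if bad:
            raise FormatError(f"manifest labels {sorted(bad)} not in class set {self.classes}")

    @property
    def labels(self) -> list[str]:
        return [e[1] for e in self.entries]

    @property
    def paths(self) -> list[str]:
        return [e[0] for e in self.entries]


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort (dz, dy, dx) in micrometres from TIFF/ImageJ metadata."""
    dz = dy = dx = None
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None and xres.value[0]:
            dx = xres.value[1] / xres.value[0]
        if yres is not None and yres.value[0]:
            dy = yres.value[1] / yres.value[0]
    except Exception:  # pragma: no cover - defensive against exotic tags
        pass
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        dz = float(meta["spacing"])
    if dz is None or dy is None or dx is None:
        return None
    return (dz, dy, dx)


def load_stack(path, spacing: tuple[float, float, float] | None = None) -> Volume:
    """Read a multi-page grayscale TIFF as a :class:`Volume`.

    ``spacing`` (config override) wins over TIFF resolution tags; if neither
    is available a :class:`FormatError` is raised.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            tag_spacing = _spacing_from_tiff(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
    if values.ndim == 2:
        values = values[None]
    if values.ndim != 3:
        raise FormatError(
            f"{path!r} is not a single-channel z-stack (shape {values.shape}); "
            "RGB/multichannel TIFFs are not supported"
        )
    use = spacing if spacing is not None else tag_spacing
    if use is None:
        raise FormatError(f"{path!r} has no resolvable voxel spacing and no override was given")
    return Volume(values=values, spacing=use, provenance=[f"loaded {path}"])


def write_stack(path, volume: Volume) -> None:
    """Write a volume as a multi-page grayscale TIFF with ImageJ spacing metadata."""
    dz, dy, dx = volume.spacing
    values = volume.values
    if values.dtype == np.float64:
        values = values.astype(np.float32)
    tifffile.imwrite(
        path,
        values,
        imagej=True,
        photometric="minisblack",
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def _resample_axis(values: np.ndarray, axis: int, coords: np.ndarray) -> np.ndarray:
    """Linear interpolation of `values` along one axis at fractional `coords`."""
    n = values.shape[axis]
    coords = np.clip(coords, 0.0, n - 1.0)
    i0 = np.floor(coords).astype(np.intp)
    i0 = np.minimum(i0, n - 2) if n > 1 else i0
    w = coords - i0
    lo = np.take(values, i0, axis=axis)
    hi = np.take(values, np.minimum(i0 + 1, n - 1), axis=axis)
    shape = [1] * values.ndim
    shape[axis] = len(coords)
    w = w.reshape(shape)
    return lo * (1.0 - w) + hi * w


def interpolate_isotropic(volume: Volume) -> Volume:
    """Trilinearly resample to equal voxel pitch (the smallest of the three).

    The depth axis is upsampled rather than the lateral axes downsampled, so
    lateral detail is preserved.  Constant volumes are preserved exactly; an
    already-isotropic volume is returned unchanged (values identical).
    """
    if volume.is_isotropic:
        return volume.with_values(volume.values, "isotropic (no-op)")
    target = min(volume.spacing)
    values = volume.values
    for axis in range(3):
        pitch = volume.spacing[axis]
        n = values.shape[axis]
        if abs(pitch - target) <= 1e-9 * target:
            continue
        if n < 2:
            raise SizeError(
                f"cannot resample axis {axis} with a single sample (pitch {pitch} -> {target})"
            )
        n_new = int(round((n - 1) * pitch / target)) + 1
        coords = np.arange(n_new) * (target / pitch)
        values = _resample_axis(values, axis, coords)
    out = Volume(
        values=values,
        spacing=(target, target, target),
        provenance=volume.provenance + [f"resampled to isotropic pitch {target} um"],
    )
    return out


def crop_depth(volume: Volume, max_depth_um: float) -> Volume:
    """Keep only slices at depth < ``max_depth_um`` from the first slice.

    SHG signal decays with imaging depth; restricting to the top of the stack
    keeps contrast comparable across specimens.  Cropping deeper than the
    volume returns the whole volume with a logged warning.
    """
    dz = volume.spacing[0]
    if max_depth_um <= dz:
        if max_depth_um <= 0:
            raise ParameterError("max_depth_um must be positive")
    n_keep = int(np.ceil(max_depth_um / dz))
    n_keep = max(n_keep, 1)
    if n_keep >= volume.shape[0]:
        if n_keep > volume.shape[0]:
            logger.warning(
                "crop_depth: requested %.3g um exceeds volume depth %.3g um; keeping all slices",
                max_depth_um,
                volume.shape[0] * dz,
            )
        return volume.with_values(volume.values, f"depth crop {max_depth_um} um (no-op)")
    return volume.with_values(
        volume.values[:n_keep], f"depth crop to {n_keep} slices (<{max_depth_um} um)"
    )


def normalize_intensity(volume: Volume) -> Volume:
    """Rescale intensities to zero mean and unit standard deviation.

    A constant volume maps to all zeros.  This global normalization stands in
    for acquisition-to-acquisition brightness differences; no per-voxel Weber
    contrast normalization is applied (config switch in the pipeline).
    """
    values = np.asarray(volume.values, dtype=np.float64)
    sd = values.std()
    if sd == 0:
        out = np.zeros_like(values)
    else:
        out = (values - values.mean()) / sd
    return volume.with_values(out, "intensity z-score normalized")


def read_manifest(path) -> LabeledStackManifest:
    """Read a CSV manifest with columns path,label,patient_id."""
    df = pd.read_csv(path, dtype=str)
    required = {"path", "label"}
    if not required <= set(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    if "patient_id" not in df.columns:
        df["patient_id"] = ""
    entries = [
        (r.path, r.label, r.patient_id if isinstance(r.patient_id, str) else "")
        for r in df.itertuples()
    ]
    classes = sorted({e[1] for e in entries})
    return LabeledStackManifest(entries=entries, classes=classes)


def write_manifest(path, manifest: LabeledStackManifest) -> None:
    df = pd.DataFrame(manifest.entries, columns=["path", "label", "patient_id"])
    df.to_csv(path, index=False)
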