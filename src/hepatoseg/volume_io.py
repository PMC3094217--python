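"""Reading and writing CT volumes, binary masks and label maps.

All in-memory grids use ``(z, y, x)`` index order: ``data[k]`` is the axial
slice at index ``k`` and ``z`` increases from inferior to superior.  Voxel
spacing and origin are stored in the same order, in millimetres.  Intensities
are kept exactly as stored on disk -- no rescaling or windowing is applied,
because every threshold used downstream is estimated from the data itself.

File formats are MetaImage (``.mhd``/``.raw``, including RLE-compressed
reads) and NIfTI (``.nii``/``.nii.gz``), handled through SimpleITK.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "Mask",
    "LabelMap",
    "VolumeFormatError",
    "read_volume",
    "read_mask",
    "read_labelmap",
    "write_volume",
    "write_mask",
    "write_labelmap",
]


class VolumeFormatError(ValueError):
    """Raised when a file does not describe a valid 3D scalar volume."""


@dataclass
class Volume:
    """A 3D scalar grid with anisotropic voxel spacing.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.
    spacing
        ``(sz, sy, sx)`` voxel spacing in mm, all strictly positive.
    origin
        ``(oz, oy, ox)`` position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D array, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx


@dataclass
class Mask(Volume):
    """Binary grid aligned with a companion :class:`Volume` (values 0/1)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise VolumeFormatError(f"mask values must be 0/1, found {vals}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class LabelMap(Volume):
    """Small-integer label grid with a legend mapping label -> name."""

    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.data < 0):
            raise VolumeFormatError("labels must be non-negative")
        self.data = self.data.astype(np.uint8)
        present = set(int(v) for v in np.unique(self.data)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise VolumeFormatError(f"labels without legend entry: {missing}")


def same_geometry(a: Volume, b: Volume, tol: float = 1e-6) -> bool:
    """True when two grids share shape and spacing (alignment check)."""
    return a.shape == b.shape and all(
        abs(x - y) <= tol for x, y in zip(a.spacing, b.spacing)
    )


# ---------------------------------------------------------------------------
# I/O


def _check_path(path: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".mhd"):
        # SimpleITK reports a generic error for a missing companion; check
        # explicitly so the message names the raw file.
        with open(path, "r", errors="replace") as fh:
            for line in fh:
                if line.startswith("ElementDataFile"):
                    raw = line.split("=", 1)[1].strip()
                    if raw in ("LOCAL", "LIST"):
                        return
                    raw_path = os.path.join(os.path.dirname(path), raw)
                    if not os.path.exists(raw_path):
                        raise VolumeFormatError(
                            f"missing companion data file {raw_path!r}"
                        )


def _read_image(path: str) -> sitk.Image:
    _check_path(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - backend message varies
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path!r} is {img.GetDimension()}D, expected a 3D volume"
        )
    if any(s <= 0 for s in img.GetSpacing()):
        raise VolumeFormatError(f"{path!r} has non-positive spacing")
    return img


def read_volume(path: str) -> Volume:
    """Read a MetaImage or NIfTI scalar volume.

    Element values are returned exactly as stored; spacing and origin come
    from the header, reordered to ``(z, y, x)``.
    """
    img = _read_image(path)
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    return Volume(
        data=data,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )


def read_mask(path: str) -> Mask:
    """Read a binary mask; values must be exactly {0, 1}."""
    v = read_volume(path)
    return Mask(data=v.data, spacing=v.spacing, origin=v.origin)


def read_labelmap(path: str, legend: dict[int, str] | None = None) -> LabelMap:
    v = read_volume(path)
    if legend is None:
        legend = {int(k): str(int(k)) for k in np.unique(v.data) if k != 0}
    return LabelMap(data=v.data, spacing=v.spacing, origin=v.origin, legend=legend)


def _to_image(vol: Volume, dtype: np.dtype) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.astype(dtype)))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    return img


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as signed 16-bit (CT Hounsfield-like) MetaImage/NIfTI."""
    sitk.WriteImage(_to_image(vol, np.int16), path)


def write_mask(mask: Mask, path: str) -> None:
    """Write a binary mask as unsigned 8-bit, readable by :func:`read_volume`."""
    sitk.WriteImage(_to_image(mask, np.uint8), path)


def write_labelmap(lmap: LabelMap, path: str) -> None:
    sitk.WriteImage(_to_image(lmap, np.uint8), path)
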