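"""Region-of-interest handling: validation, peritumoral ring, masking, crops.

The tumor mask is the radiologist-drawn (here: phantom-generated)
intratumoral ROI.  The peritumoral region is the 0–4 mm shell obtained by
dilating the tumor by a physical distance and removing the tumor itself;
with ~0.7 mm pixels and 2 mm slices the dilation is done in-plane per slice
by default (a 4 mm 3D dilation would add whole slices anisotropically), with
a 3D option.  Distances are voxel-center Euclidean distances in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIPair",
    "MIN_ROI_VOXELS",
    "validate_roi",
    "build_peritumoral_ring",
    "apply_mask",
    "crop_window",
    "mask_centroid_pixel",
]

#: Subjects whose tumor ROI has fewer voxels than this are excluded.
MIN_ROI_VOXELS = 64


@dataclass
class ROIPair:
    """Disjoint intratumoral core and peritumoral shell on one grid."""

    intratumoral: np.ndarray
    peritumoral: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.intratumoral.shape != self.peritumoral.shape:
            raise ValueError("core and ring must share one grid")
        if np.any(self.intratumoral & self.peritumoral):
            raise ValueError("core and ring overlap")
        if not self.intratumoral.any() or not self.peritumoral.any():
            raise ValueError("core and ring must both be nonempty")

    def region(self, kind: str) -> np.ndarray:
        if kind == "intratumoral":
            return self.intratumoral
        if kind == "peritumoral":
            return self.peritumoral
        raise KeyError(kind)


def validate_roi(mask: np.ndarray, min_voxels: int = MIN_ROI_VOXELS) -> bool:
    """Accept a tumor mask iff it has at least ``min_voxels`` voxels."""
    return int(np.count_nonzero(mask)) >= min_voxels


def build_peritumoral_ring(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    distance_mm: float = 4.0,
    mode: str = "2d",
) -> ROIPair:
    """Build the 0–``distance_mm`` peritumoral shell around a tumor mask.

    Parameters
    ----------
    mask : bool array, (x, y, z)
        Intratumoral ROI; axis 2 is the slice axis.
    spacing : (mm, mm, mm)
        Voxel pitch per axis.
    distance_mm : float
        Shell thickness; the shell is every out-of-mask voxel whose
        Euclidean distance to the mask is <= this.
    mode : {"2d", "3d"}
        "2d" (default) measures distance in-plane within each slice;
        "3d" uses the full anisotropic 3D distance.
    """
    if distance_mm <= 0:
        raise ValueError("dilation distance must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tumor mask")

    if mode == "2d":
        ring = np.zeros_like(mask)
        sampling = (spacing[0], spacing[1])
        for z in range(mask.shape[2]):
            sl = mask[:, :, z]
            if not sl.any():
                continue
            dist = ndimage.distance_transform_edt(~sl, sampling=sampling)
            ring[:, :, z] = (dist > 0) & (dist <= distance_mm)
    elif mode == "3d":
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        ring = (dist > 0) & (dist <= distance_mm)
    else:
        raise ValueError(f"unknown dilation mode {mode!r}")

    if not ring.any():
        raise ValueError(
            f"dilation by {distance_mm} mm produced an empty ring at "
            f"spacing {spacing}"
        )
    return ROIPair(intratumoral=mask, peritumoral=ring, spacing=tuple(spacing))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every voxel outside the mask; in-mask voxels are unchanged."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape}, mask {mask.shape}")
    return np.where(mask, image, 0)


def mask_centroid_pixel(mask: np.ndarray) -> tuple[int, int]:
    """In-plane centroid of a 3D mask, rounded to the nearest pixel.

    Exact .5 ties round toward the lower index.
    """
    idx = np.nonzero(mask)
    if len(idx[0]) == 0:
        raise ValueError("empty mask has no centroid")
    cx, cy = float(np.mean(idx[0])), float(np.mean(idx[1]))

    def _round_half_down(v: float) -> int:
        return int(np.ceil(v - 0.5))

    return _round_half_down(cx), _round_half_down(cy)


def crop_window(
    image: np.ndarray,
    mask: np.ndarray,
    size: int = 224,
) -> tuple[np.ndarray, list[int]]:
    """Crop a fixed in-plane window around the mask centroid, per slice.

    Only slices intersecting the mask are emitted.  The window center is the
    mask's in-plane centroid, fixed across all slices of the subject, and is
    zero-padded where it exceeds the volume bounds.

    Returns
    -------
    (crops, slice_indices)
        ``crops`` has shape (n_slices, size, size); ``slice_indices`` are the
        source slice positions, ascending.
    """
    if size <= 0:
        raise ValueError("crop size must be positive")
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")

    cx, cy = mask_centroid_pixel(mask)
    half = size // 2
    x0, y0 = cx - half, cy - half

    slices = [z for z in range(mask.shape[2]) if mask[:, :, z].any()]
    out = np.zeros((len(slices), size, size), dtype=np.float64)
    for i, z in enumerate(slices):
        src = image[:, :, z]
        sx0, sx1 = max(x0, 0), min(x0 + size, src.shape[0])
        sy0, sy1 = max(y0, 0), min(y0 + size, src.shape[1])
        if sx0 < sx1 and sy0 < sy1:
            out[i, sx0 - x0:sx1 - x0, sy0 - y0:sy1 - y0] = src[sx0:sx1, sy0:sy1]
    return out, slices
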