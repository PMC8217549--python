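"""ROI perturbation by morphological opening and closing.

Contour variability between readers is emulated by applying morphological
opening (erosion then dilation) and closing (dilation then erosion) with a
spherical structuring element of 1-voxel radius, yielding three versions of
each ROI: original, opening, closing.  The element is a Euclidean ball on the
voxel lattice, ignoring anisotropic spacing (the operators act in pixel
units).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import RoiMask


def spherical_structuring_element(radius_voxels: int) -> np.ndarray:
    """Binary ball of the given radius on the integer voxel grid.

    A voxel at integer offset d from the centre is included iff ||d|| <= r.
    For r=1 this is the 6-connected cross (7 voxels).
    """
    r = int(radius_voxels)
    if r < 1:
        raise ValueError("structuring-element radius must be >= 1 voxel")
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dx * dx + dy * dy + dz * dz) <= r * r


def perturb_mask(mask: RoiMask, op: str, kernel: np.ndarray | None = None) -> RoiMask:
    """Apply morphological ``opening`` or ``closing`` to a binary mask.

    Closing is computed on a zero-padded copy so a mask near (but not on) the
    border is not truncated by the image edge.
    """
    if op not in ("opening", "closing"):
        raise ValueError(f"op must be 'opening' or 'closing', got {op!r}")
    if kernel is None:
        kernel = spherical_structuring_element(1)
    grid = mask.data
    if op == "opening":
        out = ndimage.binary_opening(grid, structure=kernel)
        if not out.any():
            raise ValueError(
                "morphological opening emptied the mask (lesion too small "
                "for robustness calibration)"
            )
    else:
        pad = max(kernel.shape) // 2
        padded = np.pad(grid, pad)
        closed = ndimage.binary_closing(padded, structure=kernel)
        out = closed[pad:-pad, pad:-pad, pad:-pad]
    return RoiMask(out, mask.spacing, version=op)


def mask_versions(mask: RoiMask, radius_voxels: int = 1) -> dict[str, RoiMask]:
    """Return the three calibration versions: original, opening, closing."""
    kernel = spherical_structuring_element(radius_voxels)
    return {
        "original": RoiMask(mask.data.copy(), mask.spacing, version="original"),
        "opening": perturb_mask(mask, "opening", kernel),
        "closing": perturb_mask(mask, "closing", kernel),
    }
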