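"""Shared in-memory containers for the radiomics pipeline.

Arrays are indexed (row, column, slice); ``spacing`` gives the physical
voxel size in millimetres along the same axes.  Intensities are arbitrary
units (T2WI-like) or diffusivity-like values (ADC-like); nothing downstream
assumes a particular intensity scale because discretisation is fixed-bin-count
over the ROI's own range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: MRI sequence tags used throughout the pipeline.
SEQUENCES = ("T2W", "ADC")

#: Mask version tags produced by the perturbation stage.
MASK_VERSIONS = ("original", "opening", "closing")

#: Bin counts swept during calibration.
BIN_COUNTS = (8, 16, 32, 64, 128, 256)

#: The six MRI acquisition parameters screened in the decoupling stage.
ACQUISITION_PARAMS = (
    "te",
    "tr",
    "flip_angle",
    "slice_thickness",
    "spacing_between_slices",
    "pixel_spacing",
)

#: Clinical candidate predictors entering the clinical feature table.
CLINICAL_FEATURES = (
    "psa",
    "gland_volume",
    "psa_density",
    "likert",
    "grade_group",
    "zone_tz",
)


@dataclass
class ImageVolume:
    """A 3D scalar image with anisotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    sequence: str = "T2W"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume.data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")


@dataclass
class RoiMask:
    """A binary lesion mask aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    version: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("RoiMask.data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.version not in MASK_VERSIONS:
            raise ValueError(f"unknown mask version {self.version!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class LesionImages:
    """One lesion's volumes (one per sequence) plus its shared original mask."""

    lesion_id: str
    volumes: dict = field(default_factory=dict)  # sequence -> ImageVolume
    mask: RoiMask | None = None
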