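"""Foreground segmentation of a potato slice from a reflectance cube.

The slice sits on a dark sample plate, so a scalar projection (mean
reflectance over the retained bands) separates tissue from background by
Otsu thresholding, followed by basic morphology: closing, hole filling and
keeping the single largest 8-connected component.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .cube_io import Hypercube
from .errors import DegenerateImageError, EmptyMaskError

__all__ = [
    "Mask",
    "SegmentationParams",
    "intensity_image",
    "otsu_threshold",
    "clean_mask",
    "segment_slice",
]


@dataclasses.dataclass
class Mask:
    """Binary foreground raster with the same spatial shape as its cube."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclasses.dataclass
class SegmentationParams:
    closing_radius: int = 2
    min_object_px: int = 50


def intensity_image(cube: Hypercube) -> np.ndarray:
    """Per-pixel mean reflectance over all retained bands."""
    return np.asarray(cube.data, dtype=float).mean(axis=2)


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of the image range.

    Maximizes between-class variance; raises on a constant image.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise DegenerateImageError("constant image: no threshold exists")
    return float(filters.threshold_otsu(image, nbins=256))


def clean_mask(mask, min_object_px: int = 50, closing_radius: int = 2) -> Mask:
    """Morphological cleanup: closing, hole filling, largest 8-connected blob."""
    data = np.asarray(getattr(mask, "data", mask), dtype=bool)
    if closing_radius > 0:
        data = morphology.closing(data, morphology.disk(closing_radius))
    data = ndimage.binary_fill_holes(data)
    labels = measure.label(data, connectivity=2)
    if labels.max() == 0:
        raise EmptyMaskError("no foreground after morphological cleaning")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    if sizes[largest] < min_object_px:
        raise EmptyMaskError(
            f"largest component has {sizes[largest]} px < min_object_px={min_object_px}"
        )
    return Mask(labels == largest)


def segment_slice(cube: Hypercube, params: SegmentationParams | None = None) -> Mask:
    """Segment the slice: mean-band projection -> Otsu -> morphology."""
    params = params or SegmentationParams()
    image = intensity_image(cube)
    threshold = otsu_threshold(image)
    rough = image > threshold
    if not rough.any():
        raise EmptyMaskError("no pixels above the Otsu threshold")
    return clean_mask(rough, params.min_object_px, params.closing_radius)
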