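"""2-D greyscale and binary morphology primitives.

These are the building blocks the field pipeline composes: greyscale
opening, zero-clamped subtraction, fixed-threshold binarization, a size
filter that also removes objects enclosed by larger ones, topology
preserving skeletonization, skeleton endpoint extraction, and binary
dilation/erosion.

Conventions fixed here and relied on everywhere else:

* images are row-major, origin top-left, 0-based;
* foreground connectivity is 8, background (hole) connectivity is 4;
* ``binarize`` uses a strict ``> threshold`` comparison, which makes the
  masks invariant under any positive rescaling of image and threshold
  together — the property that lets one preset threshold serve a whole
  set of experiments regardless of staining intensity;
* all areas and lengths are plain pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as _skmorph

__all__ = [
    "GreyImage",
    "StructuringElement",
    "grey_open",
    "subtract",
    "binarize",
    "size_filter",
    "skeletonize",
    "find_endpoints",
    "dilate",
    "erode",
]

# 8-connectivity structure for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)
# kernel counting the 8-neighbourhood (centre excluded)
_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass(frozen=True)
class StructuringElement:
    """A flat structuring element: ``disk`` (Euclidean ball) or ``square``.

    ``radius`` is in pixels; a disk of radius r covers pixels within
    Euclidean distance r of the centre, a square spans (2r+1) x (2r+1).
    """

    shape: str = "disk"
    radius: int = 8

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "square"):
            raise ValueError(f"unknown structuring element shape {self.shape!r}")
        if int(self.radius) < 1:
            raise ValueError("structuring element radius must be >= 1")
        object.__setattr__(self, "radius", int(self.radius))

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return _skmorph.disk(self.radius).astype(bool)
        side = 2 * self.radius + 1
        return np.ones((side, side), dtype=bool)


@dataclass
class GreyImage:
    """A single-channel 2-D image with a nominal bit depth.

    ``pixels`` may be any numeric dtype (float is fine, e.g. after
    intensity rescaling); values must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("image must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def inverted(self) -> "GreyImage":
        """Intensity complement (for dark-on-light, e.g. Golgi stains)."""
        return GreyImage(self.max_value - np.asarray(self.pixels, dtype=np.float64),
                         bit_depth=self.bit_depth)

    def scaled(self, k: float) -> "GreyImage":
        """Multiply all intensities by ``k`` (clipped to the valid range)."""
        return GreyImage(np.clip(self.pixels * float(k), 0, self.max_value),
                         bit_depth=self.bit_depth)


def _check_se_fits(img: GreyImage, se: StructuringElement) -> None:
    if 2 * se.radius + 1 > min(img.height, img.width):
        raise ValueError("structuring element exceeds image")


def grey_open(img: GreyImage, se: StructuringElement) -> GreyImage:
    """Greyscale opening: erosion then dilation with ``se``.

    Suppresses bright structures thinner than the structuring element
    (neurites) while leaving larger blobs (somata) essentially intact.
    Anti-extensive, increasing, and idempotent.
    """
    _check_se_fits(img, se)
    opened = _skmorph.opening(np.asarray(img.pixels), se.footprint())
    return GreyImage(opened, bit_depth=img.bit_depth)


def subtract(a: GreyImage, b: GreyImage) -> GreyImage:
    """Pixelwise ``max(a - b, 0)`` — clamped at zero, never wrapping.

    ``subtract(img, grey_open(img, se))`` is the white top-hat that
    isolates fibre-like structures.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"shape mismatch: {a.pixels.shape} vs {b.pixels.shape}"
        )
    if a.bit_depth != b.bit_depth:
        raise ValueError("bit depth mismatch")
    diff = np.asarray(a.pixels, dtype=np.float64) - np.asarray(b.pixels, dtype=np.float64)
    return GreyImage(np.maximum(diff, 0.0), bit_depth=a.bit_depth)


def binarize(img: GreyImage, threshold: float) -> np.ndarray:
    """Boolean mask, true exactly where intensity is strictly above ``threshold``."""
    if not 0 <= threshold <= img.max_value:
        raise ValueError(
            f"threshold {threshold} outside [0, {img.max_value}]"
        )
    return np.asarray(img.pixels) > threshold


def size_filter(mask: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    """Remove every connected component smaller than ``min_area`` pixels.

    Works on plain component labelling, so components topologically
    enclosed by larger ones (specks trapped inside neurite loops) are
    removed just like free-standing ones. Components with area >=
    ``min_area`` pass through unchanged. Idempotent.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 1 or not mask.any():
        return mask.copy()
    structure = _STRUCT8 if connectivity == 8 else ndi.generate_binary_structure(2, 1)
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Homotopy-preserving thinning to a one-pixel-wide skeleton.

    Zhang–Suen-class thinning: the result is a subset of the input with
    the same number of 8-connected components and holes.
    """
    return _skmorph.skeletonize(np.asarray(mask, dtype=bool))


def neighbour_counts(skel: np.ndarray) -> np.ndarray:
    """Number of foreground 8-neighbours at each pixel (image border = background)."""
    return ndi.convolve(np.asarray(skel, dtype=np.uint8), _NEIGHBOUR_KERNEL,
                        mode="constant", cval=0)


def find_endpoints(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with exactly one foreground 8-neighbour.

    On one-pixel-wide input this is identical to eroding away the
    terminal pixels and subtracting the result from the skeleton, but a
    single neighbour-count convolution is cheaper.
    """
    skel = np.asarray(skel, dtype=bool)
    return skel & (neighbour_counts(skel) == 1)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation: union of ``se`` translates centred on foreground pixels."""
    return ndi.binary_dilation(np.asarray(mask, dtype=bool),
                               structure=se.footprint(), border_value=0)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion (image border treated as background)."""
    return ndi.binary_erosion(np.asarray(mask, dtype=bool),
                              structure=se.footprint(), border_value=0)
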