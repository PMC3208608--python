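"""The per-field measurement algorithm.

One field of view (a single-channel micrograph of a dense neuronal
culture, neurite-filling marker such as betaIII-tubulin/TuJ1 or MAP2)
goes through a fixed sequence of morphological filters:

1.  greyscale opening amplifies globular, cell-body-like structures;
2.  binarization of the opened image gives the raw soma mask, and
    small objects are removed by size filtering;
3.  subtracting the opened image from the original (white top-hat)
    amplifies fibre-like structures;
4.  binarization plus size filtering gives the neurite mask, which is
    thinned to a one-pixel-wide fiber skeleton;
5.  the skeleton/soma overlap is subtracted to yield the clean neurite
    representation whose pixel count is the total neurite length;
6.  neurite endpoints are the terminal pixels of the fiber skeleton
    that do not fall inside a soma;
7.  attachment points are the terminal pixels of the proximal neurite
    segments (fiber skeleton clipped to a thin dilation band around
    the somata), again excluding pixels inside the somata.

Endpoint and attachment detection deliberately operate on the fiber
skeleton *before* soma subtraction: a neurite attached to a soma
continues into the cell body there, so its root is not a terminal pixel
and only the distal tips count as endpoints. Running the same steps on
the soma-subtracted skeleton would turn every root into a spurious
endpoint and split every attachment into two proximal terminals.

Everything is a pure function of (image, config): identical inputs give
identical masks and numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .morphology import (
    GreyImage,
    StructuringElement,
    binarize,
    dilate,
    find_endpoints,
    grey_open,
    size_filter,
    skeletonize,
    subtract,
)

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "FieldMeasurements",
    "read_field_image",
    "segment_somata",
    "segment_neurites",
    "detect_endpoints",
    "detect_attachments",
    "measure_field",
    "render_overlay",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the field pipeline.

    All radii/areas are in pixels at acquisition scale (defaults are
    tuned for ~10x magnification, somata 16-28 px across):

    soma_open_se
        structuring element of the opening; must be larger than a
        neurite cross-section and no larger than a soma.
    soma_threshold / neurite_threshold
        fixed binarization thresholds for the opened image and the
        top-hat image respectively; one preset value serves a whole
        image set because the morphological amplification, not the
        absolute intensity, carries the signal.
    soma_min_area / neurite_min_area
        size-filter floors removing debris and imaging specks.
    attachment_dilation_se
        half-width of the proximal band around somata used for
        attachment detection; must bridge the 1-2 px seam left by the
        soma subtraction without merging neighbouring somata.
    reference_soma_area
        user-defined area of a typical single cell body, used to
        estimate neuron number when somata cluster.
    invert_input
        complement intensities first (dark-on-light input such as
        Golgi-stained sections).
    ratio_length_floor / ratio_soma_floor
        below these, ratio-based derived statistics are flagged as
        low-content (few cells or tiny fragments make them unreliable).
    avg_neurite_denominator
        "attachments" (default: primary neurites per field) or
        "endpoints" for the average individual-neurite length.
    """

    soma_open_se: StructuringElement = StructuringElement("disk", 8)
    soma_threshold: float = 1000.0
    neurite_threshold: float = 300.0
    soma_min_area: int = 60
    neurite_min_area: int = 30
    attachment_dilation_se: StructuringElement = StructuringElement("disk", 3)
    reference_soma_area: float = 315.0
    invert_input: bool = False
    ratio_length_floor: float = 50.0
    ratio_soma_floor: float = 100.0
    avg_neurite_denominator: str = "attachments"

    def __post_init__(self) -> None:
        if self.reference_soma_area <= 0:
            raise ValueError("reference_soma_area must be > 0")
        if min(self.soma_min_area, self.neurite_min_area) < 0:
            raise ValueError("minimum areas must be >= 0")
        if self.avg_neurite_denominator not in ("attachments", "endpoints"):
            raise ValueError("avg_neurite_denominator must be 'attachments' or 'endpoints'")

    def scaled(self, k: float) -> "PipelineConfig":
        """Config with both intensity thresholds multiplied by ``k``."""
        return replace(self, soma_threshold=self.soma_threshold * k,
                       neurite_threshold=self.neurite_threshold * k)


@dataclass
class SegmentationResult:
    """Intermediate masks of the pipeline for one field."""

    soma_mask: np.ndarray
    fiber_skeleton: np.ndarray      # thinned neurite mask, before soma subtraction
    neurite_skeleton: np.ndarray    # fiber skeleton minus somata (the length image)
    endpoints: np.ndarray
    attachment_points: np.ndarray
    overlay: np.ndarray             # H x W x 3 uint8

    def check_invariants(self) -> None:
        assert not (self.neurite_skeleton & self.soma_mask).any()
        assert (self.endpoints & ~self.neurite_skeleton).sum() == 0
        assert not (self.attachment_points & self.soma_mask).any()


@dataclass
class FieldMeasurements:
    """The seven primary per-field numbers."""

    total_neurite_length: int
    total_soma_area: int
    soma_count: int
    avg_soma_cluster_area: float
    endpoint_count: int
    attachment_count: int
    mean_intensity: float


class FieldReadError(RuntimeError):
    """Raised when a field image cannot be read; carries the file path."""


def read_field_image(path: str | Path) -> GreyImage:
    """Read a single-channel TIFF or PNG field image (8- or 16-bit grey)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - wrapped for the batch failure log
        raise FieldReadError(f"cannot read field image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an accidental RGB to luminance-ish mean
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise FieldReadError(f"cannot read field image {path}: not a 2-D image")
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return GreyImage(arr, bit_depth=bit_depth)


def segment_somata(img: GreyImage, cfg: PipelineConfig,
                   opened: GreyImage | None = None) -> np.ndarray:
    """Soma mask: open, binarize, size-filter."""
    if opened is None:
        opened = grey_open(img, cfg.soma_open_se)
    return size_filter(binarize(opened, cfg.soma_threshold), cfg.soma_min_area)


def fiber_skeleton(img: GreyImage, cfg: PipelineConfig,
                   opened: GreyImage | None = None) -> np.ndarray:
    """One-pixel-wide skeleton of the fibre (top-hat) mask, somata not yet removed."""
    if opened is None:
        opened = grey_open(img, cfg.soma_open_se)
    fibres = binarize(subtract(img, opened), cfg.neurite_threshold)
    fibres = size_filter(fibres, cfg.neurite_min_area)
    return skeletonize(fibres)


def segment_neurites(img: GreyImage, soma_mask: np.ndarray, cfg: PipelineConfig,
                     opened: GreyImage | None = None) -> np.ndarray:
    """Clean neurite skeleton: fiber skeleton minus its soma overlap.

    Neurites growing on top of cell bodies are excluded, so an
    unattached neurite crossing a soma comes out as two components
    separated by a gap over the soma footprint.
    """
    skel = fiber_skeleton(img, cfg, opened=opened)
    return skel & ~np.asarray(soma_mask, dtype=bool)


def detect_endpoints(skel: np.ndarray, soma_mask: np.ndarray) -> np.ndarray:
    """Neurite endpoints: terminal skeleton pixels outside the somata.

    ``skel`` should be the fiber skeleton *before* soma subtraction so
    that neurite roots (which continue into the cell body) are not
    mistaken for tips; terminals falling inside a soma are discarded.
    """
    return find_endpoints(skel) & ~np.asarray(soma_mask, dtype=bool)


def detect_attachments(skel: np.ndarray, soma_mask: np.ndarray,
                       cfg: PipelineConfig) -> np.ndarray:
    """Neurite-cell-body attachment points.

    The fiber skeleton is clipped to a thin dilation band around the
    somata; terminal pixels of these proximal segments that lie outside
    the soma mask mark where neurites leave their cell body. Two known
    failure modes are inherent to the construction and preserved:
    V-shaped double attachments merge in the band (undercounted), and
    an unattached neurite crossing a soma exits the band twice
    (overcounted as two attachments).
    """
    soma_mask = np.asarray(soma_mask, dtype=bool)
    proximal = np.asarray(skel, dtype=bool) & dilate(soma_mask, cfg.attachment_dilation_se)
    return find_endpoints(proximal) & ~soma_mask


def render_overlay(img: GreyImage, soma_mask: np.ndarray, neurite_skeleton: np.ndarray,
                   endpoints: np.ndarray, attachment_points: np.ndarray) -> np.ndarray:
    """Colour-coded tracing: somata red, skeleton green, endpoints cyan,
    attachments yellow, over a dimmed copy of the raw image."""
    pix = np.asarray(img.pixels, dtype=np.float64)
    hi = max(float(pix.max()), 1.0)
    base = (pix / hi * 110.0).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    marker_se = StructuringElement("disk", 2)
    rgb[soma_mask] = (210, 40, 40)
    rgb[neurite_skeleton] = (40, 210, 40)
    rgb[dilate(endpoints, marker_se)] = (0, 255, 255)
    rgb[dilate(attachment_points, marker_se)] = (255, 255, 0)
    return rgb


def measure_field(img: GreyImage, cfg: PipelineConfig) -> tuple[SegmentationResult, FieldMeasurements]:
    """Run the full pipeline on one field and report the primary numbers.

    ``mean_intensity`` is the mean of the raw input intensities over
    the whole field (before any inversion).
    """
    mean_intensity = float(np.asarray(img.pixels, dtype=np.float64).mean())
    work = img.inverted() if cfg.invert_input else img

    opened = grey_open(work, cfg.soma_open_se)
    soma_mask = segment_somata(work, cfg, opened=opened)
    skel_full = fiber_skeleton(work, cfg, opened=opened)
    neurite_skel = skel_full & ~soma_mask
    endpoints = detect_endpoints(skel_full, soma_mask)
    attachments = detect_attachments(skel_full, soma_mask, cfg)

    overlay = render_overlay(work, soma_mask, neurite_skel, endpoints, attachments)
    seg = SegmentationResult(soma_mask, skel_full, neurite_skel,
                             endpoints, attachments, overlay)
    seg.check_invariants()

    total_soma_area = int(soma_mask.sum())
    _, soma_count = ndi.label(soma_mask, structure=_STRUCT8)
    fm = FieldMeasurements(
        total_neurite_length=int(neurite_skel.sum()),
        total_soma_area=total_soma_area,
        soma_count=int(soma_count),
        avg_soma_cluster_area=(total_soma_area / soma_count) if soma_count else 0.0,
        endpoint_count=int(endpoints.sum()),
        attachment_count=int(attachments.sum()),
        mean_intensity=mean_intensity,
    )
    return seg, fm
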