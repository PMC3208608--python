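"""Brute-force reference implementations, independent of the package's
morphology code paths, used only to validate it."""

from __future__ import annotations

import numpy as np


def brute_erode_grey(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Explicit min over the structuring-element neighbourhood (border
    padded with +inf so the border behaves like 'ignore')."""
    r = footprint.shape[0] // 2
    padded = np.pad(img.astype(float), r, constant_values=np.inf)
    out = np.empty_like(img, dtype=float)
    offs = [(i - r, j - r) for i in range(footprint.shape[0])
            for j in range(footprint.shape[1]) if footprint[i, j]]
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            out[y, x] = min(padded[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def brute_dilate_grey(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    r = footprint.shape[0] // 2
    padded = np.pad(img.astype(float), r, constant_values=-np.inf)
    out = np.empty_like(img, dtype=float)
    offs = [(i - r, j - r) for i in range(footprint.shape[0])
            for j in range(footprint.shape[1]) if footprint[i, j]]
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            out[y, x] = max(padded[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def brute_open_grey(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion then dilation, both by explicit min/max loops."""
    return brute_dilate_grey(brute_erode_grey(img, footprint), footprint)


def brute_dilate_binary(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Union of footprint translates centred on every foreground pixel."""
    r = footprint.shape[0] // 2
    out = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    for y, x in zip(*np.nonzero(mask)):
        for i in range(footprint.shape[0]):
            for j in range(footprint.shape[1]):
                if footprint[i, j]:
                    yy, xx = y + i - r, x + j - r
                    if 0 <= yy < h and 0 <= xx < w:
                        out[yy, xx] = True
    return out


def label_filter_oracle(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Connected-component labelling (8-connectivity) followed by area
    thresholding, via skimage.measure — an independent route from the
    package's scipy.ndimage labelling."""
    from skimage import measure

    labels = measure.label(mask, connectivity=2)
    out = np.zeros_like(mask, dtype=bool)
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = True
    return out


def graph_leaf_endpoints(skel: np.ndarray) -> np.ndarray:
    """Endpoints as degree-1 nodes of the skeleton's pixel adjacency
    graph (8-neighbourhood), built explicitly."""
    pts = set(zip(*map(lambda a: a.tolist(), np.nonzero(skel))))
    out = np.zeros_like(skel, dtype=bool)
    for (y, x) in pts:
        deg = sum((y + dy, x + dx) in pts
                  for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                  if (dy, dx) != (0, 0))
        if deg == 1:
            out[y, x] = True
    return out


def erode_subtract_endpoints(skel: np.ndarray) -> np.ndarray:
    """The erode-terminal-pixels-then-subtract construction: remove the
    terminal pixels of every fibre, subtract the survivor set from the
    skeleton. Isolated single pixels are not fibre terminals (they have
    no fibre) and are excluded. Identical to neighbour counting on
    one-pixel-wide input."""
    pts = set(zip(*map(lambda a: a.tolist(), np.nonzero(skel))))

    def deg(y, x):
        return sum((y + dy, x + dx) in pts
                   for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                   if (dy, dx) != (0, 0))

    fibre = {p for p in pts if deg(*p) >= 1}
    eroded = {p for p in fibre if deg(*p) >= 2}
    out = np.zeros_like(skel, dtype=bool)
    for (y, x) in fibre - eroded:
        out[y, x] = True
    return out


def count_holes(mask: np.ndarray) -> int:
    """Background components (4-connectivity) not touching the border."""
    from scipy import ndimage as ndi

    inv = ~np.pad(mask, 1, constant_values=False)
    labels, n = ndi.label(inv, structure=ndi.generate_binary_structure(2, 1))
    border = set(labels[0].tolist()) | set(labels[-1].tolist()) | \
        set(labels[:, 0].tolist()) | set(labels[:, -1].tolist())
    return len({v for v in range(1, n + 1)} - border)
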