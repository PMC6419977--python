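"""Rendering of the four diagnostic overlay images.

The exact rendering (colours, marker shapes) is a quality-control aid,
not a measured output: overlays let a user verify parameter choices by
eye. Conventions: tube borders yellow, retained-tube nuclei white
crosses, other nuclei red crosses, nucleus mask borders green, Hough
circles cyan, watershed fragments magenta.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import circle_perimeter
from skimage.segmentation import find_boundaries

from .image_io import MultiChannelImage
from .nucleus_segmentation import NucleusSet
from .parameters import ParameterSet
from .tube_segmentation import TubeMask

__all__ = ["render_overlays"]

_YELLOW = (255, 255, 0)
_WHITE = (255, 255, 255)
_RED = (255, 64, 64)
_GREEN = (64, 255, 64)
_CYAN = (0, 220, 255)
_MAGENTA = (255, 64, 255)


def _to_u8(plane: np.ndarray) -> np.ndarray:
    return np.round(np.clip(plane, 0.0, 1.0) * 255).astype(np.uint8)


def _base_rgb(image: MultiChannelImage, params: ParameterSet) -> np.ndarray:
    """Green = tube channel, blue = nucleus channel composite."""
    h, w = image.height, image.width
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[:, :, 1] = _to_u8(image.pixels[:, :, params.myotube_channel - 1])
    rgb[:, :, 2] = _to_u8(image.pixels[:, :, params.nuc_channel - 1])
    return rgb


def _gray_rgb(plane: np.ndarray) -> np.ndarray:
    g = _to_u8(plane)
    return np.stack([g, g, g], axis=-1)


def _draw_cross(rgb: np.ndarray, r: int, c: int, colour, size: int = 4) -> None:
    h, w = rgb.shape[:2]
    rr = np.clip(np.arange(r - size, r + size + 1), 0, h - 1)
    cc = np.clip(np.arange(c - size, c + size + 1), 0, w - 1)
    rgb[rr, min(max(c, 0), w - 1)] = colour
    rgb[min(max(r, 0), h - 1), cc] = colour


def render_overlays(
    image: MultiChannelImage,
    tubes: TubeMask,
    nuclei: NucleusSet,
    records: list,
    params: ParameterSet,
) -> list[np.ndarray]:
    """Return the 4 RGB overlays: combined, centroids, borders, stages."""
    nuc_plane = image.pixels[:, :, params.nuc_channel - 1]
    retained_labels = {rec.label for rec in records if rec.retained}

    # 1. combined: composite + tube borders + nuclei marked by membership
    combined = _base_rgb(image, params)
    tube_borders = find_boundaries(tubes.labels, mode="outer") & (tubes.labels == 0)
    tube_borders |= find_boundaries(tubes.labels, mode="inner")
    combined[tube_borders] = _YELLOW
    for r, c in nuclei.centres:
        ir, ic = int(round(r)), int(round(c))
        lbl = int(tubes.labels[min(ir, tubes.labels.shape[0] - 1),
                               min(ic, tubes.labels.shape[1] - 1)])
        _draw_cross(combined, ir, ic, _WHITE if lbl in retained_labels else _RED)

    # 2. centroid overlay on the raw nuclear channel
    centroids = _gray_rgb(nuc_plane)
    for r, c in nuclei.centres:
        _draw_cross(centroids, int(round(r)), int(round(c)), _RED)

    # 3. nucleus border overlay
    borders = _gray_rgb(nuc_plane)
    if nuclei.mask is not None and nuclei.mask.any():
        borders[find_boundaries(nuclei.mask, mode="inner")] = _GREEN

    # 4. segmentation-stage overlay: Hough circles + watershed fragments
    stages = _gray_rgb(nuc_plane)
    h, w = stages.shape[:2]
    for (r, c), size, tag in zip(nuclei.centres, nuclei.sizes, nuclei.provenance):
        ir, ic = int(round(r)), int(round(c))
        if tag == "hough":
            rr, cc = circle_perimeter(ir, ic, int(size), shape=(h, w))
            stages[rr, cc] = _CYAN
        else:
            _draw_cross(stages, ir, ic, _MAGENTA)
    return [combined, centroids, borders, stages]
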