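"""Myotube segmentation from the cytoskeletal channel.

The tube mask is produced by flattening large-scale illumination
gradients, thresholding with a scaled automatic (between-class-variance)
threshold, filling and morphologically smoothing the binary mask, and
finally deleting connected components below the myotube size floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label

from .parameters import ParameterSet

__all__ = [
    "TubeMask",
    "normalize_illumination",
    "binarize_tubes",
    "fill_and_smooth",
    "remove_small_objects",
    "segment_myotubes",
]


@dataclass(frozen=True)
class TubeMask:
    """Labelled myotube components surviving the size filter.

    ``mask`` is the union of retained components; ``labels`` assigns each
    retained component a contiguous positive integer (0 = background);
    ``areas`` maps label -> pixel count.
    """

    mask: np.ndarray
    labels: np.ndarray
    areas: dict[int, int]

    @property
    def n_components(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> int:
        return int(sum(self.areas.values()))


def normalize_illumination(channel: np.ndarray, sigma: float = 160.0) -> np.ndarray:
    """Flatten slowly-varying illumination by dividing out a blurred background.

    The background estimate is a Gaussian blur with ``sigma`` much larger
    than any nucleus (default 4x the default maximum nuclear radius), so
    structures survive while shading gradients are removed. The result is
    rescaled to [0, 1]. An all-zero image is returned unchanged.
    """
    channel = np.asarray(channel, dtype=np.float64)
    peak = channel.max()
    if peak <= 0:
        return channel.copy()
    background = ndi.gaussian_filter(channel, sigma)
    floor = max(1e-6, 0.01 * peak)  # avoid blow-up in fully dark regions
    out = channel / np.maximum(background, floor)
    out /= out.max()
    return np.clip(out, 0.0, 1.0)


def _otsu_or_none(channel: np.ndarray) -> float | None:
    """Between-class-variance threshold, or None for a constant raster."""
    if np.ptp(channel) == 0:
        return None
    return float(threshold_otsu(channel))


def binarize_tubes(channel: np.ndarray, tube_thresh: float = 1.0) -> np.ndarray:
    """Threshold at ``tube_thresh`` times the automatic threshold.

    Foreground is ``channel > tube_thresh * T_auto`` where ``T_auto``
    maximises between-class variance, so lowering ``tube_thresh`` always
    grows the foreground (monotone) and detects fainter staining. A blank
    (constant) raster yields an empty mask.
    """
    channel = np.asarray(channel, dtype=np.float64)
    t_auto = _otsu_or_none(channel)
    if t_auto is None:
        return np.zeros(channel.shape, dtype=bool)
    return channel > tube_thresh * t_auto


def fill_and_smooth(mask: np.ndarray, fill_size: int) -> np.ndarray:
    """Fill interior holes and smooth borders (closing then opening).

    The structuring element is a disc of radius ``fill_size``; holes are
    filled both before and after closing so closing-created cavities do
    not survive.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    footprint = morphology.disk(fill_size)
    out = ndi.binary_fill_holes(mask)
    out = ndi.binary_closing(out, structure=footprint)
    out = ndi.binary_fill_holes(out)
    out = ndi.binary_opening(out, structure=footprint)
    return out


def remove_small_objects(mask: np.ndarray, min_size: int) -> TubeMask:
    """Delete 8-connected components strictly smaller than ``min_size``.

    A component of exactly ``min_size`` pixels survives ("below the
    threshold size" read strictly). Survivors are relabelled contiguously.
    """
    mask = np.asarray(mask, dtype=bool)
    # max_size semantics: removes components with area <= max_size
    kept = morphology.remove_small_objects(mask, max_size=min_size - 1, connectivity=2)
    labels, n = label(kept, connectivity=2, return_num=True)
    areas = {i: int((labels == i).sum()) for i in range(1, n + 1)}
    return TubeMask(mask=kept, labels=labels, areas=areas)


def segment_myotubes(channel: np.ndarray, params: ParameterSet) -> TubeMask:
    """Full myotube segmentation of the cytoskeletal channel."""
    normalized = normalize_illumination(channel, sigma=4.0 * params.max_circle_rad)
    binary = binarize_tubes(normalized, params.tube_thresh)
    smoothed = fill_and_smooth(binary, params.fill_size)
    return remove_small_objects(smoothed, params.smallest_myotube_pixel_count)
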