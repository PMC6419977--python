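"""Nucleus detection from the DAPI channel.

Detection runs in two passes. Rounded, well-isolated nuclei are found by
a circle Hough transform over the cleaned nuclear mask's edge map, within
the user's radius prior. Pixels claimed by those circles are erased, and
the remaining nuclear regions — clumps and irregular shapes — are split
by a marker-controlled watershed on the inverted distance transform,
with distance maxima closer than the minimum nuclear radius merged into
one marker (minima imposition). Fragments below the nucleus size floor
are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import wiener
from skimage.draw import disk as draw_disk
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops
from skimage.segmentation import watershed
from skimage.transform import hough_circle

from .errors import ParameterError
from .parameters import ParameterSet
from .tube_segmentation import fill_and_smooth, _otsu_or_none

__all__ = [
    "NucleusSet",
    "denoise_nuclei",
    "binarize_and_clean_nuclei",
    "hough_round_nuclei",
    "remove_round_nuclei",
    "watershed_split_remaining",
    "detect_nuclei",
]

#: Fraction of the theoretical perimeter vote a Hough peak must reach.
HOUGH_ACCEPT_FRACTION = 0.5
#: Extra radius (px) erased around each Hough circle, absorbing the
#: integer quantisation of the radius estimate so thin annulus residues
#: cannot be double-counted as watershed nuclei.
ERASE_MARGIN = 2


@dataclass(frozen=True)
class NucleusSet:
    """Detected nuclei: centre points, sizes, provenance, and the mask.

    ``sizes`` holds a radius (px) for Hough detections and a pixel area
    for watershed detections, distinguished by ``provenance`` tags.
    Centres are sorted row-major and each lies inside ``mask``.
    """

    centres: list[tuple[float, float]] = field(default_factory=list)
    sizes: list[float] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    mask: np.ndarray | None = None

    @property
    def count(self) -> int:
        return len(self.centres)

    def centres_array(self) -> np.ndarray:
        return np.asarray(self.centres, dtype=np.float64).reshape(-1, 2)


def denoise_nuclei(channel: np.ndarray, window: int = 5) -> np.ndarray:
    """Adaptive local-noise (Wiener) filtering, 5x5 window by default.

    Pixels where the local variance vanishes (flat regions) are passed
    through unchanged, so a constant image is a fixed point.
    """
    channel = np.asarray(channel, dtype=np.float64)
    pad = window // 2  # reflect-pad so the zero-padded window never leaks in
    padded = np.pad(channel, pad, mode="reflect")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = wiener(padded, mysize=window)
    out = np.where(np.isfinite(out), out, padded)[pad:-pad, pad:-pad]
    return np.clip(out, 0.0, 1.0)


def _threshold_and_smooth(channel: np.ndarray, nuc_fill_size: int) -> np.ndarray:
    """Automatic threshold + fill/close/open; no size gates yet."""
    channel = np.asarray(channel, dtype=np.float64)
    t = _otsu_or_none(channel)
    if t is None:
        return np.zeros(channel.shape, dtype=bool)
    return fill_and_smooth(channel > t, nuc_fill_size)


def binarize_and_clean_nuclei(channel: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Binarise the (denoised) nuclear channel and apply both size gates.

    Components strictly smaller than ``smallest_nucleus_pixel_count`` or
    strictly larger than ``H*W / max_nuc_size_divisor`` (debris / dye
    blots) are deleted.
    """
    mask = _threshold_and_smooth(channel, params.nuc_fill_size)
    if not mask.any():
        return mask
    h, w = mask.shape
    max_area = (h * w) / params.max_nuc_size_divisor
    labels, n = label(mask, connectivity=2, return_num=True)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    for i in range(1, n + 1):
        keep[i] = params.smallest_nucleus_pixel_count <= counts[i] <= max_area
    return keep[labels]


def _mask_edges(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask)


def hough_round_nuclei(
    mask: np.ndarray,
    denoised: np.ndarray,
    min_rad: int,
    max_rad: int,
) -> list[tuple[tuple[int, int], int]]:
    """Circle-Hough detection of rounded nuclei on the mask's edge map.

    The accumulator is normalised by each radius's perimeter, so a peak
    value is the fraction of the circle actually present; peaks below
    ``HOUGH_ACCEPT_FRACTION`` are rejected. Greedy non-maximum
    suppression forbids two accepted centres closer than ``min_rad``,
    with deterministic (vote, row, col) tie-breaking. Centres falling
    outside the mask are rejected.
    """
    if min_rad >= max_rad:
        raise ParameterError(f"degenerate radius range [{min_rad}, {max_rad}]")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    edges = _mask_edges(mask)
    radii = np.arange(min_rad, max_rad + 1)
    accum = hough_circle(edges, radii, normalize=True)
    candidates: list[tuple[float, int, int, int]] = []
    for spaces, radius in zip(accum, radii):
        coords = peak_local_max(
            spaces,
            min_distance=min_rad,
            threshold_abs=HOUGH_ACCEPT_FRACTION,
            exclude_border=False,
        )
        for r, c in coords:
            candidates.append((float(spaces[r, c]), int(r), int(c), int(radius)))
    # strongest votes first; ties broken spatially for determinism
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    accepted: list[tuple[tuple[int, int], int]] = []
    for vote, r, c, radius in candidates:
        if not mask[r, c]:
            continue
        if any((r - ar) ** 2 + (c - ac) ** 2 < min_rad**2 for (ar, ac), _ in accepted):
            continue
        accepted.append(((r, c), radius))
    accepted.sort(key=lambda d: d[0])
    return accepted


def remove_round_nuclei(
    mask: np.ndarray, detections: list[tuple[tuple[int, int], int]]
) -> np.ndarray:
    """Erase the pixels claimed by each detected circle from the mask."""
    remainder = np.asarray(mask, dtype=bool).copy()
    for (r, c), radius in detections:
        rr, cc = draw_disk((r, c), radius + ERASE_MARGIN, shape=remainder.shape)
        remainder[rr, cc] = False
    return remainder


def watershed_split_remaining(
    remainder: np.ndarray, params: ParameterSet
) -> list[tuple[tuple[float, float], int]]:
    """Split leftover nuclear regions by marker-controlled watershed.

    Markers are regional maxima of the distance transform; maxima closer
    than ``min_circle_rad`` are merged into a single marker so one
    convex nucleus cannot be split twice. Fragments below the nucleus
    size floor are discarded. Returns (centroid, area) pairs sorted
    row-major; a centroid falling outside its own fragment (possible for
    crescents) is snapped to the nearest fragment pixel.
    """
    remainder = np.asarray(remainder, dtype=bool)
    if not remainder.any():
        return []
    distance = ndi.distance_transform_edt(remainder)
    blobs = label(remainder, connectivity=2)
    coords = peak_local_max(
        distance,
        min_distance=params.min_circle_rad,
        labels=blobs,
        exclude_border=False,
    )
    markers = np.zeros(remainder.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    segmented = watershed(-distance, markers, mask=remainder)
    results: list[tuple[tuple[float, float], int]] = []
    for region in regionprops(segmented):
        if region.area < params.smallest_nucleus_pixel_count:
            continue
        cr, cc = region.centroid
        ir, ic = int(round(cr)), int(round(cc))
        if not (
            0 <= ir < remainder.shape[0]
            and 0 <= ic < remainder.shape[1]
            and segmented[ir, ic] == region.label
        ):
            pts = region.coords
            j = np.argmin((pts[:, 0] - cr) ** 2 + (pts[:, 1] - cc) ** 2)
            cr, cc = float(pts[j, 0]), float(pts[j, 1])
        results.append(((float(cr), float(cc)), int(region.area)))
    results.sort(key=lambda t: t[0])
    return results


def detect_nuclei(channel: np.ndarray, params: ParameterSet) -> NucleusSet:
    """Full nucleus detection: denoise, clean, Hough, erase, watershed."""
    denoised = denoise_nuclei(channel)
    mask = binarize_and_clean_nuclei(denoised, params)
    round_dets = hough_round_nuclei(
        mask, denoised, params.min_circle_rad, params.max_circle_rad
    )
    remainder = remove_round_nuclei(mask, round_dets)
    fragments = watershed_split_remaining(remainder, params)

    entries: list[tuple[tuple[float, float], float, str]] = []
    for (r, c), radius in round_dets:
        entries.append(((float(r), float(c)), float(radius), "hough"))
    for (r, c), area in fragments:
        entries.append(((float(r), float(c)), float(area), "watershed"))
    # canonical row-major order; coinciding centres collapse to one
    entries.sort(key=lambda e: e[0])
    seen: set[tuple[float, float]] = set()
    centres, sizes, provenance = [], [], []
    for centre, size, tag in entries:
        if centre in seen:
            continue
        seen.add(centre)
        centres.append(centre)
        sizes.append(size)
        provenance.append(tag)
    return NucleusSet(centres=centres, sizes=sizes, provenance=provenance, mask=mask)
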