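"""Nucleus-myotube intersection, myoblast exclusion, and reporting.

A nucleus belongs to the myotube component containing its centre point.
Cytoskeleton-positive structures with fewer than ``min_nuclei`` nuclei
are myoblasts and are excluded before the nuclear fusion index (NFI) is
computed. NFI = nuclei inside retained myotubes / all visible nuclei.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import image_io
from .errors import ConsistencyError
from .image_io import MultiChannelImage, read_image, select_channel
from .nucleus_segmentation import NucleusSet, detect_nuclei
from .overlays import render_overlays
from .parameters import ParameterSet, defaults, validate
from .tube_segmentation import TubeMask, segment_myotubes

__all__ = [
    "MyotubeRecord",
    "ImageSummary",
    "assign_nuclei",
    "build_records",
    "filter_myoblasts",
    "summarize",
    "analyze_image",
]


@dataclass
class MyotubeRecord:
    """One labelled cytoskeleton-positive component."""

    label: int
    area: int
    nucleus_count: int = 0
    retained: bool = False


@dataclass(frozen=True)
class ImageSummary:
    """Per-image metrics, the unit of text/CSV reporting."""

    source: str
    total_nuclei: int
    nuclei_in_tubes: int
    nuclei_in_retained_tubes: int
    retained_tube_area: int
    nfi: float
    n_retained_tubes: int
    retained_tube_area_um2: float | None = None


def assign_nuclei(nuclei: NucleusSet, tubes: TubeMask) -> tuple[dict[int, int], int]:
    """Count nuclei per tube component by centre-point containment.

    Returns ``(counts, unassigned)`` where ``counts`` maps component
    label -> nucleus count (every component present, possibly 0) and
    ``unassigned`` counts nuclei whose centre lies on background. A
    centre on a border pixel that is foreground belongs to that
    component; each nucleus belongs to at most one component.
    """
    if nuclei.mask is not None and nuclei.mask.shape != tubes.labels.shape:
        raise ConsistencyError(
            f"nucleus mask shape {nuclei.mask.shape} != tube raster shape {tubes.labels.shape}"
        )
    counts = {lbl: 0 for lbl in tubes.areas}
    unassigned = 0
    h, w = tubes.labels.shape
    for r, c in nuclei.centres:
        ir, ic = int(round(r)), int(round(c))
        ir = min(max(ir, 0), h - 1)
        ic = min(max(ic, 0), w - 1)
        lbl = int(tubes.labels[ir, ic])
        if lbl > 0:
            counts[lbl] += 1
        else:
            unassigned += 1
    return counts, unassigned


def build_records(tubes: TubeMask, counts: dict[int, int]) -> list[MyotubeRecord]:
    """Materialise one record per tube component with its nucleus count."""
    return [
        MyotubeRecord(label=lbl, area=area, nucleus_count=counts.get(lbl, 0))
        for lbl, area in sorted(tubes.areas.items())
    ]


def filter_myoblasts(records: list[MyotubeRecord], min_nuclei: int) -> list[MyotubeRecord]:
    """Flag records; keep only structures with >= ``min_nuclei`` nuclei.

    At the default of 3, structures with 2 or fewer nuclei (myoblasts)
    are excluded from area and NFI reporting. Returns the retained
    records; the ``retained`` flag is also set on every input record.
    """
    for rec in records:
        rec.retained = rec.nucleus_count >= min_nuclei
    return [rec for rec in records if rec.retained]


def summarize(
    nuclei: NucleusSet,
    records: list[MyotubeRecord],
    source: str = "",
    scale_um_per_px: float | None = None,
) -> ImageSummary:
    """Aggregate per-image metrics from filtered records.

    ``nfi`` is nuclei-in-retained-tubes over total nuclei (0 when the
    image holds no nuclei); the raw in-any-tube count is reported
    alongside so the alternative index can be recomputed. When a
    micron-per-pixel scale is given, the retained area is additionally
    reported in um^2.
    """
    total = nuclei.count
    in_tubes = sum(r.nucleus_count for r in records)
    retained = [r for r in records if r.retained]
    in_retained = sum(r.nucleus_count for r in retained)
    area = int(sum(r.area for r in retained))
    nfi = (in_retained / total) if total else 0.0
    area_um2 = area * scale_um_per_px**2 if scale_um_per_px else None
    return ImageSummary(
        source=source,
        total_nuclei=total,
        nuclei_in_tubes=in_tubes,
        nuclei_in_retained_tubes=in_retained,
        retained_tube_area=area,
        nfi=nfi,
        n_retained_tubes=len(retained),
        retained_tube_area_um2=area_um2,
    )


def analyze_image(
    path: str | os.PathLike | MultiChannelImage,
    params: ParameterSet | None = None,
    out_dir: str | os.PathLike | None = None,
    scale_um_per_px: float | None = None,
    taken: set[str] | None = None,
) -> ImageSummary:
    """Run the full pipeline on one image.

    ``path`` may be a TIFF path or an in-memory :class:`MultiChannelImage`.
    When ``out_dir`` is given the four diagnostic overlays and the text
    summary are written there (``taken`` forwards the batch stem
    registry). Deterministic: the same image and parameters always yield
    the same summary.
    """
    params = validate(params if params is not None else defaults())
    image = path if isinstance(path, MultiChannelImage) else read_image(path)
    validate(params, image)
    tube_channel = select_channel(image, params.myotube_channel)
    nuc_channel = select_channel(image, params.nuc_channel)

    tubes = segment_myotubes(tube_channel, params)
    nuclei = detect_nuclei(nuc_channel, params)
    counts, _ = assign_nuclei(nuclei, tubes)
    records = build_records(tubes, counts)
    filter_myoblasts(records, params.min_nuclei)
    source = image.source_path or (str(path) if not isinstance(path, MultiChannelImage) else "")
    summary = summarize(nuclei, records, source=Path(source).name if source else "",
                        scale_um_per_px=scale_um_per_px)
    if out_dir is not None:
        overlays = render_overlays(image, tubes, nuclei, records, params)
        image_io.write_outputs(summary, overlays, out_dir, taken=taken)
    return summary
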