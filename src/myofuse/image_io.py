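"""Reading input TIFFs and writing the diagnostic outputs.

Input images are bi- or tri-channel TIFFs where one channel carries the
cytoskeletal stain and another the nuclei. Intensities are rescaled to
[0, 1] by the dtype's full range on load (per-image contrast handling is
the segmentation modules' job). Each analysed image yields exactly four
diagnostic PNG overlays plus a plain-text summary; batch runs add a CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import FormatError, InputError, ParameterError, UnsupportedChannelCountError

if TYPE_CHECKING:  # pragma: no cover
    from .fusion_analysis import ImageSummary

__all__ = [
    "MultiChannelImage",
    "read_image",
    "write_image",
    "select_channel",
    "write_outputs",
    "write_batch_csv",
    "OUTPUT_SUFFIXES",
]

#: Fixed suffix per output kind, appended to the source image stem.
OUTPUT_SUFFIXES = {
    "combined": "_overlay.png",
    "centroids": "_nuclei_centroids.png",
    "borders": "_nuclei_borders.png",
    "stages": "_nuclei_stages.png",
    "summary": "_summary.txt",
}

#: Order in which summary fields appear in the text file and the CSV.
SUMMARY_FIELDS = (
    ("source", "source"),
    ("total_nuclei", "total_nuclei"),
    ("nuclei_in_tubes", "nuclei_in_tubes"),
    ("nuclei_in_retained_tubes", "nuclei_in_retained_tubes"),
    ("retained_tube_area_px", "retained_tube_area"),
    ("nfi", "nfi"),
)


@dataclass(frozen=True)
class MultiChannelImage:
    """A loaded microscopy image, channels last, intensities in [0, 1]."""

    pixels: np.ndarray  # (H, W, C) float64 in [0, 1]
    source_path: str = ""

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _dtype_range(dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0  # float TIFFs assumed already normalised


def _channels_last(arr: np.ndarray) -> np.ndarray:
    """Resolve planar (C, H, W) vs interleaved (H, W, C) layouts.

    The smaller of the candidate channel axes wins when ambiguous; real
    microscopy rasters are far larger than 3 in both spatial dimensions.
    """
    if arr.ndim != 3:
        raise UnsupportedChannelCountError(
            f"expected a 2- or 3-channel image, got array of shape {arr.shape}"
        )
    if arr.shape[0] <= 4 < arr.shape[2]:
        arr = np.moveaxis(arr, 0, -1)
    return arr


def read_image(path: str | os.PathLike) -> MultiChannelImage:
    """Read a bi- or tri-channel TIFF and normalise intensities to [0, 1].

    Raises
    ------
    InputError
        If the file does not exist.
    FormatError
        If the file is not a readable TIFF.
    UnsupportedChannelCountError
        For single-channel or >3-channel images (names the count found).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such image file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"could not read {path} as a TIFF: {exc}") from exc
    if arr.ndim == 2:
        raise UnsupportedChannelCountError(
            f"{path} has 1 channel; 2 or 3 channels are required"
        )
    arr = _channels_last(np.asarray(arr))
    n = arr.shape[2]
    if n not in (2, 3):
        raise UnsupportedChannelCountError(
            f"{path} has {n} channels; 2 or 3 channels are required"
        )
    pixels = arr.astype(np.float64) / _dtype_range(arr.dtype)
    return MultiChannelImage(pixels=np.clip(pixels, 0.0, 1.0), source_path=str(path))


def write_image(image: MultiChannelImage | np.ndarray, path: str | os.PathLike) -> Path:
    """Write an image (channels last, [0, 1] floats) as a 16-bit TIFF."""
    pixels = image.pixels if isinstance(image, MultiChannelImage) else np.asarray(image)
    data = np.round(np.clip(pixels, 0.0, 1.0) * 65535).astype(np.uint16)
    path = Path(path)
    tifffile.imwrite(path, data, photometric="rgb" if data.shape[-1] == 3 else "minisblack")
    return path


def select_channel(image: MultiChannelImage, index: int) -> np.ndarray:
    """Return the 2-D plane for a 1-based channel index.

    1-based indexing matches the published command-line convention
    (1=red, 2=green, 3=blue for RGB TIFFs).
    """
    if not 1 <= index <= image.n_channels:
        raise ParameterError(
            f"channel index {index} out of range; valid range is 1..{image.n_channels}"
        )
    return image.pixels[:, :, index - 1]


def _unique_stem(stem: str, out_dir: Path, taken: set[str] | None) -> str:
    """Disambiguate a stem against others already used in this batch."""
    if taken is None:
        return stem
    candidate, i = stem, 1
    while candidate in taken:
        i += 1
        candidate = f"{stem}-{i}"
    taken.add(candidate)
    return candidate


def summary_lines(summary: "ImageSummary") -> list[str]:
    """Stable ``key: value`` lines for the text summary."""
    lines = [f"{label}: {getattr(summary, attr)}" for label, attr in SUMMARY_FIELDS]
    lines.insert(5, f"n_retained_tubes: {summary.n_retained_tubes}")
    if summary.retained_tube_area_um2 is not None:
        lines.append(f"retained_tube_area_um2: {summary.retained_tube_area_um2:.1f}")
    return lines


def write_outputs(
    summary: "ImageSummary",
    overlays: Sequence[np.ndarray],
    out_dir: str | os.PathLike,
    taken: set[str] | None = None,
) -> list[Path]:
    """Write the 4 diagnostic images plus the text summary for one image.

    ``overlays`` must be the four RGB rasters in the order combined /
    centroids / borders / stages. ``taken`` is an optional registry of
    stems already written in this batch; colliding stems get a numeric
    suffix so two inputs named alike produce distinct outputs.
    """
    if len(overlays) != 4:
        raise ParameterError(f"expected 4 overlay images, got {len(overlays)}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise InputError(f"output directory {out_dir} is not writable")
    stem = _unique_stem(Path(summary.source).stem, out_dir, taken)
    written: list[Path] = []
    kinds = ("combined", "centroids", "borders", "stages")
    for kind, overlay in zip(kinds, overlays):
        target = out_dir / f"{stem}{OUTPUT_SUFFIXES[kind]}"
        iio.imwrite(target, np.ascontiguousarray(overlay))
        written.append(target)
    summary_path = out_dir / f"{stem}{OUTPUT_SUFFIXES['summary']}"
    summary_path.write_text("\n".join(summary_lines(summary)) + "\n", encoding="utf-8")
    written.append(summary_path)
    return written


def write_batch_csv(
    summaries: Iterable["ImageSummary"], out_path: str | os.PathLike
) -> Path:
    """Write one CSV row per analysed image, in processing order."""
    import pandas as pd

    summaries = list(summaries)
    if not summaries:
        raise ParameterError("write_batch_csv requires at least one summary")
    rows = [
        {label: getattr(s, attr) for label, attr in SUMMARY_FIELDS} for s in summaries
    ]
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path, index=False, lineterminator="\r\n")
    return out_path
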