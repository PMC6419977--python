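"""User-tunable analysis parameters.

The ten tunables control every stage of the pipeline: size floors for
myotubes and nuclei, the two colour-channel assignments, morphological
smoothing radii, the nuclear radius prior for circle detection, the
myotube threshold scale, the myoblast-exclusion nucleus count, and the
oversized-nucleus ceiling. Defaults target 20x images of
immunofluorescence-stained myogenic cultures (green cytoskeletal marker,
blue DAPI).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import TYPE_CHECKING

from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .image_io import MultiChannelImage

__all__ = ["ParameterSet", "defaults", "validate", "CLI_NAMES"]


@dataclass(frozen=True)
class ParameterSet:
    """The ten analysis tunables with their published defaults.

    Attributes
    ----------
    smallest_myotube_pixel_count:
        Smallest allowed myotube, in pixels covered. Components strictly
        below this area are discarded from the tube mask.
    smallest_nucleus_pixel_count:
        Smallest allowed nucleus, in pixels covered.
    myotube_channel:
        1-based colour channel holding the cytoskeletal stain
        (1=red, 2=green, 3=blue).
    nuc_channel:
        1-based colour channel holding the DAPI/nuclear stain.
    fill_size:
        Radius (px) of the disc structuring element used to smooth
        myotube borders.
    nuc_fill_size:
        Radius (px) of the disc used to smooth nucleus borders.
    min_circle_rad / max_circle_rad:
        Lower/upper bound for nuclear radii (px); the circle-Hough search
        range. Adjust for magnification.
    tube_thresh:
        Multiplicative scale on the automatic (between-class-variance)
        myotube threshold. Lower detects fainter staining.
    min_nuclei:
        Discard any myotube with fewer than this many recognised nuclei
        inside its borders (myoblast exclusion).
    max_nuc_size_divisor:
        Discard nuclei larger than 1/n of the total image area.
    """

    smallest_myotube_pixel_count: int = 500
    smallest_nucleus_pixel_count: int = 300
    myotube_channel: int = 2
    nuc_channel: int = 3
    fill_size: int = 10
    nuc_fill_size: int = 5
    min_circle_rad: int = 15
    max_circle_rad: int = 40
    tube_thresh: float = 1.0
    min_nuclei: int = 3
    max_nuc_size_divisor: float = 100.0

    def replace(self, **kwargs) -> "ParameterSet":
        """Return a copy with the given fields changed."""
        return replace(self, **kwargs)


#: Published command-line parameter names -> dataclass field (matched
#: case-insensitively so existing command lines work unchanged).
CLI_NAMES = {
    "SmallestMyotubePixelCount": "smallest_myotube_pixel_count",
    "SmallestNucleusPixelCount": "smallest_nucleus_pixel_count",
    "MyotubeChannel": "myotube_channel",
    "NucChannel": "nuc_channel",
    "FillSize": "fill_size",
    "NucFillSize": "nuc_fill_size",
    "MinCircleRad": "min_circle_rad",
    "MaxCircleRad": "max_circle_rad",
    "TubeThresh": "tube_thresh",
    "MinNuclei": "min_nuclei",
    "MaxNucSizeDivisor": "max_nuc_size_divisor",
}

_FIELD_TYPES = {f.name: f.type for f in fields(ParameterSet)}


def defaults() -> ParameterSet:
    """Return the published default parameter set."""
    return ParameterSet()


def validate(params: ParameterSet, image: "MultiChannelImage | None" = None) -> ParameterSet:
    """Check every parameter invariant; return ``params`` unchanged if valid.

    Raises
    ------
    ParameterError
        Naming the first violated invariant. When ``image`` is given the
        channel indices are additionally checked against its channel count.
    """
    p = params
    for name in (
        "smallest_myotube_pixel_count",
        "smallest_nucleus_pixel_count",
        "fill_size",
        "nuc_fill_size",
        "min_circle_rad",
        "max_circle_rad",
    ):
        if getattr(p, name) <= 0:
            raise ParameterError(f"{name} must be > 0, got {getattr(p, name)}")
    if p.min_circle_rad >= p.max_circle_rad:
        raise ParameterError(
            f"min_circle_rad ({p.min_circle_rad}) must be < max_circle_rad ({p.max_circle_rad})"
        )
    if p.tube_thresh <= 0:
        raise ParameterError(f"tube_thresh must be > 0, got {p.tube_thresh}")
    if p.min_nuclei < 1:
        raise ParameterError(f"min_nuclei must be >= 1, got {p.min_nuclei}")
    if p.max_nuc_size_divisor < 1:
        raise ParameterError(f"max_nuc_size_divisor must be >= 1, got {p.max_nuc_size_divisor}")
    for name in ("myotube_channel", "nuc_channel"):
        idx = getattr(p, name)
        if not (isinstance(idx, int) and idx >= 1):
            raise ParameterError(f"{name} must be a positive 1-based integer, got {idx}")
        if image is not None and idx > image.n_channels:
            raise ParameterError(
                f"{name}={idx} out of range for a {image.n_channels}-channel image"
            )
    if p.myotube_channel == p.nuc_channel:
        raise ParameterError(
            f"myotube_channel and nuc_channel must differ (both {p.nuc_channel})"
        )
    return p


def set_by_cli_name(params: ParameterSet, name: str, value: str) -> ParameterSet:
    """Set one parameter by its published (case-insensitive) CLI name.

    ``value`` is parsed as int or float according to the field; raises
    :class:`ParameterError` for unknown names or non-numeric values.
    """
    lookup = {k.lower(): v for k, v in CLI_NAMES.items()}
    field = lookup.get(name.lower())
    if field is None:
        valid = ", ".join(CLI_NAMES)
        raise ParameterError(f"unknown parameter '{name}'; valid names: {valid}")
    want_float = "float" in str(_FIELD_TYPES[field])
    try:
        parsed = float(value) if want_float else int(value)
    except ValueError as exc:
        kind = "number" if want_float else "integer"
        raise ParameterError(f"parameter '{name}' expects a {kind}, got '{value}'") from exc
    return params.replace(**{field: parsed})
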