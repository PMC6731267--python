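"""Core in-memory data model shared by all pipeline stages.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left corner of the image;
* intensities are kept in their native integer range on read and all
  downstream arithmetic is done in floating point;
* label images use 0 for background and the contiguous set ``1..n`` for
  objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "ChannelRole",
    "ChannelImage",
    "FieldOfView",
    "LabelMask",
    "SegmentationParams",
    "NucleusRecord",
    "RejectionReason",
    "ClassifierParams",
    "FociResult",
    "RadialProfile",
    "Phenotype",
    "PhenotypeCall",
    "ColocalizationResult",
]


class ChannelRole(str, Enum):
    """Biological role of an acquisition channel."""

    DAPI = "dapi"
    GH2AX = "gh2ax"
    P53BP1 = "p53bp1"
    OTHER = "other"


class RingtrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RingtrackError):
    """A run configuration is incomplete or inconsistent."""


class FormatError(RingtrackError):
    """An input file violates the supported image contract."""


class DegenerateInputError(RingtrackError):
    """An image or object is too degenerate to process (e.g. constant)."""


class CapacityError(RingtrackError):
    """A value exceeds the representable range of an output format."""


@dataclass
class ChannelImage:
    """A single-channel 2-D intensity image.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in native integer range.
    channel_role
        Which stain the channel carries.
    bit_depth
        8 or 16; intensities must not exceed ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    channel_role: ChannelRole
    bit_depth: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"channel image must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise FormatError(f"channel image must be at least 16x16, got {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1
        ):
            raise FormatError(
                f"intensities outside [0, {2**self.bit_depth - 1}] for {self.bit_depth}-bit image"
            )
        self.channel_role = ChannelRole(self.channel_role)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class FieldOfView:
    """A pixel-aligned multi-channel field with acquisition metadata."""

    channels: Mapping[ChannelRole, ChannelImage]
    field_id: str
    condition: str
    pixel_size_um: float | None = None
    magnification: str = "20x"

    def __post_init__(self) -> None:
        self.channels = {ChannelRole(k): v for k, v in self.channels.items()}
        for required in (ChannelRole.DAPI, ChannelRole.GH2AX):
            if required not in self.channels:
                raise ConfigurationError(f"field {self.field_id!r} lacks a {required.value} channel")
        shapes = {c.pixels.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise FormatError(f"channel dimensions differ within field {self.field_id!r}: {shapes}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).pixels.shape

    @property
    def dapi(self) -> ChannelImage:
        return self.channels[ChannelRole.DAPI]

    @property
    def gh2ax(self) -> ChannelImage:
        return self.channels[ChannelRole.GH2AX]

    @property
    def p53bp1(self) -> ChannelImage | None:
        return self.channels.get(ChannelRole.P53BP1)


@dataclass
class LabelMask:
    """Integer label image: 0 = background, objects labelled 1..n_objects."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label mask must be 2-D")
        if self.labels.size and self.labels.min() < 0:
            raise FormatError("label mask values must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise FormatError("labels must form the contiguous set 1..n_objects")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


@dataclass
class SegmentationParams:
    """Parameters of nucleus detection and the four object filters.

    The filter cutoffs (area > 400 px, eccentricity < 0.8,
    circularity > 0.85, mean intensity < 2x field median) are the
    published screening values; the smoothing sigma and morphology
    counts were fixed empirically by the original investigators and
    are exposed here with sensible defaults.
    """

    gaussian_sigma_px: float = 2.0
    struct_radius_px: int = 3
    n_dilations: int = 2
    n_erosions: int = 2
    min_area_px: float = 400.0
    max_eccentricity: float = 0.8
    min_circularity: float = 0.85
    intensity_median_factor: float = 2.0
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px <= 0:
            raise ValueError("gaussian_sigma_px must be positive")
        if self.struct_radius_px < 1:
            raise ValueError("struct_radius_px must be a positive integer")
        if self.n_dilations < 0 or self.n_erosions < 0:
            raise ValueError("morphology counts must be non-negative")
        if self.min_area_px <= 0:
            raise ValueError("min_area_px must be positive")
        if not 0 <= self.max_eccentricity < 1:
            raise ValueError("max_eccentricity must lie in [0, 1)")
        if self.min_circularity <= 0:
            raise ValueError("min_circularity must be positive")
        if self.intensity_median_factor <= 1:
            raise ValueError("intensity_median_factor must exceed 1")


class RejectionReason(str, Enum):
    NONE = "none"
    AREA = "area"
    ECCENTRICITY = "eccentricity"
    REGULARITY = "regularity"
    INTENSITY = "intensity"


@dataclass
class NucleusRecord:
    """Geometry and intensity measurements for one candidate nucleus."""

    nucleus_id: int
    area_px: int
    perimeter_px: float
    centroid: tuple[float, float]
    eccentricity: float
    circularity: float
    mean_dapi: float
    boundary_pixels: np.ndarray  # (k, 2) array of (row, col)
    touches_border: bool = False
    accepted: bool = False
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        if len(self.boundary_pixels) == 0:
            raise ValueError("boundary_pixels must be non-empty")


@dataclass
class ClassifierParams:
    """Parameters of the per-nucleus gamma-H2AX phenotype rules.

    ``foci_density_cutoff`` (count per px^2) and ``ring_rel_threshold``
    are the published screening cutoffs; the adaptive-threshold window
    and offset and the minimum focus area are implementation defaults.
    """

    adaptive_window_px: int = 15
    adaptive_rel_offset: float = 0.15
    min_focus_area_px: int = 4
    foci_density_cutoff: float = 0.0035
    ring_rel_threshold: float = 0.10
    n_profile_rays: int | str = "all_boundary_pixels"

    def __post_init__(self) -> None:
        if self.adaptive_window_px < 3 or self.adaptive_window_px % 2 == 0:
            raise ValueError("adaptive_window_px must be an odd integer >= 3")
        if self.min_focus_area_px < 1:
            raise ValueError("min_focus_area_px must be a positive integer")
        if self.foci_density_cutoff <= 0:
            raise ValueError("foci_density_cutoff must be positive")
        if not 0 < self.ring_rel_threshold < 1:
            raise ValueError("ring_rel_threshold must lie in (0, 1)")


@dataclass
class FociResult:
    """Outcome of the foci-density test for one nucleus."""

    foci_count: int
    foci_density: float
    is_foci: bool
    focus_centroids: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class RadialProfile:
    """Averaged, length-normalised centroid-to-boundary intensity profile.

    ``profile`` has length ``L`` equal to the longest ray in pixels.
    The radial axis is split at index ``floor(0.75 * L)``: samples below
    form the first three quartiles (the nuclear interior), samples from
    that index on form the last quartile (the periphery).
    """

    profile: np.ndarray
    mean_q4: float
    mean_q123: float
    overall_mean: float
    ring_score: float

    @property
    def L(self) -> int:
        return int(len(self.profile))


class Phenotype(str, Enum):
    FOCI = "FOCI"
    RING = "RING"
    UNIFORM = "UNIFORM"


@dataclass
class PhenotypeCall:
    """Final per-nucleus phenotype with supporting metrics.

    ``radial`` is absent for FOCI nuclei: the foci test is applied
    first and foci-positive nuclei never enter the ring/uniform split,
    so the two phenotypes are mutually exclusive by construction.
    """

    nucleus_id: int
    phenotype: Phenotype
    foci: FociResult
    radial: RadialProfile | None = None
    zero_signal: bool = False


@dataclass
class ColocalizationResult:
    """Per-nucleus Pearson correlation between two channels.

    ``pearson_r`` is NaN (flagged, not an error) when either channel is
    constant within the nucleus or the nucleus has fewer than 10 pixels.
    """

    nucleus_id: int
    pearson_r: float
    n_pixels: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.pearson_r))
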