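"""Per-nucleus gamma-H2AX phenotype classification.

Each accepted nucleus receives exactly one of three mutually exclusive
labels:

FOCI
    The gamma-H2AX signal inside the nucleus is binarised with an
    adaptive threshold — a pixel is focus-candidate if its intensity
    exceeds ``(1 + adaptive_rel_offset)`` times the local mean over a
    square window clipped to nucleus pixels — and 8-connected components
    of at least ``min_focus_area_px`` pixels are counted as foci.  The
    nucleus is FOCI when foci count / nucleus area is strictly greater
    than ``foci_density_cutoff`` (0.0035 per px^2).

RING
    For non-foci nuclei, intensity profiles are cast from the centre of
    mass to every boundary pixel, resampled to the length of the longest
    ray and averaged.  The nucleus is RING when the mean of the last
    quartile of the averaged profile (the periphery) exceeds the mean of
    the first three quartiles by strictly more than ``ring_rel_threshold``
    (10%) of the overall profile mean.  The difference is signed: the
    periphery must be the brighter side.

UNIFORM
    Everything else.

The foci test runs first, so a nucleus full of bright peripheral foci
is called FOCI, never RING.  Both binarisation and the ring score are
ratios of intensities, which makes every call invariant to a positive
rescaling of the gamma-H2AX channel.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .model import (
    ChannelImage,
    ClassifierParams,
    DegenerateInputError,
    FociResult,
    NucleusRecord,
    Phenotype,
    PhenotypeCall,
    RadialProfile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "adaptive_binarize",
    "count_foci",
    "cast_radial_profiles",
    "resample_and_average",
    "classify_ring",
    "classify_nucleus",
    "classify_field",
]


def _as_pixels(image: ChannelImage | np.ndarray) -> np.ndarray:
    return (image.pixels if isinstance(image, ChannelImage) else np.asarray(image)).astype(
        np.float64
    )


def adaptive_binarize(
    gh2ax: ChannelImage | np.ndarray,
    nucleus_mask: np.ndarray,
    params: ClassifierParams | None = None,
) -> np.ndarray:
    """Binarise the gamma-H2AX signal inside one nucleus.

    A pixel is foreground iff it lies in the nucleus and its intensity
    strictly exceeds ``(1 + adaptive_rel_offset)`` times the mean
    intensity of the nucleus pixels inside the window centred on it
    (local first-order statistics).  Pixels outside the nucleus never
    contribute to the local mean, so nuclei near bright neighbours are
    judged on their own signal.
    """
    params = params or ClassifierParams()
    pixels = _as_pixels(gh2ax)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if pixels.shape != nucleus_mask.shape:
        raise ValueError("image and nucleus mask dimensions differ")
    rows, cols = np.nonzero(nucleus_mask)
    if rows.size < 9 or np.ptp(rows) < 2 or np.ptp(cols) < 2:
        raise DegenerateInputError("nucleus smaller than 3x3; adaptive threshold undefined")

    # work on the bounding box only
    pad = params.adaptive_window_px // 2
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub_img = pixels[r0:r1, c0:c1]
    sub_mask = nucleus_mask[r0:r1, c0:c1]

    size = params.adaptive_window_px
    masked = np.where(sub_mask, sub_img, 0.0)
    local_sum = ndimage.uniform_filter(masked, size=size, mode="constant", cval=0.0) * size**2
    local_n = (
        ndimage.uniform_filter(sub_mask.astype(np.float64), size=size, mode="constant", cval=0.0)
        * size**2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = local_sum / local_n
    fg_sub = sub_mask & (sub_img > (1.0 + params.adaptive_rel_offset) * local_mean)

    out = np.zeros_like(nucleus_mask)
    out[r0:r1, c0:c1] = fg_sub
    return out


def count_foci(
    foci_mask: np.ndarray,
    nucleus: NucleusRecord,
    params: ClassifierParams | None = None,
) -> FociResult:
    """Count foci and apply the strict density cutoff.

    Foci are 8-connected components of the binarised mask with area at
    least ``min_focus_area_px``; the density is count / nucleus area and
    the nucleus is foci-positive iff density > ``foci_density_cutoff``.
    """
    params = params or ClassifierParams()
    labelled = skmeasure.label(np.asarray(foci_mask, dtype=bool), connectivity=2)
    centroids = [
        (float(r.centroid[0]), float(r.centroid[1]))
        for r in skmeasure.regionprops(labelled)
        if r.area >= params.min_focus_area_px
    ]
    count = len(centroids)
    density = count / nucleus.area_px
    return FociResult(
        foci_count=count,
        foci_density=density,
        is_foci=density > params.foci_density_cutoff,
        focus_centroids=centroids,
    )


def _ray_origin(nucleus: NucleusRecord, nucleus_mask: np.ndarray) -> tuple[float, float]:
    """Centre of mass, or the nearest member pixel if the centroid falls
    outside a concave nucleus."""
    r, c = nucleus.centroid
    ri, ci = int(round(r)), int(round(c))
    h, w = nucleus_mask.shape
    if 0 <= ri < h and 0 <= ci < w and nucleus_mask[ri, ci]:
        return (r, c)
    rows, cols = np.nonzero(nucleus_mask)
    d2 = (rows - r) ** 2 + (cols - c) ** 2
    k = int(np.argmin(d2))
    logger.info(
        "nucleus %d: centroid outside object, using nearest interior pixel", nucleus.nucleus_id
    )
    return (float(rows[k]), float(cols[k]))


def cast_radial_profiles(
    gh2ax: ChannelImage | np.ndarray,
    nucleus: NucleusRecord,
    nucleus_mask: np.ndarray,
    params: ClassifierParams | None = None,
) -> list[np.ndarray]:
    """Sample one intensity profile per boundary pixel.

    Each ray runs from the centre of mass to a boundary pixel, sampled
    at steps of at most 1 px with bilinear interpolation; both endpoints
    are included.  ``n_profile_rays`` may limit the rays to an evenly
    spaced subset of boundary pixels.
    """
    params = params or ClassifierParams()
    pixels = _as_pixels(gh2ax)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    boundary = np.asarray(nucleus.boundary_pixels, dtype=np.float64)
    if len(boundary) < 8:
        raise DegenerateInputError(
            f"nucleus {nucleus.nucleus_id}: fewer than 8 boundary pixels"
        )
    if nucleus_mask.sum() == len(boundary):
        raise DegenerateInputError(
            f"nucleus {nucleus.nucleus_id}: all pixels are boundary pixels"
        )
    if isinstance(params.n_profile_rays, int):
        take = np.linspace(0, len(boundary) - 1, params.n_profile_rays).round().astype(int)
        boundary = boundary[np.unique(take)]
    origin = np.array(_ray_origin(nucleus, nucleus_mask))

    coords: list[np.ndarray] = []
    lengths: list[int] = []
    for target in boundary:
        dist = float(np.hypot(*(target - origin)))
        n = max(2, int(np.ceil(dist)) + 1)
        t = np.linspace(0.0, 1.0, n)
        coords.append(origin[:, None] + t[None, :] * (target - origin)[:, None])
        lengths.append(n)
    all_coords = np.concatenate(coords, axis=1)
    samples = ndimage.map_coordinates(pixels, all_coords, order=1, mode="nearest")
    rays = np.split(samples, np.cumsum(lengths)[:-1])
    return [np.asarray(r) for r in rays]


def resample_and_average(rays: list[np.ndarray]) -> RadialProfile:
    """Resample all rays to the longest length and average pointwise.

    Each ray is linearly interpolated onto ``L`` equally spaced
    positions (endpoints preserved), where ``L`` is the longest ray
    length; the mean profile is split at index ``floor(0.75 * L)`` into
    the first three quartiles and the last (peripheral) quartile.
    """
    if not rays:
        raise ValueError("cannot average an empty list of rays")
    L = max(len(r) for r in rays)
    grid = np.linspace(0.0, 1.0, L)
    resampled = np.empty((len(rays), L))
    for i, ray in enumerate(rays):
        ray = np.asarray(ray, dtype=np.float64)
        if len(ray) == L:
            resampled[i] = ray
        else:
            resampled[i] = np.interp(grid, np.linspace(0.0, 1.0, len(ray)), ray)
    profile = resampled.mean(axis=0)
    split = int(np.floor(0.75 * L))
    split = min(max(split, 1), L - 1)  # both segments non-empty
    mean_q123 = float(profile[:split].mean())
    mean_q4 = float(profile[split:].mean())
    overall = float(profile.mean())
    ring_score = (mean_q4 - mean_q123) / overall if overall > 0 else float("nan")
    return RadialProfile(
        profile=profile,
        mean_q4=mean_q4,
        mean_q123=mean_q123,
        overall_mean=overall,
        ring_score=ring_score,
    )


def classify_ring(profile: RadialProfile, params: ClassifierParams | None = None) -> bool:
    """Apply the peripheral-enrichment rule.

    True iff ``mean_q4 - mean_q123 > ring_rel_threshold * overall_mean``.
    The difference is signed, so a bright centre can never qualify.
    Zero-signal profiles (overall mean 0) return False; the caller flags
    them for QC.
    """
    params = params or ClassifierParams()
    if not profile.overall_mean > 0:
        return False
    return (profile.mean_q4 - profile.mean_q123) > params.ring_rel_threshold * profile.overall_mean


def classify_nucleus(
    gh2ax: ChannelImage | np.ndarray,
    nucleus: NucleusRecord,
    nucleus_mask: np.ndarray,
    params: ClassifierParams | None = None,
) -> PhenotypeCall:
    """Assign exactly one phenotype to an accepted nucleus.

    FOCI if the foci-density rule fires; otherwise RING if the radial
    quartile rule fires; otherwise UNIFORM.  The radial profile is only
    computed (and reported) for non-foci nuclei.
    """
    params = params or ClassifierParams()
    foci_mask = adaptive_binarize(gh2ax, nucleus_mask, params)
    foci = count_foci(foci_mask, nucleus, params)
    if foci.is_foci:
        return PhenotypeCall(nucleus_id=nucleus.nucleus_id, phenotype=Phenotype.FOCI, foci=foci)
    rays = cast_radial_profiles(gh2ax, nucleus, nucleus_mask, params)
    radial = resample_and_average(rays)
    zero_signal = not radial.overall_mean > 0
    if zero_signal:
        logger.warning("nucleus %d: zero gamma-H2AX signal, reported UNIFORM", nucleus.nucleus_id)
    phenotype = Phenotype.RING if classify_ring(radial, params) else Phenotype.UNIFORM
    return PhenotypeCall(
        nucleus_id=nucleus.nucleus_id,
        phenotype=phenotype,
        foci=foci,
        radial=radial,
        zero_signal=zero_signal,
    )


def classify_field(
    gh2ax: ChannelImage | np.ndarray,
    mask,
    records: list[NucleusRecord],
    params: ClassifierParams | None = None,
) -> list[PhenotypeCall]:
    """Classify every accepted nucleus of a segmented field."""
    params = params or ClassifierParams()
    labels = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
    calls = []
    for rec in records:
        if not rec.accepted:
            continue
        calls.append(classify_nucleus(gh2ax, rec, labels == rec.nucleus_id, params))
    return calls
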