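"""Nucleus detection from the DAPI channel.

The pipeline is: Gaussian smoothing -> automatic global threshold
(Otsu, exhaustive between-class-variance maximisation over a 256-bin
histogram) -> morphological refinement (dilations, hole filling,
erosions with a disc) -> 8-connected component labelling -> per-object
measurement -> the four nucleus filters, all with strict inequalities:

* area > ``min_area_px`` (default 400 px),
* eccentricity < ``max_eccentricity`` (default 0.8),
* circularity 4*pi*Area/Perimeter^2 > ``min_circularity`` (default 0.85),
* mean DAPI intensity < ``intensity_median_factor`` x the median mean
  intensity over all candidate objects of the field (default 2x).

The intensity rule removes saturated debris and mitotic figures; its
median is computed once over every candidate, so the accepted set does
not depend on the order in which objects are examined.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .model import (
    ChannelImage,
    DegenerateInputError,
    LabelMask,
    NucleusRecord,
    RejectionReason,
    SegmentationParams,
)

logger = logging.getLogger(__name__)

__all__ = [
    "smooth_dapi",
    "global_binarize",
    "refine_mask",
    "label_objects",
    "measure_nuclei",
    "filter_nuclei",
    "segment_nuclei",
]


def smooth_dapi(dapi: ChannelImage | np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth an intensity image (reflective padding).

    Total intensity is conserved up to boundary truncation, so constant
    images stay constant and an interior impulse keeps its mass.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pixels = dapi.pixels if isinstance(dapi, ChannelImage) else np.asarray(dapi)
    return ndimage.gaussian_filter(pixels.astype(np.float64), sigma=sigma, mode="reflect")


def global_binarize(smoothed: np.ndarray, *, return_threshold: bool = False):
    """Binarise with an automatically determined global threshold.

    The threshold maximises between-class variance over a 256-bin
    histogram (Otsu); foreground is strictly above it.  Because bins
    span the image's own intensity range, the foreground set is
    invariant under positive rescaling of the intensities.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if np.ptp(smoothed) == 0:
        raise DegenerateInputError("constant image: no global threshold exists")
    threshold = float(threshold_otsu(smoothed, nbins=256))
    logger.info("global threshold (Otsu, 256 bins): %.6g", threshold)
    mask = smoothed > threshold
    return (mask, threshold) if return_threshold else mask


def refine_mask(binary: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Regularise a binary mask: dilations, hole filling, erosions.

    Each pass uses a disc of ``struct_radius_px``.  Erosion treats the
    image border as foreground so border-touching objects do not shrink
    from the edge.  Hole filling is idempotent.
    """
    binary = np.asarray(binary, dtype=bool)
    footprint = disk(params.struct_radius_px)
    out = binary
    if params.n_dilations:
        out = ndimage.binary_dilation(out, structure=footprint, iterations=params.n_dilations)
    out = ndimage.binary_fill_holes(out)
    if params.n_erosions:
        out = ndimage.binary_erosion(
            out, structure=footprint, iterations=params.n_erosions, border_value=1
        )
    return out


def label_objects(binary: np.ndarray) -> LabelMask:
    """Label 8-connected foreground components 1..n in raster-scan order.

    The object whose first pixel comes first in row-major order gets
    label 1, and so on, independent of the backend's internal order.
    """
    binary = np.asarray(binary, dtype=bool)
    raw = skmeasure.label(binary, connectivity=2)
    n = int(raw.max())
    if n == 0:
        return LabelMask(labels=raw.astype(np.int64))
    flat = raw.ravel()
    first_index = np.full(n + 1, flat.size, dtype=np.int64)
    # first raster-scan occurrence of each label
    idx = np.flatnonzero(flat)
    np.minimum.at(first_index, flat[idx], idx)
    order = np.argsort(first_index[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[1 + order] = np.arange(1, n + 1)
    return LabelMask(labels=remap[raw])


def _boundary_pixels(obj: np.ndarray) -> np.ndarray:
    """Member pixels 8-adjacent to a non-member (or to the image edge)."""
    interior = ndimage.binary_erosion(obj, structure=np.ones((3, 3), bool), border_value=0)
    rows, cols = np.nonzero(obj & ~interior)
    return np.column_stack([rows, cols])


def measure_nuclei(mask: LabelMask, dapi: ChannelImage | np.ndarray) -> list[NucleusRecord]:
    """Measure geometry and DAPI intensity for every labelled object.

    Area is the member-pixel count; the perimeter uses the standard
    digital contour-length estimator; the centroid is the unweighted
    centre of mass; eccentricity is that of the moment-matched ellipse;
    circularity is 4*pi*Area/Perimeter^2.
    """
    pixels = dapi.pixels if isinstance(dapi, ChannelImage) else np.asarray(dapi)
    if pixels.shape != mask.labels.shape:
        raise ValueError("mask and DAPI image dimensions differ")
    h, w = mask.labels.shape
    records: list[NucleusRecord] = []
    for region in skmeasure.regionprops(mask.labels, intensity_image=pixels.astype(np.float64)):
        obj = np.zeros_like(mask.labels, dtype=bool)
        rmin, cmin, rmax, cmax = region.bbox
        obj[rmin:rmax, cmin:cmax] = region.image
        perimeter = float(region.perimeter)
        circularity = (
            4.0 * np.pi * region.area / perimeter**2 if perimeter > 0 else float("inf")
        )
        boundary = _boundary_pixels(obj)
        touches = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        records.append(
            NucleusRecord(
                nucleus_id=int(region.label),
                area_px=int(region.area),
                perimeter_px=perimeter,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                eccentricity=float(region.eccentricity),
                circularity=float(circularity),
                mean_dapi=float(region.intensity_mean),
                boundary_pixels=boundary,
                touches_border=bool(touches),
            )
        )
    return records


def filter_nuclei(
    records: list[NucleusRecord], params: SegmentationParams
) -> list[NucleusRecord]:
    """Apply the four nucleus filters, setting accept/reject status in place.

    The intensity rule compares each object's mean DAPI with the median
    over *all* candidates (accepted or not), computed once up front; the
    first failed criterion, in the order area, eccentricity, regularity,
    intensity, is recorded as the rejection reason.  All comparisons are
    strict, so boundary values fail.
    """
    if not records:
        raise DegenerateInputError("no candidate objects to filter")
    median_intensity = float(np.median([r.mean_dapi for r in records]))
    intensity_cap = params.intensity_median_factor * median_intensity
    for rec in records:
        if not rec.area_px > params.min_area_px:
            reason = RejectionReason.AREA
        elif not rec.eccentricity < params.max_eccentricity:
            reason = RejectionReason.ECCENTRICITY
        elif not rec.circularity > params.min_circularity:
            reason = RejectionReason.REGULARITY
        elif not rec.mean_dapi < intensity_cap:
            reason = RejectionReason.INTENSITY
        else:
            reason = RejectionReason.NONE
        rec.rejection_reason = reason
        rec.accepted = reason is RejectionReason.NONE
    return records


def segment_nuclei(
    fov, params: SegmentationParams | None = None
) -> tuple[LabelMask, list[NucleusRecord]]:
    """Full DAPI segmentation: detect, measure and filter nuclei.

    Returns a label mask containing only accepted nuclei, relabelled
    ``1..k`` in raster-scan order, together with the complete record
    list (accepted first with ids matching the mask, then rejected
    candidates with ids ``k+1..n``) for quality control.

    With ``exclude_border`` set, candidates touching the image edge are
    dropped before the filters run (and before the intensity median is
    taken).
    """
    params = params or SegmentationParams()
    smoothed = smooth_dapi(fov.dapi, params.gaussian_sigma_px)
    binary = global_binarize(smoothed)
    refined = refine_mask(binary, params)
    candidates = label_objects(refined)
    records = measure_nuclei(candidates, fov.dapi)
    if params.exclude_border:
        records = [r for r in records if not r.touches_border]
    if not records:
        logger.warning("field %s: no candidate objects after segmentation", fov.field_id)
        return LabelMask(labels=np.zeros_like(candidates.labels)), []
    filter_nuclei(records, params)

    accepted = [r for r in records if r.accepted]
    rejected = [r for r in records if not r.accepted]
    remap = np.zeros(candidates.n_objects + 1, dtype=np.int64)
    for new_id, rec in enumerate(accepted, start=1):
        remap[rec.nucleus_id] = new_id
        rec.nucleus_id = new_id
    for new_id, rec in enumerate(rejected, start=len(accepted) + 1):
        rec.nucleus_id = new_id
    mask = LabelMask(labels=remap[candidates.labels])
    if not accepted:
        logger.warning("field %s: zero accepted nuclei", fov.field_id)
    return mask, accepted + rejected
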