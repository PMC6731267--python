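import numpy as np
import pytest

import ringtrack as rt
from ringtrack.model import DegenerateInputError, RejectionReason
from ringtrack.segmentation import _boundary_pixels

from conftest import disc_mask


# --- independent oracles -------------------------------------------------


def gaussian_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2-D convolution with the truncated, normalised Gaussian
    kernel and symmetric (reflective) padding."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-(x**2) / (2.0 * sigma**2))
    phi /= phi.sum()
    kernel = np.outer(phi, phi)
    padded = np.pad(img.astype(np.float64), radius, mode="symmetric")
    out = np.empty_like(img, dtype=np.float64)
    k = 2 * radius + 1
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sum(padded[i : i + k, j : j + k] * kernel)
    return out


def otsu_between_class_variance(img: np.ndarray):
    """Between-class variance at all 256 histogram split points, by
    exhaustive enumeration.  Returns (variances, bin centers)."""
    counts, edges = np.histogram(img.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    variances = np.full(256, -np.inf)
    for split in range(1, 256):
        w0 = counts[:split].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:split] * centers[:split]).sum() / w0
        mu1 = (counts[split:] * centers[split:]).sum() / w1
        variances[split - 1] = w0 * w1 * (mu0 - mu1) ** 2
    return variances, centers


def otsu_oracle_mask(img: np.ndarray) -> np.ndarray:
    """Foreground at the exhaustive-search between-class-variance maximiser."""
    variances, centers = otsu_between_class_variance(img)
    return img > centers[int(np.argmax(variances))]


def flood_fill_labels(binary: np.ndarray) -> np.ndarray:
    """8-connected components by explicit flood fill, labelled in
    raster-scan order of their first pixel."""
    h, w = binary.shape
    out = np.zeros((h, w), dtype=np.int64)
    next_label = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and out[i, j] == 0:
                next_label += 1
                stack = [(i, j)]
                out[i, j] = next_label
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and binary[rr, cc]
                                and out[rr, cc] == 0
                            ):
                                out[rr, cc] = next_label
                                stack.append((rr, cc))
    return out


# --- smoothing -----------------------------------------------------------


class TestSmoothDapi:
    def test_constant_image_stays_constant(self):
        img = np.full((32, 32), 7.0)
        out = rt.smooth_dapi(img, sigma=2.0)
        np.testing.assert_allclose(out, 7.0, rtol=1e-12)

    def test_impulse_mass_conserved(self):
        img = np.zeros((33, 33))
        img[16, 16] = 123.0
        out = rt.smooth_dapi(img, sigma=2.0)
        assert out.sum() == pytest.approx(123.0, rel=1e-6)

    def test_matches_direct_convolution_oracle(self):
        img = np.zeros((24, 24))
        img[7, 9] = 5.0
        img[15, 4] = 3.0
        out = rt.smooth_dapi(img, sigma=1.7)
        np.testing.assert_allclose(out, gaussian_oracle(img, 1.7), atol=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            rt.smooth_dapi(np.ones((16, 16)), sigma=0.0)


# --- global threshold ----------------------------------------------------


class TestGlobalBinarize:
    def test_bimodal_split(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.5, 10.0, 200.0)
        fg = rt.global_binarize(img)
        np.testing.assert_array_equal(fg, img == 200.0)
        np.testing.assert_array_equal(fg, otsu_oracle_mask(img))

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rt.global_binarize(np.full((32, 32), 5.0))

    def test_threshold_maximises_between_class_variance(self):
        # the variance curve can tie exactly across an empty histogram gap,
        # so the check is on the objective achieved, not the split chosen
        rng = np.random.default_rng(1)
        for _ in range(20):
            img = np.concatenate(
                [rng.normal(40, 5, 500), rng.normal(200, 10, 500)]
            ).reshape(25, 40)
            _, threshold = rt.global_binarize(img, return_threshold=True)
            variances, centers = otsu_between_class_variance(img)
            split = int(np.searchsorted(centers, threshold, side="left"))
            assert variances[split] == pytest.approx(variances.max(), rel=1e-9)

    def test_scale_invariant_foreground(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(40, 5, 300), rng.normal(150, 15, 300)]).reshape(
            20, 30
        )
        np.testing.assert_array_equal(rt.global_binarize(img), rt.global_binarize(img * 2.0))


# --- morphology + labelling ----------------------------------------------


class TestRefineMask:
    def test_hole_filled(self):
        mask = disc_mask(10)
        holey = mask.copy()
        holey[14, 14] = False
        out = rt.refine_mask(holey, rt.SegmentationParams(n_dilations=1, n_erosions=1))
        assert out[14, 14]

    def test_empty_stays_empty(self):
        out = rt.refine_mask(np.zeros((20, 20), bool), rt.SegmentationParams())
        assert not out.any()

    def test_dilate_erode_roughly_preserves_area(self):
        mask = disc_mask(10)
        out = rt.refine_mask(mask, rt.SegmentationParams(n_dilations=1, n_erosions=1))
        assert abs(out.sum() - mask.sum()) / mask.sum() <= 0.05

    def test_hole_filling_idempotent(self):
        mask = disc_mask(10)
        mask[12, 12] = False
        params = rt.SegmentationParams(n_dilations=0, n_erosions=0)
        once = rt.refine_mask(mask, params)
        np.testing.assert_array_equal(once, rt.refine_mask(once, params))


class TestLabelObjects:
    def test_diagonal_pixels_are_one_object(self):
        mask = np.zeros((16, 16), bool)
        mask[3, 3] = mask[4, 4] = True
        assert rt.label_objects(mask).n_objects == 1

    def test_separated_blobs_are_two_objects(self):
        mask = np.zeros((16, 16), bool)
        mask[1:3, 1:3] = True
        mask[10:12, 10:12] = True
        lab = rt.label_objects(mask)
        assert lab.n_objects == 2
        assert lab.labels[1, 1] == 1  # raster-scan order

    def test_matches_flood_fill_oracle_on_random_masks(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mask = rng.random((16, 16)) < 0.4
            np.testing.assert_array_equal(
                rt.label_objects(mask).labels, flood_fill_labels(mask)
            )


# --- measurement ---------------------------------------------------------


class TestMeasureNuclei:
    def test_disc_geometry(self):
        mask = disc_mask(30)
        lab = rt.label_objects(mask)
        dapi = np.full(mask.shape, 100.0)
        (rec,) = rt.measure_nuclei(lab, dapi)
        assert rec.area_px == pytest.approx(np.pi * 30**2, rel=0.02)
        assert rec.eccentricity < 0.1
        assert 0.85 <= rec.circularity <= 1.1
        assert rec.mean_dapi == 100.0

    def test_ellipse_eccentricity(self):
        n = 101
        rr, cc = np.mgrid[:n, :n]
        mask = ((rr - 50) / 20.0) ** 2 + ((cc - 50) / 40.0) ** 2 <= 1.0
        lab = rt.label_objects(mask)
        (rec,) = rt.measure_nuclei(lab, np.ones(mask.shape))
        assert rec.eccentricity == pytest.approx(np.sqrt(1 - (20 / 40) ** 2), abs=0.02)

    def test_single_pixel_object(self):
        mask = np.zeros((16, 16), bool)
        mask[5, 7] = True
        (rec,) = rt.measure_nuclei(rt.label_objects(mask), np.ones(mask.shape))
        assert rec.area_px == 1
        np.testing.assert_array_equal(rec.boundary_pixels, [[5, 7]])

    def test_boundary_pixels_are_adjacent_to_background(self):
        mask = disc_mask(8)
        boundary = _boundary_pixels(mask)
        assert len(boundary) > 0
        for r, c in boundary:
            window = mask[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
            assert mask[r, c] and not window.all()


# --- the four filters -----------------------------------------------------


def _record(nucleus_id=1, area=500, ecc=0.5, circ=0.9, mean_dapi=100.0):
    return rt.NucleusRecord(
        nucleus_id=nucleus_id,
        area_px=area,
        perimeter_px=80.0,
        centroid=(10.0, 10.0),
        eccentricity=ecc,
        circularity=circ,
        mean_dapi=mean_dapi,
        boundary_pixels=np.array([[0, 0]]),
    )


class TestFilterNuclei:
    def test_area_exactly_400_is_rejected(self):
        recs = rt.filter_nuclei([_record(area=400)], rt.SegmentationParams())
        assert not recs[0].accepted
        assert recs[0].rejection_reason is RejectionReason.AREA

    def test_eccentricity_just_below_cutoff_accepted(self):
        recs = rt.filter_nuclei([_record(ecc=0.79)], rt.SegmentationParams())
        assert recs[0].accepted

    def test_intensity_median_rule(self):
        recs = [
            _record(1, mean_dapi=100.0),
            _record(2, mean_dapi=100.0),
            _record(3, mean_dapi=250.0),
        ]
        rt.filter_nuclei(recs, rt.SegmentationParams())
        assert [r.accepted for r in recs] == [True, True, False]
        assert recs[2].rejection_reason is RejectionReason.INTENSITY

    def test_first_failed_criterion_recorded(self):
        recs = rt.filter_nuclei(
            [_record(area=100, ecc=0.95, circ=0.1)], rt.SegmentationParams()
        )
        assert recs[0].rejection_reason is RejectionReason.AREA

    def test_outcome_independent_of_record_order(self):
        recs = [
            _record(1, mean_dapi=90.0),
            _record(2, mean_dapi=110.0),
            _record(3, mean_dapi=250.0),
            _record(4, area=350),
        ]
        fwd = {r.nucleus_id: r.accepted for r in rt.filter_nuclei(list(recs), rt.SegmentationParams())}
        rev = {r.nucleus_id: r.accepted for r in rt.filter_nuclei(recs[::-1], rt.SegmentationParams())}
        assert fwd == rev

    def test_empty_record_list_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rt.filter_nuclei([], rt.SegmentationParams())


# --- full segmentation ----------------------------------------------------


class TestSegmentNuclei:
    def test_phantom_nuclei_all_accepted(self, small_phantom_analysed):
        spec, fov, truth, table, mask = small_phantom_analysed
        acc = table[table["accepted"].astype(bool)]
        assert len(acc) == spec.n_nuclei
        assert mask.n_objects == spec.n_nuclei

    def test_undersized_object_rejected(self):
        dapi = np.full((256, 256), 100.0)
        rr, cc = np.mgrid[:256, :256]
        for center, radius in (((60, 60), 20), ((160, 160), 25), ((60, 180), 9)):
            inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
            dapi[inside] = 2000.0
        chan = rt.ChannelImage(dapi.astype(np.uint16), rt.ChannelRole.DAPI, 16)
        fov = rt.FieldOfView({"dapi": chan, "gh2ax": chan}, "f", "c")
        mask, records = rt.segment_nuclei(fov, rt.SegmentationParams())
        assert sum(r.accepted for r in records) == 2
        rejected = [r for r in records if not r.accepted]
        assert rejected and all(r.rejection_reason is RejectionReason.AREA for r in rejected)

    def test_blank_field_is_degenerate(self):
        chan = rt.ChannelImage(np.zeros((64, 64), np.uint16), rt.ChannelRole.DAPI, 16)
        fov = rt.FieldOfView({"dapi": chan, "gh2ax": chan}, "f", "c")
        with pytest.raises(DegenerateInputError):
            rt.segment_nuclei(fov)

    def test_accepted_set_invariant_under_dapi_scaling(self):
        spec = rt.PhantomSpec(
            n_nuclei=8,
            field_size_px=(512, 512),
            dapi_level=600,
            dapi_background=30,
            gh2ax_base=600,
            gh2ax_background=480,
            focus_amplitude=2400,
            seed=5,
        )
        fov, _ = rt.generate_field(spec)
        baseline = None
        for k in (1.0, 0.5, 3.0, 10.0):
            scaled = rt.ChannelImage(
                fov.dapi.pixels.astype(np.float64) * k, rt.ChannelRole.DAPI, 16
            ) if k * fov.dapi.pixels.max() <= 65535 else None
            assert scaled is not None
            fov_k = rt.FieldOfView(
                {"dapi": scaled, "gh2ax": fov.gh2ax}, fov.field_id, fov.condition
            )
            _, records = rt.segment_nuclei(fov_k)
            key = sorted(
                (round(r.centroid[0]), round(r.centroid[1])) for r in records if r.accepted
            )
            if baseline is None:
                baseline = key
            assert key == baseline
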