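"""ROI IO, filtering, signal extraction, neuropil correction, dF/f."""

import numpy as np
import pytest

import colliscope as cs
from colliscope import imagej_roi
from colliscope.extraction import (
    ExtractionError,
    RoiSet,
    dff_from_baseline,
    rois_from_label_image,
)
from colliscope.imagej_roi import OVAL, POLYGON, RECT, RoiFormatError, RoiGeometry


def _disk_mask(shape, r0, c0, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2


class TestImageJRoi:
    @pytest.mark.parametrize(
        "roi",
        [
            RoiGeometry("oval1", OVAL, 10, 12, 20, 26),
            RoiGeometry("rect1", RECT, 3, 5, 9, 14),
            RoiGeometry(
                "poly1", POLYGON, 5, 5, 15, 15,
                xs=np.array([5, 14, 10]), ys=np.array([5, 6, 14]),
            ),
        ],
    )
    def test_roi_binary_round_trip(self, roi):
        back = imagej_roi.read_roi_bytes(imagej_roi.write_roi_bytes(roi), roi.name)
        assert (back.roi_type, back.top, back.left, back.bottom, back.right) == (
            roi.roi_type, roi.top, roi.left, roi.bottom, roi.right,
        )
        if roi.xs is not None:
            assert np.array_equal(back.xs, roi.xs)
            assert np.array_equal(back.ys, roi.ys)

    def test_zip_round_trip_preserves_masks(self, tmp_path):
        rois = [
            RoiGeometry("a", OVAL, 4, 4, 14, 14),
            RoiGeometry("b", RECT, 20, 20, 26, 30),
            RoiGeometry("c", POLYGON, 30, 5, 40, 15,
                        xs=np.array([5, 14, 9]), ys=np.array([30, 31, 39])),
        ]
        path = tmp_path / "RoiSet.zip"
        imagej_roi.write_roi_zip(rois, path)
        loaded = cs.load_rois(path, image_shape=(48, 48))
        assert len(loaded) == 3
        reference = cs.load_rois(path, image_shape=(48, 48))
        for cid in loaded.cell_ids:
            assert np.array_equal(loaded.masks[cid], reference.masks[cid])

    def test_bad_magic_rejected(self):
        with pytest.raises(RoiFormatError):
            imagej_roi.read_roi_bytes(b"nope" + bytes(80))

    def test_empty_archive_rejected(self, tmp_path):
        import zipfile

        path = tmp_path / "empty.zip"
        with zipfile.ZipFile(path, "w"):
            pass
        with pytest.raises(RoiFormatError):
            imagej_roi.read_roi_zip(path)

    def test_out_of_bounds_roi_clipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "edge.zip"
        imagej_roi.write_roi_zip([RoiGeometry("edge", RECT, 28, 28, 40, 40)], path)
        with caplog.at_level("WARNING", logger="colliscope.extraction"):
            rois = cs.load_rois(path, image_shape=(32, 32))
        assert rois.masks["edge"].sum() == 4 * 4
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_label_image_conversion(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[2:5, 2:5] = 1
        labels[8:12, 8:12] = 2
        rois = rois_from_label_image(labels)
        assert len(rois) == 2
        assert rois.masks["cell0001"].sum() == 9


class TestGaussianFilter:
    def test_constant_stack_unchanged(self):
        stack = np.full((6, 8, 8), 3.5)
        out = cs.gaussian_filter_stack(stack, 1.0, 2.0)
        assert np.allclose(out, 3.5)

    def test_impulse_peak_matches_closed_form_kernel(self):
        # spatial-only filtering of a unit impulse leaves the 2-D kernel
        stack = np.zeros((1, 41, 41))
        stack[0, 20, 20] = 1.0
        out = cs.gaussian_filter_stack(stack, sigma_xy_px=1.0, sigma_t_frames=0.0)
        # oracle: peak of the normalized sampled Gaussian, squared (separable axes)
        x = np.arange(-20, 21)
        k1 = np.exp(-0.5 * x**2)
        k1 /= k1.sum()
        assert out[0, 20, 20] == pytest.approx(k1.max() ** 2, abs=1e-6)
        # and close to the continuous-kernel peak 1/(2 pi sigma^2)
        assert out[0, 20, 20] == pytest.approx(1.0 / (2 * np.pi), abs=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            cs.gaussian_filter_stack(np.zeros((2, 4, 4)), -1.0, 0.0)


class TestExtractSignals:
    def test_uniform_disk_on_zero_background(self):
        shape = (32, 32)
        mask = _disk_mask(shape, 16, 16, 5)
        rois = RoiSet({"c0": mask}, shape)
        stack = np.where(mask, 7.0, 0.0)[None].repeat(4, axis=0)
        raw = cs.extract_signals(stack, rois)
        assert np.allclose(raw.cell[:, 0], 7.0)
        assert np.allclose(raw.neuropil[:, 0], 0.0)

    def test_annulus_area_at_least_four_times_roi(self):
        shape = (64, 64)
        masks = {
            "c0": _disk_mask(shape, 20, 20, 4),
            "c1": _disk_mask(shape, 44, 44, 4),
        }
        rois = RoiSet(masks, shape)
        from colliscope.extraction import _neuropil_mask

        all_cells = masks["c0"] | masks["c1"]
        for m in masks.values():
            annulus = _neuropil_mask(m, all_cells, 4.0)
            assert annulus.sum() >= 4 * m.sum()
            assert not (annulus & all_cells).any()

    def test_matches_per_pixel_mean_oracle(self, rng):
        shape = (24, 24)
        stack = rng.normal(size=(10, *shape))
        masks = {"a": _disk_mask(shape, 8, 8, 3), "b": _disk_mask(shape, 16, 16, 3)}
        rois = RoiSet(masks, shape)
        raw = cs.extract_signals(stack, rois)
        for j, cid in enumerate(rois.cell_ids):
            expected = np.array([stack[t][masks[cid]].mean() for t in range(10)])
            assert np.abs(raw.cell[:, j] - expected).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        rois = RoiSet({"c": _disk_mask((16, 16), 8, 8, 3)}, (16, 16))
        with pytest.raises(ValueError):
            cs.extract_signals(np.zeros((3, 8, 8)), rois)


class TestNeuropilCorrect:
    def test_published_coefficient_arithmetic(self):
        raw = cs.RawTraces(np.full((3, 1), 10.0), np.full((3, 1), 5.0), 29.9, ["c"])
        assert np.allclose(cs.neuropil_correct(raw, 0.4), 8.0)

    def test_zero_neuropil_is_identity(self, rng):
        cell = rng.normal(size=(20, 3)) + 10
        raw = cs.RawTraces(cell, np.zeros_like(cell), 29.9, list("abc"))
        assert np.allclose(cs.neuropil_correct(raw, 0.4), cell)

    def test_elementwise_oracle_and_linearity(self, rng):
        cell = rng.normal(size=(30, 4))
        neuropil = rng.normal(size=(30, 4))
        raw = cs.RawTraces(cell, neuropil, 29.9, list("abcd"))
        out = cs.neuropil_correct(raw, 0.4)
        assert np.abs(out - (cell - 0.4 * neuropil)).max() < 1e-12
        scaled = cs.RawTraces(3.0 * cell, 3.0 * neuropil, 29.9, list("abcd"))
        assert np.allclose(cs.neuropil_correct(scaled, 0.4), 3.0 * out)

    def test_coefficient_range_enforced(self):
        raw = cs.RawTraces(np.ones((3, 1)), np.ones((3, 1)), 29.9, ["c"])
        with pytest.raises(ValueError):
            cs.neuropil_correct(raw, 1.5)


class TestComputeDff:
    def test_trace_equal_to_baseline_gives_zero(self):
        assert np.allclose(dff_from_baseline(np.full(5, 3.0), np.full(5, 3.0)), 0.0)

    def test_trace_twice_baseline_gives_one(self):
        assert np.allclose(dff_from_baseline(np.full(5, 6.0), np.full(5, 3.0)), 1.0)

    def test_constant_trace_normalizes_to_zero(self):
        dff = cs.compute_dff(np.full((200, 2), 50.0), 29.9)
        assert np.abs(dff.dff).max() < 1e-12

    def test_gain_invariance(self, rng):
        trace = 100.0 + np.abs(rng.normal(0, 5, size=(300, 2)))
        a = cs.compute_dff(trace, 29.9).dff
        b = cs.compute_dff(7.3 * trace, 29.9).dff
        assert np.abs(a - b).max() < 1e-9

    def test_bleached_transient_amplitude_recovered(self):
        # exponential bleach with one injected transient of known dF/f
        fr, amp = 29.9, 0.4
        t = np.arange(int(40 * fr)) / fr
        bleach = np.exp(-t / 300.0)
        from colliscope.synthetic import transient_kernel

        drive = np.zeros_like(t)
        k = transient_kernel(fr)
        drive[300 : 300 + k.size] = amp * k
        trace = (100.0 * bleach * (1.0 + drive))[:, None]
        dff = cs.compute_dff(trace, fr)
        assert dff.dff.max() == pytest.approx(amp, rel=0.05)

    def test_noise_free_recovery_within_1e6(self):
        # no bleaching, sparse transient: recovered dF/f is the injected shape
        fr, amp = 29.9, 0.3
        n = int(20 * fr)
        from colliscope.synthetic import transient_kernel

        k = transient_kernel(fr)
        drive = np.zeros(n)
        drive[200 : 200 + k.size] = amp * k
        trace = (80.0 * (1.0 + drive))[:, None]
        dff = cs.compute_dff(trace, fr)
        assert np.abs(dff.dff[:, 0] - drive).max() < 1e-6

    def test_nonpositive_baseline_reported(self):
        trace = np.linspace(10, -10, 100)[:, None]
        with pytest.raises(ValueError, match="cell0000"):
            cs.compute_dff(trace, 29.9, baseline_method="linear_trend")
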