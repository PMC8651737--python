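"""Cell detection: prominence filtering, positions, crops, fragment split."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from rbcmorph.detect import (
    DetectionPoint,
    extract_crop,
    find_cell_maxima,
    peak_prominence,
    peak_prominences,
    split_cells_fragments,
)
from rbcmorph.morphometry import BinaryMask, binarize_crop
from rbcmorph.preprocess import IntensityFrame, preprocess_frame
from rbcmorph.synthetic import (
    FrameSpec,
    SequenceSpec,
    fragment_spec,
    render_frame,
    render_sequence,
    symmetric_cell_spec,
)


def gaussian_bump(shape, center, amplitude, sigma=6.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


class TestProminence:
    def test_fast_persistence_matches_reconstruction_oracle(self, rng):
        """Union-find persistence must agree with per-peak grayscale
        reconstruction (the independent definition of topographic
        prominence)."""
        from skimage.feature import peak_local_max

        for _ in range(3):
            m = ndi.gaussian_filter(rng.normal(size=(90, 90)), 5)
            m = (m - m.min()) / np.ptp(m) * 255
            peaks = [(int(r), int(c)) for r, c in peak_local_max(m, min_distance=2)]
            fast = peak_prominences(m, peaks)
            slow = [peak_prominence(m, p) for p in peaks]
            np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_two_bump_map_keeps_only_prominent_peak(self):
        m = gaussian_bump((120, 120), (40, 40), 200.0) + gaussian_bump(
            (120, 120), (40, 90), 30.0
        )
        pts = find_cell_maxima(m, min_prominence=50, min_distance=10)
        assert len(pts) == 1
        assert np.hypot(pts[0].position[0] - 40, pts[0].position[1] - 40) < 3

    def test_raising_prominence_never_increases_detections(self):
        m = sum(
            gaussian_bump((160, 160), c, a)
            for c, a in [((40, 40), 255.0), ((40, 120), 140.0), ((120, 80), 70.0)]
        )
        counts = [
            len(find_cell_maxima(m, min_prominence=p, min_distance=10))
            for p in (20, 60, 150, 300)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFindCellMaxima:
    def test_flat_map_yields_empty_list(self):
        assert find_cell_maxima(np.zeros((64, 64))) == []

    def test_clean_frame_counts_and_positions(self):
        frames, cell_truth, _ = render_sequence(
            SequenceSpec(n_frames=2, noise_sd=0.0, seed=21)
        )
        for frame in frames:
            _, edges = preprocess_frame(frame)
            pts = find_cell_maxima(edges)
            truth = cell_truth[cell_truth.frame_index == frame.frame_index]
            assert len(pts) == len(truth)
            for _, row in truth.iterrows():
                d = min(
                    np.hypot(
                        p.position[0] - row.centroid_row,
                        p.position[1] - row.centroid_col,
                    )
                    for p in pts
                )
                assert d <= 5.0

    def test_positions_are_translation_equivariant(self):
        base = gaussian_bump((200, 200), (60, 70), 220.0) + gaussian_bump(
            (200, 200), (130, 140), 180.0
        )
        shifted = np.roll(base, (11, -7), axis=(0, 1))
        p0 = find_cell_maxima(base, min_distance=10)
        p1 = find_cell_maxima(shifted, min_distance=10)
        assert len(p0) == len(p1) == 2
        for a, b in zip(p0, sorted(p1, key=lambda p: p.position)):
            assert b.position[0] - a.position[0] == pytest.approx(11, abs=0.1)
            assert b.position[1] - a.position[1] == pytest.approx(-7, abs=0.1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_cell_maxima(np.ones((8, 8)), min_prominence=0)
        with pytest.raises(ValueError):
            find_cell_maxima(np.ones((8, 8)), min_distance=0)


class TestExtractCrop:
    def test_centered_crop_origin_and_size(self):
        frame = IntensityFrame(np.arange(200 * 200, dtype=float).reshape(200, 200))
        point = DetectionPoint((100.0, 100.0), 60.0)
        crop = extract_crop(frame, point, window=64)
        assert crop.patch.shape == (64, 64)
        assert crop.origin == (68, 68)
        assert not crop.boundary_truncated

    def test_near_border_crop_flagged_truncated(self):
        frame = IntensityFrame(np.zeros((200, 200)))
        crop = extract_crop(frame, DetectionPoint((10.0, 100.0), 60.0), window=64)
        assert crop.boundary_truncated

    def test_crop_roundtrip_is_pixel_identical(self):
        rng = np.random.default_rng(4)
        frame = IntensityFrame(rng.uniform(0, 255, (128, 128)))
        crop = extract_crop(frame, DetectionPoint((64.0, 64.0), 60.0), window=32)
        r0, c0 = crop.origin
        np.testing.assert_array_equal(
            crop.patch, frame.pixels[r0 : r0 + 32, c0 : c0 + 32]
        )

    def test_point_outside_frame_rejected(self):
        frame = IntensityFrame(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="outside"):
            extract_crop(frame, DetectionPoint((90.0, 10.0), 60.0), window=16)


class TestSplitCellsFragments:
    @staticmethod
    def _disk_mask(radius):
        side = 2 * radius + 11
        rr, cc = np.mgrid[:side, :side]
        disk = (rr - side // 2) ** 2 + (cc - side // 2) ** 2 <= radius**2
        return BinaryMask.from_array(disk)

    def test_area_routes_cells_and_fragments(self):
        crops = [None, None]
        masks = [self._disk_mask(20), self._disk_mask(5)]
        cells, fragments = split_cells_fragments(crops, masks, min_cell_area=200)
        assert len(cells) == 1 and len(fragments) == 1
        assert cells[0][1].area > 200 > fragments[0][1].area

    def test_mixed_frame_tallies(self):
        cells = tuple(
            symmetric_cell_spec((90 + 90 * (i // 3), 80 + 110 * (i % 3)), 24, 12, 20.0 * i)
            for i in range(5)
        )
        frags = tuple(
            fragment_spec((300, 80 + 100 * j), 3.0, 2.5) for j in range(3)
        )
        frame, _ = render_frame(
            FrameSpec(height=384, width=384, cells=cells + frags, noise_sd=0.0, seed=2)
        )
        corrected, edges = preprocess_frame(frame)
        pts = find_cell_maxima(edges)
        assert len(pts) == 8
        crops = [extract_crop(corrected, p, 128) for p in pts]
        masks = [
            binarize_crop(
                c.patch,
                (p.position[0] - c.origin[0], p.position[1] - c.origin[1]),
            )
            for c, p in zip(crops, pts)
        ]
        got_cells, got_frags = split_cells_fragments(crops, masks, min_cell_area=200)
        assert (len(got_cells), len(got_frags)) == (5, 3)
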