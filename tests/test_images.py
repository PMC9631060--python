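"""Image container, TIFF I/O and preprocessing primitives."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from nichequant.images import (
    BinaryMask,
    DegenerateInputError,
    ImageStack,
    ValidationError,
    binarize,
    enhance_contrast,
    label_objects,
    max_project,
    read_stack,
    rolling_ball_subtract,
    write_stack,
)


class TestImageStack:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            ImageStack(data=np.zeros(5))  # 1D
        with pytest.raises(ValidationError):
            ImageStack(data=np.zeros((4, 4)), spacing=0.0)
        with pytest.raises(ValidationError):
            ImageStack(data=np.full((4, 4), np.nan))
        with pytest.raises(ValidationError):
            ImageStack(data=-np.ones((4, 4)))

    def test_scalar_spacing_broadcasts(self):
        s = ImageStack(data=np.zeros((3, 4, 5)), spacing=2.0)
        assert s.spacing == (2.0, 2.0, 2.0)
        assert s.voxel_volume_um3 == 8.0


class TestReadWrite:
    def test_single_page_identity(self, tmp_path):
        p = tmp_path / "z.tif"
        tifffile.imwrite(p, np.zeros((16, 16), dtype=np.uint8))
        s = read_stack(p, spacing=1.0)
        assert s.ndim == 2 and not s.data.any()

    def test_multipage_round_trip(self, tmp_path, rng):
        data = rng.integers(0, 255, size=(40, 12, 12)).astype(np.uint8)
        p = tmp_path / "stack.tif"
        write_stack(p, ImageStack(data=data, spacing=(5.0, 1.0, 1.0)))
        back = read_stack(p, spacing=(5.0, 1.0, 1.0))
        np.testing.assert_array_equal(back.data, data)

    def test_page_order_preserved(self, tmp_path):
        data = np.stack([np.full((8, 8), k, dtype=np.uint8) for k in range(3)])
        p = tmp_path / "pages.tif"
        tifffile.imwrite(p, data)
        s = read_stack(p, spacing=1.0)
        for k in range(3):
            assert (s.data[k] == k).all()

    def test_unreadable_file_names_path(self, tmp_path):
        p = tmp_path / "nope.tif"
        p.write_text("not a tiff")
        with pytest.raises(OSError, match="nope.tif"):
            read_stack(p, spacing=1.0)

    def test_mask_written_as_0_255(self, tmp_path):
        mask = BinaryMask(data=np.eye(4, dtype=bool), spacing=1.0)
        p = tmp_path / "m.tif"
        write_stack(p, mask)
        assert set(np.unique(tifffile.imread(p))) == {0, 255}


class TestMaxProject:
    def test_matches_bruteforce_max(self, rng):
        data = rng.integers(0, 1000, size=(7, 9, 11))
        out = max_project(ImageStack(data=data, spacing=(5.0, 1.0, 1.0)))
        expected = np.zeros((9, 11), dtype=int)
        for y in range(9):
            for x in range(11):
                expected[y, x] = max(data[z, y, x] for z in range(7))
        np.testing.assert_array_equal(out.data, expected)
        assert out.spacing == (1.0, 1.0)

    def test_rejects_2d(self):
        with pytest.raises(ValidationError):
            max_project(ImageStack(data=np.zeros((4, 4))))


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        img = ImageStack(data=np.full((32, 32), 37.0))
        out = rolling_ball_subtract(img, radius_um=5.0)
        assert np.allclose(out.data, 0.0)

    def test_small_dot_preserved(self):
        img = np.zeros((41, 41))
        img[20:22, 20:22] = 100.0
        out = rolling_ball_subtract(ImageStack(data=img), radius_um=10.0)
        assert out.data[20, 20] >= 95.0  # dot survives within 5 %
        assert (out.data >= 0).all()

    def test_broad_ramp_removed_dot_kept(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = xx.astype(float)  # broad gradient, amplitude 63
        img = ramp.copy()
        img[30:32, 30:32] += 100.0
        out = rolling_ball_subtract(ImageStack(data=img), radius_um=10.0)
        # evaluate away from the dot and a ball-radius border margin
        # (morphological background is undefined within one ball of the edge)
        interior = out.data[11:-11, 11:-11].copy()
        interior[17:23, 17:23] = 0.0
        assert interior.max() - interior.min() <= 0.1 * 63  # ≥90 % flattened
        assert abs((out.data[30, 30] - out.data[25, 25]) - 100.0) <= 10.0

    def test_subpixel_radius_rejected(self):
        img = ImageStack(data=np.zeros((8, 8)), spacing=2.0)
        with pytest.raises(ValidationError, match="larger"):
            rolling_ball_subtract(img, radius_um=1.0)


class TestEnhanceContrast:
    def test_ramp_exact_clip_counts(self):
        img = ImageStack(data=np.arange(1000.0).reshape(25, 40))
        out = enhance_contrast(img, saturated=0.35)
        # exactly the lowest 175 and highest 175 ranked pixels are clipped
        assert (out.data == out.data.min()).sum() == 175
        assert (out.data == out.data.max()).sum() == 175

    def test_zero_saturation_full_range(self):
        img = ImageStack(data=np.linspace(0, 255, 256).reshape(16, 16))
        out = enhance_contrast(img, saturated=0.0)
        assert out.data.min() == 0.0 and out.data.max() == 255.0
        assert (np.diff(np.sort(out.data, axis=None)) >= 0).all()

    def test_constant_image_unchanged(self):
        img = ImageStack(data=np.full((8, 8), 5.0))
        out = enhance_contrast(img, saturated=0.1)
        assert np.allclose(out.data, 5.0)

    def test_saturated_one_rejected(self):
        with pytest.raises(ValidationError):
            enhance_contrast(ImageStack(data=np.zeros((4, 4))), saturated=1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.floats(0, 0.5))
    def test_mapping_is_monotone(self, seed, saturated):
        data = np.random.default_rng(seed).uniform(0, 100, size=(16, 16))
        out = enhance_contrast(ImageStack(data=data), saturated=saturated)
        order = np.argsort(data, axis=None)
        assert (np.diff(out.data.ravel()[order]) >= -1e-9).all()


class TestBinarize:
    def test_fixed_threshold_strict(self):
        img = ImageStack(data=np.array([[10.0, 200.0], [100.0, 100.0]]))
        mask = binarize(img, method="fixed", threshold=100)
        np.testing.assert_array_equal(
            mask.data, [[False, True], [False, False]]
        )

    def test_otsu_matches_exhaustive_search(self, rng):
        # bimodal image; oracle = threshold maximizing between-class variance
        data = np.concatenate(
            [rng.normal(20, 3, 200), rng.normal(180, 8, 200)]
        ).clip(0).reshape(20, 20)
        mask = binarize(ImageStack(data=data), method="otsu")
        vals = np.unique(data)
        best_t, best_var = None, -1.0
        for t in vals[:-1]:
            fg, bg = data[data > t], data[data <= t]
            var = len(fg) * len(bg) * (fg.mean() - bg.mean()) ** 2
            if var > best_var:
                best_t, best_var = t, var
        np.testing.assert_array_equal(mask.data, data > best_t)

    def test_otsu_constant_degenerate(self):
        with pytest.raises(DegenerateInputError):
            binarize(ImageStack(data=np.ones((4, 4))), method="otsu")

    def test_foreground_monotone_in_threshold(self, rng):
        data = rng.uniform(0, 255, size=(32, 32))
        img = ImageStack(data=data)
        counts = [
            binarize(img, "fixed", threshold=t).data.sum()
            for t in np.linspace(0, 255, 20)
        ]
        assert (np.diff(counts) <= 0).all()


class TestLabelObjects:
    @staticmethod
    def _two_squares():
        m = np.zeros((20, 20), dtype=bool)
        m[2:7, 2:7] = True
        m[12:17, 12:17] = True
        return m

    def test_two_squares(self):
        objs = label_objects(BinaryMask(data=self._two_squares(), spacing=2.0))
        assert objs.n_objects == 2
        assert np.allclose(objs.table["area_um2"], 25 * 4.0)

    def test_min_area_filter(self):
        objs = label_objects(
            BinaryMask(data=self._two_squares(), spacing=1.0),
            min_area_um2=26.0,
        )
        assert objs.n_objects == 0
        m = self._two_squares()
        m[12:17, 12:18] = True  # enlarge one square to 30 px
        objs = label_objects(BinaryMask(data=m, spacing=1.0), min_area_um2=26.0)
        assert objs.n_objects == 1
        assert list(objs.table["label"]) == [1]  # relabeled consecutively

    def test_component_count_matches_flood_fill(self, rng):
        mask = rng.random((24, 24)) < 0.3

        def flood_count(m):
            seen = np.zeros_like(m, bool)
            count = 0
            for sy in range(m.shape[0]):
                for sx in range(m.shape[1]):
                    if m[sy, sx] and not seen[sy, sx]:
                        count += 1
                        stack = [(sy, sx)]
                        seen[sy, sx] = True
                        while stack:
                            y, x = stack.pop()
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    ny, nx = y + dy, x + dx
                                    if (0 <= ny < m.shape[0]
                                            and 0 <= nx < m.shape[1]
                                            and m[ny, nx]
                                            and not seen[ny, nx]):
                                        seen[ny, nx] = True
                                        stack.append((ny, nx))
            return count

        objs = label_objects(
            BinaryMask(data=mask, spacing=1.0), connectivity="full"
        )
        assert objs.n_objects == flood_count(mask)

    def test_area_sum_bounded_by_foreground(self, rng):
        mask = rng.random((30, 30)) < 0.4
        objs = label_objects(BinaryMask(data=mask, spacing=1.0))
        assert objs.table["area_um2"].sum() <= mask.sum() + 1e-9
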