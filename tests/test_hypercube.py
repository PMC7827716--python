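"""Cube container, unfolding, multiset augmentation, ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamcr import (
    ROI,
    HyperCube,
    augment_rowwise,
    extract_roi_mean_spectrum,
    make_grid,
    read_cube,
    refold,
    unfold,
    write_cube,
)


def random_cube(rng, h, w, grid, dataset_id="cube"):
    return HyperCube(rng.random((h, w, len(grid))), grid, dataset_id=dataset_id)


class TestGrid:
    @pytest.mark.parametrize(
        "args,n",
        [((680, 970, 2), 146), ((680, 682, 2), 2), ((680, 970, 10), 30)],
    )
    def test_count(self, args, n):
        grid = make_grid(*args)
        assert len(grid) == n
        vals = grid.values
        assert vals[0] == args[0] and vals[-1] == args[1]
        assert np.allclose(np.diff(vals), args[2])

    def test_non_divisible_range_rejected(self):
        with pytest.raises(ValueError, match="680.*971.*2"):
            make_grid(680, 971, 2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            make_grid(700, 680, 2)
        with pytest.raises(ValueError):
            make_grid(680, 970, -2)

    def test_index_of(self):
        grid = make_grid(680, 970, 2)
        assert grid.index_of(680) == 0
        assert grid.index_of(862) == 91
        with pytest.raises(ValueError):
            grid.index_of(681)


class TestCube:
    def test_negative_values_rejected_unless_clipped(self, small_grid):
        vals = np.ones((2, 2, len(small_grid)))
        vals[0, 0, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            HyperCube(vals.copy(), small_grid)
        cube = HyperCube(vals.copy(), small_grid, clip_negative=True)
        assert cube.values[0, 0, 0] == 0.0

    def test_plane_count_must_match_grid(self, small_grid):
        with pytest.raises(ValueError, match="planes"):
            HyperCube(np.ones((2, 2, 3)), small_grid)


class TestUnfoldRefold:
    def test_single_pixel_identity(self, small_grid, rng):
        cube = random_cube(rng, 1, 1, small_grid)
        mat = unfold(cube)
        assert mat.values.shape == (1, len(small_grid))
        assert np.array_equal(mat.values[0], cube.values[0, 0])

    def test_row_major_pixel_order(self, small_grid, rng):
        cube = random_cube(rng, 3, 4, small_grid)
        mat = unfold(cube)
        # row r*width + c carries the spectrum of pixel (r, c)
        assert np.array_equal(mat.values[1 * 4 + 2], cube.values[1, 2])
        assert mat.index.lookup(6) == ("cube", 1, 2)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(
        h=st.integers(1, 8),
        w=st.integers(1, 6),
        nlam=st.integers(2, 6),
        seed=st.integers(0, 100),
    )
    def test_round_trip(self, h, w, nlam, seed):
        grid = make_grid(680, 680 + 2 * (nlam - 1), 2)
        rng = np.random.default_rng(seed)
        cube = random_cube(rng, h, w, grid)
        mat = unfold(cube)
        for j in range(nlam):
            img = refold(mat.values[:, j], mat.index)["cube"]
            assert np.array_equal(img, cube.values[:, :, j])

    def test_refold_constant_vector(self, small_grid, rng):
        cube = random_cube(rng, 4, 3, small_grid)
        img = refold(np.ones(12), unfold(cube).index)["cube"]
        assert img.shape == (4, 3)
        assert np.all(img == 1.0)

    def test_refold_rejects_length_mismatch(self, small_grid, rng):
        idx = unfold(random_cube(rng, 4, 3, small_grid)).index
        with pytest.raises(ValueError, match="does not match"):
            refold(np.ones(11), idx)

    def test_two_cube_split(self, small_grid, rng):
        a = random_cube(rng, 3, 2, small_grid, "a")
        b = random_cube(rng, 2, 5, small_grid, "b")
        merged = augment_rowwise([unfold(a), unfold(b)])
        vec = merged.values[:, 0]
        out = refold(vec, merged.index)
        assert np.array_equal(out["a"], a.values[:, :, 0])
        assert np.array_equal(out["b"], b.values[:, :, 0])


class TestAugment:
    def test_rows_stack_in_order_and_index_tracks(self, small_grid, rng):
        a = random_cube(rng, 3, 2, small_grid, "a")
        b = random_cube(rng, 2, 5, small_grid, "b")
        merged = augment_rowwise([unfold(a), unfold(b)])
        assert merged.rows == 16
        # every output row equals its source row via index lookup
        for r in range(merged.rows):
            ds, i, j = merged.index.lookup(r)
            src = a if ds == "a" else b
            assert np.array_equal(merged.values[r], src.values[i, j])

    def test_single_member_identity(self, small_grid, rng):
        mat = unfold(random_cube(rng, 3, 2, small_grid))
        assert augment_rowwise([mat]) is mat

    def test_grid_mismatch_names_dataset(self, rng):
        g1, g2 = make_grid(680, 700, 2), make_grid(680, 698, 2)
        a = unfold(random_cube(rng, 2, 2, g1, "a"))
        b = unfold(random_cube(rng, 2, 2, g2, "bad_one"))
        with pytest.raises(ValueError, match="bad_one"):
            augment_rowwise([a, b])


class TestCubeIO:
    def test_round_trip(self, small_grid, rng, tmp_path):
        cube = random_cube(rng, 8, 8, small_grid, "rt")
        path = tmp_path / "cube.tif"
        # float32 storage: write values representable exactly
        cube = HyperCube(
            cube.values.astype(np.float32).astype(float), small_grid, "rt"
        )
        write_cube(cube, path)
        back = read_cube(path)
        assert back.dataset_id == "rt"
        assert back.grid == small_grid
        assert np.array_equal(back.values, cube.values)

    def test_plane_grid_mismatch_rejected(self, small_grid, rng, tmp_path):
        cube = random_cube(rng, 4, 4, small_grid)
        path = tmp_path / "cube.tif"
        write_cube(cube, path)
        sidecar = tmp_path / "cube.tif.json"
        sidecar.write_text(
            sidecar.read_text().replace('"stop_nm": 700', '"stop_nm": 702')
        )
        with pytest.raises(ValueError, match="planes"):
            read_cube(path)

    def test_missing_sidecar_rejected(self, small_grid, rng, tmp_path):
        cube = random_cube(rng, 2, 2, small_grid)
        path = tmp_path / "c.tif"
        write_cube(cube, path)
        (tmp_path / "c.tif.json").unlink()
        with pytest.raises(ValueError, match="metadata"):
            read_cube(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_cube(tmp_path / "nope.tif")


class TestRoiSpectrum:
    def test_constant_cube(self, small_grid):
        cube = HyperCube(np.full((6, 6, len(small_grid)), 7.0), small_grid)
        spec = extract_roi_mean_spectrum(cube, ROI("cube", 1, 1, 3, 3))
        assert np.allclose(spec, 7.0)

    def test_hand_mean(self, rng):
        grid = make_grid(680, 682, 2)
        vals = np.zeros((2, 1, 2))
        vals[0, 0] = [1, 2]
        vals[1, 0] = [3, 4]
        cube = HyperCube(vals, grid)
        spec = extract_roi_mean_spectrum(cube, ROI("cube", 0, 0, 2, 1))
        assert np.allclose(spec, [2, 3])

    def test_full_cube_equals_global_mean(self, small_grid, rng):
        cube = random_cube(rng, 5, 7, small_grid)
        spec = extract_roi_mean_spectrum(cube, ROI("cube", 0, 0, 5, 7))
        assert np.allclose(spec, cube.values.mean(axis=(0, 1)))

    def test_permutation_invariance_within_roi(self, small_grid, rng):
        cube = random_cube(rng, 4, 4, small_grid)
        roi = ROI("cube", 0, 0, 4, 4)
        base = extract_roi_mean_spectrum(cube, roi)
        perm = rng.permutation(16)
        shuffled = HyperCube(
            cube.values.reshape(16, -1)[perm].reshape(4, 4, -1), small_grid
        )
        assert np.allclose(extract_roi_mean_spectrum(shuffled, roi), base)

    def test_out_of_bounds_rejected(self, small_grid, rng):
        cube = random_cube(rng, 4, 4, small_grid)
        with pytest.raises(ValueError, match="does not fit"):
            extract_roi_mean_spectrum(cube, ROI("cube", 2, 2, 4, 4))
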