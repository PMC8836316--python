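import numpy as np
import pytest

from conplan import (
    FeatureStack,
    Grid,
    GridError,
    aggregate_fractional,
    exclude_classes,
    read_grid,
    read_stack,
    resample_to_grid,
    write_grid,
    write_stack,
)
from conplan.grids import read_ascii, write_ascii


def _grid(values, valid=None, cell_size=1.0):
    values = np.asarray(values)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return Grid(values, valid, cell_size)


class TestIO:
    def test_ascii_roundtrip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(3)
        g = Grid(rng.uniform(size=(7, 5)), rng.uniform(size=(7, 5)) > 0.2,
                 cell_size=2.5, origin=(10.0, 40.0))
        path = tmp_path / "g.asc"
        write_ascii(g, path)
        back = read_ascii(path)
        assert np.array_equal(back.valid, g.valid)
        assert np.array_equal(back.values[g.valid], g.values[g.valid])
        assert back.cell_size == g.cell_size
        assert back.origin == g.origin

    def test_integer_grid_roundtrip(self, tmp_path):
        g = _grid(np.arange(9).reshape(3, 3))
        write_grid(g, tmp_path / "g.asc")
        back = read_grid(tmp_path / "g.asc")
        assert np.array_equal(back.values, g.values.astype(float))

    def test_ascii_nodata_masked(self, tmp_path):
        path = tmp_path / "n.asc"
        path.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 -9999 3\n-9999 5 6\n"
        )
        g = read_ascii(path)
        assert g.valid.tolist() == [[True, False, True], [False, True, True]]

    def test_geotiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        g = Grid(rng.uniform(size=(4, 6)), rng.uniform(size=(4, 6)) > 0.3,
                 cell_size=1000.0, origin=(350000.0, 520000.0))
        path = tmp_path / "g.tif"
        write_grid(g, path, "geotiff")
        back = read_grid(path, "geotiff")
        assert np.allclose(back.values[g.valid], g.values[g.valid])
        assert np.array_equal(back.valid, g.valid)
        assert back.cell_size == g.cell_size
        assert back.origin == g.origin

    def test_stack_rejects_mismatched_cell_size(self):
        a = _grid(np.ones((3, 3)), cell_size=1.0)
        b = _grid(np.ones((3, 3)), cell_size=2.0)
        with pytest.raises(GridError, match="cell size"):
            FeatureStack.from_grids([a, b])

    def test_stack_manifest_roundtrip(self, tmp_path, small_species_stack):
        manifest = write_stack(small_species_stack, tmp_path / "stk")
        back = read_stack(manifest)
        assert back.names == small_species_stack.names
        assert back.groups == small_species_stack.groups
        assert np.allclose(back.data, small_species_stack.data)
        assert np.allclose(back.weights, small_species_stack.weights)


class TestAggregateFractional:
    def test_block_fraction_definition(self):
        # one 10x10 block with 37 cells of class 1, rest class 0
        fine = np.zeros((10, 10), dtype=np.int64)
        fine.ravel()[:37] = 1
        stack = aggregate_fractional(_grid(fine), 10)
        assert stack.shape == (1, 1)
        i1 = stack.index("class_1")
        assert stack.data[i1, 0, 0] == pytest.approx(0.37)
        assert stack.data[stack.index("class_0"), 0, 0] == pytest.approx(0.63)

    def test_single_class_gives_all_ones(self):
        stack = aggregate_fractional(_grid(np.zeros((8, 8), dtype=np.int64)), 4)
        assert stack.n_features == 1
        assert np.all(stack.data == 1.0)

    def test_fractions_sum_to_one_on_fully_valid_blocks(self):
        rng = np.random.default_rng(11)
        fine = rng.integers(0, 5, size=(40, 40))
        stack = aggregate_fractional(_grid(fine), 10)
        assert np.allclose(stack.data.sum(axis=0), 1.0)

    def test_class_area_conserved_by_direct_count(self):
        rng = np.random.default_rng(12)
        fine_vals = rng.integers(0, 6, size=(40, 40))
        valid = rng.uniform(size=(40, 40)) > 0.1
        fine = Grid(fine_vals, valid, cell_size=0.1)
        stack = aggregate_fractional(fine, 10)
        block_valid = valid.reshape(4, 10, 4, 10).sum(axis=(1, 3))
        for c in range(6):
            direct = ((fine_vals == c) & valid).sum() * 0.1**2
            agg = (stack.grid(f"class_{c}").values * block_valid).sum() * 0.1**2
            assert agg == pytest.approx(direct, abs=1e-12)

    def test_partially_valid_blocks_use_valid_denominator(self):
        vals = np.zeros((2, 2), dtype=np.int64)
        vals[0, 0] = 1
        valid = np.array([[True, True], [True, False]])
        stack = aggregate_fractional(Grid(vals, valid), 2)
        assert stack.data[stack.index("class_1"), 0, 0] == pytest.approx(1 / 3)

    def test_requires_categorical(self):
        with pytest.raises(GridError, match="categorical"):
            aggregate_fractional(_grid(np.ones((4, 4))), 2)


class TestResample:
    def test_constant_layer_preserved(self):
        g = _grid(np.full((5, 5), 0.4), cell_size=2.0)
        for method in ("bilinear", "nearest"):
            out = resample_to_grid(g, 1.0, method)
            assert out.shape == (10, 10)
            assert np.allclose(out.values, 0.4)
            assert out.cell_size == 1.0

    def test_nearest_replicates_blocks(self):
        g = _grid(np.arange(6, dtype=float).reshape(2, 3), cell_size=2.0)
        out = resample_to_grid(g, 1.0, "nearest")
        for i in range(2):
            for j in range(3):
                assert np.all(out.values[2 * i: 2 * i + 2, 2 * j: 2 * j + 2]
                              == g.values[i, j])

    def test_bilinear_matches_handrolled_oracle(self):
        rng = np.random.default_rng(21)
        src = rng.uniform(size=(10, 10))
        g = _grid(src, cell_size=2.0)
        out = resample_to_grid(g, 1.0, "bilinear")

        def oracle(r, c):
            # fine cell centre in coarse index coordinates, edge-clamped
            y = min(max((r + 0.5) / 2 - 0.5, 0.0), 9.0)
            x = min(max((c + 0.5) / 2 - 0.5, 0.0), 9.0)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, 9), min(x0 + 1, 9)
            fy, fx = y - y0, x - x0
            return ((1 - fy) * (1 - fx) * src[y0, x0]
                    + (1 - fy) * fx * src[y0, x1]
                    + fy * (1 - fx) * src[y1, x0]
                    + fy * fx * src[y1, x1])

        expected = np.array([[oracle(r, c) for c in range(20)] for r in range(20)])
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_non_integer_factor_rejected(self):
        g = _grid(np.ones((3, 3)), cell_size=3.0)
        with pytest.raises(GridError, match="integer"):
            resample_to_grid(g, 2.0)


class TestExcludeClasses:
    @pytest.fixture
    def stack42(self):
        # 42 level-2 habitat classes, six of them built-up "J" classes
        names = [f"H{i:02d}" for i in range(36)] + [f"J{i}" for i in range(1, 7)]
        vals = np.ones((42, 3, 3)) / 42
        return FeatureStack(vals, names, ["habitat"] * 42, np.ones(42),
                            np.ones((3, 3), bool))

    def test_dropping_six_builtup_leaves_36_layers(self, stack42):
        out = exclude_classes(stack42, [f"J{i}" for i in range(1, 7)], drop=True)
        assert out.n_features == 36
        assert all(not n.startswith("J") for n in out.names)

    def test_relabel_keeps_layers_as_builtup_group(self, stack42):
        out = exclude_classes(stack42, ["J1", "J2"])
        assert out.n_features == 42
        assert out.groups[out.index("J1")] == "builtup"
        assert out.groups[out.index("H00")] == "habitat"

    def test_empty_exclusion_is_identity(self, stack42):
        assert exclude_classes(stack42, []) is stack42

    def test_unknown_label_rejected(self, stack42):
        with pytest.raises(KeyError):
            exclude_classes(stack42, ["Z9"])

    def test_dropping_everything_rejected(self, stack42):
        with pytest.raises(GridError):
            exclude_classes(stack42, list(stack42.names), drop=True)
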