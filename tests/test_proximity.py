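"""Distance-transform proximity mapping and PVN binning."""

import numpy as np
import pandas as pd
import pytest

from nichequant.images import (
    BinaryMask,
    DegenerateInputError,
    LabeledObjects,
    ValidationError,
)
from nichequant.proximity import (
    BIN_LABELS,
    assign_bin,
    bin_distances,
    cell_distances,
    distance_map,
    split_by_marker,
)
from nichequant.synth import make_proximity_scene


def _mask(data, spacing=1.0):
    return BinaryMask(data=np.asarray(data, bool), spacing=spacing)


class TestDistanceMap:
    def test_three_four_five(self):
        m = np.zeros((8, 8), bool)
        m[0, 0] = True
        d = distance_map(_mask(m))
        assert d.data[3, 4] == pytest.approx(5.0)
        assert d.data[0, 0] == 0.0

    def test_vertical_line_horizontal_offset(self):
        m = np.zeros((10, 12), bool)
        m[:, 2] = True
        d = distance_map(_mask(m, spacing=2.0))
        for x in range(12):
            assert d.data[4, x] == pytest.approx(abs(x - 2) * 2.0)

    def test_matches_bruteforce_on_random_scenes(self, rng):
        for _ in range(5):
            m = rng.random((24, 24)) < 0.05
            if not m.any():
                m[4, 7] = True
            d = distance_map(_mask(m))
            ys, xs = np.nonzero(m)
            for y in range(24):
                for x in range(24):
                    brute = np.sqrt((ys - y) ** 2 + (xs - x) ** 2).min()
                    assert d.data[y, x] == pytest.approx(brute)

    def test_empty_vessels_degenerate(self):
        with pytest.raises(DegenerateInputError):
            distance_map(_mask(np.zeros((8, 8))))


def _labeled(labels, spacing=1.0):
    return LabeledObjects(
        labels=np.asarray(labels, np.int32), spacing=(spacing, spacing)
    )


class TestCellDistances:
    def test_single_pixel_cell_at_25um(self):
        vessels = np.zeros((60, 60), bool)
        vessels[:, 0] = True
        cells = np.zeros((60, 60), np.int32)
        cells[30, 25] = 1
        rec = cell_distances(_labeled(cells), distance_map(_mask(vessels)))
        assert rec.loc[0, "distance_um"] == pytest.approx(25.0)
        assert rec.loc[0, "bin"] == "[20,30)"

    def test_cell_on_vessel_distance_zero(self):
        vessels = np.zeros((20, 20), bool)
        vessels[8:12, 8:12] = True
        cells = np.zeros((20, 20), np.int32)
        cells[9:11, 9:11] = 1
        rec = cell_distances(_labeled(cells), distance_map(_mask(vessels)))
        assert rec.loc[0, "distance_um"] == 0.0
        assert rec.loc[0, "bin"] == "[0,10)"

    def test_mean_aggregation_hand_arithmetic(self):
        # 3-px cell at per-pixel distances {9, 10, 11} → mean 10 → [10,20)
        vessels = np.zeros((5, 20), bool)
        vessels[:, 0] = True
        cells = np.zeros((5, 20), np.int32)
        cells[2, 9:12] = 1
        rec = cell_distances(_labeled(cells), distance_map(_mask(vessels)))
        assert rec.loc[0, "distance_um"] == pytest.approx(10.0)
        assert rec.loc[0, "bin"] == "[10,20)"

    def test_min_and_centroid_aggregations(self):
        vessels = np.zeros((5, 20), bool)
        vessels[:, 0] = True
        cells = np.zeros((5, 20), np.int32)
        cells[2, 9:12] = 1
        dmap = distance_map(_mask(vessels))
        assert cell_distances(_labeled(cells), dmap, "min").loc[0, "distance_um"] == 9.0
        assert cell_distances(_labeled(cells), dmap, "centroid").loc[0, "distance_um"] == 10.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cell_distances(
                _labeled(np.ones((4, 4))),
                distance_map(_mask(np.ones((5, 5)))),
            )

    def test_border_cells_flagged(self):
        vessels = np.zeros((10, 10), bool)
        vessels[:, 0] = True
        cells = np.zeros((10, 10), np.int32)
        cells[0, 5] = 1  # touches border
        cells[5, 5] = 2  # interior
        rec = cell_distances(_labeled(cells), distance_map(_mask(vessels)))
        assert rec.set_index("label")["on_border"].to_dict() == {1: True, 2: False}


class TestBinning:
    def test_bin_edges_left_closed(self):
        assert assign_bin(0.0) == "[0,10)"
        assert assign_bin(10.0) == "[10,20)"
        assert assign_bin(49.999) == "[40,50)"
        assert assign_bin(50.0) == "[50,inf)"  # exactly 50 is outside PVN

    def test_hand_counted_fractions(self):
        rec = pd.DataFrame({"distance_um": [5.0, 15.0, 55.0]})
        h = bin_distances(rec)
        np.testing.assert_allclose(h.fractions, [1/3, 1/3, 0, 0, 0, 1/3])
        assert h.pvn_fraction == pytest.approx(2/3)

    def test_all_on_vessel(self):
        h = bin_distances(pd.DataFrame({"distance_um": [0.0] * 4}))
        np.testing.assert_allclose(h.fractions, [1, 0, 0, 0, 0, 0])
        assert h.pvn_fraction == 1.0

    def test_fractions_sum_to_one(self, rng):
        rec = pd.DataFrame({"distance_um": rng.uniform(0, 80, 333)})
        h = bin_distances(rec)
        assert h.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert h.pvn_fraction + h.fractions[-1] == pytest.approx(1.0, abs=1e-9)

    def test_empty_degenerate(self):
        with pytest.raises(DegenerateInputError):
            bin_distances(pd.DataFrame({"distance_um": []}))


class TestMarkerSplit:
    @staticmethod
    def _records(n=10, n_pos=4):
        return pd.DataFrame({
            "distance_um": np.linspace(0, 60, n),
            "ki67": [True] * n_pos + [False] * (n - n_pos),
        })

    def test_partition_counts(self):
        neg, pos = split_by_marker(self._records(), "ki67")
        assert pos.n_cells == 4 and neg.n_cells == 6
        assert pos.n_cells + neg.n_cells == 10

    def test_all_positive_empty_negative_flagged(self):
        rec = self._records(n=5, n_pos=5)
        neg, pos = split_by_marker(rec, "ki67")
        assert neg.empty and neg.n_cells == 0
        assert pos.n_cells == 5

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValidationError):
            split_by_marker(self._records(), "sox2")

    def test_planted_marker_distance_separation(self):
        specs = [{"distance_um": d, "edu": d < 20} for d in (5, 10, 15, 55, 60, 65)]
        vessel, cells, markers, _ = make_proximity_scene(specs, seed=3)
        rec = cell_distances(cells, distance_map(vessel), markers=markers)
        neg, pos = split_by_marker(rec, "edu")
        assert pos.pvn_fraction == 1.0
        assert neg.pvn_fraction == 0.0


class TestInvariances:
    def test_translation_invariance(self):
        vessels = np.zeros((40, 40), bool)
        vessels[10:30, 10] = True
        cells = np.zeros((40, 40), np.int32)
        cells[18:21, 20:23] = 1
        rec1 = cell_distances(_labeled(cells), distance_map(_mask(vessels)))
        rec2 = cell_distances(
            _labeled(np.roll(cells, (3, 4), (0, 1))),
            distance_map(_mask(np.roll(vessels, (3, 4), (0, 1)))),
        )
        assert rec1.loc[0, "distance_um"] == pytest.approx(rec2.loc[0, "distance_um"])
        assert rec1.loc[0, "bin"] == rec2.loc[0, "bin"]

    def test_dilating_vessels_never_increases_distance(self, rng):
        from scipy import ndimage as ndi

        vessels = rng.random((40, 40)) < 0.03
        vessels[5, 5] = True
        cells = np.zeros((40, 40), np.int32)
        cells[30:33, 30:33] = 1
        cells[10:12, 20:22] = 2
        d1 = cell_distances(_labeled(cells), distance_map(_mask(vessels)))
        dil = ndi.binary_dilation(vessels, iterations=2)
        d2 = cell_distances(_labeled(cells), distance_map(_mask(dil)))
        assert (d2["distance_um"] <= d1["distance_um"] + 1e-9).all()


class TestPlantedScene:
    def test_all_six_bins_hit(self):
        specs = [{"distance_um": d} for d in (5, 15, 25, 35, 45, 55)]
        vessel, cells, markers, truth = make_proximity_scene(specs, seed=0)
        rec = cell_distances(cells, distance_map(vessel))
        assert sorted(rec["bin"]) == sorted(BIN_LABELS)
        got = rec.sort_values("label")["distance_um"].to_numpy()
        planted = truth["cells"].sort_values("planted_label")["distance_um"].to_numpy()
        np.testing.assert_allclose(got, planted, atol=0.5)
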