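"""Zone areas, overlap arithmetic and backward delineation."""

import numpy as np
import pytest

from gfzones import (backward_delineate, overlap_report, read_zone_map,
                     write_zone_map, zone_areas)
from gfzones.compare import CompareError
from gfzones.grids import ZoneMap
from gfzones.zonation import delineate

from test_zonation import blobs


def zmap(labels, cell=800.0, **kw):
    return ZoneMap(np.asarray(labels, dtype=np.int64), cell, **kw)


class TestZoneAreas:
    def test_cell_counting(self):
        z = zmap(np.ones((10, 10)))          # 100 cells of 0.64 km^2
        areas = zone_areas(z)
        assert areas[1] == pytest.approx(64.0)

    def test_partition_sums_to_range_area(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:, :6] = 1                    # 60 cells
        labels[:, 6:] = 2                    # 40 cells
        areas = zone_areas(zmap(labels))
        assert areas[1] == pytest.approx(38.4)
        assert areas[2] == pytest.approx(25.6)
        assert areas.sum() == pytest.approx(64.0)

    def test_absent_zone_has_no_row(self):
        areas = zone_areas(zmap(np.ones((4, 4))))
        assert 7 not in areas.index


class TestOverlapReport:
    def test_identical_maps_full_overlap(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 4, size=(12, 12))
        z = zmap(labels)
        rep = overlap_report(z, z, [([i], [i]) for i in z.zone_ids])
        assert (rep.pairs["rate_pct"] == 100.0).all()
        assert rep.average_rate == pytest.approx(100.0)

    def test_disjoint_zones_zero_overlap(self):
        a = np.zeros((6, 6), dtype=int)
        b = np.zeros((6, 6), dtype=int)
        a[:3] = 1
        b[3:] = 1
        rep = overlap_report(zmap(a), zmap(b), [([1], [1])])
        assert rep.pairs.loc[0, "rate_pct"] == 0.0

    def test_hand_counted_rate(self):
        """GF zone covering 30 of a 40-cell reference zone -> 75.0%."""
        ref = np.zeros((10, 10), dtype=int)
        ref[:4, :] = 1                        # 40-cell reference zone
        ref[4:, :] = 2
        gf = np.zeros((10, 10), dtype=int)
        gf[:3, :] = 1                         # overlaps 30 of those cells
        gf[3:, :] = 2
        rep = overlap_report(zmap(gf), zmap(ref), [([1], [1])])
        assert rep.pairs.loc[0, "rate_pct"] == pytest.approx(75.0)
        assert rep.pairs.loc[0, "overlap_km2"] == pytest.approx(30 * 0.64)

    def test_many_to_one_correspondence(self):
        ref = np.zeros((8, 8), dtype=int)
        ref[:, :4] = 1
        ref[:, 4:] = 2
        gf = np.zeros((8, 8), dtype=int)
        gf[:4, :4] = 1
        gf[4:, :4] = 2
        gf[:, 4:] = 3
        rep = overlap_report(zmap(gf), zmap(ref), [([1, 2], [1])])
        assert rep.pairs.loc[0, "rate_pct"] == pytest.approx(100.0)

    def test_area_symmetry(self):
        rng = np.random.default_rng(1)
        a = zmap(rng.integers(1, 4, size=(9, 9)))
        b = zmap(rng.integers(1, 3, size=(9, 9)))
        fwd = overlap_report(a, b, [([1], [2])])
        bwd = overlap_report(b, a, [([2], [1])])
        assert fwd.pairs.loc[0, "overlap_km2"] == \
            bwd.pairs.loc[0, "overlap_km2"]

    def test_full_partition_overlap_sums_to_shared_area(self):
        rng = np.random.default_rng(2)
        a = zmap(rng.integers(1, 4, size=(10, 10)))
        b = zmap(rng.integers(1, 3, size=(10, 10)))
        pairs = [([i], [j]) for i in a.zone_ids for j in b.zone_ids]
        rep = overlap_report(a, b, pairs)
        assert rep.pairs["overlap_km2"].sum() == pytest.approx(
            100 * 0.64)

    def test_refinement_invariance(self):
        rng = np.random.default_rng(3)
        coarse_a = rng.integers(1, 4, size=(6, 6))
        coarse_b = rng.integers(1, 3, size=(6, 6))
        fine_a = np.kron(coarse_a, np.ones((2, 2), dtype=int))
        fine_b = np.kron(coarse_b, np.ones((2, 2), dtype=int))
        rep_c = overlap_report(zmap(coarse_a), zmap(coarse_b), [([1], [1])])
        rep_f = overlap_report(zmap(fine_a, cell=400.0),
                               zmap(fine_b, cell=400.0), [([1], [1])])
        assert rep_c.pairs.loc[0, "rate_pct"] == pytest.approx(
            rep_f.pairs.loc[0, "rate_pct"])

    @pytest.mark.parametrize("denominator,expected", [
        ("reference", 50.0),   # overlap 8 of ref 16
        ("gf", 100.0),         # overlap 8 of gf 8
        ("union", 50.0),       # overlap 8 of union 16
    ])
    def test_denominator_conventions(self, denominator, expected):
        ref = np.zeros((4, 8), dtype=int)
        ref[:2, :] = 1              # 16 cells
        gf = np.zeros((4, 8), dtype=int)
        gf[:1, :] = 1               # 8 cells, all inside ref zone 1
        rep = overlap_report(zmap(gf), zmap(ref), [([1], [1])],
                             denominator=denominator)
        assert rep.pairs.loc[0, "rate_pct"] == pytest.approx(expected)

    def test_unknown_zone_rejected(self):
        z = zmap(np.ones((3, 3)))
        with pytest.raises(CompareError, match="unknown"):
            overlap_report(z, z, [([1], [9])])

    def test_geometry_mismatch_rejected(self):
        a = zmap(np.ones((3, 3)), cell=800.0)
        b = zmap(np.ones((3, 3)), cell=400.0)
        with pytest.raises(CompareError, match="co-registered"):
            overlap_report(a, b, [([1], [1])])

    def test_reference_cells_outside_gf_range_still_count(self):
        # the denominator is the reference zone's full area, so cells the
        # gf map does not cover dilute the rate instead of vanishing
        ref = np.zeros((4, 4), dtype=int)
        ref[0, :] = 1               # 4 cells
        gf = np.zeros((4, 4), dtype=int)
        gf[0, :2] = 1               # covers 2 of them; rest outside range
        rep = overlap_report(zmap(gf), zmap(ref), [([1], [1])])
        assert rep.pairs.loc[0, "rate_pct"] == pytest.approx(50.0)

    def test_report_reproducible_from_persisted_maps(self, tmp_path):
        rng = np.random.default_rng(4)
        a = zmap(rng.integers(1, 4, size=(8, 8)))
        b = zmap(rng.integers(1, 3, size=(8, 8)))
        pairs = [([1], [1]), ([2, 3], [2])]
        rep1 = overlap_report(a, b, pairs)
        a2 = read_zone_map(write_zone_map(a, tmp_path / "a.asc"))
        b2 = read_zone_map(write_zone_map(b, tmp_path / "b.asc"))
        rep2 = overlap_report(a2, b2, pairs)
        assert rep1.pairs.equals(rep2.pairs)
        assert rep1.average_rate == rep2.average_rate


class TestBackwardDelineation:
    def test_forced_k_reproduces_forward_map(self):
        pts, _ = blobs(3, per=60, sep=8, seed=5)
        mask = np.ones((12, 15), dtype=bool)
        fwd = delineate(pts, mask, 800.0, k=3, seed=6)
        bwd = backward_delineate(pts, mask, 800.0, k=3, seed=6)
        np.testing.assert_array_equal(fwd.labels, bwd.labels)

    def test_forced_k_label_count_and_refinement(self):
        pts, _ = blobs(6, per=50, sep=8, seed=7)
        mask = np.ones((15, 20), dtype=bool)
        z4 = backward_delineate(pts, mask, 800.0, k=4, seed=8)
        z6 = backward_delineate(pts, mask, 800.0, k=6, seed=8)
        assert len(z4.zone_ids) == 4 and len(z6.zone_ids) == 6
        # k=6 refines k=4: most cells of each k=6 zone sit inside one
        # k=4 zone
        agree = 0
        for z in z6.zone_ids:
            sel = z6.labels == z
            _, counts = np.unique(z4.labels[sel], return_counts=True)
            agree += counts.max()
        assert agree / mask.sum() >= 0.9
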