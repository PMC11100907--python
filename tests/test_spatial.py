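import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_cells, random_pattern
from dcistme.errors import ConfigError, QCWarning, ValidationError
from dcistme.spatial import (
    cross_nn_distances,
    distance_from_epithelium,
    g_curve,
    hex_bin,
    mh_pair,
    morisita_horn,
    myoep_continuity_raw,
    myoep_continuity_score,
    sps,
    sps_pair,
)
from oracles import brute_force_nn, morisita_horn_direct


class TestHexBin:
    def test_coincident_cells_share_one_hex(self):
        t = make_cells([[10.0, 10.0], [10.0, 10.0]], {"A": [1, 0], "B": [0, 1]})
        hc = hex_bin(t, "A", "B", side=100.0)
        assert len(hc.counts) == 1
        assert list(hc.counts.values()) == [[1, 1]]

    def test_totals_conserved_on_random_patterns(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 120))
            xy = random_pattern(rng, n, extent=900.0)
            a = rng.uniform(size=n) < 0.6
            b = ~a
            t = make_cells(xy, {"A": a, "B": b})
            hc = hex_bin(t, "A", "B", side=100.0)
            ca, cb = hc.arrays()
            assert ca.sum() == a.sum() and cb.sum() == b.sum()

    def test_distant_cells_fall_in_different_hexes(self):
        # the hexagon diameter is 2·side, so 1000 μm apart cannot share one
        t = make_cells([[0.0, 0.0], [1000.0, 0.0]], {"A": [1, 0], "B": [0, 1]})
        hc = hex_bin(t, "A", "B", side=100.0)
        assert len(hc.counts) == 2

    def test_side_must_be_positive(self):
        t = make_cells([[0, 0]], {"A": [1], "B": [1]})
        with pytest.raises(ConfigError):
            hex_bin(t, "A", "B", side=0.0)


class TestMorisitaHorn:
    def test_worked_examples(self):
        assert morisita_horn(([2, 0], [0, 2])) == 0.0
        assert morisita_horn(([1, 1], [1, 1])) == 1.0
        # 2·(3·1+1·3) / [(10/16 + 10/16)·16] = 12/20
        assert morisita_horn(([3, 1], [1, 3])) == pytest.approx(0.6)

    def test_symmetry_and_self_similarity(self, two_type_table):
        assert mh_pair(two_type_table, "A", "B") == pytest.approx(
            mh_pair(two_type_table, "B", "A")
        )
        assert mh_pair(two_type_table, "A", "A") == pytest.approx(1.0)

    def test_zero_count_type_is_missing_with_qc(self):
        with pytest.warns(QCWarning):
            assert np.isnan(morisita_horn(([0, 0], [1, 2])))

    def test_matches_independent_formula_on_random_counts(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 15))
            a = rng.integers(0, 8, size=k)
            b = rng.integers(0, 8, size=k)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert morisita_horn((a, b)) == pytest.approx(
                morisita_horn_direct(a, b), abs=1e-12
            )

    def test_range_zero_one_on_random_patterns(self, rng):
        for _ in range(20):
            xy = random_pattern(rng, 80, extent=600.0)
            a = rng.uniform(size=80) < 0.5
            t = make_cells(xy, {"A": a, "B": ~a})
            v = mh_pair(t, "A", "B")
            assert 0.0 <= v <= 1.0 + 1e-12


class TestCrossNN:
    def test_three_four_five_triangle(self):
        t = make_cells([[0, 0], [3, 4], [10, 0]],
                       {"A": [1, 0, 0], "B": [0, 1, 1]})
        assert cross_nn_distances(t, "A", "B").tolist() == [5.0]

    def test_self_never_own_neighbor(self):
        # identical ref and target sets: distance is to the nearest *other* cell
        t = make_cells([[0, 0], [1, 0], [5, 0]], {"A": [1, 1, 1]})
        d = cross_nn_distances(t, "A", "A")
        assert sorted(d.tolist()) == [1.0, 1.0, 4.0]

    def test_coincident_distinct_cell_is_legal_neighbor(self):
        t = make_cells([[2, 2], [2, 2]], {"A": [1, 1]})
        assert cross_nn_distances(t, "A", "A").tolist() == [0.0, 0.0]

    def test_matches_brute_force_on_random_patterns(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            xy = random_pattern(rng, n)
            a = rng.uniform(size=n) < 0.5
            b = rng.uniform(size=n) < 0.5
            if not a.any() or not b.any():
                continue
            t = make_cells(xy, {"A": a, "B": b})
            got = np.sort(cross_nn_distances(t, "A", "B"))
            ref_idx = np.flatnonzero(a)
            tgt_idx = np.flatnonzero(b)
            same = [np.flatnonzero(tgt_idx == i)[0] if i in tgt_idx else -1 for i in ref_idx]
            want = np.sort(brute_force_nn(xy[a], xy[b], same=same))
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_no_targets_is_missing_with_qc(self):
        t = make_cells([[0, 0]], {"A": [1], "B": [0]})
        with pytest.warns(QCWarning):
            assert len(cross_nn_distances(t, "A", "B")) == 0


class TestGCurveAndSps:
    def test_single_distance_step(self):
        g = g_curve(np.array([5.0]))
        assert g(4.999) == 0.0 and g(5.0) == 1.0 and g(100.0) == 1.0

    def test_counting_midpoint(self):
        g = g_curve(np.array([5.0, 30.0]))
        assert g(20.0) == 0.5

    def test_monotone_cdf_property(self, rng):
        d = rng.exponential(10.0, size=200)
        g = g_curve(d)
        r = np.linspace(0, 60, 300)
        v = g(r)
        assert (np.diff(v) >= 0).all() and v[-1] <= 1.0

    def test_sps_worked_directional_pair(self):
        # targets at 5 and 30 μm from the lone ref in one direction...
        assert sps(g_curve(np.array([5.0]))) == 15.0
        # ...and both refs mapping to the same target going back
        assert sps(g_curve(np.array([5.0, 30.0]))) == 7.5

    def test_sps_directionality_on_cells(self):
        t = make_cells([[0, 0], [0, 5], [0, 30]],
                       {"A": [1, 0, 0], "B": [0, 1, 1]})
        assert sps_pair(t, "A", "B") == 15.0
        assert sps_pair(t, "B", "A") == 7.5

    def test_sps_saturates_at_rmax_for_coincident_sets(self):
        # each ref has a distinct target cell at its own location → G ≡ 1
        t = make_cells([[1, 1], [4, 4], [1, 1], [4, 4]],
                       {"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]})
        assert sps_pair(t, "A", "B") == 20.0

    def test_rmax_must_be_positive(self):
        with pytest.raises(ConfigError):
            sps(g_curve(np.array([1.0])), r_max=0.0)

    def test_rigid_motion_invariance(self, rng):
        xy = random_pattern(rng, 120)
        a = rng.uniform(size=120) < 0.5
        t1 = make_cells(xy, {"A": a, "B": ~a})
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        t2 = make_cells(xy @ R.T + np.array([123.4, -56.7]), {"A": a, "B": ~a})
        assert sps_pair(t2, "A", "B") == pytest.approx(sps_pair(t1, "A", "B"), abs=1e-9)


class TestDistanceFromEpithelium:
    def myo_table(self, extra_xy, extra_phen):
        n = len(extra_xy)
        base = {"aSMA": [0] * n, "p63": [0] * n, "CD3": [0] * n}
        base.update(extra_phen)
        xy = list(extra_xy)
        return make_cells(xy, {k: np.array(v, bool) for k, v in base.items()})

    def test_single_pair(self):
        t = self.myo_table([[0, 0], [0, 7]],
                           {"CD3": [1, 0], "aSMA": [0, 1], "p63": [0, 1]})
        assert distance_from_epithelium(t, "CD3") == 7.0

    def test_mean_over_marker_cells(self):
        t = self.myo_table(
            [[0, 4], [0, -6], [0, 0]],
            {"CD3": [1, 1, 0], "aSMA": [0, 0, 1], "p63": [0, 0, 1]},
        )
        assert distance_from_epithelium(t, "CD3") == 5.0

    def test_asma_single_positive_rule(self):
        # numerator for aSMA excludes the aSMA+p63+ co-positives
        t = self.myo_table(
            [[0, 3], [0, 0]],
            {"aSMA": [1, 1], "p63": [0, 1]},
        )
        assert distance_from_epithelium(t, "aSMA") == 3.0

    def test_matches_brute_force(self, rng):
        n = 80
        xy = random_pattern(rng, n)
        cd3 = rng.uniform(size=n) < 0.4
        myo = ~cd3 & (rng.uniform(size=n) < 0.3)  # disjoint from CD3+
        t = make_cells(xy, {"CD3": cd3, "aSMA": myo, "p63": myo})
        want = brute_force_nn(xy[cd3], xy[myo]).mean()
        assert distance_from_epithelium(t, "CD3") == pytest.approx(want, abs=1e-12)

    def test_empty_set_missing_with_qc(self):
        t = self.myo_table([[0, 0]], {"CD3": [1]})
        with pytest.warns(QCWarning):
            assert np.isnan(distance_from_epithelium(t, "CD3"))


def myoep_cells(points_by_region, sample="S0"):
    rows = []
    for rid, pts in points_by_region.items():
        for x, y in pts:
            rows.append({"sample": sample, "x": float(x), "y": float(y),
                         "aSMA": True, "p63": True,
                         "region_class": "DCIS", "region_id": rid})
    from dcistme.io_model import CellTable

    return CellTable(pd.DataFrame(rows), validate=False)


def region_table(rids, sample="S0"):
    return pd.DataFrame(
        {"sample": sample, "region_id": list(rids),
         "region_class": "DCIS", "area": 1e4}
    )


class TestContinuity:
    def test_collinear_triplet(self):
        t = myoep_cells({"r1": [(0, 0), (10, 0), (20, 0)]})
        raw = myoep_continuity_raw(t, region_table(["r1"]))
        assert raw["S0"] == 10.0

    def test_cell_weighted_average_over_regions(self):
        # region means 10 and 20 with equal cell counts → sample mean 15
        t = myoep_cells({
            "r1": [(0, 0), (10, 0), (20, 0)],
            "r2": [(0, 100), (20, 100), (40, 100)],
        })
        raw = myoep_continuity_raw(t, region_table(["r1", "r2"]))
        assert raw["S0"] == 15.0

    def test_singleton_region_excluded(self):
        t = myoep_cells({"r1": [(0, 0), (10, 0), (20, 0)], "r2": [(500, 500)]})
        raw = myoep_continuity_raw(t, region_table(["r1", "r2"]))
        assert raw["S0"] == 10.0

    def test_distances_never_cross_regions(self):
        # two regions 1 μm apart spatially: still scored independently
        t = myoep_cells({"r1": [(0, 0), (10, 0)], "r2": [(0, 1), (10, 1)]})
        raw = myoep_continuity_raw(t, region_table(["r1", "r2"]))
        assert raw["S0"] == 10.0

    def test_no_scorable_region_missing_with_qc(self):
        t = myoep_cells({"r1": [(0, 0)]})
        with pytest.warns(QCWarning):
            raw = myoep_continuity_raw(t, region_table(["r1"]))
        assert np.isnan(raw["S0"])

    def test_reverse_scoring_worked_example(self):
        assert myoep_continuity_score({"A": 10.0, "B": 30.0}) == {"A": 21.0, "B": 1.0}

    def test_single_sample_scores_one(self):
        assert myoep_continuity_score({"A": 7.0}) == {"A": 1.0}

    def test_score_order_reverses_raw_order(self, rng):
        raw = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(5, 50, 8))}
        score = myoep_continuity_score(raw)
        order_raw = sorted(raw, key=raw.get)
        order_score = sorted(score, key=score.get, reverse=True)
        assert order_raw == order_score

    def test_all_missing_raises(self):
        with pytest.raises(ValidationError):
            myoep_continuity_score({"A": float("nan")})
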