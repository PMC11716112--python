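"""Chromatin-trace geometry: QC, distance/contact maps, loop statistics."""

import numpy as np
import pandas as pd
import pytest

from extruderquant.traces import (
    ChromatinTrace,
    TraceEnsemble,
    completeness,
    contact_map,
    difference_map,
    knn_count_within_radius,
    knn_mean_distance,
    median_distance_matrix,
    nested_loop_frequency,
    qc_filter,
    scaling_curve,
    scaling_exponent,
    trace_contacts,
    traces_from_dataframe,
)
from extruderquant.synth import gen_trace_ensemble


def straight_chain(n_bins, step_nm=30.0):
    xyz = np.zeros((n_bins, 3))
    xyz[:, 0] = np.arange(n_bins) * step_nm
    return ChromatinTrace("straight", xyz)


def random_trace(n_bins, seed, missing=0):
    rng = np.random.default_rng(seed)
    xyz = rng.normal(0, 100, size=(n_bins, 3))
    if missing:
        xyz[rng.choice(n_bins, missing, replace=False)] = np.nan
    return ChromatinTrace(f"rand{seed}", xyz)


class TestQcAndCompleteness:
    def test_below_threshold_removed_at_exactly_19(self):
        xyz = np.full((100, 3), np.nan)
        xyz[:19] = 1.0
        short = ChromatinTrace("short", xyz)
        xyz2 = xyz.copy()
        xyz2[:20] = 1.0
        ok = ChromatinTrace("ok", xyz2)
        kept = qc_filter(TraceEnsemble([short, ok]), min_positions=20)
        assert [t.trace_id for t in kept] == ["ok"]

    def test_fully_present_trace_unchanged(self):
        trace = random_trace(30, 0)
        kept = qc_filter(TraceEnsemble([trace]), min_positions=20)
        assert np.array_equal(kept.traces[0].xyz_nm, trace.xyz_nm)

    def test_qc_mask_applied_before_counting(self):
        trace = random_trace(30, seed=2)
        qc = {"rand2": np.zeros(30, bool)}
        kept = qc_filter(TraceEnsemble([trace]), min_positions=1, qc_pass=qc)
        assert len(kept) == 0

    def test_survivor_count_matches_enumeration(self):
        rng = np.random.default_rng(3)
        traces, expected = [], 0
        for i in range(50):
            missing = int(rng.integers(0, 100))
            traces.append(random_trace(100, seed=100 + i, missing=missing))
            traces[-1].trace_id = f"t{i}"
            if 100 - missing >= 20:
                expected += 1
        # brute-force enumeration of traces with >= 20 present positions
        brute = sum(1 for t in traces if int(t.present.sum()) >= 20)
        assert brute == expected
        kept = qc_filter(TraceEnsemble(traces), min_positions=20)
        assert len(kept) == expected

    def test_completeness_values(self):
        assert completeness(straight_chain(100)) == 1.0
        xyz = np.zeros((100, 3))
        xyz[80:] = np.nan
        assert completeness(ChromatinTrace("p", xyz)) == pytest.approx(0.8)


class TestDistanceMatrix:
    def test_single_trace_returns_own_matrix(self):
        trace = random_trace(20, 5)
        result = median_distance_matrix(TraceEnsemble([trace]))
        assert np.allclose(result.median_nm, trace.distances(), equal_nan=True)

    def test_median_of_two_traces(self):
        a = straight_chain(5, 30.0)
        b = straight_chain(5, 90.0)
        result = median_distance_matrix(TraceEnsemble([a, b]))
        assert result.median_nm[0, 1] == pytest.approx(60.0)  # median of 30, 90

    def test_matches_brute_force_nested_loops(self):
        traces = [random_trace(20, seed=s, missing=3) for s in range(10)]
        result = median_distance_matrix(TraceEnsemble(traces))
        for i in range(20):
            for j in range(20):
                vals = []
                for t in traces:
                    if t.present[i] and t.present[j]:
                        vals.append(np.linalg.norm(t.xyz_nm[i] - t.xyz_nm[j]))
                if vals:
                    assert result.median_nm[i, j] == pytest.approx(np.median(vals))
                    assert result.counts[i, j] == len(vals)
                else:
                    assert np.isnan(result.median_nm[i, j])

    def test_rigid_motion_invariance(self):
        traces = [random_trace(15, seed=s) for s in range(5)]
        base = median_distance_matrix(TraceEnsemble(traces)).median_nm
        # rotate about z by 40 degrees and translate
        theta = np.deg2rad(40)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = [ChromatinTrace(t.trace_id, t.xyz_nm @ rot.T + [50, -20, 7])
                 for t in traces]
        assert np.allclose(median_distance_matrix(TraceEnsemble(moved)).median_nm,
                           base)


class TestContactMap:
    def test_all_close_pairs_contact(self):
        trace = straight_chain(10, step_nm=5.0)  # every distance <= 45 nm
        cmap = contact_map(TraceEnsemble([trace]), threshold_nm=120.0)
        assert np.all(cmap.frequency == 1.0)

    def test_threshold_below_all_distances(self):
        trace = straight_chain(10, step_nm=200.0)
        cmap = contact_map(TraceEnsemble([trace]), threshold_nm=100.0)
        assert np.nansum(cmap.frequency) == pytest.approx(10.0)  # diagonal only

    def test_planted_loop_frequency(self):
        ens = gen_trace_ensemble(400, 100, 100.0, loops=[(10, 60, 40.0, 0.7)],
                                 seed=9)
        cmap = contact_map(ens, 120.0)
        assert cmap.frequency[10, 60] == pytest.approx(0.7, abs=0.06)

    def test_monotone_in_threshold(self):
        ens = gen_trace_ensemble(50, 40, 80.0, seed=10)
        maps = [contact_map(ens, thr).frequency for thr in (60.0, 120.0, 240.0)]
        assert np.all(maps[0] <= maps[1]) and np.all(maps[1] <= maps[2])

    def test_present_pair_normalization(self):
        xyz_a = np.zeros((3, 3))
        trace_a = ChromatinTrace("a", xyz_a)          # all in contact
        xyz_b = np.zeros((3, 3))
        xyz_b[2] = np.nan                              # pair (0,2) absent
        trace_b = ChromatinTrace("b", xyz_b)
        cmap = contact_map(TraceEnsemble([trace_a, trace_b]), 10.0)
        assert cmap.counts[0, 2] == 1
        assert cmap.frequency[0, 2] == 1.0


class TestDifferenceMap:
    def test_identical_inputs_zero(self):
        ens = gen_trace_ensemble(20, 30, 80.0, seed=11)
        m = median_distance_matrix(ens)
        assert np.allclose(difference_map(m, m), 0.0, equal_nan=True)

    def test_antisymmetry(self):
        a = median_distance_matrix(gen_trace_ensemble(20, 30, 80.0, seed=12))
        b = median_distance_matrix(gen_trace_ensemble(20, 30, 90.0, seed=13))
        assert np.allclose(difference_map(a, b), -difference_map(b, a),
                           equal_nan=True)

    def test_planted_decompaction_is_positive(self):
        compact = median_distance_matrix(gen_trace_ensemble(100, 30, 80.0, seed=14))
        loose = median_distance_matrix(gen_trace_ensemble(100, 30, 110.0, seed=15))
        diff = difference_map(loose, compact)
        off = ~np.eye(30, dtype=bool)
        assert np.nanmedian(diff[off]) > 0

    def test_type_and_shape_mismatch_rejected(self):
        ens = gen_trace_ensemble(5, 10, 80.0, seed=16)
        with pytest.raises(ValueError):
            difference_map(median_distance_matrix(ens), contact_map(ens))


class TestScalingCurve:
    def test_straight_chain_exact_linear(self):
        curve = scaling_curve(TraceEnsemble([straight_chain(30, 30.0)]))
        assert np.allclose(curve["median_nm"], 30.0 * curve["separation_bins"])
        assert scaling_exponent(curve) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_chain_slope_half(self):
        ens = gen_trace_ensemble(300, 100, 100.0, seed=17)
        assert scaling_exponent(scaling_curve(ens)) == pytest.approx(0.5, abs=0.05)

    def test_single_pair_trace(self):
        trace = ChromatinTrace("pair", np.array([[0, 0, 0], [50.0, 0, 0]]))
        curve = scaling_curve(TraceEnsemble([trace]))
        assert len(curve) == 1 and curve["median_nm"].iloc[0] == 50.0


class TestTraceContacts:
    def test_straight_chain_analytic_count(self):
        n = 20
        trace = straight_chain(n, 30.0)
        # pairs j > i+1 with 30*s < 100: s=2 (60 nm) and s=3 (90 nm)
        assert trace_contacts(trace, 100.0) == (n - 2) + (n - 3)

    def test_collapsed_trace_counts_all_nonadjacent_pairs(self):
        n = 12
        trace = ChromatinTrace("collapsed", np.zeros((n, 3)))
        assert trace_contacts(trace, 100.0) == (n * (n - 1)) // 2 - (n - 1)

    def test_matches_brute_force(self):
        trace = random_trace(25, seed=18, missing=4)
        brute = 0
        for i in range(25):
            for j in range(i + 2, 25):
                if trace.present[i] and trace.present[j]:
                    if np.linalg.norm(trace.xyz_nm[i] - trace.xyz_nm[j]) < 100.0:
                        brute += 1
        assert trace_contacts(trace, 100.0) == brute


class TestKnn:
    def test_equilateral_triangle(self):
        d = 70.0
        xyz = np.array([[0, 0, 0], [d, 0, 0], [d / 2, d * np.sqrt(3) / 2, 0]])
        assert knn_mean_distance(ChromatinTrace("tri", xyz), k=2) == pytest.approx(d)

    def test_collinear_equidistant(self):
        trace = straight_chain(10, 40.0)
        assert knn_mean_distance(trace, k=1) == pytest.approx(40.0)

    def test_matches_brute_force(self):
        trace = random_trace(20, seed=19, missing=3)
        xyz = trace.xyz_nm[trace.present]
        k = 3
        acc = []
        for i in range(len(xyz)):
            dists = sorted(np.linalg.norm(xyz[i] - xyz[j])
                           for j in range(len(xyz)) if j != i)
            acc.append(np.mean(dists[:k]))
        assert knn_mean_distance(trace, k) == pytest.approx(np.mean(acc))

    def test_count_within_radius_reading(self):
        trace = straight_chain(10, 40.0)
        # neighbors within 100 nm: at 40 and 80 nm each side
        assert knn_count_within_radius(trace, 100.0) == pytest.approx(
            np.mean([2, 3, 4, 4, 4, 4, 4, 4, 3, 2]))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            knn_mean_distance(straight_chain(5), k=5)


class TestNestedLoops:
    def test_shared_anchor_pair_counted_once(self):
        xyz = np.zeros((100, 3))
        xyz[:, 0] = np.arange(100) * 1000.0  # far apart by default
        xyz[40, :] = xyz[5, :] + [50.0, 0, 0]   # loop (5, 40)
        xyz[80, :] = xyz[40, :] + [0, 90.0, 0]  # loop (40, 80); (5, 80) > 100 nm
        count, rate = nested_loop_frequency(ChromatinTrace("n", xyz), 100.0)
        assert count == 1
        assert rate == pytest.approx(1 / 2)

    def test_no_contacts_no_loops(self):
        trace = straight_chain(30, 500.0)
        assert nested_loop_frequency(trace, 100.0) == (0, 0.0)

    def test_planted_shared_anchor_recovery(self):
        ens = gen_trace_ensemble(
            100, 100, 100.0,
            loops=[(10, 40, 30.0, 1.0), (40, 70, 30.0, 1.0)], seed=20)
        counts = [nested_loop_frequency(t, 100.0)[0] for t in ens]
        assert np.mean(counts) >= 1.0  # the planted stacked pair is recovered


class TestDataFrameRoundTrip:
    def test_long_format_round_trip(self):
        ens = gen_trace_ensemble(5, 20, 80.0, missing_fraction=0.1, seed=21)
        rows = []
        for t in ens:
            for b in range(t.n_bins):
                if t.present[b]:
                    rows.append({"trace_id": t.trace_id, "condition": t.condition,
                                 "bin_index": b, "x_nm": t.xyz_nm[b, 0],
                                 "y_nm": t.xyz_nm[b, 1], "z_nm": t.xyz_nm[b, 2],
                                 "qc_pass": True})
        back = traces_from_dataframe(pd.DataFrame(rows), n_bins=20)
        assert len(back) == 5
        for orig, rebuilt in zip(ens, back):
            assert np.allclose(orig.xyz_nm, rebuilt.xyz_nm, equal_nan=True)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            traces_from_dataframe(pd.DataFrame({"trace_id": ["a"]}))
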