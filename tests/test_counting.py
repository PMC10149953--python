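"""Blink grouping, molecule clustering, counting — with exhaustive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsmlm.counting import (
    AnalysisConfig,
    analyze_roi,
    cluster_molecules,
    corrected_density,
    derive_group_radius,
    group_blinks,
    link_radius_from_fit,
)
from qsmlm.errors import QSMLMError
from qsmlm.preprocess import ROI, filter_precision
from qsmlm.simulate import PALM_ACQ, PatternParams, generate_pattern, simulate_blinking, PAGFP_BLINK

from conftest import make_table


class TestCorrectedDensity:
    ROI10 = ROI(0.0, 0.0, np.sqrt(10.0) * 1000.0, np.sqrt(10.0) * 1000.0)

    def test_arithmetic_example(self, rng):
        side = self.ROI10.x1
        table = make_table(x=rng.uniform(0, side, 500), y=rng.uniform(0, side, 500))
        assert corrected_density(table, self.ROI10, 5.0) == pytest.approx(10.0)

    def test_alpha_one_is_raw_density(self, rng):
        side = self.ROI10.x1
        table = make_table(x=rng.uniform(0, side, 237), y=rng.uniform(0, side, 237))
        assert corrected_density(table, self.ROI10, 1.0) == pytest.approx(23.7)

    def test_alpha_below_one_rejected(self, small_table):
        with pytest.raises(QSMLMError):
            corrected_density(small_table, self.ROI10, 0.5)

    def test_unbiased_on_simulation(self):
        """dSTORM-like alpha=3 counting recovers the true density."""
        from qsmlm.simulate import AF647_BLINK, DSTORM_ACQ
        from dataclasses import replace

        pat = generate_pattern(PatternParams(fraction_clustered=0.0, seed=9))
        roi = ROI(0.0, 0.0, pat.side_nm, pat.side_nm)
        true_density = pat.n_molecules / pat.params.roi_area_um2
        estimates = [
            corrected_density(
                simulate_blinking(pat, replace(AF647_BLINK, seed=s), DSTORM_ACQ),
                roi, 3.0,
            )
            for s in range(50)
        ]
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / np.sqrt(50)
        assert abs(mean - true_density) < 2 * sem + 0.005 * true_density


class TestDeriveGroupRadius:
    def test_three_times_max_precision(self):
        table = make_table(x=[0, 0, 0], y=[0, 0, 0], sigma=[5.0, 10.0, 20.0])
        assert derive_group_radius(table) == 60.0

    def test_single_row(self):
        assert derive_group_radius(make_table(x=[0], y=[0], sigma=[12.0])) == 36.0

    def test_composes_with_precision_filter(self):
        table = make_table(
            x=np.zeros(100), y=np.zeros(100), sigma=np.arange(1.0, 101.0)
        )
        filtered = filter_precision(table, 98.0)
        assert derive_group_radius(filtered) == 3 * filtered["sigma_nm"].max()
        assert derive_group_radius(filtered) <= 3 * filtered.attrs["precision_cutoff_nm"]

    def test_empty_is_error(self, small_table):
        with pytest.raises(QSMLMError):
            derive_group_radius(small_table.iloc[:0])


def oracle_group_blinks(table, group_radius, max_dark_time, frame_time):
    """Independent re-implementation: lists of members, centroid from scratch."""
    order = np.argsort(table["frame"].to_numpy(), kind="stable")
    x = table["x_nm"].to_numpy()[order]
    y = table["y_nm"].to_numpy()[order]
    f = table["frame"].to_numpy()[order]
    s = table["sigma_nm"].to_numpy()[order]
    molecules = []  # list of member index lists
    assignment = np.empty(len(order), dtype=int)
    for i in range(len(order)):
        best, best_d = None, np.inf
        for mid, members in enumerate(molecules):
            last_frame = f[members[-1]]
            if (f[i] - last_frame) * frame_time > max_dark_time + 1e-12:
                continue
            w = 1.0 / s[members] ** 2
            cx = np.sum(x[members] * w) / w.sum()
            cy = np.sum(y[members] * w) / w.sum()
            d = np.hypot(cx - x[i], cy - y[i])
            if d <= group_radius and d < best_d:
                best, best_d = mid, d
        if best is None:
            molecules.append([i])
            assignment[i] = len(molecules) - 1
        else:
            molecules[best].append(i)
            assignment[i] = best
    out = np.empty(len(order), dtype=int)
    out[order] = assignment
    return out


def partitions_equal(a, b):
    """Compare two labelings as partitions (label-permutation invariant)."""
    amap, bmap = {}, {}
    for la, lb in zip(a, b):
        if amap.setdefault(la, lb) != lb or bmap.setdefault(lb, la) != la:
            return False
    return True


class TestGroupBlinks:
    def test_co_located_blinks_merge(self):
        table = make_table(
            x=[100.0, 100.0, 100.0, 600.0],
            y=[100.0, 100.0, 100.0, 100.0],
            frame=[1, 2, 3, 2],
        )
        mols = group_blinks(table, group_radius=50.0, max_dark_time=5.0, frame_time=0.1)
        assert mols.n_molecules == 2
        assert sorted(mols.table["n_locs"]) == [1, 3]

    def test_dark_time_threshold_splits(self):
        table = make_table(x=[100.0, 100.0], y=[100.0, 100.0], frame=[1, 200])
        mols = group_blinks(table, 50.0, max_dark_time=5.0, frame_time=0.1)
        assert mols.n_molecules == 2  # 19.9 s gap > 5 s

    def test_within_dark_time_merges(self):
        table = make_table(x=[100.0, 100.0], y=[100.0, 100.0], frame=[1, 49])
        mols = group_blinks(table, 50.0, max_dark_time=5.0, frame_time=0.1)
        assert mols.n_molecules == 1

    def test_matches_exhaustive_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 200))
            table = make_table(
                x=rng.uniform(0, 800, n),
                y=rng.uniform(0, 800, n),
                frame=rng.integers(0, 300, n),
                sigma=rng.uniform(5, 25, n),
            )
            mols = group_blinks(table, 60.0, max_dark_time=5.0, frame_time=0.1)
            want = oracle_group_blinks(table, 60.0, 5.0, 0.1)
            assert partitions_equal(mols.assignment, want), f"seed {seed}"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        table = make_table(
            x=rng.uniform(0, 500, n), y=rng.uniform(0, 500, n),
            frame=rng.integers(0, 100, n), sigma=rng.uniform(5, 20, n),
        )
        mols = group_blinks(table, 40.0)
        assert mols.table["n_locs"].sum() == n
        assert np.all(np.bincount(mols.assignment) == mols.table["n_locs"].to_numpy())

    def test_alpha_one_groups_nothing_when_sparse(self):
        pat = generate_pattern(PatternParams(fraction_clustered=0.0, seed=2))
        from dataclasses import replace
        from qsmlm.simulate import BlinkModel

        table = simulate_blinking(pat, BlinkModel(alpha=1.0, seed=0), PALM_ACQ)
        mols = group_blinks(table, 1e-9, max_dark_time=0.0, frame_time=0.1)
        assert mols.n_molecules == len(table)


def oracle_components(points, link_radius):
    """Union-find over the full distance matrix."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= link_radius:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


def molecule_set_from_points(points):
    from qsmlm.counting import MoleculeSet
    import pandas as pd

    table = pd.DataFrame(
        {
            "x_nm": points[:, 0], "y_nm": points[:, 1],
            "n_locs": 1, "first_frame": 0, "last_frame": 0, "mean_sigma_nm": 10.0,
        }
    )
    return MoleculeSet(table=table, assignment=np.arange(len(points)))


class TestClusterMolecules:
    def test_four_mutually_close_molecules_one_cluster(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        res = cluster_molecules(molecule_set_from_points(pts), 50.0)
        assert res.fraction_clustered == 1.0
        assert list(res.cluster_sizes) == [4]

    def test_dimer_not_counted_as_clustered(self):
        pts = np.array([[0, 0], [10, 0], [5000, 5000]], float)
        res = cluster_molecules(molecule_set_from_points(pts), 50.0)
        assert res.fraction_clustered == 0.0
        assert res.class_counts == {"monomer": 1, "dimer": 2, "clustered": 0}

    def test_matches_union_find_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            n = int(rng.integers(2, 300))
            pts = rng.uniform(0, 2000, (n, 2))
            res = cluster_molecules(molecule_set_from_points(pts), 80.0)
            want = oracle_components(pts, 80.0)
            assert partitions_equal(res.component, want), f"seed {seed}"

    def test_invariant_to_input_order(self, rng):
        pts = rng.uniform(0, 1500, (120, 2))
        perm = rng.permutation(120)
        a = cluster_molecules(molecule_set_from_points(pts), 80.0)
        b = cluster_molecules(molecule_set_from_points(pts[perm]), 80.0)
        assert a.fraction_clustered == b.fraction_clustered
        assert sorted(a.cluster_sizes) == sorted(b.cluster_sizes)

    def test_radius_of_gyration(self):
        pts = np.array([[0, 0], [20, 0], [10, 17.32]], float)  # ~equilateral
        res = cluster_molecules(molecule_set_from_points(pts), 50.0)
        center = pts.mean(axis=0)
        want = np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1)))
        assert res.cluster_radii_nm[0] == pytest.approx(want)

    def test_empty_is_error(self):
        empty = molecule_set_from_points(np.empty((0, 2)))
        with pytest.raises(QSMLMError):
            cluster_molecules(empty, 50.0)


class TestLinkRadiusFromFit:
    def test_deconvolves_precision_broadening(self):
        assert link_radius_from_fit(85.0, 15.0) == pytest.approx(
            np.sqrt(85.0**2 - 2 * 15.0**2)
        )

    def test_floors_at_fallback_scale(self):
        assert link_radius_from_fit(10.0, 15.0) == 30.0


class TestAnalyzeROI:
    def test_full_pipeline_on_clustered_field(self):
        pat = generate_pattern(PatternParams(seed=21))
        from dataclasses import replace

        table = simulate_blinking(pat, replace(PAGFP_BLINK, seed=22), PALM_ACQ)
        roi = ROI(0.0, 0.0, pat.side_nm, pat.side_nm)
        res = analyze_roi(table, roi, PALM_ACQ)
        assert res.fit.converged
        assert 0.0 < res.clustering.fraction_clustered < 1.0
        assert res.density_per_um2 == pytest.approx(
            pat.n_molecules / 16.0, rel=0.25
        )
        # both counting routes agree to ~15% on simulation
        qc = res.molecules.n_molecules / (res.n_locs / PALM_ACQ.alpha)
        assert 0.8 < qc < 1.2
        assert res.group_radius_nm == pytest.approx(
            3 * res.precision_cutoff_nm, rel=0.05
        )
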