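"""Group summaries, Welch's one-tailed test, histogram conventions."""

import numpy as np
import pytest
from scipy import stats as sstats

from qsmlm.counting import ClusteringResult
from qsmlm.errors import QSMLMError
from qsmlm.stats import (
    class_fractions,
    comparison_table,
    occupancy_histogram,
    radius_histogram,
    summarize_group,
    welch_one_tailed,
)


def clustering(sizes, radii=None, density=40.0):
    """Build a ClusteringResult from component sizes (>=3 become clusters)."""
    sizes = np.asarray(sizes)
    comp = np.repeat(np.arange(sizes.size), sizes)
    per = sizes[comp]
    classes = np.where(per == 1, "monomer", np.where(per == 2, "dimer", "clustered"))
    cl = sizes[sizes >= 3]
    return ClusteringResult(
        component=comp,
        classes=classes,
        fraction_clustered=float(np.mean(per >= 3)),
        cluster_sizes=cl,
        cluster_radii_nm=np.asarray(radii if radii is not None else np.full(cl.size, 50.0), float),
        link_radius_nm=80.0,
        n_molecules=int(sizes.sum()),
        density_per_um2=density,
    )


def welch_oracle(a, b, alternative):
    """Textbook Welch t with Welch-Satterthwaite df, one tail."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    if alternative == "greater":
        return t, df, sstats.t.sf(t, df)
    return t, df, sstats.t.cdf(t, df)


class TestSummarizeGroup:
    def test_mean_and_sem_hand_example(self):
        g = summarize_group([clustering([3, 1, 1, 1, 1, 1, 1, 1]),  # frac 0.3 over 10
                             clustering([3, 3, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1])],
                            "demo")
        # fractions are 0.3 and 0.285714...; check SEM = SD/sqrt(n), ddof=1
        vals = g.values("fraction_clustered")
        assert g.mean["fraction_clustered"] == pytest.approx(vals.mean())
        assert g.sem["fraction_clustered"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(2)
        )

    def test_fractions_02_04_give_mean_03_sem_01(self):
        a = clustering([3] + [1] * 12)  # 3/15 = 0.2
        b = clustering([4] + [1] * 6)   # 4/10 = 0.4
        g = summarize_group([a, b], "demo")
        assert g.mean["fraction_clustered"] == pytest.approx(0.3)
        assert g.sem["fraction_clustered"] == pytest.approx(0.1)

    def test_single_roi_flagged_sem_nan(self):
        g = summarize_group([clustering([3, 1])], "one")
        assert g.single_roi
        assert np.isnan(g.sem["fraction_clustered"])

    def test_identical_rois_zero_sem(self):
        g = summarize_group([clustering([3, 1]), clustering([3, 1])], "same")
        assert g.sem["fraction_clustered"] == 0.0

    def test_invariant_to_roi_order(self):
        rois = [clustering([3, 1]), clustering([4, 1, 1]), clustering([1, 1])]
        a = summarize_group(rois, "x")
        b = summarize_group(rois[::-1], "x")
        for k in a.mean:
            assert a.mean[k] == pytest.approx(b.mean[k])
            assert a.sem[k] == pytest.approx(b.sem[k])


class TestWelch:
    def test_identical_samples_p_half(self):
        res = welch_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_matches_reference_implementation(self):
        res = welch_one_tailed([1, 2, 3], [1, 2, 3, 4, 5], "greater")
        t, df, p = welch_oracle([1, 2, 3], [1, 2, 3, 4, 5], "greater")
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_hundred_random_fixtures_to_1e10(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            b = rng.normal(0, 1, rng.integers(3, 30))
            alt = "greater" if rng.random() < 0.5 else "less"
            res = welch_one_tailed(a, b, alt)
            _, _, p = welch_oracle(a, b, alt)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_swap_and_flip_leaves_p_unchanged(self):
        a = [0.2, 0.4, 0.35]
        b = [0.5, 0.6, 0.55, 0.45]
        p1 = welch_one_tailed(a, b, "greater").p
        p2 = welch_one_tailed(b, a, "less").p
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_constant_equal_flagged(self):
        res = welch_one_tailed([1.0, 1.0], [1.0, 1.0], "greater")
        assert res.degenerate and res.p == 0.5

    def test_short_samples_rejected(self):
        with pytest.raises(QSMLMError):
            welch_one_tailed([1.0], [1.0, 2.0], "greater")


class TestHistograms:
    def test_occupancy_two_bin_example(self):
        res = clustering([3, 3, 9])
        h = occupancy_histogram([res], edges=(3, 9, np.inf))
        assert list(h["frequency"]) == pytest.approx([2 / 3, 1 / 3])

    def test_empty_flagged_all_zero(self):
        h = occupancy_histogram([clustering([1, 1, 2])])
        assert h.attrs["empty"]
        assert h["frequency"].sum() == 0.0

    def test_normalized_across_simulated_runs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sizes = rng.integers(1, 15, 30)
            h = occupancy_histogram([clustering(sizes)])
            if not h.attrs["empty"]:
                assert h["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_radius_tail_example(self):
        res = clustering([3, 3, 3], radii=[40.0, 90.0, 120.0])
        h = radius_histogram([res], edges=(0.0, 80.0, np.inf))
        assert list(h["frequency"]) == pytest.approx([1 / 3, 2 / 3])
        assert h["bin"].iloc[-1] == ">80"

    def test_bin_edge_uses_half_open_convention(self):
        res = clustering([3], radii=[80.0])
        h = radius_histogram([res], edges=(0.0, 80.0, np.inf))
        # 80 falls in [80, inf), not [0, 80)
        assert h["frequency"].iloc[-1] == 1.0


class TestClassFractions:
    def test_counting_example(self):
        assert class_fractions([clustering([1, 1, 2, 3])]) == pytest.approx(
            (2 / 7, 2 / 7, 3 / 7)
        )

    def test_all_monomers(self):
        assert class_fractions([clustering([1, 1, 1])]) == (1.0, 0.0, 0.0)

    def test_sums_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            sizes = rng.integers(1, 10, 25)
            assert sum(class_fractions([clustering(sizes)])) == pytest.approx(1.0)


def test_plot_group_summary_writes_figure(tmp_path):
    from qsmlm.stats import plot_group_summary

    groups = {
        "steady": [clustering([3, 1, 1]), clustering([4, 1])],
        "treated": [clustering([5, 3, 1]), clustering([9, 1])],
    }
    out = tmp_path / "panels.png"
    plot_group_summary(groups, out)
    assert out.stat().st_size > 0


def test_comparison_table_against_reference():
    groups = {
        "a": summarize_group([clustering([3, 1]), clustering([3, 1, 1]),
                              clustering([4, 1])], "a"),
        "ref": summarize_group([clustering([1, 1]), clustering([3, 1, 1, 1, 1, 1]),
                                clustering([1, 1, 1])], "ref"),
    }
    table = comparison_table(groups, "fraction_clustered", "ref")
    assert len(table) == 1
    _, _, p = welch_oracle(
        groups["a"].values("fraction_clustered"),
        groups["ref"].values("fraction_clustered"),
        "greater",
    )
    assert table["p"].iloc[0] == pytest.approx(p, abs=1e-10)
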