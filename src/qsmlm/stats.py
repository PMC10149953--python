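"""Group-level summaries and significance testing of per-ROI results.

The unit of statistical analysis is the ROI: each treatment group carries a
list of per-ROI metric records (fraction clustered, alpha-corrected
density, fitted cluster radius, cluster occupancies).  Group comparisons
use Welch's two-sample unequal-variance t-test with a one-tailed p value.
Distributions (molecules per cluster, cluster radii) are pooled across
ROIs and reported as normalized frequencies over half-open bins with an
open-ended top class (default: more than 8 molecules, more than 80 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .counting import CLASS_NAMES, ClusteringResult, ROIResult
from .errors import QSMLMError

__all__ = [
    "TreatmentGroup",
    "ComparisonResult",
    "summarize_group",
    "welch_one_tailed",
    "occupancy_histogram",
    "radius_histogram",
    "class_fractions",
]

#: default molecules-per-cluster bin edges: classes 3..8 and ">8"
OCCUPANCY_EDGES = (3, 4, 5, 6, 7, 8, 9, np.inf)
#: default cluster-radius bin edges (nm): 10 nm classes and ">80"
RADIUS_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, np.inf)


def _as_clustering(r) -> ClusteringResult:
    return r.clustering if isinstance(r, ROIResult) else r


@dataclass
class TreatmentGroup:
    """Per-ROI metrics of one treatment condition with group summaries."""

    label: str
    metrics: pd.DataFrame          # one row per ROI
    mean: dict[str, float]
    sem: dict[str, float]          # NaN when n == 1
    n_rois: int
    single_roi: bool = False       # flagged: SEM undefined

    def values(self, metric: str) -> np.ndarray:
        return self.metrics[metric].to_numpy()


@dataclass
class ComparisonResult:
    """Welch's unequal-variance t-test between two groups, one-tailed."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    alternative: str
    degenerate: bool = False   # both groups constant and equal


def summarize_group(results: list, label: str) -> TreatmentGroup:
    """Tabulate per-ROI metrics and compute group mean and SEM.

    SEM uses the n-1 (sample) standard deviation over ROIs; with a single
    ROI it is undefined and reported as NaN with ``single_roi`` set.
    """
    if not results:
        raise QSMLMError("summarize_group needs at least one ROI result")
    rows = []
    for r in results:
        c = _as_clustering(r)
        row = {
            "fraction_clustered": c.fraction_clustered,
            "density_per_um2": c.density_per_um2,
            "n_molecules": c.n_molecules,
        }
        if isinstance(r, ROIResult):
            row["xi_nm"] = r.fit.xi_nm if r.fit.converged else np.nan
            row["pc_molecules_per_cluster"] = r.pc_molecules_per_cluster
        rows.append(row)
    metrics = pd.DataFrame(rows)
    n = len(metrics)
    mean = {k: float(metrics[k].mean()) for k in metrics.columns}
    if n > 1:
        sem = {k: float(metrics[k].std(ddof=1) / np.sqrt(n)) for k in metrics.columns}
    else:
        sem = {k: float("nan") for k in metrics.columns}
    return TreatmentGroup(
        label=label, metrics=metrics, mean=mean, sem=sem, n_rois=n, single_roi=n == 1
    )


def welch_one_tailed(
    a, b, alternative: str = "greater", label_a: str = "A", label_b: str = "B"
) -> ComparisonResult:
    """Welch's heteroscedastic two-sample t-test with a one-tailed p value.

    ``alternative="greater"`` tests mean(a) > mean(b).  Degrees of freedom
    follow Welch-Satterthwaite.  When both samples are constant and equal
    the statistic is undefined; by convention p = 0.5 is returned, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise QSMLMError("each sample needs at least two values")
    if alternative not in ("greater", "less"):
        raise QSMLMError("alternative must be 'greater' or 'less'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    degenerate = va == 0 and vb == 0 and a.mean() == b.mean()
    if degenerate:
        t, p, dof = 0.0, 0.5, float(a.size + b.size - 2)
    else:
        res = sstats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        t, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        t=t,
        df=dof,
        p=p,
        alternative=alternative,
        degenerate=degenerate,
    )


def _histogram(values: np.ndarray, edges, integer_values: bool = False) -> pd.DataFrame:
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise QSMLMError("bin edges must be strictly increasing")
    if not np.isinf(edges[-1]):
        raise QSMLMError("final bin must be open-ended (inf upper edge)")
    counts = np.zeros(len(edges) - 1, dtype=int)
    if values.size:
        idx = np.searchsorted(edges, values, side="right") - 1
        ok = (idx >= 0) & (idx < counts.size)
        counts = np.bincount(idx[ok], minlength=counts.size)
    total = counts.sum()
    freq = counts / total if total else counts.astype(float)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(hi):
            # integer quantities: [9, inf) means "more than 8"
            v = lo - 1 if integer_values else lo
            labels.append(f">{v:g}")
        elif integer_values and hi == lo + 1:
            labels.append(f"{lo:g}")
        else:
            labels.append(f"[{lo:g}, {hi:g})")
    out = pd.DataFrame({"bin": labels, "lo": edges[:-1], "hi": edges[1:],
                        "count": counts, "frequency": freq})
    out.attrs["empty"] = bool(total == 0)
    return out


def occupancy_histogram(results, edges=OCCUPANCY_EDGES) -> pd.DataFrame:
    """Normalized distribution of detected molecules per cluster.

    Pools cluster occupancies (components of more than two molecules)
    across ROIs.  Bins are half-open ``[lo, hi)``; the default top class is
    ">8" molecules.  An all-zero histogram (no clusters) is flagged via
    ``attrs["empty"]``.
    """
    sizes = [np.asarray(_as_clustering(r).cluster_sizes, dtype=float) for r in results]
    values = np.concatenate(sizes) if sizes else np.empty(0)
    return _histogram(values, edges, integer_values=True)


def radius_histogram(results, edges=RADIUS_EDGES) -> pd.DataFrame:
    """Normalized distribution of per-cluster radii (radius of gyration, nm).

    Half-open ``[lo, hi)`` bins with the default ">80" nm tail as the final
    open class.
    """
    radii = [np.asarray(_as_clustering(r).cluster_radii_nm, dtype=float) for r in results]
    values = np.concatenate(radii) if radii else np.empty(0)
    return _histogram(values, edges)


def class_fractions(results) -> tuple[float, float, float]:
    """Molecule-weighted (monomer, dimer, clustered) fractions over ROIs."""
    if not results:
        raise QSMLMError("class_fractions needs at least one result")
    counts = {c: 0 for c in CLASS_NAMES}
    for r in results:
        for c, k in _as_clustering(r).class_counts.items():
            counts[c] += k
    total = sum(counts.values())
    if total == 0:
        return (0.0, 0.0, 0.0)
    return tuple(counts[c] / total for c in CLASS_NAMES)


def comparison_table(groups: dict[str, TreatmentGroup], metric: str,
                     reference: str, alternative: str = "greater") -> pd.DataFrame:
    """Welch one-tailed comparisons of every group against a reference."""
    ref = groups[reference]
    rows = []
    for label, g in groups.items():
        if label == reference:
            continue
        c = welch_one_tailed(
            g.values(metric), ref.values(metric), alternative=alternative,
            label_a=label, label_b=reference,
        )
        rows.append(
            {
                "group": label,
                "reference": reference,
                "metric": metric,
                "mean": c.mean_a,
                "sem": c.sem_a,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "alternative": c.alternative,
            }
        )
    return pd.DataFrame(rows)


def plot_group_summary(results_by_group: dict[str, list], path=None):
    """Three-panel summary figure: occupancy, radius, fraction clustered.

    Panels mirror the standard presentation of cluster statistics: pooled
    molecules-per-cluster and cluster-radius distributions per group, and
    the group means of the clustered fraction with SEM error bars.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    labels = list(results_by_group)
    width = 0.8 / max(len(labels), 1)
    for gi, label in enumerate(labels):
        occ = occupancy_histogram(results_by_group[label])
        rad = radius_histogram(results_by_group[label])
        axes[0].bar(np.arange(len(occ)) + gi * width, occ["frequency"], width, label=label)
        axes[1].bar(np.arange(len(rad)) + gi * width, rad["frequency"], width, label=label)
    axes[0].set_xticks(np.arange(len(occ)), occ["bin"], rotation=45, ha="right")
    axes[0].set_xlabel("molecules per cluster")
    axes[1].set_xticks(np.arange(len(rad)), rad["bin"], rotation=45, ha="right")
    axes[1].set_xlabel("cluster radius (nm)")
    for ax in axes[:2]:
        ax.set_ylabel("frequency")
        ax.legend(fontsize=7)
    groups = {l: summarize_group(results_by_group[l], l) for l in labels}
    means = [groups[l].mean["fraction_clustered"] for l in labels]
    sems = [groups[l].sem["fraction_clustered"] for l in labels]
    axes[2].bar(range(len(labels)), means, yerr=sems, capsize=3)
    axes[2].set_xticks(range(len(labels)), labels, rotation=30, ha="right")
    axes[2].set_ylabel("fraction clustered")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
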