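"""Blinking-corrected counting and spatiotemporal clustering of molecules.

Two complementary counting routes are implemented:

* **alpha counting** — the number of in-ROI localizations divided by the
  probe's mean localizations-per-molecule alpha gives the detected
  molecular density (:func:`corrected_density`);
* **blink grouping** — localizations are greedily merged into molecules
  using a spatial threshold (group radius, by default three times the
  maximum localization precision of the filtered table) and a temporal
  threshold (maximum fluorophore dark time, 5 s by default)
  (:func:`group_blinks`).

Grouped molecules are then organized into spatial components by
single-linkage at the cluster radius obtained from pair-correlation
analysis (:func:`cluster_molecules`); components of size 1 are monomers,
size 2 dimers, and more than two receptors constitute a cluster.  Only the
last class counts toward the fraction of clustered molecules.
:func:`analyze_roi` orchestrates the whole per-ROI pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import QSMLMError
from .io import AcquisitionMeta
from .paircorr import PCFitResult, autocorr_fft, fit_pcf, molecules_per_cluster
from .preprocess import ROI, filter_precision, render_binary

__all__ = [
    "MoleculeSet",
    "ClusteringResult",
    "AnalysisConfig",
    "ROIResult",
    "corrected_density",
    "derive_group_radius",
    "group_blinks",
    "cluster_molecules",
    "analyze_roi",
]

CLASS_NAMES = ("monomer", "dimer", "clustered")


@dataclass
class MoleculeSet:
    """Blink-grouped localizations collapsed to molecules.

    ``table`` has one row per molecule: precision-weighted centroid
    (``x_nm``, ``y_nm``), member count ``n_locs``, ``first_frame``,
    ``last_frame`` and ``mean_sigma_nm``.  ``assignment[i]`` is the molecule
    index of input localization ``i`` (every localization is assigned to
    exactly one molecule — the partition property).
    """

    table: pd.DataFrame
    assignment: np.ndarray = field(repr=False, default=None)

    @property
    def n_molecules(self) -> int:
        return len(self.table)


@dataclass
class ClusteringResult:
    """Molecule-level clustering of one ROI."""

    component: np.ndarray       # per-molecule component id
    classes: np.ndarray         # per-molecule class name (monomer/dimer/clustered)
    fraction_clustered: float   # molecules in components of size > 2 / total
    cluster_sizes: np.ndarray   # occupancy of each component with size >= 3
    cluster_radii_nm: np.ndarray  # radius of gyration of those components
    link_radius_nm: float
    n_molecules: int
    density_per_um2: float | None = None   # alpha-corrected detected density
    used_fallback_radius: bool = False

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in CLASS_NAMES}


def corrected_density(table: pd.DataFrame, roi: ROI, alpha: float) -> float:
    """Blinking-corrected molecular density: (in-ROI localizations / alpha) / area."""
    if alpha < 1:
        raise QSMLMError("alpha must be >= 1")
    n = int(roi.contains(table["x_nm"].to_numpy(), table["y_nm"].to_numpy()).sum())
    return n / alpha / roi.area_um2


def derive_group_radius(table: pd.DataFrame) -> float:
    """Blink-grouping radius: three times the maximum localization precision.

    Meant to be applied *after* the percentile precision filter, so the
    maximum is the filter cutoff rather than an outlier.
    """
    if len(table) == 0:
        raise QSMLMError("cannot derive a group radius from an empty table")
    return 3.0 * float(table["sigma_nm"].max())


def group_blinks(
    table: pd.DataFrame,
    group_radius: float,
    max_dark_time: float = 5.0,
    frame_time: float = 0.1,
) -> MoleculeSet:
    """Greedy temporal grouping of blinks into molecules.

    Localizations are visited in frame order.  A localization joins an open
    molecule iff its distance to that molecule's running precision-weighted
    centroid is <= *group_radius* and the time since the molecule's last
    appearance is <= *max_dark_time*; among several eligible molecules the
    nearest centroid wins, ties broken by lowest molecule id.  Otherwise a
    new molecule is opened.  Molecules whose dark window has lapsed are
    closed and never rejoined.
    """
    if group_radius <= 0:
        raise QSMLMError("group_radius must be > 0")
    if max_dark_time < 0:
        raise QSMLMError("max_dark_time must be >= 0")
    order = np.argsort(table["frame"].to_numpy(), kind="stable")
    x = table["x_nm"].to_numpy()[order]
    y = table["y_nm"].to_numpy()[order]
    f = table["frame"].to_numpy()[order]
    s = table["sigma_nm"].to_numpy()[order]
    n = x.size
    max_gap = max_dark_time / frame_time + 1e-9

    cx = np.empty(n)
    cy = np.empty(n)
    wsum = np.empty(n)
    last = np.empty(n, dtype=np.int64)
    first = np.empty(n, dtype=np.int64)
    n_mol = 0
    open_ids: list[int] = []
    assignment = np.empty(n, dtype=np.int64)

    for i in range(n):
        fi = f[i]
        if open_ids:
            ids = np.asarray(open_ids)
            still = (fi - last[ids]) <= max_gap
            if not still.all():
                open_ids = [int(j) for j in ids[still]]
                ids = ids[still]
        chosen = -1
        if open_ids:
            d2 = (cx[ids] - x[i]) ** 2 + (cy[ids] - y[i]) ** 2
            j = int(np.argmin(d2))  # first minimum = lowest id (ids ascending)
            if d2[j] <= group_radius**2:
                chosen = int(ids[j])
        w = 1.0 / s[i] ** 2
        if chosen < 0:
            chosen = n_mol
            n_mol += 1
            cx[chosen] = x[i]
            cy[chosen] = y[i]
            wsum[chosen] = w
            first[chosen] = fi
            open_ids.append(chosen)
        else:
            tot = wsum[chosen] + w
            cx[chosen] = (cx[chosen] * wsum[chosen] + x[i] * w) / tot
            cy[chosen] = (cy[chosen] * wsum[chosen] + y[i] * w) / tot
            wsum[chosen] = tot
        last[chosen] = fi
        assignment[i] = chosen

    # map back to the input row order
    assignment_in = np.empty(n, dtype=np.int64)
    assignment_in[order] = assignment
    n_locs = np.bincount(assignment, minlength=n_mol)
    mean_sigma = np.bincount(assignment, weights=s, minlength=n_mol) / n_locs
    mol = pd.DataFrame(
        {
            "x_nm": cx[:n_mol],
            "y_nm": cy[:n_mol],
            "n_locs": n_locs,
            "first_frame": first[:n_mol],
            "last_frame": last[:n_mol],
            "mean_sigma_nm": mean_sigma,
        }
    )
    assert int(mol["n_locs"].sum()) == n, "grouping must partition localizations"
    return MoleculeSet(table=mol, assignment=assignment_in)


def link_radius_from_fit(
    xi_nm: float, mean_precision_nm: float, fallback_scale: float = 2.0
) -> float:
    """Clustering link radius from a fitted cluster correlation length.

    The pair correlation is measured on raw localizations, so its cluster
    scale is broadened by the localization precision: in quadrature,
    xi_meas^2 ~ xi_true^2 + 2 sigma_loc^2 (the pair-difference of two
    independent precision draws).  Molecule centroids average several
    localizations and are far less blurred, so the link radius applied to
    them is the deconvolved scale sqrt(xi^2 - 2 sigma^2), floored at the
    precision-scale fallback radius.
    """
    deblurred = np.sqrt(max(xi_nm**2 - 2.0 * mean_precision_nm**2, 0.0))
    return float(max(deblurred, fallback_scale * mean_precision_nm))


def cluster_molecules(mols: MoleculeSet, link_radius: float) -> ClusteringResult:
    """Single-linkage spatial components of molecule centroids.

    Two molecules are linked when their centroids are within *link_radius*;
    connected components define the groups.  Component size 1 -> monomer,
    2 -> dimer, >= 3 -> cluster; the fraction clustered counts only
    molecules in components of more than two receptors.  Per-cluster radius
    is the radius of gyration of the member centroids.
    """
    if mols.n_molecules == 0:
        raise QSMLMError("cannot cluster an empty MoleculeSet")
    if link_radius <= 0:
        raise QSMLMError("link_radius must be > 0")
    pts = mols.table[["x_nm", "y_nm"]].to_numpy()
    n = len(pts)
    pairs = cKDTree(pts).query_pairs(link_radius, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, comp = connected_components(graph, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    per_mol_size = sizes[comp]
    classes = np.where(
        per_mol_size == 1, "monomer", np.where(per_mol_size == 2, "dimer", "clustered")
    )
    frac = float(np.mean(per_mol_size >= 3))
    cluster_ids = np.flatnonzero(sizes >= 3)
    radii = np.empty(cluster_ids.size)
    for k, cid in enumerate(cluster_ids):
        member = pts[comp == cid]
        center = member.mean(axis=0)
        radii[k] = np.sqrt(np.mean(np.sum((member - center) ** 2, axis=1)))
    return ClusteringResult(
        component=comp,
        classes=classes,
        fraction_clustered=frac,
        cluster_sizes=sizes[cluster_ids],
        cluster_radii_nm=radii,
        link_radius_nm=float(link_radius),
        n_molecules=n,
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-ROI pipeline.

    ``min_pc_molecules`` gates the use of the fitted cluster radius as the
    clustering link radius: when the pair-correlation cluster term accounts
    for fewer molecules per cluster than this, the fit has detected no
    clustering beyond blinking, its correlation length is not meaningful,
    and the link radius falls back to ``fallback_link_scale`` times the
    mean localization precision (the only remaining physically meaningful
    spatial scale: molecules closer than ~2 sigma are unresolvable).
    """

    percentile: float = 98.0
    apply_precision_filter: bool = True
    pixel_size: float = 10.0
    max_r: float = 1000.0
    r_fit_range: tuple[float, float] = (20.0, 1000.0)
    max_dark_time: float = 5.0
    group_radius: float | None = None      # None -> 3 x max precision
    link_radius: float | None = None       # None -> from PC fit
    min_pc_molecules: float = 1.0
    fallback_link_scale: float = 2.0       # x mean precision


@dataclass
class ROIResult:
    """Everything the per-ROI pipeline produced, with parameters logged."""

    roi: ROI
    fit: PCFitResult
    pc: "object"
    molecules: MoleculeSet
    clustering: ClusteringResult
    density_per_um2: float
    pc_molecules_per_cluster: float
    n_locs: int
    group_radius_nm: float
    link_radius_nm: float
    used_fallback_radius: bool
    precision_cutoff_nm: float | None
    mean_precision_nm: float = float("nan")


def analyze_roi(
    table: pd.DataFrame,
    roi: ROI,
    acq: AcquisitionMeta,
    config: AnalysisConfig = AnalysisConfig(),
) -> ROIResult:
    """Run the full quantitative pipeline on one ROI.

    Steps: precision filter (per acquisition table) -> crop to ROI ->
    binarize -> FFT pair correlation -> model fit -> alpha-corrected
    density -> blink grouping (group radius three times the maximum
    precision, dark-time threshold) -> single-linkage clustering at the
    fitted cluster radius (with the configured fallback when the fit
    detects no cluster term or fails to converge).
    """
    cutoff = None
    if config.apply_precision_filter:
        table = filter_precision(table, config.percentile)
        cutoff = table.attrs.get("precision_cutoff_nm")
    inside = roi.contains(table["x_nm"].to_numpy(), table["y_nm"].to_numpy())
    cropped = table.loc[inside].reset_index(drop=True)
    if len(cropped) == 0:
        raise QSMLMError("ROI contains no localizations after filtering")

    image = render_binary(cropped, roi, config.pixel_size)
    pc = autocorr_fft(image, config.max_r)
    mean_sigma = float(cropped["sigma_nm"].mean())
    fit = fit_pcf(pc, sigma_init=np.sqrt(2.0) * mean_sigma, r_fit_range=config.r_fit_range)

    density = corrected_density(cropped, roi, acq.alpha)
    # molecules per cluster attributed to the PC cluster term: zero when the
    # fitted amplitude is statistically insignificant (raw fit kept in .fit)
    if not fit.converged:
        nc_pc = float("nan")
    elif not fit.cluster_term_significant():
        nc_pc = 0.0
    else:
        nc_pc = molecules_per_cluster(fit, density)

    group_radius = (
        config.group_radius if config.group_radius is not None else derive_group_radius(cropped)
    )
    mols = group_blinks(
        cropped, group_radius, max_dark_time=config.max_dark_time, frame_time=acq.frame_time
    )

    used_fallback = False
    if config.link_radius is not None:
        link = config.link_radius
    elif (
        fit.cluster_term_significant()
        and np.isfinite(nc_pc)
        and nc_pc >= config.min_pc_molecules
    ):
        link = link_radius_from_fit(fit.xi_nm, mean_sigma, config.fallback_link_scale)
    else:
        link = config.fallback_link_scale * mean_sigma
        used_fallback = True

    clustering = cluster_molecules(mols, link)
    clustering.density_per_um2 = density
    clustering.used_fallback_radius = used_fallback
    return ROIResult(
        roi=roi,
        fit=fit,
        pc=pc,
        molecules=mols,
        clustering=clustering,
        density_per_um2=density,
        pc_molecules_per_cluster=nc_pc,
        n_locs=len(cropped),
        group_radius_nm=float(group_radius),
        link_radius_nm=float(link),
        used_fallback_radius=used_fallback,
        precision_cutoff_nm=cutoff,
        mean_precision_nm=mean_sigma,
    )
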