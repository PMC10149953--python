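"""Ground-truth receptor patterns and PALM/dSTORM blinking simulation.

This module produces localization tables with *known* truth so that every
downstream estimator (blinking-corrected counting, pair-correlation fitting,
spatiotemporal clustering) can be validated by parameter recovery.

The generative model
--------------------
Molecules live in a square region treated as a torus (coordinates wrap), so
the pattern is stationary and clusters are never truncated at an edge:

* a fraction ``phi`` of the molecules is organized in clusters whose centers
  are complete-spatial-randomness (CSR) uniform; cluster occupancy is
  Poisson with mean ``n_bar`` truncated at >= 3 (so a ground-truth "cluster"
  always satisfies the operational more-than-two-receptors definition);
  member positions are the center plus isotropic Gaussian displacement of
  scale ``cluster_radius_nm``;
* the remaining molecules are CSR monomers.

Imaging is emulated per molecule: it is detected at all with probability
``detection_prob``; a detected molecule blinks ``k ~ Geometric(mean alpha)``
times (support >= 1, memoryless photophysics — only the mean is
constrained by the blinking calibration of the probe); the first appearance
is uniform over the acquisition, subsequent appearances are separated by
geometric dark times; appearances past the end of the acquisition are lost.
Each appearance is displaced by Gaussian noise whose scale is that
localization's own precision draw (lognormal), and carries a lognormal
photon count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QSMLMError, ScenarioError
from .io import AcquisitionMeta

__all__ = [
    "PatternParams",
    "GroundTruthPattern",
    "BlinkModel",
    "PALM_ACQ",
    "DSTORM_ACQ",
    "SCENARIOS",
    "generate_pattern",
    "simulate_blinking",
    "make_scenario",
]


@dataclass(frozen=True)
class PatternParams:
    """Parameters of the ground-truth point pattern.

    Defaults describe a moderately clustered membrane at the density and
    cluster scale used throughout the validation suite: 50 molecules/um^2,
    half of them in clusters of Gaussian scale 80 nm with mean occupancy 8.
    """

    roi_area_um2: float = 16.0
    density_per_um2: float = 50.0
    fraction_clustered: float = 0.5
    cluster_radius_nm: float = 80.0
    mean_occupancy: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_um2 <= 0:
            raise QSMLMError("density_per_um2 must be > 0")
        if not 0 <= self.fraction_clustered <= 1:
            raise QSMLMError("fraction_clustered must be in [0, 1]")
        if self.cluster_radius_nm <= 0:
            raise QSMLMError("cluster_radius_nm must be > 0")
        if self.fraction_clustered > 0 and self.mean_occupancy < 3:
            raise QSMLMError(
                "mean_occupancy must be >= 3 when fraction_clustered > 0: "
                "a cluster is defined as more than two molecules"
            )

    @property
    def side_nm(self) -> float:
        return float(np.sqrt(self.roi_area_um2) * 1000.0)


@dataclass
class GroundTruthPattern:
    """Simulated molecule positions with cluster labels.

    ``labels[i] == 0`` marks a monomer; ``labels[i] == k >= 1`` marks
    membership in cluster ``k``.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    params: PatternParams

    @property
    def n_molecules(self) -> int:
        return self.x.size

    @property
    def side_nm(self) -> float:
        return self.params.side_nm

    @property
    def true_fraction_clustered(self) -> float:
        if self.n_molecules == 0:
            return 0.0
        return float(np.mean(self.labels >= 1))


@dataclass(frozen=True)
class BlinkModel:
    """Photophysics of a probe: blinking, precision, and photon statistics.

    ``alpha`` is the mean number of localizations per detected molecule; the
    blink-count law is geometric on {1, 2, ...}.  Dark times between
    appearances are geometric in frames with mean ``mean_dark_s``.  The
    per-localization precision is lognormal with the given median and
    geometric SD; photons likewise.
    """

    alpha: float = 5.0
    detection_prob: float = 1.0
    mean_dark_s: float = 0.5
    precision_median_nm: float = 15.0
    precision_gsd: float = 1.4
    photon_median: float = 2000.0
    photon_gsd: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise QSMLMError("alpha must be >= 1")
        if not 0 < self.detection_prob <= 1:
            raise QSMLMError("detection_prob must be in (0, 1]")


#: PALM conditions: paGFP, 100 ms frames, alpha ~ 5
PALM_ACQ = AcquisitionMeta(
    frame_time=0.1, fov=(27_000.0, 27_000.0), fluorophore="paGFP", alpha=5.0, n_frames=15_000
)
#: dSTORM conditions: AF647-labelled antibody, 10 ms frames, alpha ~ 3
DSTORM_ACQ = AcquisitionMeta(
    frame_time=0.01, fov=(41_000.0, 41_000.0), fluorophore="AF647", alpha=3.0, n_frames=30_000
)

PAGFP_BLINK = BlinkModel(alpha=5.0, precision_median_nm=15.0)
AF647_BLINK = BlinkModel(alpha=3.0, precision_median_nm=10.0)


def truncated_poisson_mean(mean: float, min_value: int = 3) -> float:
    """Mean of a Poisson(mean) conditioned on being >= min_value."""
    k = np.arange(min_value)
    pmf = stats.poisson.pmf(k, mean)
    tail = 1.0 - pmf.sum()
    if tail <= 0:
        raise QSMLMError("truncated Poisson mean underflow")
    return float((mean - (k * pmf).sum()) / tail)


def _sample_truncated_poisson(rng: np.random.Generator, mean: float, size: int, min_value: int = 3) -> np.ndarray:
    """Rejection-sample Poisson(mean) conditioned on >= min_value."""
    out = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        draw = rng.poisson(mean, size=max(2 * (size - filled), 16))
        draw = draw[draw >= min_value]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_pattern(params: PatternParams) -> GroundTruthPattern:
    """Draw a ground-truth receptor pattern from :class:`PatternParams`.

    The number of clusters is Poisson with mean chosen so that the expected
    number of clustered molecules equals ``phi * density * area``; monomer
    count is Poisson with the complementary mean.  Fully reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    side = params.side_nm
    n_expected = params.density_per_um2 * params.roi_area_um2

    xs, ys, labels = [], [], []
    if params.fraction_clustered > 0:
        occ_mean = truncated_poisson_mean(params.mean_occupancy)
        n_clusters = rng.poisson(params.fraction_clustered * n_expected / occ_mean)
        if n_clusters > 0:
            occupancies = _sample_truncated_poisson(rng, params.mean_occupancy, n_clusters)
            centers = rng.uniform(0, side, size=(n_clusters, 2))
            total = int(occupancies.sum())
            cid = np.repeat(np.arange(1, n_clusters + 1), occupancies)
            disp = rng.normal(0, params.cluster_radius_nm, size=(total, 2))
            pos = centers[cid - 1] + disp
            xs.append(pos[:, 0] % side)
            ys.append(pos[:, 1] % side)
            labels.append(cid)
    n_mono = rng.poisson((1.0 - params.fraction_clustered) * n_expected)
    if n_mono > 0:
        mono = rng.uniform(0, side, size=(n_mono, 2))
        xs.append(mono[:, 0])
        ys.append(mono[:, 1])
        labels.append(np.zeros(n_mono, dtype=np.int64))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        lab = np.concatenate(labels)
    else:  # pathologically small expected counts
        x = y = np.empty(0)
        lab = np.empty(0, dtype=np.int64)
    return GroundTruthPattern(x=x, y=y, labels=lab, params=params)


def _group_cumsum(values: np.ndarray, group_starts: np.ndarray) -> np.ndarray:
    """Cumulative sum restarted at each index in group_starts."""
    cs = np.cumsum(values)
    offsets = np.zeros_like(cs)
    offsets[group_starts] = cs[group_starts] - values[group_starts]
    # propagate each group's offset forward
    offsets = np.maximum.accumulate(offsets)
    return cs - offsets


def simulate_blinking(
    pattern: GroundTruthPattern, blink: BlinkModel, acq: AcquisitionMeta
) -> pd.DataFrame:
    """Image a ground-truth pattern through the blinking model.

    Returns a localization table (native dialect) sorted by frame.  The
    molecule of origin of every localization is recorded in the
    ``molecule`` column (dropped by file round-trips; for validation only).
    """
    rng = np.random.default_rng(blink.seed)
    n = pattern.n_molecules
    detected = rng.random(n) < blink.detection_prob
    idx = np.flatnonzero(detected)
    if idx.size == 0:
        return pd.DataFrame(columns=["x_nm", "y_nm", "frame", "photons", "sigma_nm", "channel", "molecule"])

    k = rng.geometric(1.0 / blink.alpha, size=idx.size)
    total = int(k.sum())
    mol = np.repeat(idx, k)

    mean_dark_frames = max(blink.mean_dark_s / acq.frame_time, 1.0)
    gaps = rng.geometric(1.0 / mean_dark_frames, size=total)
    starts = np.zeros(total, dtype=bool)
    starts[np.cumsum(k)[:-1]] = True
    starts[0] = True
    start_idx = np.flatnonzero(starts)
    gaps[start_idx] = 0
    first = rng.integers(0, acq.n_frames, size=idx.size)
    frames = np.repeat(first, k) + _group_cumsum(gaps, start_idx)

    keep = frames < acq.n_frames
    mol, frames = mol[keep], frames[keep]
    m = mol.size
    sigma = rng.lognormal(np.log(blink.precision_median_nm), np.log(blink.precision_gsd), size=m)
    noise = rng.normal(0.0, 1.0, size=(m, 2)) * sigma[:, None]
    side = pattern.side_nm
    x = (pattern.x[mol] + noise[:, 0]) % side
    y = (pattern.y[mol] + noise[:, 1]) % side
    photons = rng.lognormal(np.log(blink.photon_median), np.log(blink.photon_gsd), size=m)

    df = pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": y,
            "frame": frames.astype(np.int64),
            "photons": photons,
            "sigma_nm": sigma,
            "channel": acq.fluorophore,
            "molecule": mol,
        }
    )
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: Named acquisition scenarios.  The clustered presets qualitatively mirror
#: an untreated membrane ("steady_state": low clustered fraction, small
#: clusters), a single crosslinking treatment ("mab_single"), and a
#: combination treatment ("mab_combo": high clustered fraction, larger and
#: more occupied clusters).  "csr" is the null: monomers only.
SCENARIOS: dict[str, dict] = {
    "csr": dict(
        pattern=PatternParams(fraction_clustered=0.0),
        blink=PAGFP_BLINK,
        acq=PALM_ACQ,
    ),
    "steady_state": dict(
        pattern=PatternParams(fraction_clustered=0.2, cluster_radius_nm=70.0, mean_occupancy=6.0),
        blink=PAGFP_BLINK,
        acq=PALM_ACQ,
    ),
    "mab_single": dict(
        pattern=PatternParams(fraction_clustered=0.5, cluster_radius_nm=80.0, mean_occupancy=8.0),
        blink=PAGFP_BLINK,
        acq=PALM_ACQ,
    ),
    "mab_combo": dict(
        pattern=PatternParams(fraction_clustered=0.75, cluster_radius_nm=100.0, mean_occupancy=12.0),
        blink=PAGFP_BLINK,
        acq=PALM_ACQ,
    ),
    "dstorm_steady": dict(
        pattern=PatternParams(fraction_clustered=0.2, cluster_radius_nm=70.0, mean_occupancy=6.0),
        blink=AF647_BLINK,
        acq=DSTORM_ACQ,
    ),
}


def make_scenario(
    name: str, seed: int
) -> tuple[GroundTruthPattern, pd.DataFrame, dict]:
    """Generate a preset pattern + localization table pair, reproducibly.

    Two independent integer streams (pattern and blinking) are derived from
    *seed* via :class:`numpy.random.SeedSequence`, so the same (name, seed)
    always yields the same table on any platform.

    Returns
    -------
    (pattern, table, meta)
        *meta* records the full parameter set (JSON-serializable).
    """
    try:
        preset = SCENARIOS[name]
    except KeyError:
        raise ScenarioError(
            f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
        ) from None
    s_pat, s_blk = (int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(2))
    params = replace(preset["pattern"], seed=s_pat)
    blink = replace(preset["blink"], seed=s_blk)
    acq: AcquisitionMeta = preset["acq"]
    pattern = generate_pattern(params)
    table = simulate_blinking(pattern, blink, acq)
    meta = {
        "scenario": name,
        "seed": seed,
        "pattern": asdict(params),
        "blink": asdict(blink),
        "acq": {
            "frame_time": acq.frame_time,
            "fov": list(acq.fov),
            "fluorophore": acq.fluorophore,
            "alpha": acq.alpha,
            "n_frames": acq.n_frames,
        },
    }
    return pattern, table, meta


def write_scenario(name: str, seed: int, out_dir) -> None:
    """Materialize a scenario on disk: locs.csv, truth.csv, meta.json."""
    from pathlib import Path

    from .io import write_localizations

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pattern, table, meta = make_scenario(name, seed)
    write_localizations(table, out / "locs.csv")
    pd.DataFrame(
        {"x_nm": pattern.x, "y_nm": pattern.y, "cluster_label": pattern.labels}
    ).to_csv(out / "truth.csv", index=False)
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
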