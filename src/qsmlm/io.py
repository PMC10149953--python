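"""Localization-table I/O, fiducial detection, and lateral drift correction.

The package's universal currency is the *localization table*: a
:class:`pandas.DataFrame` with one row per detected fluorophore appearance
(a "blink") and the columns

========== =========================================================
column      meaning
========== =========================================================
``x_nm``    lateral position, nanometres, single global frame
``y_nm``    lateral position, nanometres
``frame``   acquisition frame index (integer >= 0)
``photons`` detected photon count (> 0; NaN when the source file
            did not report photons)
``sigma_nm`` lateral localization precision sigma_loc, nanometres (> 0)
``channel`` fluorophore label, e.g. ``"paGFP"`` or ``"AF647"``
========== =========================================================

Coordinates stay continuous (no pixel grid) until an image is rendered.
Files are plain CSV with a header row; the native dialect uses exactly the
column names above.  A column-mapping dialect mechanism accepts exports from
common localization software (e.g. ThunderSTORM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FormatError, ParseError, QSMLMError

#: canonical column order of the native dialect
LOC_COLUMNS = ["x_nm", "y_nm", "frame", "photons", "sigma_nm", "channel"]

#: columns that must be present (photons and channel are optional)
REQUIRED_COLUMNS = ["x_nm", "y_nm", "frame", "sigma_nm"]

#: built-in reader dialects: maps file column name -> canonical name
DIALECTS: dict[str, dict[str, str]] = {
    "qsmlm": {c: c for c in LOC_COLUMNS},
    # ThunderSTORM default CSV export
    "thunderstorm": {
        "x [nm]": "x_nm",
        "y [nm]": "y_nm",
        "frame": "frame",
        "intensity [photon]": "photons",
        "uncertainty [nm]": "sigma_nm",
    },
}


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata needed to interpret a localization table.

    Parameters
    ----------
    frame_time
        Seconds per camera frame (0.1 for the PALM conditions, 0.01 for
        dSTORM).
    fov
        Field-of-view (width, height) in nm.
    fluorophore
        Label of the probe, e.g. ``"paGFP"`` or ``"AF647"``.
    alpha
        Mean number of localizations per molecule for this probe and
        imaging condition (blinking constant used for counting;
        approximately 5 for paGFP and 3 for AF647).
    n_frames
        Number of frames in the acquisition.
    """

    frame_time: float
    fov: tuple[float, float]
    fluorophore: str
    alpha: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise QSMLMError("frame_time must be > 0")
        if self.alpha < 1:
            raise QSMLMError("alpha must be >= 1")
        if self.n_frames < 1:
            raise QSMLMError("n_frames must be >= 1")


@dataclass
class FiducialTrack:
    """A persistent bright emitter (bead) tracked across the acquisition."""

    bead_id: int
    frames: np.ndarray          # frames where the bead was detected
    x: np.ndarray               # per-detected-frame mean x, nm
    y: np.ndarray
    presence: float             # detected frames / total frames, in (0, 1]
    indices: np.ndarray = field(repr=False, default=None)  # member row labels

    @property
    def center(self) -> tuple[float, float]:
        return float(np.mean(self.x)), float(np.mean(self.y))


def _coerce_numeric(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Convert columns to float, raising ParseError with the first bad row."""
    for col in cols:
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = converted
    return df


def validate_localizations(
    df: pd.DataFrame, fov: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Drop rows violating the table invariants; record the count.

    Invariants: finite coordinates, ``sigma_nm`` > 0, integral ``frame`` >= 0,
    ``photons`` > 0 where reported, and (if *fov* is given) coordinates inside
    ``[0, fov]``.  The number of dropped rows is stored in
    ``df.attrs["n_rejected"]``.
    """
    ok = (
        np.isfinite(df["x_nm"])
        & np.isfinite(df["y_nm"])
        & (df["sigma_nm"] > 0)
        & (df["frame"] >= 0)
        & (df["frame"] == np.floor(df["frame"]))
    )
    ok &= df["photons"].isna() | (df["photons"] > 0)
    if fov is not None:
        ok &= (
            (df["x_nm"] >= 0)
            & (df["x_nm"] <= fov[0])
            & (df["y_nm"] >= 0)
            & (df["y_nm"] <= fov[1])
        )
    n_rejected = int((~ok).sum())
    out = df.loc[ok].reset_index(drop=True)
    out["frame"] = out["frame"].astype(np.int64)
    out.attrs["n_rejected"] = n_rejected
    return out


def read_localizations(
    path,
    dialect: str = "qsmlm",
    column_map: dict[str, str] | None = None,
    fov: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Read a localization CSV into a validated table.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Name of a built-in column mapping (see :data:`DIALECTS`).
    column_map
        Explicit ``{file column: canonical column}`` mapping overriding the
        dialect; use this for software exports not covered by a built-in.
    fov
        Optional declared field of view (nm); rows outside it are rejected.

    Returns
    -------
    pandas.DataFrame
        Canonical table; ``attrs["n_rejected"]`` counts dropped invalid rows.
    """
    if column_map is None:
        try:
            column_map = DIALECTS[dialect]
        except KeyError:
            raise FormatError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    df = pd.read_csv(path)
    df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    if "photons" not in df.columns:
        df["photons"] = np.nan
    if "channel" not in df.columns:
        df["channel"] = "unknown"
    df = df[LOC_COLUMNS]
    df = _coerce_numeric(df, ["x_nm", "y_nm", "frame", "photons", "sigma_nm"])
    df["channel"] = df["channel"].astype(str)
    return validate_localizations(df, fov=fov)


def write_localizations(df: pd.DataFrame, path) -> None:
    """Write a table in the native CSV dialect (full float precision)."""
    df.to_csv(path, index=False, columns=LOC_COLUMNS)


def detect_fiducials(
    table: pd.DataFrame,
    min_presence: float = 0.5,
    search_radius: float = 100.0,
    n_frames: int | None = None,
) -> list[FiducialTrack]:
    """Find fiducial beads: emitters persistent at one position.

    A bead is a group of localizations recurring within *search_radius* of a
    common position in at least ``min_presence`` of all frames.  Blinking
    fluorophores appear for only a handful of frames and never qualify under
    the default threshold.

    Parameters
    ----------
    table
        Localization table (non-empty).
    min_presence
        Minimum fraction of frames in which the emitter must be detected.
    search_radius
        Linking radius around the candidate position, nm.
    n_frames
        Total frames of the acquisition; defaults to ``max(frame) + 1``.

    Returns
    -------
    list of FiducialTrack
        One track per qualifying bead (possibly empty).  Each track records
        the row labels of its member localizations so they can be removed
        from downstream analysis with :func:`remove_fiducials`.
    """
    if len(table) == 0:
        raise QSMLMError("cannot detect fiducials in an empty table")
    if not 0 < min_presence <= 1:
        raise QSMLMError("min_presence must be in (0, 1]")
    total = int(n_frames) if n_frames is not None else int(table["frame"].max()) + 1
    xy = table[["x_nm", "y_nm"]].to_numpy(float)
    frames = table["frame"].to_numpy()
    tree = cKDTree(xy)

    # coarse candidate cells; a bead split across at most 4 adjacent cells
    # still keeps >= 1/4 of its detections in one cell
    cells = pd.DataFrame(
        {"gx": np.floor(xy[:, 0] / search_radius), "gy": np.floor(xy[:, 1] / search_radius)}
    )
    counts = cells.groupby(["gx", "gy"]).size().sort_values(ascending=False)
    min_count = 0.25 * min_presence * total
    tracks: list[FiducialTrack] = []
    centers: list[np.ndarray] = []
    for (gx, gy), cnt in counts.items():
        if cnt < min_count:
            break
        center = np.array([(gx + 0.5) * search_radius, (gy + 0.5) * search_radius])
        # refine the center on the member localizations
        for _ in range(3):
            idx = tree.query_ball_point(center, search_radius)
            if not idx:
                break
            center = xy[idx].mean(axis=0)
        if not idx:
            continue
        if any(np.hypot(*(center - c)) < search_radius for c in centers):
            continue  # same bead found from an adjacent cell
        member_frames = frames[idx]
        presence = np.unique(member_frames).size / total
        if presence < min_presence:
            continue
        members = table.iloc[idx]
        per_frame = members.groupby("frame")[["x_nm", "y_nm"]].mean()
        tracks.append(
            FiducialTrack(
                bead_id=len(tracks),
                frames=per_frame.index.to_numpy(),
                x=per_frame["x_nm"].to_numpy(),
                y=per_frame["y_nm"].to_numpy(),
                presence=float(presence),
                indices=members.index.to_numpy(),
            )
        )
        centers.append(np.asarray(center))
    return tracks


def remove_fiducials(table: pd.DataFrame, tracks: list[FiducialTrack]) -> pd.DataFrame:
    """Return the table without any localization belonging to a track."""
    if not tracks:
        return table
    drop = np.concatenate([t.indices for t in tracks])
    return table.drop(index=pd.Index(drop).unique())


def correct_drift(
    table: pd.DataFrame,
    tracks: list[FiducialTrack],
    smooth_window: int = 100,
    n_frames: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract lateral stage drift estimated from fiducial tracks.

    The per-frame drift is the average displacement of all beads relative to
    their mean position over the first *smooth_window* frames, smoothed with
    a centered rolling mean of the same window, linearly interpolated where a
    bead was not detected, and anchored so that the first window has zero
    mean drift.

    Returns
    -------
    (table, drift)
        The corrected table (same rows, shifted coordinates) and a drift
        trace DataFrame with columns ``frame``, ``dx_nm``, ``dy_nm``.
    """
    if not tracks:
        raise QSMLMError(
            "no fiducial tracks given; to analyse without drift correction, "
            "skip correct_drift explicitly"
        )
    if smooth_window < 1:
        raise QSMLMError("smooth_window must be >= 1")
    total = int(n_frames) if n_frames is not None else int(table["frame"].max()) + 1
    all_frames = pd.RangeIndex(total)
    per_track = []
    for t in tracks:
        s = pd.DataFrame({"x": t.x, "y": t.y}, index=t.frames)
        s = s[~s.index.duplicated()].reindex(all_frames)
        s = s.interpolate(method="linear", limit_direction="both")
        ref = s.iloc[: min(smooth_window, len(s))].mean()
        per_track.append(s - ref)
    drift = sum(per_track) / len(per_track)
    drift = drift.rolling(smooth_window, center=True, min_periods=1).mean()
    drift -= drift.iloc[: min(smooth_window, len(drift))].mean()

    out = table.copy()
    f = out["frame"].to_numpy()
    f = np.clip(f, 0, total - 1)
    out["x_nm"] = out["x_nm"].to_numpy() - drift["x"].to_numpy()[f]
    out["y_nm"] = out["y_nm"].to_numpy() - drift["y"].to_numpy()[f]
    trace = pd.DataFrame(
        {"frame": np.arange(total), "dx_nm": drift["x"].to_numpy(), "dy_nm": drift["y"].to_numpy()}
    )
    return out, trace
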