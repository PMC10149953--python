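"""Localization filtering, ROI selection, and binary rendering.

Analysis proceeds on rectangular regions of interest (ROIs) of 10-18 um^2
placed across a cell.  Before any spatial statistic, localizations whose
precision lies beyond the 98th percentile of the acquisition are discarded
as noise; an optional minimum-photon filter reproduces the upstream
detection threshold.  For pair-correlation analysis the in-ROI
localizations are *binarized* onto a pixel grid: a pixel is set iff at
least one localization center falls inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PlacementError, QSMLMError

#: default ROI area bounds, um^2 (config-overridable)
ROI_AREA_RANGE = (10.0, 18.0)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle, nm coordinates, half-open on the max edges."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise QSMLMError("ROI must have positive extent")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area_um2(self) -> float:
        return self.width * self.height / 1e6

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # closed on the max boundary: a point exactly on it belongs to the
        # last pixel (see render_binary)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def overlaps(self, other: "ROI") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass
class RenderedImage:
    """Binary occupancy grid of a ROI.

    ``grid[iy, ix]`` is True iff at least one localization center fell in
    pixel ``[origin + i*p, origin + (i+1)*p)``; the pixel holding the max
    boundary is closed above.
    """

    grid: np.ndarray          # bool, shape (ny, nx)
    pixel_size: float         # nm
    origin: tuple[float, float]  # (x0, y0), nm

    @property
    def n_set(self) -> int:
        return int(self.grid.sum())


def filter_precision(table: pd.DataFrame, percentile: float = 98.0) -> pd.DataFrame:
    """Remove noise localizations with precision beyond a percentile cutoff.

    The cutoff is the *percentile*-th value of ``sigma_nm`` under the
    linear-interpolation percentile definition (NumPy's default): for
    precisions 1..100 nm the 98th percentile is 98.02 nm, retaining 98 of
    the 100 localizations.  The cutoff used is recorded in
    ``attrs["precision_cutoff_nm"]``; re-applying the filter at the same
    percentile is a no-op (idempotent).
    """
    if len(table) == 0:
        raise QSMLMError("cannot filter an empty table")
    if not 0 < percentile <= 100:
        raise QSMLMError("percentile must be in (0, 100]")
    cutoff = float(np.percentile(table["sigma_nm"].to_numpy(), percentile))
    out = table.loc[table["sigma_nm"] <= cutoff].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    out.attrs["precision_cutoff_nm"] = cutoff
    return out


def filter_photons(table: pd.DataFrame, min_photons: float = 700.0) -> pd.DataFrame:
    """Retain localizations with at least *min_photons* detected photons.

    Matches the upstream detection threshold (700 photons minimum); the
    boundary is inclusive.  Rows with unreported (NaN) photon counts are
    kept — they carry no evidence either way.
    """
    keep = table["photons"].isna() | (table["photons"] >= min_photons)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def _snap_up(value: float, step: float) -> float:
    return float(np.ceil(value / step - 1e-9) * step)


def select_rois(
    table: pd.DataFrame,
    n_rois: int,
    area_um2: float = 16.0,
    strategy: str = "grid",
    min_locs: int = 100,
    seed: int | None = None,
    fov: tuple[float, float] | None = None,
    rects: list[tuple[float, float, float, float]] | None = None,
    pixel_size: float = 10.0,
    area_range: tuple[float, float] = ROI_AREA_RANGE,
) -> list[ROI]:
    """Place non-overlapping square ROIs containing enough localizations.

    Strategies: ``"grid"`` tiles the bounding region row-major and keeps
    qualifying tiles; ``"random"`` rejection-samples positions with the
    given *seed*; ``"manual"`` validates explicit *rects*.  ROI sides are
    snapped up to a multiple of *pixel_size* so a rendered grid covers the
    ROI exactly.

    Raises
    ------
    PlacementError
        If fewer than *n_rois* qualifying non-overlapping ROIs exist; the
        message reports how many could be placed.
    """
    if n_rois < 1:
        raise QSMLMError("n_rois must be >= 1")
    if strategy == "manual":
        if not rects:
            raise QSMLMError("manual strategy requires explicit rects")
        rois = [ROI(*r) for r in rects[:n_rois]]
    else:
        if not area_range[0] <= area_um2 <= area_range[1]:
            raise QSMLMError(
                f"ROI area {area_um2} um^2 outside allowed range {area_range}"
            )
        side = _snap_up(np.sqrt(area_um2) * 1000.0, pixel_size)
        x = table["x_nm"].to_numpy()
        y = table["y_nm"].to_numpy()
        if fov is not None:
            bounds = (0.0, 0.0, fov[0], fov[1])
        else:
            bounds = (x.min(), y.min(), x.max(), y.max())

        def count(roi: ROI) -> int:
            return int(roi.contains(x, y).sum())

        rois = []
        if strategy == "grid":
            ny = int((bounds[3] - bounds[1]) // side)
            nx = int((bounds[2] - bounds[0]) // side)
            for iy in range(ny):
                for ix in range(nx):
                    r = ROI(
                        bounds[0] + ix * side,
                        bounds[1] + iy * side,
                        bounds[0] + (ix + 1) * side,
                        bounds[1] + (iy + 1) * side,
                    )
                    if count(r) >= min_locs:
                        rois.append(r)
                    if len(rois) == n_rois:
                        break
                if len(rois) == n_rois:
                    break
        elif strategy == "random":
            rng = np.random.default_rng(seed)
            tries = 0
            while len(rois) < n_rois and tries < 2000 * n_rois:
                tries += 1
                rx = rng.uniform(bounds[0], max(bounds[2] - side, bounds[0]))
                ry = rng.uniform(bounds[1], max(bounds[3] - side, bounds[1]))
                r = ROI(rx, ry, rx + side, ry + side)
                if any(r.overlaps(o) for o in rois):
                    continue
                if count(r) >= min_locs:
                    rois.append(r)
        else:
            raise QSMLMError(f"unknown strategy {strategy!r}")

    if len(rois) < n_rois:
        raise PlacementError(
            f"could only place {len(rois)} of {n_rois} requested ROIs "
            f"with >= {min_locs} localizations"
        )
    return rois


def render_binary(
    table: pd.DataFrame, roi: ROI, pixel_size: float = 10.0
) -> RenderedImage:
    """Binarize localization centers onto a pixel grid covering the ROI.

    Pixels are half-open ``[i*p, (i+1)*p)``; a localization exactly on the
    ROI's max boundary is assigned to the last pixel.  Localizations
    outside the ROI are ignored.  Binarization records occupancy, not
    counts: several localizations in one pixel set it once.
    """
    if pixel_size <= 0:
        raise QSMLMError("pixel_size must be > 0")
    nx = int(np.ceil(roi.width / pixel_size - 1e-9))
    ny = int(np.ceil(roi.height / pixel_size - 1e-9))
    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    inside = roi.contains(x, y)
    ix = np.minimum(((x[inside] - roi.x0) / pixel_size).astype(np.int64), nx - 1)
    iy = np.minimum(((y[inside] - roi.y0) / pixel_size).astype(np.int64), ny - 1)
    grid = np.zeros((ny, nx), dtype=bool)
    grid[iy, ix] = True
    return RenderedImage(grid=grid, pixel_size=float(pixel_size), origin=(roi.x0, roi.y0))
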