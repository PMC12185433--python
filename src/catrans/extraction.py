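"""Disk-ROI fluorescence extraction and dF/F conversion.

Each manually selected soma center defines a fixed disk ROI of radius 5 px;
the cell's fluorescence F_ij is the mean luminance over the disk in each
frame, and dF/F is (F_ij - F_i0)/F_i0 with F_i0 the median fluorescence of
the cell over all frames.  Because the baseline is the median, dF/F can
fluctuate below zero; that is expected and does not indicate
hyperpolarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidRoiError
from .movie import Movie

DEFAULT_ROI_RADIUS_PX = 5.0


@dataclass
class CellROI:
    cell_id: object
    center: tuple[float, float]  # (x, y) pixels
    radius_px: float
    mask: tuple[np.ndarray, np.ndarray]  # (rows, cols) index arrays
    clipped: bool = False

    @property
    def n_pixels(self) -> int:
        return len(self.mask[0])


@dataclass
class FluorescenceMatrix:
    F: np.ndarray  # cells x frames
    frame_duration_s: float
    cell_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be cells x frames")
        if not self.cell_ids:
            self.cell_ids = list(range(self.F.shape[0]))


@dataclass
class DffTrace:
    """Per-cell dF/F with the defining baseline and its dispersion.

    ``sd`` is the SD of each cell's full-session raw (unsmoothed) dF/F
    series, events included; it is the scale against which both the 1.96-SD
    detection threshold and the +-1-SD baseline gate are expressed.
    """

    dff: np.ndarray          # cells x frames
    f0: np.ndarray           # per-cell median raw fluorescence
    sd: np.ndarray           # per-cell SD of dF/F
    frame_duration_s: float
    cell_ids: list = field(default_factory=list)
    excluded_cells: list = field(default_factory=list)  # (cell_id, reason)

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def disk_mask(center: tuple[float, float], radius_px: float,
              image_shape: tuple[int, int]) -> tuple[tuple[np.ndarray, np.ndarray], bool]:
    """Integer pixels whose center lies within ``radius_px`` of ``center``.

    Membership uses squared distances, exact for integer centers/radii.
    Returns the (rows, cols) index arrays and whether clipping at the image
    border removed any pixel.
    """
    cx, cy = center
    h, w = image_shape
    r = float(radius_px)
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    px, py = np.meshgrid(xs, ys)
    inside = (px - cx) ** 2 + (py - cy) ** 2 <= r * r
    rows, cols = py[inside], px[inside]
    in_img = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    clipped = bool((~in_img).any())
    return (rows[in_img], cols[in_img]), clipped


def build_rois(centers: pd.DataFrame | np.ndarray,
               radius_px: float = DEFAULT_ROI_RADIUS_PX,
               image_shape: tuple[int, int] | None = None) -> list[CellROI]:
    """Build disk ROIs from a table of manually selected centers.

    ``centers`` is either an (n, 2) array of (x, y) or a DataFrame with
    columns ``cell_id, x_px, y_px``.  Centers must lie inside the image;
    duplicates are rejected; masks extending past the border are clipped
    with a warning.
    """
    if image_shape is None:
        raise InvalidRoiError("image_shape is required")
    if isinstance(centers, pd.DataFrame):
        ids = list(centers["cell_id"])
        xy = centers[["x_px", "y_px"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(centers, dtype=float).reshape(-1, 2)
        ids = list(range(len(xy)))
    if len(np.unique(xy, axis=0)) != len(xy):
        raise InvalidRoiError("duplicate cell centers")
    h, w = image_shape
    rois = []
    for cid, (cx, cy) in zip(ids, xy):
        if not (0 <= cx < w and 0 <= cy < h):
            raise InvalidRoiError(f"cell {cid}: center ({cx}, {cy}) outside image {image_shape}")
        mask, clipped = disk_mask((cx, cy), radius_px, image_shape)
        if len(mask[0]) == 0:
            raise InvalidRoiError(f"cell {cid}: empty mask")
        if clipped:
            warnings.warn(f"cell {cid}: ROI clipped at image border", stacklevel=2)
        rois.append(CellROI(cell_id=cid, center=(cx, cy), radius_px=radius_px,
                            mask=mask, clipped=clipped))
    return rois


def extract_fluorescence(movie: Movie, rois: list[CellROI]) -> FluorescenceMatrix:
    """Mean luminance inside each disk, per frame."""
    if not rois:
        raise InvalidRoiError("no ROIs given")
    F = np.empty((len(rois), movie.n_frames))
    data = movie.data.astype(float)
    for i, roi in enumerate(rois):
        if roi.n_pixels == 0:
            raise InvalidRoiError(f"cell {roi.cell_id}: empty mask")
        F[i] = data[:, roi.mask[0], roi.mask[1]].mean(axis=1)
    return FluorescenceMatrix(F=F, frame_duration_s=movie.frame_duration_s,
                              cell_ids=[r.cell_id for r in rois])


def compute_dff(fm: FluorescenceMatrix) -> DffTrace:
    """Convert raw fluorescence to dF/F about the per-cell median.

    Cells whose median fluorescence is non-positive have no defined dF/F;
    they are excluded and reported rather than propagated as NaN.
    """
    f0 = np.median(fm.F, axis=1)
    bad = f0 <= 0
    excluded = [(fm.cell_ids[i], f"non-positive median fluorescence ({f0[i]:g})")
                for i in np.flatnonzero(bad)]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} cell(s) with non-positive median fluorescence",
                      stacklevel=2)
    keep = ~bad
    F = fm.F[keep]
    f0k = f0[keep]
    dff = (F - f0k[:, None]) / f0k[:, None]
    sd = dff.std(axis=1, ddof=1)
    return DffTrace(dff=dff, f0=f0k, sd=sd, frame_duration_s=fm.frame_duration_s,
                    cell_ids=[cid for cid, k in zip(fm.cell_ids, keep) if k],
                    excluded_cells=excluded)
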