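"""Rigid in-plane motion correction.

Per-frame (x, y) translation is estimated by phase cross-correlation against
a fixed template (the mean of the first 100 frames) with 0.1-px subpixel
precision, and removed by linear-interpolation translation with
median-of-frame border fill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .movie import Movie

DEFAULT_MAX_SHIFT_PX = 20.0
TEMPLATE_FRAMES = 100


@dataclass
class ShiftSeries:
    """Estimated per-frame displacement (dx, dy) relative to the template.

    A positive dx means the frame content sits dx pixels to the right of
    where the template has it; correction translates by the negated shift.
    """

    shifts: np.ndarray  # (n_frames, 2) float, columns (dx, dy)
    template_id: str = "mean of first 100 frames"
    max_shift_px: float = DEFAULT_MAX_SHIFT_PX

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")

    def __len__(self) -> int:
        return self.shifts.shape[0]


def estimate_shifts(movie: Movie,
                    max_shift_px: float = DEFAULT_MAX_SHIFT_PX,
                    template_frames: int = TEMPLATE_FRAMES,
                    upsample_factor: int = 10) -> ShiftSeries:
    """Estimate per-frame rigid translation against a mean-image template.

    Uses cross-correlation in the Fourier domain with subpixel refinement
    (``upsample_factor=10`` gives 0.1-px precision).  Shift components are
    capped at ``max_shift_px``.  An all-constant movie has no correlation
    structure; it yields zero shifts with a warning.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate motion")
    data = movie.data.astype(float)
    if np.ptp(data) == 0:
        warnings.warn("movie is constant; returning zero shifts", stacklevel=2)
        return ShiftSeries(np.zeros((movie.n_frames, 2)), max_shift_px=max_shift_px)
    n_t = min(template_frames, movie.n_frames)
    template = data[:n_t].mean(axis=0)
    shifts = np.empty((movie.n_frames, 2))
    for j in range(movie.n_frames):
        (dy, dx), _, _ = phase_cross_correlation(
            template, data[j], upsample_factor=upsample_factor, normalization=None)
        # returned vector registers the frame onto the template, i.e. minus
        # the frame's displacement
        shifts[j] = (-dx, -dy)
    shifts = np.clip(shifts, -max_shift_px, max_shift_px)
    return ShiftSeries(shifts, template_id=f"mean of first {n_t} frames",
                       max_shift_px=max_shift_px)


def apply_shifts(movie: Movie, shifts: ShiftSeries) -> Movie:
    """Translate each frame by the negated estimated shift.

    Fractional shifts use linear interpolation; pixels entering from outside
    the field are filled with the frame median so downstream ROI means are
    not biased at the edges.  Integer shifts reproduce pixel values exactly
    in the overlap region.
    """
    if len(shifts) != movie.n_frames:
        raise ValueError(f"{len(shifts)} shifts for {movie.n_frames} frames")
    out = np.empty_like(movie.data, dtype=float)
    for j in range(movie.n_frames):
        frame = movie.data[j].astype(float)
        dx, dy = shifts.shifts[j]
        out[j] = ndimage.shift(frame, (-dy, -dx), order=1,
                               mode="constant", cval=float(np.median(frame)))
    return Movie(data=out, frame_duration_s=movie.frame_duration_s,
                 pixel_size_um=movie.pixel_size_um, source=movie.source)


def correct(movie: Movie, max_shift_px: float = DEFAULT_MAX_SHIFT_PX) -> tuple[Movie, ShiftSeries]:
    """Estimate and remove rigid motion in one call."""
    shifts = estimate_shifts(movie, max_shift_px=max_shift_px)
    return apply_shifts(movie, shifts), shifts
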