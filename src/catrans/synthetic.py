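"""Synthetic GCaMP6f-like sessions with ground truth.

The generator produces the statistical structure the downstream analysis
assumes: somata as bright Gaussian-profile disks on a dim background, calcium
transients timed as a per-window homogeneous Poisson process and convolved
with a fast-rise / slow-decay indicator kernel, additive Gaussian noise, a
slow sinusoidal baseline drift, and (for rendered movies) per-frame rigid
jitter.  Every stochastic choice is recorded in a :class:`GroundTruth` so
each pipeline stage can be scored against what was actually injected.

Units: times in seconds, rates in events per cell per 300-s window,
luminance in arbitrary camera units, transient amplitude in dF/F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError, InvalidParameterError
from .movie import DEFAULT_FRAME_DURATION_S, DEFAULT_PIXEL_SIZE_UM, Movie

#: seconds covered by one counting window
WINDOW_LENGTH_S = 300.0


@dataclass(frozen=True)
class TransientKernel:
    """Fast-indicator transient shape: difference of exponentials.

    The continuous kernel is ``exp(-t/decay) - exp(-t/rise)`` (positive for
    ``decay > rise``), discretized at the frame duration and normalized to a
    unit peak.  Defaults emulate a fast genetically encoded indicator:
    sub-frame rise, ~0.4-s decay.  ``amplitude_dff`` is the dF/F peak of a
    single transient; multi-event bursts sum linearly.
    """

    rise_time_s: float = 0.05
    decay_time_s: float = 0.4
    amplitude_dff: float = 0.5
    frame_duration_s: float = DEFAULT_FRAME_DURATION_S

    def __post_init__(self) -> None:
        for name in ("rise_time_s", "decay_time_s", "amplitude_dff", "frame_duration_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.decay_time_s <= self.rise_time_s:
            raise InvalidParameterError("decay_time_s must exceed rise_time_s")


@dataclass(frozen=True)
class SessionSpec:
    """Conditions of one simulated imaging session.

    ``rate_per_window`` holds the expected number of transients per cell in
    each consecutive 300-s window; its length sets the session's number of
    windows.  ``n_frames`` defaults to exactly covering those windows
    (1205 frames per window at the default 0.249-s frame duration).
    The seed fully determines the output.
    """

    n_cells: int = 100
    rate_per_window: tuple[float, ...] = (3.0, 3.0, 3.0, 3.0)
    frame_duration_s: float = DEFAULT_FRAME_DURATION_S
    n_frames: int | None = None
    noise_sd: float = 5.0
    drift_amplitude: float = 3.0
    baseline_f0: float = 100.0
    motion_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rate_per_window", tuple(float(r) for r in self.rate_per_window))
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if any(r < 0 for r in self.rate_per_window) or not self.rate_per_window:
            raise InvalidParameterError("rates must be non-negative and non-empty")
        if self.baseline_f0 <= 0:
            raise InvalidParameterError("baseline_f0 must be positive (dF/F undefined otherwise)")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.motion_sd_px < 0:
            raise InvalidParameterError("noise_sd, drift_amplitude, motion_sd_px must be >= 0")
        if self.frame_duration_s <= 0:
            raise InvalidParameterError("frame_duration_s must be positive")
        if self.n_frames is None:
            object.__setattr__(self, "n_frames", self.n_windows * self.frames_per_window)
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")

    @property
    def n_windows(self) -> int:
        return len(self.rate_per_window)

    @property
    def frames_per_window(self) -> int:
        """Frames spanning one 300-s window (1205 at 0.249 s/frame)."""
        return int(round(WINDOW_LENGTH_S / self.frame_duration_s))


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    event_times: list[np.ndarray]          # per cell, onset frame indices, sorted
    shifts: np.ndarray                     # (n_frames, 2) float, (dx, dy) pixels
    cell_centers: np.ndarray | None = None  # (n_cells, 2) float, (x, y) pixels

    def total_events(self) -> int:
        return int(sum(len(t) for t in self.event_times))

    def events_per_window(self, frames_per_window: int, n_windows: int) -> np.ndarray:
        """Tally injected onsets into complete windows: cells x windows."""
        counts = np.zeros((len(self.event_times), n_windows), dtype=int)
        for i, times in enumerate(self.event_times):
            w = (np.asarray(times) // frames_per_window).astype(int)
            keep = w < n_windows
            np.add.at(counts[i], w[keep], 1)
        return counts


def make_kernel(kernel: TransientKernel, length_s: float | None = None) -> np.ndarray:
    """Discretize the transient kernel to a unit-peak weight sequence.

    Samples the difference of exponentials at multiples of the frame
    duration.  The sequence is non-negative, has a single maximum, and decays
    monotonically after the peak; its tail ratio between consecutive frames
    approaches ``exp(-frame_duration_s/decay_time_s)``.
    """
    if length_s is None:
        length_s = max(5.0 * kernel.decay_time_s, 3.0)
    if length_s < 5.0 * kernel.decay_time_s:
        raise InvalidParameterError("length_s must cover at least 5 decay times")
    n = int(np.ceil(length_s / kernel.frame_duration_s)) + 1
    t = np.arange(n) * kernel.frame_duration_s
    k = np.exp(-t / kernel.decay_time_s) - np.exp(-t / kernel.rise_time_s)
    peak = k.max()
    if peak <= 0:  # pragma: no cover - guarded by TransientKernel validation
        raise InvalidParameterError("kernel is degenerate: no positive peak")
    return k / peak


def _draw_event_frames(rng: np.random.Generator, spec: SessionSpec) -> np.ndarray:
    """Poisson-timed onsets for one cell, per-window rates, within n_frames."""
    fpw = spec.frames_per_window
    onsets: list[np.ndarray] = []
    for w, rate in enumerate(spec.rate_per_window):
        lo, hi = w * fpw, min((w + 1) * fpw, spec.n_frames)
        if hi <= lo:
            break
        lam = rate * (hi - lo) / fpw  # partial final window: proportional rate
        n_ev = rng.poisson(lam)
        if n_ev:
            onsets.append(rng.integers(lo, hi, size=n_ev))
    if not onsets:
        return np.empty(0, dtype=int)
    return np.sort(np.concatenate(onsets))


def simulate_traces(spec: SessionSpec,
                    kernel: TransientKernel | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Simulate raw per-cell fluorescence traces (cells x frames).

    Each trace is ``baseline_f0 + drift + amplitude_dff * baseline_f0 *
    (events (*) kernel) + N(0, noise_sd)``, with drift a one-cycle-per-session
    sinusoid of amplitude ``drift_amplitude`` and a random per-cell phase.
    One master seed spawns an independent stream per cell, so the simulation
    is reproducible cell-by-cell.
    """
    if kernel is None:
        kernel = TransientKernel(frame_duration_s=spec.frame_duration_s)
    kern = make_kernel(kernel)
    T = spec.n_frames
    streams = [np.random.Generator(np.random.PCG64(s))
               for s in np.random.SeedSequence(spec.seed).spawn(spec.n_cells)]
    F = np.empty((spec.n_cells, T))
    event_times: list[np.ndarray] = []
    tt = np.arange(T) / T
    for i, rng in enumerate(streams):
        onsets = _draw_event_frames(rng, spec)
        event_times.append(onsets)
        spikes = np.zeros(T)
        np.add.at(spikes, onsets, 1.0)
        signal = np.convolve(spikes, kern)[:T]
        phase = rng.uniform(0, 2 * np.pi)
        drift = spec.drift_amplitude * np.sin(2 * np.pi * tt + phase)
        noise = rng.normal(0.0, spec.noise_sd, T) if spec.noise_sd > 0 else 0.0
        F[i] = spec.baseline_f0 + drift + kernel.amplitude_dff * spec.baseline_f0 * signal + noise
    gt = GroundTruth(event_times=event_times, shifts=np.zeros((T, 2)))
    return F, gt


def _default_centers(n_cells: int, height: int, width: int,
                     spacing: float, margin: float) -> np.ndarray:
    xs = np.arange(margin, width - margin + 1e-9, spacing)
    ys = np.arange(margin, height - margin + 1e-9, spacing)
    grid = [(x, y) for y in ys for x in xs]
    if len(grid) < n_cells:
        raise InvalidGeometryError(
            f"field {height}x{width} fits only {len(grid)} cells at spacing {spacing}, "
            f"need {n_cells}")
    return np.array(grid[:n_cells], dtype=float)


def simulate_movie(spec: SessionSpec,
                   kernel: TransientKernel | None = None,
                   *,
                   height: int = 128,
                   width: int = 128,
                   centers: np.ndarray | None = None,
                   background: float = 20.0,
                   cell_sigma_px: float = 3.0,
                   roi_radius_px: float = 5.0,
                   pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> tuple[Movie, GroundTruth]:
    """Render simulated traces as a movie of Gaussian-profile somata.

    Each cell is an isotropic Gaussian (SD ``cell_sigma_px``, truncated at
    3 SD) whose peak luminance follows that cell's simulated trace, on a
    constant dim background.  Per-frame rigid shifts are drawn i.i.d. with SD
    ``motion_sd_px`` and applied analytically (cells rendered at displaced
    positions), so ground-truth shifts are exact.  Output luminance is
    quantized to 16-bit.
    """
    trunc = 3.0 * cell_sigma_px
    margin = trunc + 3.0 * spec.motion_sd_px + 1.0
    if centers is None:
        spacing = max(2.0 * roi_radius_px + 1.0, 2.0 * trunc + 1.0)
        centers = _default_centers(spec.n_cells, height, width, spacing, margin)
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (spec.n_cells, 2):
        raise InvalidGeometryError("centers must be (n_cells, 2)")
    if (centers[:, 0].min() < margin or centers[:, 0].max() > width - margin
            or centers[:, 1].min() < margin or centers[:, 1].max() > height - margin):
        raise InvalidGeometryError("cells too close to the field edge for the configured jitter")
    if spec.n_cells > 1:
        d = np.sqrt(((centers[None] - centers[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < 2.0 * roi_radius_px:
            raise InvalidGeometryError("cell centers closer than two ROI radii")

    traces, gt = simulate_traces(spec, kernel)
    # shift stream is the last spawn child, independent of the per-cell streams
    shift_seed = np.random.SeedSequence(spec.seed).spawn(spec.n_cells + 1)[-1]
    shift_rng = np.random.Generator(np.random.PCG64(shift_seed))
    if spec.motion_sd_px > 0:
        shifts = shift_rng.normal(0.0, spec.motion_sd_px, (spec.n_frames, 2))
    else:
        shifts = np.zeros((spec.n_frames, 2))

    yy, xx = np.mgrid[0:height, 0:width]
    data = np.full((spec.n_frames, height, width), background)
    half = int(np.ceil(trunc)) + int(np.ceil(3.0 * spec.motion_sd_px)) + 1
    for i, (cx, cy) in enumerate(centers):
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, width)
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, height)
        px = xx[y0:y1, x0:x1]
        py = yy[y0:y1, x0:x1]
        for j in range(spec.n_frames):
            dx, dy = shifts[j]
            r2 = (px - (cx + dx)) ** 2 + (py - (cy + dy)) ** 2
            prof = np.where(r2 <= trunc ** 2, np.exp(-r2 / (2.0 * cell_sigma_px ** 2)), 0.0)
            data[j, y0:y1, x0:x1] += traces[i, j] * prof

    data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    movie = Movie(data=data, frame_duration_s=spec.frame_duration_s, pixel_size_um=pixel_size_um)
    gt.shifts = shifts
    gt.cell_centers = centers
    return movie, gt
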