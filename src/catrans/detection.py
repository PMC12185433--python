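"""Calcium-transient detection, validation, and per-window counting.

The algorithm operates on each cell's dF/F trace:

1. smooth with a 5-frame centered moving average;
2. mark candidate onsets where the smoothed trace crosses 1.96 x SD of the
   cell's (raw, full-session) dF/F from below; once above threshold no new
   onset is admitted until the trace falls back below (hysteresis), so one
   transient is never counted twice;
3. validate each candidate against its local trace: the crossing is traced
   back to the *apparent onset* — the first frame of the contiguous run above
   1 x SD that leads up to the crossing — and the 8 smoothed frames (~2 s)
   before the apparent onset must all lie within +-1 SD of zero (a flat
   baseline), while the mean of the smoothed trace over the 3 s from the
   apparent onset must differ significantly (Welch two-sample two-tailed t,
   p < 0.05) from — and exceed — the baseline mean;
4. tally validated events per cell into consecutive 5-min windows by onset
   time.

Counts per cell per window are the unit of all downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidDesignError, InvalidParameterError
from .extraction import DffTrace
from .movie import DEFAULT_FRAME_DURATION_S


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection/validation algorithm.

    Defaults follow the procedure the pipeline implements: 5-frame
    smoothing, 1.96-SD threshold, 8-frame (~2 s) baseline, 3-s response
    window, alpha 0.05, 300-s counting windows.
    """

    smooth_frames: int = 5
    z_threshold: float = 1.96
    baseline_frames: int = 8
    response_window_s: float = 3.0
    alpha: float = 0.05
    window_length_s: float = 300.0

    def __post_init__(self) -> None:
        if self.smooth_frames < 1 or self.smooth_frames % 2 == 0:
            raise InvalidParameterError("smooth_frames must be odd and positive "
                                        "(even windows have no unambiguous center)")
        for name in ("z_threshold", "baseline_frames", "response_window_s",
                     "alpha", "window_length_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    def response_frames(self, frame_duration_s: float) -> int:
        """Response-window length in frames (12 at 0.249 s/frame)."""
        return int(round(self.response_window_s / frame_duration_s))

    def frames_per_window(self, frame_duration_s: float) -> int:
        return int(round(self.window_length_s / frame_duration_s))


@dataclass
class CalciumEvent:
    """One candidate transient and the outcome of its validation."""

    cell_id: object
    onset_frame: int              # apparent onset (start of the supra-1-SD run)
    onset_time_s: float
    local_trace: np.ndarray       # smoothed dF/F, baseline through response window
    baseline_ok: bool
    p_value: float
    validated: bool
    crossing_frame: int | None = None  # where the 1.96-SD threshold was crossed
    reason: str | None = None     # why validation failed / event was discarded


@dataclass
class EventCountTable:
    """Validated-event counts: cells x consecutive 5-min windows."""

    counts: np.ndarray                 # (n_cells, n_windows) int
    cell_ids: list
    groups: list                       # group label per cell
    window_labels: list[str]
    n_dropped: int = 0                 # validated events beyond the last complete window

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise InvalidDesignError("negative event counts")
        if len(self.cell_ids) != self.counts.shape[0] or len(self.groups) != self.counts.shape[0]:
            raise InvalidDesignError("cell_ids/groups length mismatch with counts")
        if len(self.window_labels) != self.counts.shape[1]:
            raise InvalidDesignError("window_labels length mismatch with counts")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    def to_long(self) -> pd.DataFrame:
        """Tidy cells x windows table (one row per cell-window) for ANOVA."""
        n, w = self.counts.shape
        return pd.DataFrame({
            "cell": np.repeat(self.cell_ids, w),
            "group": np.repeat(self.groups, w),
            "window": np.tile(self.window_labels, n),
            "count": self.counts.ravel(),
        })


def default_window_labels(n_windows: int) -> list[str]:
    return [f"{5 * k + 1}-{5 * (k + 1)} min" for k in range(n_windows)]


def smooth_trace(dff_row: np.ndarray, smooth_frames: int = 5) -> np.ndarray:
    """Centered moving average with edge truncation (length preserved)."""
    if smooth_frames < 1 or smooth_frames % 2 == 0:
        raise InvalidParameterError("smooth_frames must be odd and positive")
    x = np.asarray(dff_row, dtype=float)
    if x.size < smooth_frames:
        raise InvalidParameterError("trace shorter than the smoothing window")
    w = np.ones(smooth_frames)
    return np.convolve(x, w, mode="same") / np.convolve(np.ones_like(x), w, mode="same")


def detect_candidates(dff_row: np.ndarray, sd_cell: float,
                      config: DetectionConfig = DetectionConfig(),
                      smoothed: np.ndarray | None = None) -> np.ndarray:
    """Onset frames where the smoothed trace crosses ``z_threshold * sd_cell``.

    A crossing is a frame above threshold whose predecessor is at or below
    it; while the trace stays above threshold no further onset is admitted
    (hysteresis).  Onsets with fewer than ``baseline_frames`` preceding
    frames are discarded, since they cannot be baseline-validated.
    """
    if sd_cell < 0 or not np.isfinite(sd_cell):
        raise InvalidParameterError("sd_cell must be finite and non-negative")
    if sd_cell == 0:
        warnings.warn("zero-variance trace: no candidates", stacklevel=2)
        return np.empty(0, dtype=int)
    s = smooth_trace(dff_row, config.smooth_frames) if smoothed is None else smoothed
    above = s > config.z_threshold * sd_cell
    crossing = above.copy()
    crossing[1:] &= ~above[:-1]
    onsets = np.flatnonzero(crossing)
    return onsets[onsets >= config.baseline_frames]


def apparent_onset(smoothed: np.ndarray, crossing: int, sd_cell: float) -> int:
    """First frame of the contiguous supra-1-SD run leading to a crossing.

    A centered moving average spreads a transient backward by half its
    window, so the trace leaves the +-1-SD baseline band one or two frames
    before it crosses the detection threshold; the apparent onset is where
    that excursion begins.
    """
    j = int(crossing)
    while j > 0 and smoothed[j - 1] > sd_cell:
        j -= 1
    return j


def validate_event(dff_row: np.ndarray, onset: int, sd_cell: float,
                   frame_duration_s: float = DEFAULT_FRAME_DURATION_S,
                   config: DetectionConfig = DetectionConfig(),
                   cell_id: object = None,
                   smoothed: np.ndarray | None = None) -> CalciumEvent:
    """Validate one candidate threshold crossing against its local trace.

    ``onset`` is the candidate crossing frame from :func:`detect_candidates`;
    it is first traced back to the apparent onset of the excursion.
    ``baseline_ok`` requires every one of the ``baseline_frames`` samples
    before the apparent onset to lie within +-1 x sd_cell of zero (the dF/F
    median).  The mean over the 3-s response window from the apparent onset
    is then compared to the baseline mean with a Welch two-sample two-tailed
    t-test; the event is validated iff the baseline is flat, p < alpha, and
    the response mean exceeds the baseline mean (transients are
    positive-going).
    """
    if onset < config.baseline_frames:
        raise InvalidParameterError("onset has fewer than baseline_frames preceding frames")
    s = smooth_trace(dff_row, config.smooth_frames) if smoothed is None else smoothed
    n_resp = config.response_frames(frame_duration_s)
    crossing = int(onset)
    onset = apparent_onset(s, crossing, sd_cell)
    onset_time = onset * frame_duration_s
    if onset < config.baseline_frames:
        return CalciumEvent(cell_id, int(onset), onset_time, s[:onset + n_resp],
                            baseline_ok=False, p_value=np.nan, validated=False,
                            crossing_frame=crossing,
                            reason="insufficient pre-onset frames for baseline")
    if onset + n_resp > s.size:
        return CalciumEvent(cell_id, int(onset), onset_time,
                            s[onset - config.baseline_frames:],
                            baseline_ok=False, p_value=np.nan, validated=False,
                            crossing_frame=crossing,
                            reason="insufficient post-onset frames")
    baseline = s[onset - config.baseline_frames:onset]
    response = s[onset:onset + n_resp]
    local = s[onset - config.baseline_frames:onset + n_resp]
    baseline_ok = bool(np.all(np.abs(baseline) <= sd_cell))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_res = sps.ttest_ind(response, baseline, equal_var=False)
    p = float(t_res.pvalue)
    rises = bool(response.mean() > baseline.mean())
    validated = baseline_ok and np.isfinite(p) and p < config.alpha and rises
    reason = None
    if not validated:
        if not baseline_ok:
            reason = "baseline not flat (sample beyond 1 SD)"
        elif not np.isfinite(p) or p >= config.alpha:
            reason = "response not significantly different from baseline"
        else:
            reason = "response below baseline (negative-going)"
    return CalciumEvent(cell_id, int(onset), onset_time, local,
                        baseline_ok=baseline_ok, p_value=p, validated=validated,
                        crossing_frame=crossing, reason=reason)


def count_events(events: list[CalciumEvent], n_windows: int,
                 config: DetectionConfig = DetectionConfig(),
                 cell_ids: list | None = None,
                 groups: list | None = None) -> EventCountTable:
    """Tally validated events into half-open 5-min windows by onset time.

    Event at time t lands in window k iff t in [k*300, (k+1)*300).  Events
    beyond the last complete window are dropped and counted in
    ``n_dropped``.
    """
    validated = [e for e in events if e.validated]
    if cell_ids is None:
        cell_ids = sorted({e.cell_id for e in validated})
    if groups is None:
        groups = ["na"] * len(cell_ids)
    index = {cid: i for i, cid in enumerate(cell_ids)}
    counts = np.zeros((len(cell_ids), n_windows), dtype=int)
    dropped = 0
    for e in validated:
        if e.onset_time_s < 0:
            raise InvalidParameterError(f"negative onset time {e.onset_time_s}")
        k = int(e.onset_time_s // config.window_length_s)
        if k >= n_windows:
            dropped += 1
            continue
        counts[index[e.cell_id], k] += 1
    if dropped:
        warnings.warn(f"{dropped} validated event(s) beyond the last complete window dropped",
                      stacklevel=2)
    return EventCountTable(counts=counts, cell_ids=list(cell_ids), groups=list(groups),
                           window_labels=default_window_labels(n_windows), n_dropped=dropped)


def run_detection(dff: DffTrace,
                  config: DetectionConfig = DetectionConfig(),
                  groups: list | None = None,
                  n_windows: int | None = None) -> tuple[list[CalciumEvent], EventCountTable]:
    """Full per-session detection: smooth, detect, validate, count.

    Returns every candidate event (with its validation outcome) and the
    counts table over complete 5-min windows.  Deterministic given inputs.
    """
    if n_windows is None:
        n_windows = int(dff.n_frames * dff.frame_duration_s // config.window_length_s)
    if n_windows < 1:
        raise InvalidDesignError("session shorter than one counting window")
    events: list[CalciumEvent] = []
    for i in range(dff.n_cells):
        row = dff.dff[i]
        sd = dff.sd[i]
        if sd == 0:
            warnings.warn(f"cell {dff.cell_ids[i]}: zero-variance trace, skipped", stacklevel=2)
            continue
        s = smooth_trace(row, config.smooth_frames)
        last_onset = -1
        for crossing in detect_candidates(row, sd, config, smoothed=s):
            ev = validate_event(row, int(crossing), sd, dff.frame_duration_s,
                                config, cell_id=dff.cell_ids[i], smoothed=s)
            # two crossings separated by a dip that never returned to baseline
            # trace back to the same excursion: one transient, one event
            if ev.onset_frame == last_onset:
                continue
            last_onset = ev.onset_frame
            events.append(ev)
    table = count_events(events, n_windows, config, cell_ids=dff.cell_ids, groups=groups)
    return events, table


def events_to_frame(events: list[CalciumEvent]) -> pd.DataFrame:
    """Flatten events to a tidy table (local traces omitted)."""
    return pd.DataFrame([{
        "cell_id": e.cell_id,
        "onset_frame": e.onset_frame,
        "onset_time_s": e.onset_time_s,
        "baseline_ok": e.baseline_ok,
        "p_value": e.p_value,
        "validated": e.validated,
        "reason": e.reason,
    } for e in events])
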