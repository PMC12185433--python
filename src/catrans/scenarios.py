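"""Study-design presets: two treatment groups, two neuronal populations.

These encode the simulated analogue of the comparison the pipeline exists
for: after a subthreshold convulsant challenge, drug-treated animals show
*increased* excitatory-neuron event rates and *decreased* PV+ interneuron
event rates relative to vehicle-treated animals, with the largest effect in
the 11-15-min window (window 3 of 4).  Rates are events per cell per 5-min
window; cell counts default to the sizes of the groups being emulated
(161 vs 145 excitatory, 15 vs 24 PV+ neurons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import DetectionConfig, EventCountTable, run_detection
from .extraction import DffTrace
from .synthetic import SessionSpec, TransientKernel, simulate_traces

#: vehicle-group rate, flat across windows
CONTROL_RATES = (3.0, 3.0, 3.0, 3.0)
#: treated excitatory neurons: elevated everywhere, 2x peak in window 3
EXCITATORY_TREATED_RATES = (4.0, 4.0, 6.0, 4.0)
#: treated PV+ interneurons: reduced everywhere, 2x trough in window 3
PV_TREATED_RATES = (2.0, 2.0, 1.5, 2.5)

EXCITATORY_N = {"treated": 161, "control": 145}
PV_N = {"treated": 15, "control": 24}


@dataclass(frozen=True)
class GroupScenario:
    """One two-group session design (rates and cell counts per group)."""

    name: str
    control_rates: tuple[float, ...]
    treated_rates: tuple[float, ...]
    n_control: int
    n_treated: int


EXCITATORY = GroupScenario("excitatory", CONTROL_RATES, EXCITATORY_TREATED_RATES,
                           EXCITATORY_N["control"], EXCITATORY_N["treated"])
PV = GroupScenario("pv", CONTROL_RATES, PV_TREATED_RATES,
                   PV_N["control"], PV_N["treated"])


def dff_from_traces(F: np.ndarray, frame_duration_s: float,
                    cell_ids: list | None = None) -> DffTrace:
    """dF/F about the per-cell median, straight from a raw trace matrix."""
    f0 = np.median(F, axis=1)
    dff = (F - f0[:, None]) / f0[:, None]
    return DffTrace(dff=dff, f0=f0, sd=dff.std(axis=1, ddof=1),
                    frame_duration_s=frame_duration_s,
                    cell_ids=cell_ids or list(range(F.shape[0])))


def simulate_two_group_counts(scenario: GroupScenario, seed: int,
                              n_control: int | None = None,
                              n_treated: int | None = None,
                              kernel: TransientKernel | None = None,
                              config: DetectionConfig | None = None,
                              ) -> tuple[EventCountTable, EventCountTable]:
    """Simulate both groups' sessions and run the full detection pipeline.

    Returns (detected counts, ground-truth counts) as matching tables so
    detection can be scored against what was injected.  Group labels are
    "control" and "treated".
    """
    config = config or DetectionConfig()
    n_control = n_control if n_control is not None else scenario.n_control
    n_treated = n_treated if n_treated is not None else scenario.n_treated
    counts_parts, truth_parts, ids, labels = [], [], [], []
    for gi, (label, rates, n) in enumerate([
            ("control", scenario.control_rates, n_control),
            ("treated", scenario.treated_rates, n_treated)]):
        spec = SessionSpec(n_cells=n, rate_per_window=rates, seed=seed * 2 + gi)
        F, gt = simulate_traces(spec, kernel)
        cell_ids = [f"{label}_{i}" for i in range(n)]
        dff = dff_from_traces(F, spec.frame_duration_s, cell_ids)
        _, table = run_detection(dff, config, groups=[label] * n, n_windows=spec.n_windows)
        counts_parts.append(table.counts)
        truth_parts.append(gt.events_per_window(spec.frames_per_window, spec.n_windows))
        ids.extend(cell_ids)
        labels.extend([label] * n)
    detected = EventCountTable(np.vstack(counts_parts), ids, labels,
                               window_labels=_labels(len(scenario.control_rates)))
    truth = EventCountTable(np.vstack(truth_parts), list(ids), list(labels),
                            window_labels=_labels(len(scenario.control_rates)))
    return detected, truth


def _labels(n_windows: int) -> list[str]:
    from .detection import default_window_labels
    return default_window_labels(n_windows)


def match_events(true_onsets: np.ndarray, detected_onsets: np.ndarray,
                 tolerance_frames: int = 2) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true onsets.

    Returns (true positives, false positives, false negatives).  A detected
    onset matches an unused true onset within ``tolerance_frames``.
    """
    true_onsets = np.sort(np.asarray(true_onsets))
    detected_onsets = np.sort(np.asarray(detected_onsets))
    used = np.zeros(true_onsets.size, dtype=bool)
    tp = 0
    for d in detected_onsets:
        cand = np.flatnonzero(~used & (np.abs(true_onsets - d) <= tolerance_frames))
        if cand.size:
            used[cand[0]] = True
            tp += 1
    fp = detected_onsets.size - tp
    fn = true_onsets.size - tp
    return tp, fp, fn


def detection_f1(scenario_rates: tuple[float, ...], n_cells: int, seed: int,
                 tolerance_frames: int = 2,
                 kernel: TransientKernel | None = None,
                 config: DetectionConfig | None = None) -> dict:
    """Simulate one session and score detected onsets against ground truth.

    Detected onsets are compared to injected onsets with a +-2-frame
    tolerance, plus the smoothing half-width (a centered moving average
    advances the apparent threshold crossing by up to half its window).
    """
    config = config or DetectionConfig()
    spec = SessionSpec(n_cells=n_cells, rate_per_window=scenario_rates, seed=seed)
    F, gt = simulate_traces(spec, kernel)
    dff = dff_from_traces(F, spec.frame_duration_s)
    events, _ = run_detection(dff, config, n_windows=spec.n_windows)
    tol = tolerance_frames + config.smooth_frames // 2
    tp = fp = fn = 0
    by_cell: dict = {i: [] for i in range(n_cells)}
    for e in events:
        if e.validated:
            by_cell[e.cell_id].append(e.onset_frame)
    for i in range(n_cells):
        t, f, m = match_events(gt.event_times[i], np.asarray(by_cell[i]), tol)
        tp, fp, fn = tp + t, fp + f, fn + m
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}
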