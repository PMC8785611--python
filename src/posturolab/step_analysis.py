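"""Compensatory-step detection from single-plate unloading.

A recovery step shows up on the force plates as one plate's vertical force
dropping to (near) zero for at least 50 ms while the foot is repositioned.
Real plates never read exactly zero, so "zero pressure" is operationalised
as force at or below a small threshold (default 5 N). The repositioning
clause — the step must change the base of support — is operationalised as
the stepping plate's CoP landing at least 20 mm (default) away from where
it was before lift-off, measured as force-weighted-free plate CoP means
over short loaded windows flanking the unload interval. Brief contact
chatter at touchdown is absorbed by merging unload intervals separated by
less than 30 ms.

Strategies: 0 steps = in-place, 1 = single step, >= 2 = multiple steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SignalGapError
from .signal_io import PlateSignal

FORCE_THRESHOLD_N = 5.0
MIN_STEP_DURATION_S = 0.05
MERGE_GAP_S = 0.03
MIN_LANDING_OFFSET_MM = 20.0
OFFSET_WINDOW_S = 0.1


@dataclass(frozen=True)
class StepEvent:
    """One detected step: which foot, when, and where it landed."""

    foot: str  # 'left' | 'right'
    start_s: float
    end_s: float
    landing_offset: tuple  # (d_ap, d_ml) mm, post-reload minus pre-unload CoP

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("step end must follow its start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def offset_magnitude(self) -> float:
        return float(np.hypot(*self.landing_offset))


@dataclass
class StepAnalysis:
    """Steps found in a response window plus the derived strategy."""

    steps: list
    strategy: str
    total_displacement: float  # mm
    discarded: bool = False
    discard_reason: str = ""


def _runs(mask: np.ndarray) -> list:
    """(start, stop) index pairs of maximal True runs, stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def _merge_runs(runs: list, max_gap: int) -> list:
    merged = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def _plate_cop_mean(plate: PlateSignal, idx: np.ndarray) -> tuple | None:
    """Mean (ap, ml) CoP of a plate over loaded samples, or None if unloaded."""
    if len(idx) == 0:
        return None
    return (float(np.mean(plate.cop_y[idx])), float(np.mean(plate.cop_x[idx])))


def detect_steps(left: PlateSignal, right: PlateSignal,
                 window: tuple | None = None,
                 force_threshold_n: float = FORCE_THRESHOLD_N,
                 min_duration_s: float = MIN_STEP_DURATION_S,
                 merge_gap_s: float = MERGE_GAP_S,
                 min_offset_mm: float = MIN_LANDING_OFFSET_MM,
                 offset_window_s: float = OFFSET_WINDOW_S) -> list:
    """Detect compensatory steps within a trial-relative time window.

    Returns a time-sorted list of :class:`StepEvent`. An unload interval
    qualifies as a step when it lasts at least ``min_duration_s`` (interval
    duration = number of below-threshold samples / fs, so 6 samples at
    120 Hz is exactly the 50 ms boundary) *and* the plate's CoP after
    reloading differs from before unloading by at least ``min_offset_mm``.
    Intervals with no loaded samples afterwards (the participant stepped
    off the instrumented area) are skipped here and flagged by
    :func:`analyze_steps`.

    Raises :class:`SignalGapError` if both plates are below the force
    threshold at the same sample.
    """
    fs = left.fs
    n = left.n
    if window is None:
        i0, i1 = 0, n
    else:
        i0 = max(int(np.floor(window[0] * fs + 1e-9)), 0)
        i1 = min(int(np.ceil(window[1] * fs - 1e-9)), n)
    below_l = left.fz[i0:i1] <= force_threshold_n
    below_r = right.fz[i0:i1] <= force_threshold_n
    if np.any(below_l & below_r):
        j = i0 + int(np.argmax(below_l & below_r))
        raise SignalGapError(
            f"both plates unloaded at sample {j} (t = {j / fs:.3f} s)")

    max_gap = int(np.ceil(merge_gap_s * fs - 1e-9))
    n_off = max(int(round(offset_window_s * fs)), 1)
    events = []
    for plate, below in ((left, below_l), (right, below_r)):
        for start, stop in _merge_runs(_runs(below), max_gap):
            duration = (stop - start) / fs
            if duration < min_duration_s - 1e-9:
                continue
            a, b = i0 + start, i0 + stop
            loaded = plate.fz > force_threshold_n
            pre_idx = np.flatnonzero(loaded[:a])[-n_off:]
            post_idx = a + np.flatnonzero(loaded[a:])  # reload onwards
            post_idx = post_idx[post_idx >= b][:n_off]
            pre = _plate_cop_mean(plate, pre_idx)
            post = _plate_cop_mean(plate, post_idx)
            if pre is None or post is None:
                continue  # no reload: off-plate, handled by analyze_steps
            offset = (post[0] - pre[0], post[1] - pre[1])
            if np.hypot(*offset) < min_offset_mm:
                continue  # weight shift without base-of-support change
            events.append(StepEvent(foot=plate.plate_id, start_s=a / fs,
                                    end_s=b / fs, landing_offset=offset))
    return sorted(events, key=lambda e: e.start_s)


def classify_strategy(steps: list) -> str:
    """Map a step count to the balance-recovery strategy label."""
    if len(steps) == 0:
        return "in_place"
    if len(steps) == 1:
        return "single_step"
    return "multiple_steps"


def step_total_displacement(steps: list) -> float:
    """Sum of per-step landing-offset magnitudes (distance equation), mm."""
    return float(sum(s.offset_magnitude for s in steps))


def analyze_steps(left: PlateSignal, right: PlateSignal,
                  window: tuple | None = None, **kwargs) -> StepAnalysis:
    """Detect, classify and total the steps of one response window.

    If a plate unloads past the end of the window without reloading, the
    response is flagged discarded ("off_plate"): the participant left the
    instrumented area and the step geometry cannot be measured.
    """
    fs = left.fs
    thr = kwargs.get("force_threshold_n", FORCE_THRESHOLD_N)
    steps = detect_steps(left, right, window=window, **kwargs)
    # off-plate check: unloaded at the end of the window with no reload
    i1 = left.n if window is None else min(int(np.ceil(window[1] * fs)), left.n)
    tail = slice(max(i1 - 1, 0), i1)
    off_plate = bool((left.fz[tail] <= thr).any()
                     or (right.fz[tail] <= thr).any())
    return StepAnalysis(
        steps=steps, strategy=classify_strategy(steps),
        total_displacement=step_total_displacement(steps),
        discarded=off_plate,
        discard_reason="off_plate" if off_plate else "")
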