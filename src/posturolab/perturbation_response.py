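"""Dynamic-balance outcomes per platform perturbation.

Each perturbation is analysed over a fixed segment starting 5 s before and
ending 4.5 s after its onset. Displacement is referenced to the mean CoP of
the 5 s pre-perturbation window, so it is near zero before onset by
construction. A piecewise-linear *envelope* through the local maxima of the
absolute CoP velocity (after a zero-phase 10 Hz low-pass) summarises the
magnitude of ongoing postural activity; the participant has *recovered*
when that envelope re-enters the pre-perturbation steady-state band — mean
plus 2 SD of the pre-window envelope — and stays inside it for at least
0.5 s. Segments whose window is truncated by the trial bounds are flagged
discarded, and responses whose envelope never re-enters the band within
4.5 s are reported at 4.5 s and flagged censored.

The steady-state band parameters (k·SD multiplier and dwell time) are this
package's operationalisation of "return to steady state" and are exposed
in the analysis configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError
from .signal_io import (CoPTrajectory, DisplacementSeries, TrialRecord,
                        VelocitySeries, cop_velocity, displacement_magnitude,
                        PERTURBATION_TYPES)
from .static_sway import SwayMetrics, ellipse_area_95

PRE_WINDOW_S = 5.0
POST_WINDOW_S = 4.5


@dataclass(frozen=True)
class PerturbationEvent:
    """Onset (trial-relative seconds) and type of a platform perturbation."""

    onset_s: float
    ptype: str

    def __post_init__(self):
        if self.ptype not in PERTURBATION_TYPES:
            raise ValueError(f"unknown perturbation type '{self.ptype}'; "
                             f"expected one of {PERTURBATION_TYPES}")


@dataclass
class PerturbationSegment:
    """A clipped [-5 s, +4.5 s] analysis segment around one perturbation."""

    event: PerturbationEvent
    traj: CoPTrajectory
    d: DisplacementSeries
    v: VelocitySeries
    envelope: np.ndarray
    onset_index: int
    discarded: bool = False
    discard_reason: str = ""
    envelope_lowpass_hz: float | None = 10.0

    @property
    def fs(self) -> float:
        return self.traj.fs

    @property
    def pre_slice(self) -> slice:
        return slice(0, self.onset_index)

    @property
    def post_slice(self) -> slice:
        return slice(self.onset_index, self.traj.n)


@dataclass(frozen=True)
class RecoveryResult:
    """Detected recovery instant relative to perturbation onset."""

    time_s: float
    censored: bool
    band: float  # steady-state envelope threshold (mm/s)
    index: int  # segment sample index of the recovery instant


@dataclass
class ResponseMetrics:
    """Per-perturbation dynamic-balance outcomes."""

    recovery_time: float  # s, in (0, 4.5]; 4.5 when censored
    cop_max: float  # mm, maximal displacement after onset
    mean_recovery_velocity: float  # mm/s over [onset, recovery]
    strategy: str = "in_place"
    n_steps: int = 0
    step_total_displacement: float = 0.0  # mm
    censored: bool = False
    discarded: bool = False
    discard_reason: str = ""


def velocity_envelope(v: VelocitySeries | np.ndarray, fs: float | None = None,
                      lowpass_hz: float = 10.0) -> np.ndarray:
    """Piecewise-linear envelope through local maxima of absolute velocity.

    The velocity is first smoothed with a zero-phase 4th-order Butterworth
    low-pass (default 10 Hz) so the envelope tracks bursts of postural
    activity rather than sample-to-sample noise; the first and last samples
    anchor the interpolation so the envelope is defined everywhere.
    """
    if isinstance(v, VelocitySeries):
        arr, fs = v.v, v.fs
    else:
        arr = np.asarray(v, dtype=float)
        if fs is None:
            raise ValueError("fs is required for a bare array")
    n = len(arr)
    if n < 5:
        raise InsufficientDataError("envelope needs at least 5 samples")
    if lowpass_hz is not None and lowpass_hz < fs / 2:
        sos = sps.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        smooth = sps.sosfiltfilt(sos, arr)
        smooth = np.clip(smooth, 0.0, None)
    else:
        smooth = arr
    peaks, _ = sps.find_peaks(smooth)
    anchors = np.concatenate(([0], peaks, [n - 1]))
    anchors = np.unique(anchors)
    return np.interp(np.arange(n), anchors, smooth[anchors])


def segment_perturbation(trial: TrialRecord, event: PerturbationEvent,
                         pre_s: float = PRE_WINDOW_S,
                         post_s: float = POST_WINDOW_S,
                         envelope_lowpass_hz: float = 10.0
                         ) -> PerturbationSegment:
    """Clip and derive signals for one perturbation.

    If the [onset - pre_s, onset + post_s] window is truncated by the trial
    bounds the segment is flagged ``discarded`` (reason "technical"), with
    whatever signal exists attached for inspection.
    """
    fs = trial.fs
    start = event.onset_s - pre_s
    end = event.onset_s + post_s
    truncated = start < -0.5 / fs or end > trial.duration + 0.5 / fs
    traj = trial.combined().slice(max(start, 0.0), min(end, trial.duration))
    onset_index = int(round((event.onset_s - traj.t0) * fs))
    onset_index = min(max(onset_index, 1), traj.n - 1)
    pre_ap = traj.ap[:onset_index]
    pre_ml = traj.ml[:onset_index]
    reference = (float(np.mean(pre_ap)), float(np.mean(pre_ml)))
    d = displacement_magnitude(traj, reference=reference)
    v = cop_velocity(d)
    env = velocity_envelope(v, lowpass_hz=envelope_lowpass_hz)
    return PerturbationSegment(
        event=event, traj=traj, d=d, v=v, envelope=env,
        onset_index=onset_index, discarded=bool(truncated),
        discard_reason="technical" if truncated else "",
        envelope_lowpass_hz=envelope_lowpass_hz)


def recovery_time(seg: PerturbationSegment, band_k: float = 2.0,
                  dwell_s: float = 0.5) -> RecoveryResult:
    """Time for the velocity envelope to return to its steady-state band.

    The band is the mean plus ``band_k`` SD of the envelope over the 5 s
    pre-perturbation window, with that envelope computed on the pre-window
    in isolation so interpolation toward the large perturbation peak
    cannot leak into the resting statistics. Recovery is the first
    post-onset instant at which the segment envelope stays within the band
    continuously for ``dwell_s``. If the envelope never re-enters the band
    within the segment the time is reported as the full post-window length
    with ``censored=True``.
    """
    fs = seg.fs
    # final pre-window sample excluded: its central difference spans onset
    pre_v = seg.v.v[:max(seg.onset_index - 1, 0)]
    if len(pre_v) < 5:
        raise InsufficientDataError("no pre-perturbation window")
    pre = velocity_envelope(pre_v, fs=fs, lowpass_hz=seg.envelope_lowpass_hz)
    band = float(np.mean(pre) + band_k * np.std(pre, ddof=1))
    post = seg.envelope[seg.onset_index:]
    inside = post <= band
    dwell_n = max(int(round(dwell_s * fs)), 1)
    # first index where `inside` holds for dwell_n consecutive samples
    csum = np.concatenate(([0], np.cumsum(inside)))
    ok = np.flatnonzero(csum[dwell_n:] - csum[:-dwell_n] == dwell_n)
    post_len_s = (seg.traj.n - seg.onset_index) / fs
    if len(ok) == 0:
        return RecoveryResult(time_s=post_len_s, censored=True, band=band,
                              index=seg.traj.n - 1)
    i = int(ok[0])
    t = max(i, 1) / fs  # recovery time is strictly positive
    return RecoveryResult(time_s=t, censored=False, band=band,
                          index=seg.onset_index + max(i, 1))


def response_metrics(seg: PerturbationSegment, steps=None,
                     recovery: RecoveryResult | None = None,
                     band_k: float = 2.0, dwell_s: float = 0.5
                     ) -> ResponseMetrics:
    """Assemble the per-perturbation outcome set.

    ``steps`` is an optional :class:`~posturolab.step_analysis.StepAnalysis`;
    without it the response is classified in-place. Displacement maxima are
    taken over the post-onset window only, and mean velocity over
    [onset, recovery instant].
    """
    if recovery is None:
        recovery = recovery_time(seg, band_k=band_k, dwell_s=dwell_s)
    post = seg.post_slice
    cop_max = float(np.max(seg.d.d[post]))
    rec_end = max(recovery.index, seg.onset_index + 1)
    mean_rec_v = float(np.mean(seg.v.v[seg.onset_index:rec_end + 1]))
    if steps is None:
        strategy, n_steps, step_disp = "in_place", 0, 0.0
        step_discard, step_reason = False, ""
    else:
        strategy, n_steps = steps.strategy, len(steps.steps)
        step_disp = steps.total_displacement
        step_discard = steps.discarded
        step_reason = steps.discard_reason
    return ResponseMetrics(
        recovery_time=float(recovery.time_s), cop_max=cop_max,
        mean_recovery_velocity=mean_rec_v, strategy=strategy,
        n_steps=n_steps, step_total_displacement=float(step_disp),
        censored=recovery.censored,
        discarded=seg.discarded or step_discard,
        discard_reason=seg.discard_reason or step_reason)


def pre_perturbation_sway(seg: PerturbationSegment) -> SwayMetrics:
    """Static sway outcomes of the 5 s standing window before onset.

    Measures anticipatory postural activity; the same ellipse and velocity
    definitions as quiet-stance sway, on the pre-window only.
    """
    if seg.discarded and seg.onset_index < 2:
        raise InsufficientDataError("truncated pre-perturbation window")
    pre = seg.pre_slice
    sub = CoPTrajectory(seg.traj.ap[pre], seg.traj.ml[pre], seg.fs,
                        t0=seg.traj.t0)
    area = ellipse_area_95(sub)
    # drop the final pre sample: its central difference spans the onset
    v_pre = seg.v.v[:max(seg.onset_index - 1, 1)]
    return SwayMetrics(ellipse_area=area,
                       mean_velocity=float(np.mean(v_pre)),
                       window=(seg.traj.t0, seg.traj.t0 + len(v_pre) / seg.fs),
                       n_samples=int(len(v_pre)))
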