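"""Dual force-plate recordings and the derived center-of-pressure signals.

The data model mirrors a posturography rig with two plates embedded in the
standing surface, each reporting vertical force ``fz`` (N) and a CoP
coordinate pair at a common sampling rate (120 Hz in the reference
protocol, but always read from the data).

Coordinate convention
---------------------
AP (anterior-posterior) positive = forward, ML (medial-lateral) positive =
rightward; all positions in millimetres, times in seconds relative to trial
start. In trial CSV files the per-plate columns are ``copx`` (ML) and
``copy`` (AP).

The combined two-plate CoP is the per-sample vertical-force-weighted mean
of the plate CoPs, which reduces to the loaded plate's CoP whenever the
other foot is in the air — the property compensatory-step detection relies
on. Scalar displacement is the Euclidean distance from a reference point
(``D = sqrt(dAP^2 + dML^2)``), and CoP velocity is the absolute time
derivative of that scalar displacement (not the 2-D path speed; see
:func:`path_velocity` for the alternative).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SignalGapError, TrialParseError

if TYPE_CHECKING:  # avoid an import cycle; events are defined downstream
    from .dualtask import CountingRecord
    from .perturbation_response import PerturbationEvent

PLATE_IDS = ("left", "right")
GROUPS = ("PD", "control")
CONDITIONS = ("EO_NoDT", "EO_DT", "EC_NoDT", "EC_DT")
TRIAL_KINDS = ("sway", "perturbation")

TRIAL_COLUMNS = ("t", "fz_L", "copx_L", "copy_L", "fz_R", "copx_R", "copy_R")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class PlateSignal:
    """One force plate's vertical force and CoP coordinates over a trial.

    ``cop_x`` is the ML coordinate, ``cop_y`` the AP coordinate (mm).
    CoP values are meaningful only while the plate carries load; they must
    be finite wherever ``fz > 0``.
    """

    plate_id: str
    fz: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "fz", _as_float_array(self.fz, "fz"))
        object.__setattr__(self, "cop_x", _as_float_array(self.cop_x, "cop_x"))
        object.__setattr__(self, "cop_y", _as_float_array(self.cop_y, "cop_y"))
        if self.plate_id not in PLATE_IDS:
            raise ValueError(f"plate_id must be one of {PLATE_IDS}")
        n = len(self.fz)
        if len(self.cop_x) != n or len(self.cop_y) != n:
            raise ValueError("fz, cop_x and cop_y must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.any(self.fz < 0):
            raise ValueError("vertical force must be non-negative")
        loaded = self.fz > 0
        if not (np.all(np.isfinite(self.cop_x[loaded]))
                and np.all(np.isfinite(self.cop_y[loaded]))):
            raise ValueError("CoP must be finite wherever the plate is loaded")

    @property
    def n(self) -> int:
        return len(self.fz)

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class CoPTrajectory:
    """Combined two-plate CoP in AP/ML axes (mm) at sampling rate ``fs``."""

    ap: np.ndarray
    ml: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "ap", _as_float_array(self.ap, "ap"))
        object.__setattr__(self, "ml", _as_float_array(self.ml, "ml"))
        if len(self.ap) != len(self.ml):
            raise ValueError("ap and ml must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not (np.all(np.isfinite(self.ap)) and np.all(np.isfinite(self.ml))):
            raise ValueError("trajectory must be finite")

    @property
    def n(self) -> int:
        return len(self.ap)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def slice(self, start_s: float, end_s: float) -> "CoPTrajectory":
        """Half-open time slice [start_s, end_s) in trial-relative seconds."""
        i0 = int(np.ceil(round((start_s - self.t0) * self.fs, 9)))
        i1 = int(np.ceil(round((end_s - self.t0) * self.fs, 9)))
        i0, i1 = max(i0, 0), min(i1, self.n)
        if i1 <= i0:
            raise InsufficientDataError(
                f"empty trajectory slice [{start_s}, {end_s})")
        return CoPTrajectory(self.ap[i0:i1], self.ml[i0:i1], self.fs,
                             t0=self.t0 + i0 / self.fs)


@dataclass(frozen=True)
class DisplacementSeries:
    """Scalar CoP displacement magnitude from a fixed reference point (mm)."""

    d: np.ndarray
    fs: float
    reference: tuple  # (ap0, ml0) in mm
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "d", _as_float_array(self.d, "d"))
        object.__setattr__(self, "reference",
                           (float(self.reference[0]), float(self.reference[1])))
        if np.any(self.d < 0):
            raise ValueError("displacement magnitude must be non-negative")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return len(self.d)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class VelocitySeries:
    """Absolute CoP velocity (mm/s), same length as its source displacement."""

    v: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "v", _as_float_array(self.v, "v"))
        if np.any(self.v < 0):
            raise ValueError("absolute velocity must be non-negative")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return len(self.v)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class TrialRecord:
    """One recorded trial: two plate signals plus metadata and events."""

    participant_id: str
    group: str
    condition: str
    trial_kind: str
    plates: tuple  # (left PlateSignal, right PlateSignal)
    events: list = field(default_factory=list)
    counting: Optional["CountingRecord"] = None

    def __post_init__(self):
        left, right = self.plates
        if left.plate_id != "left" or right.plate_id != "right":
            raise ValueError("plates must be ordered (left, right)")
        if left.n != right.n or left.fs != right.fs:
            raise ValueError("plates must share length and sampling rate")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.trial_kind not in TRIAL_KINDS:
            raise ValueError(f"trial_kind must be one of {TRIAL_KINDS}")
        onsets = [e.onset_s for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        self._combined: CoPTrajectory | None = None

    @property
    def left(self) -> PlateSignal:
        return self.plates[0]

    @property
    def right(self) -> PlateSignal:
        return self.plates[1]

    @property
    def fs(self) -> float:
        return self.left.fs

    @property
    def duration(self) -> float:
        return self.left.duration

    def combined(self) -> CoPTrajectory:
        """Force-weighted two-plate CoP trajectory (cached)."""
        if self._combined is None:
            self._combined = combine_plates(self.left, self.right)
        return self._combined


def combine_plates(left: PlateSignal, right: PlateSignal) -> CoPTrajectory:
    """Per-sample force-weighted mean of the two plate CoPs.

    During single-support (one plate fully unloaded) the combined CoP
    equals the loaded plate's CoP. Raises :class:`SignalGapError` if both
    plates read zero force at any sample, which is physically impossible
    in a standing protocol.
    """
    if left.n != right.n:
        raise ValueError("plate signals must have equal length")
    if left.fs != right.fs:
        raise ValueError("plate signals must share a sampling rate")
    total = left.fz + right.fz
    if np.any(total <= 0):
        i = int(np.argmax(total <= 0))
        raise SignalGapError(
            f"zero total force at sample {i} (t = {i / left.fs:.3f} s)")
    w_l = left.fz / total
    w_r = right.fz / total
    # unloaded-plate CoP may be ill-defined; its weight is exactly zero
    ap = w_l * np.where(w_l > 0, left.cop_y, 0.0) \
        + w_r * np.where(w_r > 0, right.cop_y, 0.0)
    ml = w_l * np.where(w_l > 0, left.cop_x, 0.0) \
        + w_r * np.where(w_r > 0, right.cop_x, 0.0)
    return CoPTrajectory(ap, ml, left.fs)


def displacement_magnitude(traj: CoPTrajectory,
                           reference: Sequence[float] | None = None
                           ) -> DisplacementSeries:
    """Euclidean distance of the CoP from a reference point, per sample.

    With no explicit ``reference`` the mean CoP of the trajectory is used,
    which makes the displacement zero-mean-referenced under stationary
    quiet stance.
    """
    if reference is None:
        reference = (float(np.mean(traj.ap)), float(np.mean(traj.ml)))
    ap0, ml0 = float(reference[0]), float(reference[1])
    if not (np.isfinite(ap0) and np.isfinite(ml0)):
        raise ValueError("reference point must be finite")
    d = np.hypot(traj.ap - ap0, traj.ml - ml0)
    return DisplacementSeries(d, traj.fs, (ap0, ml0), t0=traj.t0)


def cop_velocity(d: DisplacementSeries) -> VelocitySeries:
    """Absolute derivative of scalar displacement over time.

    Symmetric central differences at interior samples, one-sided at the
    ends, then absolute value. Note this is the derivative of the scalar
    distance-from-reference, so a CoP circling the reference at constant
    radius has (near-)zero velocity by this definition.
    """
    if d.n < 3:
        raise InsufficientDataError(
            "velocity needs at least 3 displacement samples")
    v = np.abs(np.gradient(d.d, 1.0 / d.fs))
    return VelocitySeries(v, d.fs, t0=d.t0)


def path_velocity(traj: CoPTrajectory) -> VelocitySeries:
    """2-D path speed |d(ap, ml)/dt| — the alternative velocity reading.

    Provided for comparison; the scalar-displacement derivative
    (:func:`cop_velocity`) is the default throughout the pipeline.
    """
    if traj.n < 3:
        raise InsufficientDataError("path speed needs at least 3 samples")
    dt = 1.0 / traj.fs
    v = np.hypot(np.gradient(traj.ap, dt), np.gradient(traj.ml, dt))
    return VelocitySeries(v, traj.fs, t0=traj.t0)


# ---------------------------------------------------------------------------
# Trial CSV dialect
#
# Header lines: '# fs_hz=<float>', '# participant=<id>', '# group=<PD|control>',
# '# condition=<EO|EC>_<DT|NoDT>', '# kind=<sway|perturbation>'
# Columns: t,fz_L,copx_L,copy_L,fz_R,copx_R,copy_R  (s, N, mm)
# Event CSV columns: onset_s,type
# ---------------------------------------------------------------------------

PERTURBATION_TYPES = ("trans_fwd", "trans_bwd", "trans_left", "trans_right",
                      "tilt_fwd", "tilt_bwd", "tilt_left", "tilt_right")


def _read_header(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def read_trial(path, events_path=None, counting: "CountingRecord | None" = None,
               meta_overrides: dict | None = None) -> TrialRecord:
    """Read one trial CSV (and optionally its event CSV) into a TrialRecord.

    The sampling rate is taken from the ``fs_hz`` header, never assumed.
    Malformed files raise :class:`TrialParseError` naming the first
    offending data row (1-based, excluding header and column-name lines).
    """
    path = Path(path)
    meta, _ = _read_header(path)
    if meta_overrides:
        meta = {**meta, **meta_overrides}
    for key in ("fs_hz", "participant", "group", "condition", "kind"):
        if key not in meta:
            raise TrialParseError(f"{path}: missing '# {key}=' header line")
    try:
        fs = float(meta["fs_hz"])
    except ValueError as exc:
        raise TrialParseError(f"{path}: fs_hz is not numeric") from exc
    if not fs > 0:
        raise TrialParseError(f"{path}: fs_hz must be positive")

    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise TrialParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    if tuple(df.columns) != TRIAL_COLUMNS:
        raise TrialParseError(
            f"{path}: expected columns {','.join(TRIAL_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}")
    values = df.to_numpy(dtype=float, na_value=np.nan)
    bad = ~np.isfinite(values[:, [0, 1, 4]])  # t and forces must be present
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0]) + 1
        raise TrialParseError(f"{path}: missing or non-numeric value", row=row)
    t = values[:, 0]
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 2
            raise TrialParseError(f"{path}: time column is not strictly "
                                  "increasing", row=row)
    for col, name in ((1, "fz_L"), (4, "fz_R")):
        if np.any(values[:, col] < 0):
            row = int(np.argmax(values[:, col] < 0)) + 1
            raise TrialParseError(f"{path}: negative force in {name}", row=row)

    left = PlateSignal("left", values[:, 1], values[:, 2], values[:, 3], fs)
    right = PlateSignal("right", values[:, 4], values[:, 5], values[:, 6], fs)
    events = read_events(events_path) if events_path is not None else []
    return TrialRecord(
        participant_id=meta["participant"], group=meta["group"],
        condition=meta["condition"], trial_kind=meta["kind"],
        plates=(left, right), events=events, counting=counting)


def read_events(path) -> list:
    """Read a perturbation-event CSV (columns onset_s,type)."""
    from .perturbation_response import PerturbationEvent

    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if tuple(df.columns) != ("onset_s", "type"):
        raise TrialParseError(f"{path}: expected columns onset_s,type")
    events = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.type not in PERTURBATION_TYPES:
            raise TrialParseError(f"{path}: unknown perturbation type "
                                  f"'{rec.type}'", row=i)
        events.append(PerturbationEvent(onset_s=float(rec.onset_s),
                                        ptype=str(rec.type)))
    return sorted(events, key=lambda e: e.onset_s)


def write_trial(trial: TrialRecord, path, events_path=None) -> None:
    """Write a trial (and optionally its events) in the package CSV dialect."""
    path = Path(path)
    left, right = trial.left, trial.right
    t = np.arange(left.n) / trial.fs
    buf = io.StringIO()
    buf.write(f"# fs_hz={trial.fs:g}\n")
    buf.write(f"# participant={trial.participant_id}\n")
    buf.write(f"# group={trial.group}\n")
    buf.write(f"# condition={trial.condition}\n")
    buf.write(f"# kind={trial.trial_kind}\n")
    df = pd.DataFrame({
        "t": t, "fz_L": left.fz, "copx_L": left.cop_x, "copy_L": left.cop_y,
        "fz_R": right.fz, "copx_R": right.cop_x, "copy_R": right.cop_y,
    })
    df.to_csv(buf, index=False, float_format="%.6f")
    path.write_text(buf.getvalue())
    if events_path is not None:
        write_events(trial.events, events_path)


def write_events(events, path) -> None:
    df = pd.DataFrame({"onset_s": [e.onset_s for e in events],
                       "type": [e.ptype for e in events]})
    df.to_csv(path, index=False, float_format="%.6f")
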