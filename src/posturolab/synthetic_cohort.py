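"""Seeded synthetic dual-plate cohort generator.

No raw recordings accompany the study this pipeline re-implements, so this
module generates force-plate trials carrying the statistical structure the
analysis assumes, with known ground truth:

* **Quiet-stance sway** — each CoP axis is a stationary Ornstein-Uhlenbeck
  process (mean reversion ``k`` 1/s, drive ``sigma`` mm/sqrt(s), stationary
  variance ``sigma^2 / 2k``), simulated by exact discretisation on a coarse
  knot grid (the sway bandwidth, default 2 Hz knot rate) and reconstructed
  at the plate rate by polyphase (near-sinc) upsampling, plus white fast
  jitter. Variance (hence
  ellipse area) and mean velocity are thereby tunable near-independently:
  area follows the OU variance, velocity follows bandwidth plus jitter —
  exactly the degrees of freedom the "postural rigidity" phenotype needs
  (smaller area *and* higher velocity in the clinical group).
* **Perturbation responses** — a double-exponential displacement kernel
  ``peak-normalised A * (exp(-t/tau2) - exp(-t/tau1))`` oriented along the
  perturbation direction, on top of anticipation-inflated sway, with an
  analytically known decay so a ground-truth recovery instant can be
  recorded; occasional compensatory steps unload one plate for >= 50 ms
  and relocate its CoP.
* **Counting records** — Poisson correct-count tallies at per-group,
  per-context rates.

Group defaults are calibrated to the printed scales of the reference
cohort (control eyes-open sway area ~148 mm^2 at ~9 mm/s; clinical-group
area ratio ~0.7 with velocity ratio ~1.4; recovery time-constants giving
~2.1 s vs ~1.6 s recoveries; counting rates 17.5 vs 11.9 per minute), with
eyes-closed, dual-task and pre-perturbation anticipation factors taken
from the same tables. All randomness flows from one master seed through
named substreams, so identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np
from scipy.signal import resample_poly

from .dualtask import CountingRecord
from .errors import ConfigError
from .perturbation_response import (PerturbationEvent, velocity_envelope,
                                    PRE_WINDOW_S, POST_WINDOW_S)
from .signal_io import PlateSignal, TrialRecord, CONDITIONS

# direction unit vectors (ap, ml) per perturbation type
_DIRECTIONS = {
    "fwd": (1.0, 0.0), "bwd": (-1.0, 0.0),
    "left": (0.0, -1.0), "right": (0.0, 1.0),
}


@dataclass
class GroupParams:
    """Per-group generative parameters (see module docstring for units)."""

    stiffness: float  # OU mean reversion k (1/s)
    drive: float  # OU drive sigma (mm/sqrt(s)); variance = drive^2/(2k)
    jitter: float  # fast-jitter SD (mm) added per axis at the plate rate
    ec_area_factor: float  # eyes-closed multiplier on sway variance
    ec_velocity_factor: float  # eyes-closed multiplier on jitter
    dt_area_factor: float  # dual-task multiplier on sway variance
    dt_velocity_factor: float  # dual-task multiplier on jitter
    anticipation_area_factor: float  # pre-perturbation variance inflation
    anticipation_velocity_factor: float  # pre-perturbation jitter inflation
    recovery_tau: float  # kernel decay time-constant tau2 (s)
    p_step: float  # probability a perturbation evokes a step response
    p_multiple: float  # probability a step response has >= 2 steps
    counting_rate: float  # reference correct-count rate (counts/min)
    counting_rate_sd: float  # between-participant SD of that rate
    sway_count_factor: float  # context multiplier on the rate during sway
    pert_count_factor: float  # ... during perturbation trials

    def validate(self):
        for name in ("stiffness", "drive", "recovery_tau", "counting_rate"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("p_step", "p_multiple"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be a probability")


@dataclass
class PerturbationParams:
    """Perturbation-protocol parameters shared by both groups."""

    amplitude_mm: float = 140.0  # peak CoP displacement of the kernel
    tilt_scale: float = 0.7  # tilt amplitude relative to translation
    rise_tau: float = 0.08  # kernel rise time-constant tau1 (s)
    gap_range: tuple = (9.0, 15.0)  # inter-perturbation interval (s)
    n_events: int = 8


def _default_groups() -> dict:
    # magnitudes target the reference cohort's printed group means
    return {
        "control": GroupParams(
            stiffness=2.0, drive=5.86, jitter=0.07,
            ec_area_factor=1.09, ec_velocity_factor=1.19,
            dt_area_factor=4.25, dt_velocity_factor=2.5,
            anticipation_area_factor=4.4, anticipation_velocity_factor=3.4,
            recovery_tau=0.80, p_step=0.39, p_multiple=0.10,
            counting_rate=17.5, counting_rate_sd=3.6,
            sway_count_factor=1.14, pert_count_factor=0.93),
        "PD": GroupParams(
            stiffness=2.857, drive=5.86, jitter=0.16,
            ec_area_factor=0.82, ec_velocity_factor=0.91,
            dt_area_factor=3.83, dt_velocity_factor=1.21,
            anticipation_area_factor=6.6, anticipation_velocity_factor=3.0,
            recovery_tau=0.60, p_step=0.36, p_multiple=0.60,
            counting_rate=11.9, counting_rate_sd=3.6,
            sway_count_factor=1.08, pert_count_factor=0.82),
    }


@dataclass
class GeneratorConfig:
    """Full cohort-generation configuration (defaults = study conditions)."""

    n_control: int = 11
    n_pd: int = 12
    fs: float = 120.0
    sway_knot_hz: float = 2.0  # OU knot rate; sets the sway bandwidth
    sway_duration_s: float = 30.0
    body_weight_n: float = 700.0
    load_modulation: float = 0.08  # slow anti-phase left/right load share
    load_modulation_hz: float = 0.3
    force_noise_n: float = 0.5  # per-plate force sensor noise SD
    stance_half_width_mm: float = 100.0  # foot CoP offset from midline (ML)
    participant_cv: float = 0.10  # lognormal between-participant spread
    groups: dict = field(default_factory=_default_groups)
    perturbation: PerturbationParams = field(default_factory=PerturbationParams)
    sway_conditions: tuple = CONDITIONS
    perturbation_conditions: tuple = ("NoDT", "DT")
    seed: int = 0

    def validate(self):
        if not (self.fs > 0 and self.sway_knot_hz > 0):
            raise ConfigError("rates must be positive")
        if self.n_control < 1 or self.n_pd < 1:
            raise ConfigError("need at least one participant per group")
        for gp in self.groups.values():
            gp.validate()


@dataclass
class ParticipantParams:
    """Per-participant multipliers drawn once per simulated participant."""

    stiffness_mult: float = 1.0
    drive_mult: float = 1.0
    jitter_mult: float = 1.0
    recovery_tau_mult: float = 1.0
    counting_rate: float = 17.5


@dataclass
class SyntheticCohort:
    """Generated trials, counting records and per-trial ground truth."""

    trials: list
    truth: dict  # trial_id -> dict
    counting: list  # dicts: participant_id, group, context, record
    config: GeneratorConfig

    def trial_id(self, trial: TrialRecord) -> str:
        return f"{trial.participant_id}_{trial.trial_kind}_{trial.condition}"


def draw_participant(cfg: GeneratorConfig, group: str,
                     rng: np.random.Generator) -> ParticipantParams:
    """Draw one participant's multiplicative deviations from group means."""
    gp = cfg.groups[group]
    cv = cfg.participant_cv
    sig = np.sqrt(np.log1p(cv ** 2))  # lognormal with unit mean, given CV
    mults = np.exp(rng.normal(-sig ** 2 / 2, sig, size=4))
    rate = max(rng.normal(gp.counting_rate, gp.counting_rate_sd), 2.0)
    return ParticipantParams(stiffness_mult=float(mults[0]),
                             drive_mult=float(mults[1]),
                             jitter_mult=float(mults[2]),
                             recovery_tau_mult=float(mults[3]),
                             counting_rate=float(rate))


def _condition_factors(gp: GroupParams, condition: str) -> tuple:
    """(variance factor, jitter factor) for an EO/EC x DT/NoDT condition."""
    eyes, _, task = condition.partition("_")
    f_var, f_jit = 1.0, 1.0
    if eyes == "EC":
        f_var *= gp.ec_area_factor
        f_jit *= gp.ec_velocity_factor
    if task == "DT":
        f_var *= gp.dt_area_factor
        f_jit *= gp.dt_velocity_factor
    return f_var, f_jit


def _ou_knots(rng: np.random.Generator, n: int, dt: float, k: float,
              sigma: float) -> np.ndarray:
    """Exact-discretisation stationary OU sample path at knot spacing dt."""
    var = sigma ** 2 / (2.0 * k)
    rho = np.exp(-k * dt)
    innov_sd = np.sqrt(var * (1.0 - rho ** 2))
    x = np.empty(n)
    x[0] = rng.normal(0.0, np.sqrt(var))
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + shocks[i - 1]
    return x


def _sway_axes(rng: np.random.Generator, n: int, fs: float, knot_hz: float,
               k: float, sigma: float, jitter: float) -> tuple:
    """Band-limited OU + white jitter for both axes, n samples at fs.

    The OU path is simulated exactly at the knot rate and reconstructed at
    the plate rate by polyphase (near-sinc) upsampling, which preserves the
    stationary variance of the sampled process — so the closed-form
    ``sigma^2 / (2 k)`` per-axis variance holds at the plate rate too —
    while confining the smooth component's power below the knot Nyquist.
    """
    q = max(int(round(fs / knot_hz)), 1)
    pad = 12  # knots discarded on each side to absorb the FIR edge taper
    n_knots = int(np.ceil(n / q)) + 2 * pad + 2
    out = []
    for _axis in range(2):
        knots = _ou_knots(rng, n_knots, q / fs, k, sigma)
        smooth = resample_poly(knots, q, 1)[pad * q:pad * q + n]
        out.append(smooth + rng.normal(0.0, jitter, size=n))
    return out[0], out[1]


def _build_plates(rng: np.random.Generator, ap: np.ndarray, ml: np.ndarray,
                  cfg: GeneratorConfig) -> tuple:
    """Split a target combined CoP into two consistent plate signals.

    Body weight is shared with slow anti-phase modulation; per-plate CoPs
    are placed about the stance width such that the force-weighted mean
    reproduces the target exactly (before sensor noise).
    """
    n = len(ap)
    t = np.arange(n) / cfg.fs
    w = cfg.body_weight_n
    phase = rng.uniform(0, 2 * np.pi)
    share = 0.5 * (1.0 + cfg.load_modulation
                   * np.sin(2 * np.pi * cfg.load_modulation_hz * t + phase))
    fz_l = w * share
    fz_r = w * (1.0 - share)
    total = fz_l + fz_r
    half = cfg.stance_half_width_mm
    # offsets o_l, o_r with fz_l*o_l + fz_r*o_r = 0 and |o| ~ stance width
    o_l = -2.0 * half * fz_r / total
    o_r = 2.0 * half * fz_l / total
    return (fz_l, ap.copy(), ml + o_l), (fz_r, ap.copy(), ml + o_r)


def _finalize_plates(rng, left_parts, right_parts, cfg) -> tuple:
    out = []
    for plate_id, (fz, cop_ap, cop_ml) in (("left", left_parts),
                                           ("right", right_parts)):
        noisy = np.clip(fz + rng.normal(0.0, cfg.force_noise_n, len(fz)),
                        0.0, None)
        out.append(PlateSignal(plate_id, noisy, cop_ml, cop_ap, cfg.fs))
    return tuple(out)


def simulate_sway(cfg: GeneratorConfig, group: str, condition: str,
                  duration_s: float | None = None,
                  rng: np.random.Generator | None = None,
                  participant: ParticipantParams | None = None,
                  participant_id: str = "S01") -> tuple:
    """One quiet-stance trial plus its generative ground truth."""
    cfg.validate()
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    participant = participant or ParticipantParams(
        counting_rate=cfg.groups[group].counting_rate)
    duration_s = duration_s if duration_s is not None else cfg.sway_duration_s
    if duration_s < 30.0:
        raise ConfigError("sway trials must last at least 30 s")
    gp = cfg.groups[group]
    f_var, f_jit = _condition_factors(gp, condition)
    k = gp.stiffness * participant.stiffness_mult
    sigma = gp.drive * participant.drive_mult * np.sqrt(f_var)
    jitter = gp.jitter * participant.jitter_mult * f_jit
    n = int(round(duration_s * cfg.fs))
    ap, ml = _sway_axes(rng, n, cfg.fs, cfg.sway_knot_hz, k, sigma, jitter)
    left, right = _finalize_plates(rng, *_build_plates(rng, ap, ml, cfg), cfg)
    trial = TrialRecord(participant_id=participant_id, group=group,
                        condition=condition, trial_kind="sway",
                        plates=(left, right))
    var = sigma ** 2 / (2.0 * k)
    truth = {"per_axis_variance": float(var),
             "expected_area": float(np.pi * 5.991464547107979 * var),
             "stiffness": float(k), "drive": float(sigma),
             "jitter": float(jitter)}
    return trial, truth


def _kernel(t: np.ndarray, amplitude: float, tau1: float,
            tau2: float) -> np.ndarray:
    """Peak-normalised double-exponential displacement kernel, mm."""
    t_peak = np.log(tau2 / tau1) / (1.0 / tau1 - 1.0 / tau2)
    peak = np.exp(-t_peak / tau2) - np.exp(-t_peak / tau1)
    raw = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau2)
                   - np.exp(-np.clip(t, 0, None) / tau1), 0.0)
    return amplitude * raw / peak


def _kernel_speed(t: np.ndarray, amplitude: float, tau1: float,
                  tau2: float) -> np.ndarray:
    t_peak = np.log(tau2 / tau1) / (1.0 / tau1 - 1.0 / tau2)
    peak = np.exp(-t_peak / tau2) - np.exp(-t_peak / tau1)
    tc = np.clip(t, 0, None)
    deriv = -np.exp(-tc / tau2) / tau2 + np.exp(-tc / tau1) / tau1
    return np.where(t >= 0, np.abs(amplitude * deriv / peak), 0.0)


def _true_recovery(onset: float, fs: float, amplitude: float, tau1: float,
                   tau2: float, resting_level: float) -> tuple:
    """Noise-free recovery instant for one simulated perturbation.

    The response is over once the deterministic kernel's speed has decayed
    into the segment's own resting velocity-envelope level (its pre-window
    mean): past that point the response is indistinguishable from resting
    postural activity. The noisy total envelope rides roughly one resting
    level above the kernel speed, so this instant is also where the
    detector's mean + 2 SD band crossing lands. Returns
    (recovery_s, censored).
    """
    tg = np.arange(0.0, POST_WINDOW_S, 1.0 / fs)
    speed = _kernel_speed(tg, amplitude, tau1, tau2)
    thresh = max(resting_level, 1e-9)
    above = np.flatnonzero(speed > thresh)
    if len(above) == 0:
        return 1.0 / fs, False
    if above[-1] == len(tg) - 1:
        return POST_WINDOW_S, True
    return float(tg[above[-1] + 1]), False


def simulate_perturbation_trial(cfg: GeneratorConfig, group: str,
                                condition: str = "NoDT",
                                n_events: int | None = None,
                                rng: np.random.Generator | None = None,
                                participant: ParticipantParams | None = None,
                                participant_id: str = "S01") -> tuple:
    """One perturbation trial (sway background + responses) with truth.

    ``condition`` is "NoDT" or "DT"; the stored trial condition is
    "EO_<condition>" (perturbation trials are performed eyes-open).
    Ground truth records, per event: injected steps, the kernel's peak
    displacement, and the noise-free recovery instant and censoring flag.
    """
    cfg.validate()
    if condition not in ("NoDT", "DT"):
        raise ConfigError("perturbation condition must be 'NoDT' or 'DT'")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    participant = participant or ParticipantParams(
        counting_rate=cfg.groups[group].counting_rate)
    gp = cfg.groups[group]
    pp = cfg.perturbation
    n_events = n_events if n_events is not None else pp.n_events
    if n_events < 1:
        raise ConfigError("need at least one perturbation")
    tau2 = gp.recovery_tau * participant.recovery_tau_mult
    if tau2 > POST_WINDOW_S:
        import warnings
        warnings.warn("recovery tau exceeds the post-onset window; "
                      "responses will be censored", stacklevel=2)
    fs = cfg.fs

    # onsets with 9-15 s gaps after a 5 s lead-in
    onsets = [PRE_WINDOW_S + rng.uniform(0.0, 1.0)]
    for _ in range(n_events - 1):
        onsets.append(onsets[-1] + rng.uniform(*pp.gap_range))
    duration = onsets[-1] + POST_WINDOW_S + 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # anticipation-inflated sway background (plus DT factors when relevant)
    f_var, f_jit = _condition_factors(gp, f"EO_{condition}")
    k = gp.stiffness * participant.stiffness_mult
    sigma = gp.drive * participant.drive_mult \
        * np.sqrt(f_var * gp.anticipation_area_factor)
    jitter = gp.jitter * participant.jitter_mult * f_jit \
        * gp.anticipation_velocity_factor
    ap, ml = _sway_axes(rng, n, fs, cfg.sway_knot_hz, k, sigma, jitter)

    # perturbation kernels
    types = [f"{kind}_{direction}" for kind in ("trans", "tilt")
             for direction in ("fwd", "bwd", "left", "right")]
    order = list(rng.permutation(len(types)))
    events = []
    per_event = []
    for j, onset in enumerate(onsets):
        ptype = types[order[j % len(types)]]
        kind, direction = ptype.split("_")
        amp = pp.amplitude_mm * (pp.tilt_scale if kind == "tilt" else 1.0)
        u_ap, u_ml = _DIRECTIONS[direction]
        span = (t >= onset) & (t < onset + POST_WINDOW_S + 1.0)
        kern = _kernel(t[span] - onset, amp, pp.rise_tau, tau2)
        ap[span] += u_ap * kern
        ml[span] += u_ml * kern
        events.append(PerturbationEvent(onset_s=float(onset), ptype=ptype))
        per_event.append({"onset_s": float(onset), "ptype": ptype,
                          "amplitude_mm": float(amp), "tau2": float(tau2)})

    (fz_l, capL, cmlL), (fz_r, capR, cmlR) = _build_plates(rng, ap, ml, cfg)
    plates = {"left": [fz_l, capL, cmlL], "right": [fz_r, capR, cmlR]}

    # compensatory steps: unload one plate >= 50 ms and relocate its CoP
    for j, onset in enumerate(onsets):
        info = per_event[j]
        info["n_steps"], info["steps"] = 0, []
        if rng.uniform() >= gp.p_step:
            continue
        n_steps = 1
        if rng.uniform() < gp.p_multiple:
            n_steps = int(rng.integers(2, 4))
        foot = "left" if rng.uniform() < 0.5 else "right"
        start = onset + rng.uniform(0.35, 0.6)
        u_ap, u_ml = _DIRECTIONS[info["ptype"].split("_")[1]]
        for _s in range(n_steps):
            dur = rng.uniform(0.12, 0.25)
            mag = rng.uniform(40.0, 90.0)
            ang = rng.normal(0.0, 0.3)
            off_ap = mag * (u_ap * np.cos(ang) - u_ml * np.sin(ang))
            off_ml = mag * (u_ap * np.sin(ang) + u_ml * np.cos(ang))
            i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
            i1 = min(i1, n - 1)
            if i1 <= i0 + 1:
                break
            swing, stance = plates[foot], plates[
                "right" if foot == "left" else "left"]
            total = swing[0][i0:i1] + stance[0][i0:i1]
            stance[0][i0:i1] = total
            swing[0][i0:i1] = 0.0
            swing[1][i0:i1] = swing[1][i0 - 1]  # hold CoP while in the air
            swing[2][i0:i1] = swing[2][i0 - 1]
            # the foot lands `offset` away from where it left the surface,
            # then eases back toward the marked stance position over ~2 s
            d_ap = off_ap - (swing[1][i1] - swing[1][i0 - 1])
            d_ml = off_ml - (swing[2][i1] - swing[2][i0 - 1])
            ramp_t = np.array([i1 / fs, i1 / fs + 0.8, i1 / fs + 2.3])
            ramp = np.interp(t[i1:], ramp_t, [1.0, 1.0, 0.0])
            swing[1][i1:] += d_ap * ramp
            swing[2][i1:] += d_ml * ramp
            info["steps"].append({"foot": foot, "start_s": i0 / fs,
                                  "end_s": i1 / fs,
                                  "offset_mm": (float(off_ap), float(off_ml))})
            foot = "right" if foot == "left" else "left"
            start = i1 / fs + rng.uniform(0.15, 0.35)
        info["n_steps"] = len(info["steps"])

    left, right = _finalize_plates(rng, tuple(plates["left"]),
                                   tuple(plates["right"]), cfg)
    trial = TrialRecord(participant_id=participant_id, group=group,
                        condition=f"EO_{condition}", trial_kind="perturbation",
                        plates=(left, right), events=events)

    # ground-truth recovery: noise-free kernel speed vs the resting band
    traj = trial.combined()
    for info in per_event:
        onset = info["onset_s"]
        pre = traj.slice(onset - PRE_WINDOW_S, onset)
        ref = (float(np.mean(pre.ap)), float(np.mean(pre.ml)))
        d = np.hypot(pre.ap - ref[0], pre.ml - ref[1])
        v = np.abs(np.gradient(d, 1.0 / fs))
        env = velocity_envelope(v, fs=fs)
        rec, cens = _true_recovery(onset, fs, info["amplitude_mm"],
                                   pp.rise_tau, info["tau2"],
                                   float(np.mean(env)))
        info["recovery_s"] = rec
        info["censored"] = cens
    truth = {"events": per_event, "stiffness": float(k),
             "drive": float(sigma), "jitter": float(jitter),
             "tau2": float(tau2)}
    return trial, truth


def simulate_counting(cfg: GeneratorConfig, group: str, context: str,
                      duration_s: float,
                      rng: np.random.Generator | None = None,
                      participant: ParticipantParams | None = None
                      ) -> CountingRecord:
    """Poisson correct-count tally for one counting context."""
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    gp = cfg.groups[group]
    rate = participant.counting_rate if participant is not None \
        else gp.counting_rate
    factor = {"reference": 1.0, "sway": gp.sway_count_factor,
              "perturbation": gp.pert_count_factor}[context]
    n = int(rng.poisson(rate * factor * duration_s / 60.0))
    return CountingRecord(n_correct_counts=n, duration_s=float(duration_s),
                          context=context)


def simulate_cohort(cfg: GeneratorConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full two-group cohort under the configured protocol."""
    cfg = cfg if cfg is not None else GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    trials, truth, counting = [], {}, []
    cohort = SyntheticCohort(trials=trials, truth=truth, counting=counting,
                             config=cfg)
    roster = [("control", f"HC{i + 1:02d}") for i in range(cfg.n_control)] \
        + [("PD", f"PD{i + 1:02d}") for i in range(cfg.n_pd)]
    streams = master.spawn(len(roster))
    for (group, pid), stream in zip(roster, streams):
        rng = np.random.default_rng(stream)
        part = draw_participant(cfg, group, rng)
        rec = simulate_counting(cfg, group, "reference", 60.0, rng, part)
        counting.append({"participant_id": pid, "group": group,
                         "context": "reference", "record": rec})
        for condition in cfg.sway_conditions:
            trial, tr = simulate_sway(cfg, group, condition, rng=rng,
                                      participant=part, participant_id=pid)
            if condition.endswith("_DT"):
                trial.counting = simulate_counting(
                    cfg, group, "sway", trial.duration, rng, part)
                counting.append({"participant_id": pid, "group": group,
                                 "context": "sway",
                                 "record": trial.counting})
            trials.append(trial)
            truth[cohort.trial_id(trial)] = tr
        for pcond in cfg.perturbation_conditions:
            trial, tr = simulate_perturbation_trial(
                cfg, group, pcond, rng=rng, participant=part,
                participant_id=pid)
            if pcond == "DT":
                trial.counting = simulate_counting(
                    cfg, group, "perturbation", trial.duration, rng, part)
                counting.append({"participant_id": pid, "group": group,
                                 "context": "perturbation",
                                 "record": trial.counting})
            trials.append(trial)
            truth[cohort.trial_id(trial)] = tr
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort as trial/event/counting CSVs plus a truth JSON."""
    import json
    from pathlib import Path

    from .dualtask import counting_rate
    from .signal_io import write_events, write_trial

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trial in cohort.trials:
        tid = cohort.trial_id(trial)
        write_trial(trial, out / f"{tid}.csv")
        if trial.events:
            write_events(trial.events, out / f"{tid}_events.csv")
    rows = ["participant_id,group,context,n_correct_counts,duration_s,"
            "rate_per_min"]
    for rec in cohort.counting:
        r = rec["record"]
        rows.append(f"{rec['participant_id']},{rec['group']},{rec['context']},"
                    f"{r.n_correct_counts},{r.duration_s:.3f},"
                    f"{counting_rate(r):.4f}")
    (out / "counting.csv").write_text("\n".join(rows) + "\n")
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=1))
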