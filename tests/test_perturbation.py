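"""Segmentation, velocity envelope and recovery-time detection."""

import numpy as np
import pytest

from posturolab.perturbation_response import (PerturbationEvent,
                                              pre_perturbation_sway,
                                              recovery_time, response_metrics,
                                              segment_perturbation,
                                              velocity_envelope)
from posturolab.signal_io import VelocitySeries

from conftest import make_trial

FS = 120.0


def make_pert_trial(ap, ml, onset, ptype="trans_fwd"):
    return make_trial(ap, ml, kind="perturbation", condition="EO_NoDT",
                      events=[PerturbationEvent(onset, ptype)])


def smooth_noise(rng, n, fs=FS, cutoff_hz=4.0, sd=1.0):
    """Band-limited Gaussian noise (so envelopes track it closely)."""
    from scipy import signal as sps
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.normal(0, 1, n))
    return sd * x / np.std(x)


class TestEnvelope:
    def test_constant_signal_is_its_own_envelope(self):
        env = velocity_envelope(np.full(100, 7.0), fs=FS)
        np.testing.assert_allclose(env, 7.0)

    def test_rectified_sinusoid_envelope_near_amplitude(self):
        # |A sin|: after the 10 Hz low-pass of a 2 Hz rectified sine the
        # envelope should ride near the lobe peaks
        t = np.arange(int(5 * FS)) / FS
        amp = 30.0
        v = np.abs(amp * np.sin(2 * np.pi * 2.0 * t))
        env = velocity_envelope(v, fs=FS, lowpass_hz=None)
        interior = env[int(FS):int(4 * FS)]
        assert np.all(interior > 0.9 * amp)
        assert np.all(interior < 1.05 * amp)

    def test_positive_homogeneity(self, rng):
        v = np.abs(rng.normal(10, 3, 400))
        e1 = velocity_envelope(v, fs=FS)
        e3 = velocity_envelope(3.0 * v, fs=FS)
        np.testing.assert_allclose(e3, 3.0 * e1, rtol=1e-9)


class TestSegmentation:
    def test_segment_length_and_centering(self, rng):
        n = int(60 * FS)
        ap = smooth_noise(rng, n, sd=2.0) + 50.0
        ml = smooth_noise(rng, n, sd=2.0)
        trial = make_pert_trial(ap, ml, onset=20.0)
        seg = segment_perturbation(trial, trial.events[0])
        assert not seg.discarded
        assert seg.traj.n == int(9.5 * FS)  # 1140 samples
        # displacement referenced to pre-window mean CoP: near zero before
        pre_d = seg.d.d[:seg.onset_index]
        assert np.mean(pre_d) < 3 * np.std(seg.traj.ap[:seg.onset_index])

    def test_truncated_window_is_discarded(self, rng):
        n = int(20 * FS)
        trial = make_pert_trial(smooth_noise(rng, n), smooth_noise(rng, n),
                                onset=3.0)
        seg = segment_perturbation(trial, trial.events[0])
        assert seg.discarded and seg.discard_reason == "technical"


def build_envelope_model_segment(rng, tau=0.5, a_over_sigma=20.0, sigma=3.0,
                                 onset=6.0, n_s=12.0, baseline=15.0):
    """Velocity = dithered baseline + smooth noise + decaying exponential.

    The every-other-sample dither anchors the peak-interpolated envelope at
    (almost) every sample, so the envelope's resting fluctuation SD equals
    the constructed ``sigma`` and the mean + 2 SD band crossing of the
    added ``A exp(-t/tau)`` term has the closed analytic form
    ``tau * ln(A / (2 sigma))``.
    """
    n = int(n_s * FS)
    t = np.arange(n) / FS
    v = baseline + sigma * (np.arange(n) % 2) \
        + smooth_noise(rng, n, cutoff_hz=1.0, sd=sigma)
    amp = a_over_sigma * sigma
    v = v + np.where(t >= onset, amp * np.exp(-(t - onset) / tau), 0.0)
    return make_segment_from_velocity(np.clip(v, 0.0, None),
                                      onset_index=int(onset * FS))


def make_segment_from_velocity(v, fs=FS, onset_index=None, lowpass=None):
    """A PerturbationSegment built directly from a velocity series."""
    from posturolab.perturbation_response import PerturbationSegment
    from posturolab.signal_io import CoPTrajectory, DisplacementSeries
    v = np.asarray(v, dtype=float)
    n = len(v)
    onset_index = onset_index if onset_index is not None else n // 2
    env = velocity_envelope(v, fs=fs, lowpass_hz=lowpass)
    zeros = np.zeros(n)
    return PerturbationSegment(
        event=PerturbationEvent(onset_index / fs, "trans_fwd"),
        traj=CoPTrajectory(zeros, zeros, fs),
        d=DisplacementSeries(zeros, fs, (0.0, 0.0)),
        v=VelocitySeries(v, fs), envelope=env, onset_index=onset_index,
        envelope_lowpass_hz=lowpass)


class TestRecovery:
    def test_constructed_noise_free_return_is_sample_exact(self):
        """A response decaying to exactly baseline at 1 s is timed to a sample.

        The baseline dithers every other sample so the peak-interpolated
        envelope has an anchor at every crossing; the linear decay reaches
        zero exactly 1 s after onset.
        """
        n = int(12 * FS)
        onset_index = int(6.0 * FS)
        t = np.arange(n) / FS
        v = 10.0 + (np.arange(n) % 2)  # alternating 10 / 11 baseline
        ramp = 300.0 * np.clip(1.0 - (t - 6.0), 0.0, None) * (t >= 6.0)
        seg = make_segment_from_velocity(v + ramp,
                                         onset_index=onset_index)
        rec = recovery_time(seg)
        assert not rec.censored
        assert rec.time_s == pytest.approx(1.0, abs=1.5 / FS)

    def test_exponential_decay_median_matches_analytic(self):
        """A e^{-t/tau} over noise sigma: crossing ~ tau ln(A / 2 sigma).

        With A = 20 sigma and tau = 0.5 s the analytic mean+2SD band
        crossing is at ~1.151 s; the detected median over 100 seeded
        realizations must sit within 0.1 s of it.
        """
        tau, ratio = 0.5, 20.0
        expected = tau * np.log(ratio / 2.0)
        times = []
        for s in range(100):
            rng = np.random.default_rng(7000 + s)
            seg = build_envelope_model_segment(rng, tau=tau,
                                               a_over_sigma=ratio)
            rec = recovery_time(seg)
            times.append(rec.time_s)
        assert np.median(times) == pytest.approx(expected, abs=0.1)

    def test_never_decaying_envelope_is_censored(self):
        n = int(12 * FS)
        t = np.arange(n) / FS
        v = np.full(n, 5.0) + np.where(t >= 6.0, 300.0, 0.0)
        d = np.cumsum(v) / FS
        trial = make_pert_trial(d, np.zeros(n), onset=6.0)
        seg = segment_perturbation(trial, trial.events[0])
        rec = recovery_time(seg)
        assert rec.censored and rec.time_s == pytest.approx(4.5)

    def test_invariance_under_uniform_velocity_scaling(self, rng):
        # baseline band and response scale together, so the crossing is fixed
        seg = build_envelope_model_segment(rng)
        t1 = recovery_time(seg).time_s
        seg2 = make_segment_from_velocity(5.0 * seg.v.v,
                                          onset_index=seg.onset_index)
        t2 = recovery_time(seg2).time_s
        assert t2 == pytest.approx(t1, abs=2.0 / FS)

    def test_recovery_monotone_in_generator_tau(self):
        # physiological range; a peak-displacement-normalised kernel's
        # speed scale shrinks with tau, flattening the relation above ~1.3 s
        import posturolab.synthetic_cohort as sc
        medians = []
        for tau in (0.3, 0.6, 1.0):
            cfg = sc.GeneratorConfig(participant_cv=0.0)
            cfg.groups["control"].recovery_tau = tau
            cfg.groups["control"].p_step = 0.0
            times = []
            for s in range(12):
                trial, _ = sc.simulate_perturbation_trial(
                    cfg, "control", "NoDT", n_events=3,
                    rng=np.random.default_rng(300 + s))
                for ev in trial.events:
                    seg = segment_perturbation(trial, ev)
                    times.append(recovery_time(seg).time_s)
            medians.append(np.median(times))
        assert medians[0] < medians[1] < medians[2]


class TestResponseMetrics:
    def test_cop_max_and_recovery_velocity(self, rng):
        # constructed single displacement peak of 140 mm -> cop_max 140
        n = int(12 * FS)
        t = np.arange(n) / FS
        onset = 6.0
        bump = 140.0 * np.exp(-((t - onset - 1.0) ** 2) / (2 * 0.3 ** 2))
        trial = make_pert_trial(bump, np.zeros(n), onset=onset)
        seg = segment_perturbation(trial, trial.events[0])
        m = response_metrics(seg)
        assert m.cop_max == pytest.approx(140.0, rel=0.01)
        assert m.strategy == "in_place" and m.n_steps == 0

    def test_pre_window_sway_of_constant_trajectory(self):
        n = int(12 * FS)
        t = np.arange(n) / FS
        onset = 6.0
        ap = np.where(t >= onset, 50.0 * np.exp(-(t - onset)), 0.0)
        trial = make_pert_trial(ap, np.zeros(n), onset=onset)
        seg = segment_perturbation(trial, trial.events[0])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = pre_perturbation_sway(seg)
        assert m.ellipse_area == 0.0
        assert m.mean_velocity == pytest.approx(0.0, abs=1e-9)

    def test_anticipation_inflates_pre_window_sway(self):
        """Pre-perturbation standing shows the configured variance inflation."""
        import posturolab.synthetic_cohort as sc
        from posturolab.static_sway import sway_metrics
        cfg = sc.GeneratorConfig(participant_cv=0.0)
        cfg.groups["control"].p_step = 0.0
        pre_areas, sway_areas = [], []
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            pt, _ = sc.simulate_perturbation_trial(cfg, "control", "NoDT",
                                                   n_events=2, rng=rng)
            for ev in pt.events:
                seg = segment_perturbation(pt, ev)
                pre_areas.append(pre_perturbation_sway(seg).ellipse_area)
            st, _ = sc.simulate_sway(cfg, "control", "EO_NoDT", rng=rng)
            sway_areas.append(sway_metrics(st).ellipse_area)
        ratio = np.median(pre_areas) / np.median(sway_areas)
        # configured anticipation variance factor is 4.4; 5-s windows are
        # noisy, so only the direction and rough scale are asserted
        assert 2.0 < ratio < 9.0
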