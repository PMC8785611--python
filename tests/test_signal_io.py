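"""Plate combination, displacement, velocity and trial file round-trips."""

import numpy as np
import pytest

from posturolab.errors import (InsufficientDataError, SignalGapError,
                               TrialParseError)
from posturolab.perturbation_response import PerturbationEvent
from posturolab.signal_io import (CoPTrajectory, PlateSignal, combine_plates,
                                  cop_velocity, displacement_magnitude,
                                  path_velocity, read_trial, write_trial)

from conftest import make_trial


def plate(plate_id, fz, x, y, fs=120.0):
    return PlateSignal(plate_id, fz, x, y, fs)


class TestCombinePlates:
    @pytest.mark.parametrize("fz_l, fz_r, cop_l, cop_r, expected", [
        # symmetric load, mirrored feet -> midline
        (600.0, 600.0, (-100.0, 0.0), (100.0, 0.0), (0.0, 0.0)),
        # 3:1 load split: weighted mean (600*(-100) + 200*100) / 800 = -50
        (600.0, 200.0, (-100.0, 10.0), (100.0, 10.0), (-50.0, 10.0)),
        # single support: combined equals the loaded plate
        (500.0, 0.0, (-80.0, 5.0), (123.0, -7.0), (-80.0, 5.0)),
    ])
    def test_weighted_mean(self, fz_l, fz_r, cop_l, cop_r, expected):
        n = 4
        left = plate("left", np.full(n, fz_l), np.full(n, cop_l[0]),
                     np.full(n, cop_l[1]))
        right = plate("right", np.full(n, fz_r), np.full(n, cop_r[0]),
                      np.full(n, cop_r[1]))
        traj = combine_plates(left, right)
        assert traj.ml == pytest.approx(np.full(n, expected[0]))
        assert traj.ap == pytest.approx(np.full(n, expected[1]))

    def test_label_exchange_invariance(self, rng):
        n = 50
        fz_l, fz_r = rng.uniform(100, 600, n), rng.uniform(100, 600, n)
        xl, yl = rng.normal(-100, 5, n), rng.normal(0, 5, n)
        xr, yr = rng.normal(100, 5, n), rng.normal(0, 5, n)
        a = combine_plates(plate("left", fz_l, xl, yl),
                           plate("right", fz_r, xr, yr))
        b = combine_plates(plate("left", fz_r, xr, yr),
                           plate("right", fz_l, xl, yl))
        np.testing.assert_allclose(a.ap, b.ap)
        np.testing.assert_allclose(a.ml, b.ml)

    def test_double_unload_is_a_signal_gap(self):
        fz = np.array([300.0, 0.0, 300.0])
        left = plate("left", fz, np.zeros(3), np.zeros(3))
        right = plate("right", fz, np.zeros(3), np.zeros(3))
        with pytest.raises(SignalGapError, match="sample 1"):
            combine_plates(left, right)


class TestDisplacement:
    def test_distance_equation(self):
        traj = CoPTrajectory(ap=[3.0, 0.0, 1.0], ml=[4.0, 0.0, 1.0], fs=120.0)
        d = displacement_magnitude(traj, reference=(0.0, 0.0))
        assert d.d == pytest.approx([5.0, 0.0, np.sqrt(2)])

    def test_constant_trajectory_is_zero(self):
        traj = CoPTrajectory(ap=np.full(10, 2.0), ml=np.full(10, -3.0),
                             fs=120.0)
        d = displacement_magnitude(traj, reference=(2.0, -3.0))
        assert np.all(d.d == 0.0)

    def test_rotation_invariance(self, rng):
        ap, ml = rng.normal(0, 5, 200), rng.normal(0, 5, 200)
        theta = 0.7
        ap_r = ap * np.cos(theta) - ml * np.sin(theta)
        ml_r = ap * np.sin(theta) + ml * np.cos(theta)
        d1 = displacement_magnitude(CoPTrajectory(ap, ml, 120.0), (0, 0))
        d2 = displacement_magnitude(CoPTrajectory(ap_r, ml_r, 120.0), (0, 0))
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-9)

    def test_default_reference_is_mean(self, rng):
        ap, ml = rng.normal(3, 1, 100), rng.normal(-2, 1, 100)
        d = displacement_magnitude(CoPTrajectory(ap, ml, 120.0))
        assert d.reference == pytest.approx((ap.mean(), ml.mean()))


class TestVelocity:
    def test_linear_drift_recovers_rate(self):
        fs = 120.0
        t = np.arange(600) / fs
        traj = CoPTrajectory(ap=10.0 * t, ml=np.zeros_like(t), fs=fs)
        v = cop_velocity(displacement_magnitude(traj, reference=(0.0, 0.0)))
        # interior samples see the exact drift rate of 10 mm/s
        np.testing.assert_allclose(v.v[1:-1], 10.0, rtol=1e-9)

    def test_constant_displacement_gives_zero(self):
        d = displacement_magnitude(
            CoPTrajectory(np.full(50, 5.0), np.zeros(50), 120.0), (0.0, 0.0))
        v = cop_velocity(d)
        assert np.all(v.v == 0.0)

    def test_circular_path_has_near_zero_scalar_velocity(self):
        # CoP circling the reference: scalar displacement is constant, so
        # the velocity reading is ~0 even though the path speed is r*omega
        fs, r, omega = 120.0, 10.0, 2 * np.pi
        t = np.arange(int(2 * fs)) / fs
        traj = CoPTrajectory(r * np.cos(omega * t), r * np.sin(omega * t), fs)
        v = cop_velocity(displacement_magnitude(traj, reference=(0.0, 0.0)))
        assert np.max(v.v[1:-1]) < 0.1
        # whereas the 2-D path speed sees the full tangential motion
        pv = path_velocity(traj)
        assert np.median(pv.v) == pytest.approx(r * omega, rel=0.01)

    def test_time_reversal_symmetry(self, rng):
        d_vals = np.abs(rng.normal(5, 1, 100))
        from posturolab.signal_io import DisplacementSeries
        fwd = cop_velocity(DisplacementSeries(d_vals, 120.0, (0, 0)))
        rev = cop_velocity(DisplacementSeries(d_vals[::-1], 120.0, (0, 0)))
        np.testing.assert_allclose(rev.v, fwd.v[::-1], atol=1e-9)

    def test_too_short_series_rejected(self):
        from posturolab.signal_io import DisplacementSeries
        with pytest.raises(InsufficientDataError):
            cop_velocity(DisplacementSeries([1.0, 2.0], 120.0, (0, 0)))


class TestTrialFiles:
    def test_round_trip(self, tmp_path, rng):
        ap, ml = rng.normal(0, 5, 360), rng.normal(0, 5, 360)
        trial = make_trial(ap, ml, kind="perturbation",
                           events=[PerturbationEvent(1.5, "trans_fwd")])
        write_trial(trial, tmp_path / "t.csv", tmp_path / "t_events.csv")
        back = read_trial(tmp_path / "t.csv",
                          events_path=tmp_path / "t_events.csv")
        assert back.participant_id == trial.participant_id
        assert back.condition == trial.condition
        assert back.fs == trial.fs
        np.testing.assert_allclose(back.left.fz, trial.left.fz, atol=1e-5)
        np.testing.assert_allclose(back.right.cop_x, trial.right.cop_x,
                                   atol=1e-5)
        assert len(back.events) == 1
        assert back.events[0].ptype == "trans_fwd"

    def test_duration_from_rows_and_rate(self, tmp_path, rng):
        trial = make_trial(rng.normal(0, 5, 3600), rng.normal(0, 5, 3600))
        write_trial(trial, tmp_path / "t.csv")
        assert read_trial(tmp_path / "t.csv").duration == pytest.approx(30.0)

    def _write_lines(self, path, rows):
        header = ("# fs_hz=120\n# participant=P01\n# group=control\n"
                  "# condition=EO_NoDT\n# kind=sway\n"
                  "t,fz_L,copx_L,copy_L,fz_R,copx_R,copy_R\n")
        path.write_text(header + "\n".join(rows) + "\n")

    def test_negative_force_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        self._write_lines(path, [
            "0.0,350,0,0,350,0,0",
            "0.00833,-1,0,0,350,0,0",
            "0.01667,350,0,0,350,0,0"])
        with pytest.raises(TrialParseError, match="row 2"):
            read_trial(path)

    def test_time_restart_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        self._write_lines(path, [
            "0.0,350,0,0,350,0,0",
            "0.00833,350,0,0,350,0,0",
            "0.0,350,0,0,350,0,0"])
        with pytest.raises(TrialParseError, match="not strictly increasing"):
            read_trial(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,fz_L,copx_L,copy_L,fz_R,copx_R,copy_R\n"
                        "0,350,0,0,350,0,0\n")
        with pytest.raises(TrialParseError, match="fs_hz"):
            read_trial(path)
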