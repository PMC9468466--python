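"""Breath timing, SIMV triggering, alarms, disconnection, and closed-loop
behaviour of the PRVC/PCV state machines."""

import numpy as np
import pytest

from turbovent.modes import (
    AlarmBounds,
    BreathRecord,
    SettingsError,
    VentSettings,
    check_alarms,
    compute_timing,
    detect_disconnection,
    run_mode,
    simv_should_trigger,
)
from turbovent.patient_sim import LungParams, make_scenario


class TestComputeTiming:
    def test_breath_cycle_time(self):
        assert compute_timing(10, 2.0).bct == pytest.approx(6.0)

    def test_expiratory_time_is_complement(self):
        t = compute_timing(12, 2.0)
        assert t.te == pytest.approx(3.0)
        assert t.ti + t.te == pytest.approx(t.bct)

    def test_sync_window_boundaries(self):
        t = compute_timing(10, 2.0, sync_window_fraction=0.1)
        assert t.non_sync_time == pytest.approx(5.4)
        assert t.sync_time == pytest.approx(3.4)

    def test_ti_exceeding_cycle_rejected(self):
        with pytest.raises(SettingsError):
            compute_timing(10, 6.5)

    def test_degenerate_window_rejected(self):
        # ti so long that syncTime = nonSyncTime - Ti would be negative
        with pytest.raises(SettingsError):
            compute_timing(10, 5.8, sync_window_fraction=0.05)


class TestSimvTrigger:
    timing = compute_timing(10, 2.0, sync_window_fraction=0.1)
    # window: expiratory elapsed in (3.4, 4.0] i.e. cycle elapsed (5.4, 6.0]

    @pytest.mark.parametrize(
        "elapsed,flow,phase,expected",
        [
            (5.7, 25.0, "exhale", True),  # inside window, above threshold
            (5.7, 20.0, "exhale", True),  # >= comparator at the setpoint
            (5.7, 19.9, "exhale", False),  # below threshold
            (3.0, 100.0, "exhale", False),  # before the window
            (5.4, 100.0, "exhale", False),  # boundary: window is open interval
            (6.0, 100.0, "exhale", True),  # closed at the cycle end
            (1.0, 100.0, "inhale", False),  # not expiratory
        ],
    )
    def test_trigger_rule(self, elapsed, flow, phase, expected):
        got = simv_should_trigger(elapsed, self.timing, flow, 20.0, phase)
        assert got is expected

    def test_window_covers_final_fraction_of_cycle(self):
        """Over 1000 evenly spread candidate times, triggers are possible
        exactly in the final window fraction of the cycle."""
        t40 = compute_timing(10, 2.0, sync_window_fraction=0.4)
        times = np.linspace(0.0, 6.0, 1001)
        fired = [
            t
            for t in times
            if simv_should_trigger(t, t40, 1e3, 20.0, "exhale" if t > 2.0 else "inhale")
        ]
        assert min(fired) > 3.6 - 1e-9  # non_sync_time
        assert max(fired) <= 6.0
        # the window spans 40% of the cycle
        assert len(fired) / len(times) == pytest.approx(0.4, abs=0.01)


class TestDisconnectionRule:
    def test_below_threshold_at_end_inspiration(self):
        assert detect_disconnection(4.9, "inhale_end") is True

    def test_boundary_is_strict(self):
        assert detect_disconnection(5.0, "inhale_end") is False

    def test_other_phases_never_flag(self):
        assert detect_disconnection(0.0, "exhale") is False


class TestAlarms:
    settings = VentSettings(
        alarms=AlarmBounds(tv=(280.0, 600.0), pip=(5.0, 30.0), peep=(2.0, 8.0))
    )

    @staticmethod
    def record(**kw):
        base = dict(
            breath_index=0,
            t_start=0.0,
            delivered_volume=350.0,
            pip=20.0,
            peep_estimate=5.0,
            min_pressure=4.5,
        )
        base.update(kw)
        return BreathRecord(**base)

    def test_all_in_bounds_is_quiet(self):
        state = check_alarms(self.record(), self.settings)
        assert state.active == frozenset()
        assert state.audible is False

    def test_low_tidal_volume_alarm(self):
        state = check_alarms(self.record(delivered_volume=250.0), self.settings)
        assert state.active == {"TV"}
        assert state.audible

    def test_simultaneous_independent_alarms(self):
        state = check_alarms(
            self.record(pip=35.0, peep_estimate=1.0), self.settings
        )
        assert state.active == {"PIP", "PEEP"}

    def test_flow_sensor_disconnect_alarm(self):
        state = check_alarms(self.record(flow_sensor_ok=False), self.settings)
        assert "flow_sensor_disconnect" in state.active

    def test_misordered_bounds_rejected(self):
        with pytest.raises(SettingsError):
            AlarmBounds(tv=(600.0, 280.0))


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"tidal_volume": 50.0},
            {"tidal_volume": 1200.0},
            {"pip_target": 40.0},
            {"bpm": 4.0},
            {"peep": 15.0},
            {"ti": 6.0, "bpm": 12.0},
            {"mode": "CPAP"},
            {"p_max": 10.0, "pip_target": 20.0},
        ],
    )
    def test_out_of_range_settings_rejected(self, kw):
        with pytest.raises(SettingsError):
            VentSettings(**kw)

    def test_defaults_valid(self):
        VentSettings()  # must not raise


class TestClosedLoopPRVC:
    def test_volume_convergence(self, prvc_run):
        dv = [b.delivered_volume for b in prvc_run.breaths[15:20]]
        assert all(abs(v - 350.0) / 350.0 < 0.05 for v in dv)

    def test_recovery_after_compliance_halved(self, prvc_run):
        # compliance halves at breath 20; within 5 breaths volume is back
        dv = [b.delivered_volume for b in prvc_run.breaths[22:26]]
        assert all(abs(v - 350.0) / 350.0 < 0.05 for v in dv)

    def test_pressure_never_exceeds_cap(self, prvc_run):
        assert max(prvc_run.samples["p_wye"]) <= prvc_run.settings.p_max

    def test_machine_breaths_evenly_spaced(self, prvc_run):
        starts = [b.t_start for b in prvc_run.breaths]
        gaps = np.diff(starts)
        assert np.allclose(gaps, 6.0, atol=0.01)  # 60/bpm at bpm 10

    def test_peep_floor_held(self, prvc_run):
        for b in prvc_run.breaths[2:]:
            assert b.peep_estimate == pytest.approx(5.0, abs=1.0)
            assert b.min_pressure == pytest.approx(5.0, abs=1.0)


class TestClosedLoopPCV:
    def test_plateau_tracks_target(self, pcv_run):
        for b in pcv_run.breaths[-5:]:
            assert b.pip == pytest.approx(20.0, abs=1.0)

    def test_expiratory_minimum_tracks_peep(self, pcv_run):
        for b in pcv_run.breaths[-5:]:
            assert b.min_pressure == pytest.approx(5.0, abs=1.0)
            assert b.peep_estimate == pytest.approx(5.0, abs=1.0)

    def test_pip_uses_band_filter_not_raw_max(self, pcv_run):
        df = pcv_run.to_dataframe()
        for b in pcv_run.breaths[-3:]:
            insp = df[(df.breath_index == b.breath_index) & (df.phase == "inhale")]
            assert b.pip <= insp.pressure_sensed.max() + 1e-9
            # the filtered PIP is smoother than the raw noisy max
            assert b.pip < insp.pressure_sensed.max()

    def test_conservation_entire_run(self, pcv_run):
        assert pcv_run.max_balance_residual < 1e-9

    def test_reproducible_bit_for_bit(self):
        s = VentSettings(mode="PCV", bpm=12, ti=2.0)
        a = run_mode(s, n_breaths=2, seed=99)
        b = run_mode(s, n_breaths=2, seed=99)
        assert a.samples == b.samples
        assert a.breaths == b.breaths

    def test_p_max_cap_engages_when_low(self):
        """With a deliberately low firmware cap the inhale speed collapses
        and the airway pressure stays at or below the cap."""
        s = VentSettings(
            mode="PRVC", tidal_volume=800.0, bpm=10, ti=2.0, peep=3.0,
            pip_target=10.0, p_max=12.0,
        )
        r = run_mode(s, n_breaths=4, seed=21)
        assert max(r.samples["p_wye"]) < 12.0 + 1.0  # sensed-cap + noise margin


class TestSimvRun:
    def test_patient_triggers_only_inside_window(self, simv_run):
        timing_window = 0.4 * 6.0  # 2.4 s before the next machine breath
        for prev, cur in zip(simv_run.breaths, simv_run.breaths[1:]):
            if cur.trigger_type == "patient":
                cycle_elapsed = cur.t_start - prev.t_start
                assert 6.0 - timing_window < cycle_elapsed <= 6.0

    def test_scripted_efforts_trigger_breaths(self, simv_run):
        # efforts at 4.5 s and 14.6 s are inside windows; 7.0 s is not
        patient_starts = [
            b.t_start for b in simv_run.breaths if b.trigger_type == "patient"
        ]
        assert any(abs(t - 4.5) < 0.3 for t in patient_starts)
        assert all(abs(t - 7.0) > 0.5 for t in patient_starts)

    def test_triggered_breath_advances_cycle(self, simv_run):
        starts = [b.t_start for b in simv_run.breaths]
        gaps = np.diff(starts)
        # at least one early (patient) cycle and no cycle longer than BCT
        assert (gaps < 6.0 - 1e-6).any()
        assert (gaps <= 6.0 + 0.01).all()


class TestDisconnectionRun:
    def test_alarm_raised_within_two_breaths(self, disconnect_run):
        # leak opens at 12 s; breath cycle is 5 s
        flagged = [
            b for b in disconnect_run.breaths if "disconnection" in b.alarms
        ]
        assert flagged
        assert flagged[0].t_start <= 12.0 + 2 * 5.0

    def test_pip_collapses_below_threshold(self, disconnect_run):
        flagged = [
            b for b in disconnect_run.breaths if "disconnection" in b.alarms
        ]
        assert all(b.pip < 5.0 for b in flagged)

    def test_alarm_clears_after_reconnection(self, disconnect_run):
        # reconnected at 32 s
        after = [b for b in disconnect_run.breaths if b.t_start >= 37.0]
        assert after
        assert all("disconnection" not in b.alarms for b in after)

    def test_pressure_recovers_after_reconnection(self, disconnect_run):
        last = disconnect_run.breaths[-1]
        assert last.pip == pytest.approx(20.0, abs=2.0)
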