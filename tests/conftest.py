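"""Shared fixtures: the expensive closed-loop runs are computed once per
session and reused by both the behavioural and the acceptance tests."""

from __future__ import annotations

import pytest

from turbovent import (
    LungParams,
    VentSettings,
    make_scenario,
    run_mode,
)


@pytest.fixture(scope="session")
def prvc_run():
    """26-breath PRVC run, 350 ml target, compliance halved at breath 20."""
    settings = VentSettings(mode="PRVC", tidal_volume=350.0, bpm=10, ti=2.0, peep=5.0)
    return run_mode(
        settings,
        n_breaths=26,
        seed=11,
        lung_params_schedule={20: LungParams(compliance=25.0)},
    )


@pytest.fixture(scope="session")
def pcv_run():
    """60 s PCV run (12 breaths at 12 BPM), PIP 20 / PEEP 5 on the default lung."""
    settings = VentSettings(mode="PCV", pip_target=20.0, bpm=12, ti=2.0, peep=5.0)
    return run_mode(settings, n_breaths=12, seed=12)


@pytest.fixture(scope="session")
def simv_run():
    """SIMV-enabled PRVC with the 40% trigger window and scripted efforts.

    Efforts at 4.5 s and 14.6 s land inside the window (BCT 6 s, Ti 2 s,
    window = final 2.4 s of each cycle); the effort at 7.0 s lands outside.
    """
    scenario = make_scenario(
        "spontaneous", effort_times=(4.5, 7.0, 14.6), effort_amplitude=-3.0
    )
    settings = VentSettings(
        mode="PRVC",
        tidal_volume=300.0,
        bpm=10,
        ti=2.0,
        peep=3.0,
        sync_window_fraction=0.4,
        simv=True,
    )
    return run_mode(settings, n_breaths=6, seed=13, scenario=scenario)


@pytest.fixture(scope="session")
def disconnect_run():
    """PCV run with the circuit disconnected at 12 s and reconnected at 32 s."""
    scenario = make_scenario("reconnect", event_times=(12.0, 32.0))
    settings = VentSettings(mode="PCV", pip_target=20.0, bpm=12, ti=2.0, peep=5.0)
    return run_mode(settings, n_breaths=10, seed=14, scenario=scenario)
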