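"""Shared fixtures: calibrated model conditions, protocol trials, and
lightweight synthetic trials for the imaging/statistics tests."""

from __future__ import annotations

import numpy as np
import pytest

from kagate import cable_model as cm
from kagate import protocols as pro


@pytest.fixture(scope="session")
def default_model():
    return cm.ModelSpec()


@pytest.fixture(scope="session")
def calibrated(default_model):
    """(graph, holding current, stimulus amplitude) at control gK_A."""
    graph, i_hold, amp_min = pro.calibrate_condition(default_model)
    amp = pro.calibrate_test_stimulus(graph, i_hold, amp_min)
    return graph, i_hold, amp


@pytest.fixture(scope="session")
def single_trials(default_model, calibrated):
    """bAP / IPSP-bAP / IPSP trials at control gK_A."""
    graph, i_hold, amp = calibrated
    return {
        tt: pro.run_trial(pro.ProtocolSpec(tt, model=default_model),
                          graph=graph, i_hold=i_hold, amp=amp)
        for tt in ("bAP", "IPSP-bAP", "IPSP")
    }


@pytest.fixture(scope="session")
def sweep_result(default_model):
    """Full 7-point A-type density sweep."""
    return pro.run_gka_sweep(model=default_model)


@pytest.fixture(scope="session")
def train_table(default_model):
    """Train-scaling study at control and low gK_A, 50 and 100 Hz."""
    return pro.train_scaling_study(model=default_model)


def make_synthetic_trial(
    trial_type: str = "bAP",
    amplitude: float = 2e-6,
    t_test: float = 60.0,
    duration: float = 190.0,
    dt: float = 0.1,
    width: float = 3.0,
    rest_current: float = 1e-8,
) -> pro.TrialResult:
    """Analytic stand-in for a simulated trial (synthetic; no cable solve).

    The reporter current is a Gaussian inward transient at the test-pulse
    time on top of a constant resting pedestal; IPSP-only types carry no
    transient. Used to exercise the imaging/statistics chain quickly with
    exactly known ground truth.
    """
    spec = pro.ProtocolSpec(trial_type)
    t = np.arange(0.0, duration + dt / 2, dt)
    has_bap = "bAP" in trial_type.split("-")
    # transient centered well after test onset so its tail is negligible in
    # every trial type's pre-event baseline window
    bump = amplitude * np.exp(-0.5 * ((t - (t_test + 6 * width)) / width) ** 2)
    ica = -(rest_current + (bump if has_bap else np.zeros_like(t)))
    v = np.full_like(t, -64.0)
    traces = {
        site: cm.Trace(t, {"v": v.copy(), "ica": ica.copy()})
        for site in ("spine", "shaft")
    }
    return pro.TrialResult(
        spec=spec,
        traces=traces,
        holding_current=0.0,
        stim_amplitude=0.0,
        t_test=t_test,
        vmin=v.copy(),
        spike_count=1 if has_bap else 0,
        expected_spikes=1 if has_bap else 0,
    )


@pytest.fixture()
def synthetic_trials():
    """Synthetic trial triplet with a known inhibition fraction of 0.25."""
    return {
        "bAP": make_synthetic_trial("bAP", amplitude=2e-6),
        "IPSP-bAP": make_synthetic_trial("IPSP-bAP", amplitude=1.5e-6),
        "IPSP": make_synthetic_trial("IPSP"),
    }
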