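"""Stimulation protocols and condition sweeps.

Reproduces the experimental design in the model: a somatic holding current
keeps the resting potential at -64.00 +/- 0.001 mV; back-propagating action
potentials (bAPs) are evoked by brief somatic pulses (0.5 ms, calibrated
from a 1.5-2.5 nA bracket to the smallest single-spike amplitude); the
GABA-A conductance precedes the test pulse by 15 ms; spike trains (5 pulses
at 50 or 100 Hz) end 20 ms before the test pulse. The A-type maximum
density is swept 10-70 mS/cm2 to emulate control vs 4-AP conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import calcium_analysis as ca
from .cable_model import (
    CompartmentGraph,
    CurrentPulse,
    ModelSpec,
    SolverConfig,
    Trace,
    build_model,
    simulate,
    steady_state,
)

__all__ = [
    "TRIAL_TYPES",
    "StimulusPulse",
    "ProtocolSpec",
    "TrialResult",
    "SweepResult",
    "CalibrationError",
    "find_holding_current",
    "calibrate_spike_stimulus",
    "calibrate_condition",
    "count_spikes",
    "run_trial",
    "run_train_trial",
    "run_gka_sweep",
    "train_scaling_study",
    "trial_timeline",
]

# The seven interleaved trial types of the experimental design.
TRIAL_TYPES = (
    "bAP",
    "IPSP-bAP",
    "IPSP",
    "train-bAP",
    "train-IPSP-bAP",
    "train-IPSP",
    "train",
)

StimulusPulse = CurrentPulse

HOLD_TARGET = -64.0       # mV
HOLD_TOL = 1e-3           # mV
PULSE_WIDTH = 0.5         # ms
SPIKE_THRESHOLD = 0.0     # mV, upward crossing defines a somatic spike


class CalibrationError(RuntimeError):
    """Holding-current or stimulus calibration failed."""


@dataclass
class ProtocolSpec:
    """One trial's stimulus program plus the model condition it runs in."""

    trial_type: str = "bAP"
    train_freq: float = 100.0   # Hz
    train_count: int = 5
    ipsp_lead: float = 15.0     # ms before the test pulse
    train_gap: float = 20.0     # ms between train end and test pulse onset
    model: ModelSpec = field(default_factory=ModelSpec)
    dt: float = 0.005           # ms
    pre_window: float = 40.0    # ms of baseline before the first event
    post_window: float = 130.0  # ms recorded after the test pulse onset

    def __post_init__(self):
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.train_freq <= 0 or self.train_count < 1:
            raise ValueError("invalid train parameters")
        if self.post_window < 100.0:
            raise ValueError("post_window must cover the 100-ms quantification window")

    @property
    def parts(self) -> set[str]:
        return set(self.trial_type.split("-"))

    @property
    def has_train(self) -> bool:
        return "train" in self.parts

    @property
    def has_ipsp(self) -> bool:
        return "IPSP" in self.parts

    @property
    def has_test_pulse(self) -> bool:
        return "bAP" in self.parts


def trial_timeline(spec: ProtocolSpec):
    """(t_test, duration, train_onsets) for a protocol.

    The test-pulse onset is placed so that a train of ``train_count``
    pulses starting at ``pre_window`` ends ``train_gap`` ms before it; the
    timeline is shared by all trial types with the same train settings so
    that trials differing only in later events are sample-identical up to
    the first differing event.
    """
    isi = 1000.0 / spec.train_freq
    train_span = (spec.train_count - 1) * isi + PULSE_WIDTH
    if spec.has_train:
        t_test = spec.pre_window + train_span + spec.train_gap
        train_onsets = [spec.pre_window + k * isi for k in range(spec.train_count)]
    else:
        t_test = spec.pre_window + spec.ipsp_lead + 5.0
        train_onsets = []
    duration = t_test + spec.post_window
    return t_test, duration, train_onsets


@dataclass
class TrialResult:
    """Traces and stimulus metadata for one protocol trial."""

    spec: ProtocolSpec
    traces: dict[str, Trace]
    holding_current: float      # nA
    stim_amplitude: float       # nA
    t_test: float               # ms, test-pulse onset (window start)
    vmin: np.ndarray            # per-compartment minimum V over the trial
    spike_count: int
    expected_spikes: int

    @property
    def flagged(self) -> bool:
        """True when the somatic spike count deviates from the design
        (bursting or failed pulses), mirroring the experimental exclusion."""
        return self.spike_count != self.expected_spikes

    def ca_response(
        self, site: str, window: float = 100.0, baseline_corrected: bool = True
    ) -> ca.CaResponse:
        """Evoked Ca flux over the 100-ms window from test-pulse onset.

        By default the standing (resting) reporter current is subtracted
        before integrating, mirroring the baseline subtraction of the
        fluorescence analysis; trials start at the held steady state, so
        the first sample defines the pedestal.
        """
        tr = self.traces[site]
        flux = np.clip(-np.asarray(tr["ica"], dtype=float), 0.0, None)
        if baseline_corrected:
            flux = flux - flux[0]
        evoked = Trace(tr.t, {"flux": flux})
        return ca.ca_flux_integral(
            evoked, t0=self.t_test, window=window, series="flux",
            mode="signed", site=site,
        )


def count_spikes(v: np.ndarray, threshold: float = SPIKE_THRESHOLD) -> int:
    """Number of upward threshold crossings."""
    v = np.asarray(v, dtype=float)
    return int(np.sum((v[:-1] < threshold) & (v[1:] >= threshold)))


def find_holding_current(
    graph: CompartmentGraph,
    target: float = HOLD_TARGET,
    tol: float = HOLD_TOL,
    max_iter: int = 60,
) -> float:
    """Constant somatic current (nA) holding the somatic rest at ``target``.

    Iterative (secant) search on the self-consistent steady-state somatic
    potential as a function of injected current, starting from the natural
    resting point so that every evaluation stays in the subthreshold
    regime. The returned current reproduces the target within ``tol`` mV
    in a long unstimulated simulation. Re-run this for every
    channel-density condition.
    """
    soma = graph.sites["soma"]

    def v_of(i_hold: float) -> float:
        try:
            return float(steady_state(graph, i_hold).v[soma])
        except RuntimeError as exc:
            raise CalibrationError(f"no steady state at {i_hold:g} nA: {exc}") from exc

    i0, v0 = 0.0, v_of(0.0)
    i1 = 0.01 if target > v0 else -0.01
    v1 = v_of(i1)
    for _ in range(max_iter):
        if abs(v1 - target) < tol * 1e-3:
            break
        if v1 == v0:
            raise CalibrationError("holding-current search stalled (flat V-I relation)")
        i2 = i1 + (target - v1) * (i1 - i0) / (v1 - v0)
        i0, v0 = i1, v1
        i1, v1 = i2, v_of(i2)
    r = abs(v1 - target)
    if r > tol:
        raise CalibrationError(
            f"holding-current search residual {r:.2e} mV exceeds {tol} mV"
        )
    return float(i1)


def _spike_count_for_amplitude(graph, i_hold, amp, state0, dt) -> int:
    pulse = CurrentPulse(onset=5.0, width=PULSE_WIDTH, amplitude=amp, target="soma")
    cfg = SolverConfig(dt=dt, duration=50.0, record_sites=("soma",))
    traces = simulate(graph, cfg, pulses=[pulse], i_hold=i_hold, state0=state0)
    return count_spikes(traces["soma"]["v"])


def calibrate_spike_stimulus(
    graph: CompartmentGraph,
    i_hold: float,
    bracket: tuple[float, float] = (1.5, 2.5),
    tol: float = 0.01,
    dt: float = 0.005,
    max_expansions: int = 8,
) -> float:
    """Smallest somatic 0.5-ms pulse amplitude (nA) evoking exactly one spike.

    Bisection to ``tol`` nA starting from the experimental 1.5-2.5 nA
    bracket, expanding if needed. Conditions in which the threshold
    stimulus evokes more than one spike (bursting) raise
    :class:`CalibrationError`, mirroring the experimental exclusion rule.
    """
    state0 = steady_state(graph, i_hold)
    lo, hi = bracket
    k = 0
    while _spike_count_for_amplitude(graph, i_hold, lo, state0, dt) > 0:
        lo /= 2.0
        k += 1
        if k > max_expansions:
            raise CalibrationError("no subthreshold amplitude found")
    k = 0
    while _spike_count_for_amplitude(graph, i_hold, hi, state0, dt) == 0:
        hi *= 2.0
        k += 1
        if k > max_expansions:
            raise CalibrationError("no suprathreshold amplitude found")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _spike_count_for_amplitude(graph, i_hold, mid, state0, dt) == 0:
            lo = mid
        else:
            hi = mid
    n = _spike_count_for_amplitude(graph, i_hold, hi, state0, dt)
    if n != 1:
        raise CalibrationError(
            f"threshold stimulus evokes {n} spikes (bursting condition excluded)"
        )
    return float(hi)


def calibrate_train_stimulus(
    graph: CompartmentGraph,
    i_hold: float,
    amp_start: float,
    freqs: Sequence[float] = (50.0, 100.0),
    count: int = 5,
    gap: float = 20.0,
    step: float = 0.05,
    max_amp: float = 10.0,
    dt: float = 0.005,
) -> float:
    """Smallest pulse amplitude reliable across the train protocol family.

    The minimal single-spike amplitude generally fails during the relative
    refractory period of a train and for the test pulse that follows the
    train by ``gap`` ms, so the amplitude is scanned upward from
    ``amp_start`` in ``step``-nA increments until (a) a single pulse evokes
    exactly one spike and (b) for every train frequency, ``count`` train
    pulses plus the delayed test pulse each evoke exactly one spike.
    Amplitudes that evoke extra spikes (bursting) raise
    :class:`CalibrationError`.
    """
    state0 = steady_state(graph, i_hold)
    ipsp_lead = 15.0

    def pulse_program(freq: float | None):
        if freq is None:
            return [5.0]
        isi = 1000.0 / freq
        onsets = [5.0 + k * isi for k in range(count)]
        onsets.append(onsets[-1] + PULSE_WIDTH + gap)
        return onsets

    def counts_ok(amp: float) -> bool:
        for freq in (None, *freqs):
            onsets = pulse_program(freq)
            for with_ipsp in (False, True):
                pulses = [CurrentPulse(o, PULSE_WIDTH, amp, "soma") for o in onsets]
                syn = [onsets[-1] - ipsp_lead] if with_ipsp else []
                cfg = SolverConfig(
                    dt=dt, duration=onsets[-1] + 30.0, record_sites=("soma",)
                )
                traces = simulate(graph, cfg, pulses=pulses, syn_onsets=syn,
                                  i_hold=i_hold, state0=state0)
                n = count_spikes(traces["soma"]["v"])
                if n != len(onsets):
                    # too few: refractory failure; too many: bursting zone —
                    # either way this amplitude is unusable, keep scanning
                    return False
        return True

    amp = amp_start
    while amp <= max_amp:
        if counts_ok(amp):
            return float(amp)
        amp += step
    raise CalibrationError("no train-capable stimulus amplitude found")


def calibrate_test_stimulus(
    graph: CompartmentGraph,
    i_hold: float,
    amp_start: float,
    step: float = 0.05,
    max_amp: float = 10.0,
    dt: float = 0.005,
    ipsp_lead: float = 15.0,
) -> float:
    """Smallest amplitude evoking exactly one spike with and without an IPSP.

    Starting from the minimal single-spike amplitude, the pulse is
    strengthened until the spike also survives a preceding GABAergic
    conductance, as in the experiments where spikes persisted on IPSP
    trials.
    """
    state0 = steady_state(graph, i_hold)
    amp = amp_start
    while amp <= max_amp:
        ok = True
        for with_ipsp in (False, True):
            pulse = CurrentPulse(5.0 + ipsp_lead, PULSE_WIDTH, amp, "soma")
            cfg = SolverConfig(dt=dt, duration=50.0 + ipsp_lead, record_sites=("soma",))
            traces = simulate(
                graph, cfg, pulses=[pulse], syn_onsets=[5.0] if with_ipsp else [],
                i_hold=i_hold, state0=state0,
            )
            if count_spikes(traces["soma"]["v"]) != 1:
                ok = False
                break
        if ok:
            return float(amp)
        amp += step
    raise CalibrationError("no IPSP-robust stimulus amplitude found")


def calibrate_condition(model: ModelSpec, dt: float = 0.005):
    """Build and calibrate one model condition.

    Returns (graph, holding current nA, stimulus amplitude nA).
    """
    graph = build_model(model)
    i_hold = find_holding_current(graph)
    amp = calibrate_spike_stimulus(graph, i_hold, dt=dt)
    return graph, i_hold, amp


def run_trial(
    spec: ProtocolSpec,
    graph: CompartmentGraph | None = None,
    i_hold: float | None = None,
    amp: float | None = None,
) -> TrialResult:
    """Run one protocol trial from the calibrated held state.

    The trial starts at the self-consistent held steady state, so no
    settling window is needed; all events are resolved to the nearest
    solver step. Deterministic: identical inputs give identical samples.
    """
    if graph is None:
        graph = build_model(spec.model)
    if i_hold is None:
        i_hold = find_holding_current(graph)
    if amp is None and (spec.has_test_pulse or spec.has_train):
        amp = calibrate_spike_stimulus(graph, i_hold, dt=spec.dt)
    amp = 0.0 if amp is None else amp

    t_test, duration, train_onsets = trial_timeline(spec)
    pulses = []
    expected = 0
    if spec.has_train:
        for onset in train_onsets:
            pulses.append(CurrentPulse(onset, PULSE_WIDTH, amp, "soma"))
        expected += spec.train_count
    if spec.has_test_pulse:
        pulses.append(CurrentPulse(t_test, PULSE_WIDTH, amp, "soma"))
        expected += 1
    syn_onsets = [t_test - spec.ipsp_lead] if spec.has_ipsp else []

    cfg = SolverConfig(dt=spec.dt, duration=duration,
                       record_sites=("soma", "synapse", "spine", "shaft"))
    state0 = steady_state(graph, i_hold)
    traces = simulate(graph, cfg, pulses=pulses, syn_onsets=syn_onsets,
                      i_hold=i_hold, state0=state0)
    vmin = traces.pop("_vmin")["v"]
    n_spikes = count_spikes(traces["soma"]["v"])
    return TrialResult(
        spec=spec,
        traces=traces,
        holding_current=i_hold,
        stim_amplitude=amp,
        t_test=t_test,
        vmin=vmin,
        spike_count=n_spikes,
        expected_spikes=expected,
    )


def run_train_trial(spec: ProtocolSpec, **kwargs) -> TrialResult:
    """Run a train-containing trial (thin wrapper with a type check)."""
    if not spec.has_train:
        raise ValueError("run_train_trial requires a train-containing trial type")
    return run_trial(spec, **kwargs)


# ---------------------------------------------------------------------------
# Condition sweeps
# ---------------------------------------------------------------------------

DEFAULT_SWEEP = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
SITES = ("spine", "shaft")


def paired_inhibition_fraction(
    ctl: TrialResult,
    inh: TrialResult,
    inh_baseline: TrialResult | None,
    site: str,
    window: float = 100.0,
    ctl_baseline: TrialResult | None = None,
) -> ca.InhibitionResult:
    """Inhibition fraction with experiment-style baseline pairing.

    The control response is the evoked flux of the control trial (minus
    its train-alone baseline trial when given, else minus the resting
    pedestal); the inhibited response subtracts the matched
    inhibition-alone trial (IPSP or train-IPSP), which removes both the
    pedestal and the IPSP-induced change in standing Ca influx — the same
    arithmetic the fluorescence analysis applies via uncaging-alone
    subtraction.
    """
    if ctl_baseline is not None:
        d_ctl = (ctl.ca_response(site, window, baseline_corrected=False).integral
                 - ctl_baseline.ca_response(site, window, baseline_corrected=False).integral)
    else:
        d_ctl = ctl.ca_response(site, window).integral
    if inh_baseline is not None:
        d_inh = (inh.ca_response(site, window, baseline_corrected=False).integral
                 - inh_baseline.ca_response(site, window, baseline_corrected=False).integral)
    else:
        d_inh = inh.ca_response(site, window).integral
    return ca.inhibition_fraction(
        ca.CaResponse(site, d_ctl, ctl.t_test, window),
        ca.CaResponse(site, d_inh, inh.t_test, window),
    )


@dataclass
class SweepResult:
    """Per-condition metrics across the A-type density sweep."""

    table: pd.DataFrame
    trials: dict[float, dict[str, TrialResult]]
    failures: dict[float, str]

    def site_table(self, site: str) -> pd.DataFrame:
        return self.table[self.table["site"] == site].sort_values("gka").reset_index(drop=True)

    def convexity(self, site: str = "spine", condition: str = "ctl") -> ca.ConvexityResult:
        """Supralinearity of peak Ca current vs peak AP voltage across the sweep."""
        sub = self.site_table(site)
        return ca.convexity_check(
            sub[f"ap_peak_{condition}"], np.abs(sub[f"peak_ica_{condition}"])
        )


def _trial_metrics(trial: TrialResult, site: str, window: float = 100.0):
    tr = trial.traces[site].window(trial.t_test - 2.0, trial.t_test + window)
    m = ca.ap_metrics(tr, baseline=HOLD_TARGET)
    flux = trial.ca_response(site, window=window).integral
    return m, flux


def run_gka_sweep(
    g_values: Sequence[float] = DEFAULT_SWEEP,
    model: ModelSpec | None = None,
    dt: float = 0.005,
) -> SweepResult:
    """Sweep the distal A-type maximum density and quantify bAP +/- IPSP.

    For each density the holding current and spike stimulus are
    recalibrated; a bAP and an IPSP-bAP trial are run; AP peak and
    half-width, peak reporter Ca current, 100-ms Ca flux, and the
    inhibition fraction are tabulated per site. A calibration failure marks
    the condition and the sweep continues.
    """
    if len(g_values) < 2:
        raise ValueError("sweep requires at least 2 density values")
    base = model or ModelSpec()
    rows = []
    trials: dict[float, dict[str, TrialResult]] = {}
    failures: dict[float, str] = {}
    for g in g_values:
        mspec = replace(base, gka_distal=float(g))
        try:
            graph, i_hold, amp = calibrate_condition(mspec, dt=dt)
            amp = calibrate_test_stimulus(graph, i_hold, amp, dt=dt)
            ctl = run_trial(ProtocolSpec("bAP", model=mspec, dt=dt),
                            graph=graph, i_hold=i_hold, amp=amp)
            inh = run_trial(ProtocolSpec("IPSP-bAP", model=mspec, dt=dt),
                            graph=graph, i_hold=i_hold, amp=amp)
            ipsp = run_trial(ProtocolSpec("IPSP", model=mspec, dt=dt),
                             graph=graph, i_hold=i_hold, amp=amp)
        except CalibrationError as exc:
            failures[float(g)] = str(exc)
            continue
        trials[float(g)] = {"bAP": ctl, "IPSP-bAP": inh, "IPSP": ipsp}
        for site in SITES:
            m_ctl, flux_ctl = _trial_metrics(ctl, site)
            m_inh, flux_inh = _trial_metrics(inh, site)
            frac = paired_inhibition_fraction(ctl, inh, ipsp, site).fraction
            rows.append({
                "gka": float(g),
                "site": site,
                "holding_current": i_hold,
                "stim_amplitude": amp,
                "ap_peak_ctl": m_ctl.peak,
                "ap_peak_inh": m_inh.peak,
                "half_width_ctl": m_ctl.half_width,
                "half_width_inh": m_inh.half_width,
                "peak_ica_ctl": m_ctl.peak_ica,
                "peak_ica_inh": m_inh.peak_ica,
                "flux_ctl": flux_ctl,
                "flux_inh": flux_inh,
                "inhibition_fraction": frac,
            })
    return SweepResult(table=pd.DataFrame(rows), trials=trials, failures=failures)


def _train_fraction(
    graph, mspec, i_hold, amp, freq: float, dt: float, window: float = 100.0
) -> dict[str, float]:
    """Inhibition fraction of the test-pulse Ca response after a train.

    The test-pulse response in train trials is isolated by subtracting the
    matched train-only baseline flux over the same window:
    dCa = flux(train+test) - flux(train-alone), and analogously with IPSP.
    """
    out = {}
    kw = dict(model=mspec, dt=dt, train_freq=freq)
    t_ctl = run_trial(ProtocolSpec("train-bAP", **kw), graph=graph, i_hold=i_hold, amp=amp)
    t_inh = run_trial(ProtocolSpec("train-IPSP-bAP", **kw), graph=graph, i_hold=i_hold, amp=amp)
    t_base = run_trial(ProtocolSpec("train", **kw), graph=graph, i_hold=i_hold, amp=amp)
    t_base_i = run_trial(ProtocolSpec("train-IPSP", **kw), graph=graph, i_hold=i_hold, amp=amp)
    for trial in (t_ctl, t_inh, t_base, t_base_i):
        if trial.flagged:
            raise CalibrationError(
                f"train trial {trial.spec.trial_type!r} evoked {trial.spike_count} "
                f"spikes, expected {trial.expected_spikes}"
            )
    for site in SITES:
        out[site] = paired_inhibition_fraction(
            t_ctl, t_inh, t_base_i, site, window=window, ctl_baseline=t_base
        ).fraction
    out["trials"] = {
        "train-bAP": t_ctl, "train-IPSP-bAP": t_inh,
        "train": t_base, "train-IPSP": t_base_i,
    }
    return out


def train_scaling_study(
    g_values: Sequence[float] = (70.0, 10.0),
    freqs: Sequence[float] = (50.0, 100.0),
    model: ModelSpec | None = None,
    dt: float = 0.005,
) -> pd.DataFrame:
    """Model analogue of the train experiments: inhibition fraction for a
    single bAP vs after 5-spike trains, per A-type condition and frequency.

    Returns a tidy table with one row per (gka, site, condition), where
    condition is "single" or "train@<freq>Hz", plus the A-type inactivation
    gate value at the synapse at test-pulse onset.
    """
    base = model or ModelSpec()
    rows = []
    for g in g_values:
        mspec = replace(base, gka_distal=float(g))
        graph, i_hold, amp_min = calibrate_condition(mspec, dt=dt)
        # one fixed suprathreshold amplitude per condition, reliable at the
        # highest train frequency, used for single and train trials alike
        amp = calibrate_train_stimulus(
            graph, i_hold, amp_min, freqs=freqs, dt=dt
        )
        ctl = run_trial(ProtocolSpec("bAP", model=mspec, dt=dt),
                        graph=graph, i_hold=i_hold, amp=amp)
        inh = run_trial(ProtocolSpec("IPSP-bAP", model=mspec, dt=dt),
                        graph=graph, i_hold=i_hold, amp=amp)
        ipsp = run_trial(ProtocolSpec("IPSP", model=mspec, dt=dt),
                         graph=graph, i_hold=i_hold, amp=amp)
        b_single = _gate_at(ctl, "ka_b", ctl.t_test)
        for site in SITES:
            frac = paired_inhibition_fraction(ctl, inh, ipsp, site).fraction
            rows.append({
                "gka": float(g), "site": site, "condition": "single",
                "freq": 0.0, "inhibition_fraction": frac, "ka_b_at_test": b_single,
            })
        for freq in freqs:
            res = _train_fraction(graph, mspec, i_hold, amp, freq, dt)
            b_train = _gate_at(res["trials"]["train-bAP"], "ka_b",
                               res["trials"]["train-bAP"].t_test)
            for site in SITES:
                rows.append({
                    "gka": float(g), "site": site,
                    "condition": f"train@{freq:g}Hz", "freq": float(freq),
                    "inhibition_fraction": res[site], "ka_b_at_test": b_train,
                })
    return pd.DataFrame(rows)


def _gate_at(trial: TrialResult, series: str, t: float) -> float:
    tr = trial.traces["synapse"]
    idx = int(np.argmin(np.abs(tr.t - t)))
    return float(tr[series][idx])
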