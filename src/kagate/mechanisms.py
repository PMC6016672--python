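"""Voltage-gated channel kinetics and the GABAergic synaptic conductance.

The mechanism set is the one used by the compartmental model: fast sodium and
delayed-rectifier potassium channels in classic Hodgkin-Huxley form (rate
constants shifted so that spike threshold sits near -50 mV from a -64 mV
holding level), a rapidly activating/inactivating A-type potassium channel
whose density rises linearly along the apical trunk, a low-density
"reporter" calcium channel with medium-threshold activation, and a
peak-normalized biexponential GABA-A conductance.

Units package-wide: mV, ms, nA, nS, uA/cm2, mS/cm2, uF/cm2, um, Ohm*cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "SynapseSpec",
    "MechanismState",
    "gate_steady_state",
    "gate_step",
    "channel_current",
    "ka_density_at",
    "biexp_conductance",
    "biexp_peak_time",
    "na_channel",
    "kdr_channel",
    "ka_channel",
    "ca_reporter",
    "gaba_synapse",
    "MECHANISM_LIBRARY",
    "E_NA",
    "E_K",
    "E_CA",
    "E_CL",
]

# Reversal potentials (mV). E_K is aligned with the chloride/leak reversal so
# that no mechanism can drive the membrane below the GABA-A reversal.
E_NA = 60.0
E_K = -70.0
E_CA = 120.0
E_CL = -70.0


def _efun(u):
    """u / (1 - exp(-u)), series-expanded near u = 0 for numerical safety."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-6
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 + u / 2.0, safe / (1.0 - np.exp(-np.clip(safe, -500, 500))))
    return out if out.ndim else float(out)


def _sigmoid(v, v_half, k):
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-np.clip((v - v_half) / k, -500, 500)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating variable.

    ``steady_state`` and ``time_constant`` are vectorized functions of
    membrane potential (mV); ``exponent`` is the power applied to the gate
    value in the channel's open-fraction product.
    """

    name: str
    steady_state: Callable[[np.ndarray], np.ndarray]
    time_constant: Callable[[np.ndarray], np.ndarray]
    exponent: int = 1


@dataclass(frozen=True)
class ChannelSpec:
    """An ohmic conductance with a product of gates.

    ``max_density`` in mS/cm2, ``reversal`` in mV.
    """

    name: str
    gates: tuple[GateSpec, ...]
    max_density: float
    reversal: float

    def __post_init__(self):
        if self.max_density < 0:
            raise ValueError(f"max_density must be >= 0, got {self.max_density}")
        if not np.isfinite(self.reversal):
            raise ValueError("reversal must be finite")

    def open_fraction(self, gate_values: Sequence[float]) -> float:
        out = 1.0
        for g, x in zip(self.gates, gate_values, strict=True):
            out = out * np.asarray(x, dtype=float) ** g.exponent
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "max_density": self.max_density,
            "reversal": self.reversal,
            "gates": [g.name for g in self.gates],
        }


@dataclass
class MechanismState:
    """Gate values for one channel instance plus derived quantities."""

    channel: ChannelSpec
    gate_values: np.ndarray

    def __post_init__(self):
        self.gate_values = np.asarray(self.gate_values, dtype=float)
        if np.any(self.gate_values < -1e-12) or np.any(self.gate_values > 1 + 1e-12):
            raise ValueError("gate values must lie in [0, 1]")

    def open_fraction(self) -> float:
        return float(self.channel.open_fraction(self.gate_values))

    def conductance(self, density: float | None = None) -> float:
        """Instantaneous conductance density (mS/cm2)."""
        d = self.channel.max_density if density is None else density
        return d * self.open_fraction()

    def current(self, v: float, density: float | None = None) -> float:
        return channel_current(
            self.channel.max_density if density is None else density,
            self,
            v,
            self.channel.reversal,
        )


def gate_steady_state(v, gate: GateSpec):
    """Steady-state activation of ``gate`` at potential ``v`` (mV), in [0, 1]."""
    return np.clip(gate.steady_state(v), 0.0, 1.0)


def gate_step(m, v, dt: float, gate: GateSpec):
    """Exact exponential update of a gate over ``dt`` at frozen voltage.

    m' = m_inf + (m - m_inf) * exp(-dt / tau(v)).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    m_inf = gate_steady_state(v, gate)
    tau = gate.time_constant(v)
    return m_inf + (np.asarray(m, dtype=float) - m_inf) * np.exp(-dt / tau)


def channel_current(density: float, state: MechanismState, v, reversal: float):
    """Ohmic channel current density I = g_max * prod(gate^p) * (V - E).

    Positive values are outward currents; units uA/cm2 for ``density`` in
    mS/cm2 and voltages in mV.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    return density * state.open_fraction() * (np.asarray(v, dtype=float) - reversal)


# ---------------------------------------------------------------------------
# Sodium channel (m^3 h), classic squid-type rates referenced to a -65 mV rest
# ---------------------------------------------------------------------------

# overall rate scale: squid-type kinetics are too slow for a cortical cell
# at the model's operating point; 2.5x gives ~1.5-2 ms somatic spikes
_NA_RATE_SCALE = 2.5


def _na_m_alpha(v):
    return _NA_RATE_SCALE * _efun((np.asarray(v, dtype=float) + 40.0) / 10.0)


def _na_m_beta(v):
    return _NA_RATE_SCALE * 4.0 * np.exp(-(np.asarray(v, dtype=float) + 65.0) / 18.0)


def _na_h_alpha(v):
    return _NA_RATE_SCALE * 0.07 * np.exp(-(np.asarray(v, dtype=float) + 65.0) / 20.0)


def _na_h_beta(v):
    return _NA_RATE_SCALE * _sigmoid(v, -35.0, 10.0)


def _rate_gate(name, alpha, beta, exponent=1):
    return GateSpec(
        name=name,
        steady_state=lambda v: alpha(v) / (alpha(v) + beta(v)),
        time_constant=lambda v: 1.0 / (alpha(v) + beta(v)),
        exponent=exponent,
    )


def na_channel(density: float = 4.0) -> ChannelSpec:
    """Fast transient Na+ channel; default density 4 mS/cm2, uniform."""
    return ChannelSpec(
        name="na",
        gates=(
            _rate_gate("m", _na_m_alpha, _na_m_beta, exponent=3),
            _rate_gate("h", _na_h_alpha, _na_h_beta, exponent=1),
        ),
        max_density=density,
        reversal=E_NA,
    )


# ---------------------------------------------------------------------------
# Delayed-rectifier K+ (n^4)
# ---------------------------------------------------------------------------

def _kdr_n_inf(v):
    return _sigmoid(v, -50.0, 5.0)


def _kdr_n_tau(v):
    # fast activation during the spike, slow deactivation at subthreshold
    # voltages: after spiking the rectifier lingers open and restores the
    # membrane toward rest (E_K = E_leak here, so it cannot undershoot)
    v = np.asarray(v, dtype=float)
    return 0.8 + 6.2 / (1.0 + np.exp(np.clip((v + 45.0) / 8.0, -500, 500)))


def kdr_channel(density: float = 0.1) -> ChannelSpec:
    """Hodgkin-Huxley style delayed rectifier; default density 0.1 mS/cm2."""
    return ChannelSpec(
        name="kdr",
        gates=(GateSpec("n", _kdr_n_inf, _kdr_n_tau, exponent=4),),
        max_density=density,
        reversal=E_K,
    )


# ---------------------------------------------------------------------------
# A-type K+ channel (a * b): fast activation by depolarization, voltage-
# dependent inactivation with slow recovery, in the style of published
# distal-dendrite A-current formulations. 4-AP block is modelled exclusively
# as a scaling of the maximum density.
# ---------------------------------------------------------------------------

def _ka_a_inf(v):
    return _sigmoid(v, -15.0, 12.0)


def _ka_a_tau(v):
    v = np.asarray(v, dtype=float)
    return 0.5 + 1.8 / (1.0 + np.exp(np.clip((v + 40.0) / 12.0, -500, 500)))


def _ka_b_inf(v):
    # steep low-voltage inactivation: sustained subthreshold depolarization
    # (e.g. between train spikes) produces graded, frequency-sensitive
    # inactivation
    return _sigmoid(v, -57.0, -3.0)


def _ka_b_tau(v):
    # inactivation develops within tens of ms just above rest and recovers
    # with ~100 ms at rest, so a 100-Hz spike train accumulates inactivation
    # that survives the 20-ms gap before a test spike
    v = np.asarray(v, dtype=float)
    return 6.0 + 94.0 / (1.0 + np.exp(np.clip((v + 60.0) / 3.0, -500, 500)))


def ka_channel(density: float) -> ChannelSpec:
    """A-type K+ channel; ``density`` is position dependent (see ka_density_at)."""
    return ChannelSpec(
        name="ka",
        gates=(
            GateSpec("a", _ka_a_inf, _ka_a_tau, exponent=1),
            GateSpec("b", _ka_b_inf, _ka_b_tau, exponent=1),
        ),
        max_density=density,
        reversal=E_K,
    )


# ---------------------------------------------------------------------------
# Reporter Ca2+ channel (m^2): medium-threshold activation, no inactivation.
# Density is tiny (1e-7 mS/cm2) so the channel reads out voltage without
# perturbing it.
# ---------------------------------------------------------------------------

def _ca_m_inf(v):
    return _sigmoid(v, -30.0, 9.0)


def _ca_m_tau(v):
    v = np.asarray(v, dtype=float)
    return np.full_like(v, 2.0) if v.ndim else 2.0


def ca_reporter(density: float = 1e-7) -> ChannelSpec:
    return ChannelSpec(
        name="ca",
        gates=(GateSpec("m", _ca_m_inf, _ca_m_tau, exponent=2),),
        max_density=density,
        reversal=E_CA,
    )


MECHANISM_LIBRARY: dict[str, Callable[..., ChannelSpec]] = {
    "na": na_channel,
    "kdr": kdr_channel,
    "ka": ka_channel,
    "ca": ca_reporter,
}


# ---------------------------------------------------------------------------
# A-type density gradient along the apical trunk
# ---------------------------------------------------------------------------

def ka_density_at(
    x: float,
    g_distal: float,
    trunk_length: float = 500.0,
    n_seg: int = 100,
):
    """A-type density (mS/cm2) at path distance ``x`` (um) from the soma.

    The density is zero at the soma and over the proximal trunk segment and
    rises linearly with distance, reaching ``g_distal`` in the distal
    segment. The ramp is anchored at segment centers: zero at the proximal
    segment center (trunk_length / (2 n_seg)) and ``g_distal`` at the distal
    segment center, clipped to [0, g_distal]. With the default 100 x 5 um
    discretization this puts 17.0 mS/cm2 at the synapse site (122.5 um) for
    g_distal = 70 and 2.4 mS/cm2 for g_distal = 10.
    """
    if g_distal < 0:
        raise ValueError("g_distal must be >= 0")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > trunk_length):
        raise ValueError(f"x must lie within the trunk [0, {trunk_length}] um")
    half = trunk_length / (2.0 * n_seg)
    frac = (x_arr - half) / (trunk_length - 2.0 * half)
    out = g_distal * np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Biexponential (Exp2Syn-style) GABA-A conductance
# ---------------------------------------------------------------------------

@dataclass
class SynapseSpec:
    """Peak-normalized difference-of-exponentials synaptic conductance.

    ``g_max`` (nS) is the conductance at the waveform peak; ``tau_rise`` and
    ``tau_decay`` (ms) must satisfy tau_decay > tau_rise > 0. ``reversal``
    defaults to the chloride reversal (-70 mV).
    """

    g_max: float = 2.0
    tau_rise: float = 5.0
    tau_decay: float = 74.0
    reversal: float = E_CL
    onset_times: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError(
                f"require tau_decay > tau_rise > 0, got "
                f"tau_rise={self.tau_rise}, tau_decay={self.tau_decay}"
            )
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")

    @property
    def norm(self) -> float:
        """Factor scaling (exp(-t/tau_decay) - exp(-t/tau_rise)) to unit peak."""
        tp = biexp_peak_time(self.tau_rise, self.tau_decay)
        return 1.0 / (np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))

    def to_dict(self) -> dict:
        return {
            "g_max": self.g_max,
            "tau_rise": self.tau_rise,
            "tau_decay": self.tau_decay,
            "reversal": self.reversal,
            "onset_times": list(self.onset_times),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseSpec":
        return cls(**d)


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of the difference of exponentials (ms)."""
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    )


def biexp_conductance(t, syn: SynapseSpec):
    """Conductance (nS) ``t`` ms after a single onset; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    g = (
        syn.g_max
        * syn.norm
        * (np.exp(-np.clip(t, 0, None) / syn.tau_decay)
           - np.exp(-np.clip(t, 0, None) / syn.tau_rise))
    )
    out = np.where(t < 0, 0.0, g)
    return out if out.ndim else float(out)


def gaba_synapse(
    g_max: float = 2.0,
    tau_rise: float = 5.0,
    tau_decay: float = 74.0,
    onset_times: Sequence[float] = (),
) -> SynapseSpec:
    """The model's GABA-A synapse: 2 nS peak, 5/74 ms kinetics, E = -70 mV."""
    return SynapseSpec(
        g_max=g_max,
        tau_rise=tau_rise,
        tau_decay=tau_decay,
        reversal=E_CL,
        onset_times=list(onset_times),
    )
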