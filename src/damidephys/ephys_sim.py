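"""Conductance-model simulator for voltage- and current-clamp sweeps.

The voltage-clamp response of a space-clamped cell is an exact closed-form
sum per step — capacitive transient, ohmic leak, a fast-activating
inactivating K+ current and a slow-activating non-inactivating K+ current —
so feature extractors can be validated against analytic values. Samples
are emitted as exact averages of the analytic current over each 50 us
sampling bin (emulating the integrating anti-alias stage of acquisition),
which makes the discrete integral of the capacity transient equal C*dV
exactly.

Kinetic forms (Boltzmann activation, single-exponential (in)activation)
are minimal stand-ins chosen to reproduce the measured phenotype — a fast
transient component suppressed by a depolarized prepulse plus a slow
sustained component — not fitted channel kinetics. E_K = -90 mV
approximates the Nernst potential of the recording solutions. Segments
are treated simply: fast-current inactivation enters each segment at its
steady state for the previous voltage (this carries the prepulse effect),
while slow activation restarts from zero at every voltage change.

Current clamp integrates a Hodgkin-Huxley-style membrane equation
(instantaneous Na activation; first-order Na inactivation, delayed
rectifier, A-type inactivation and slow K activation) by fixed-step
forward Euler on the 20 kHz grid with internal substeps for stability.

Units throughout: mV, ms, pA, pF, nS, MOhm (so nS*mV = pA and
MOhm*pF = us).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["VCProtocol", "CCProtocol", "CellParams", "SweepSet",
           "simulate_voltage_clamp", "simulate_p4_subsweeps",
           "simulate_current_clamp", "params_for_target_densities",
           "dmn_like", "vmn_like"]


def boltzmann(v: float, v_half: float, k: float) -> float:
    """Sigmoid activation 1/(1+exp(-(v-v_half)/k)); negative k inverts it."""
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


@dataclass(frozen=True)
class VCProtocol:
    """Voltage-clamp protocol: hold, prepulse, then a family of test steps.

    Defaults follow the neuronal recording configuration: hold -60 mV,
    prepulse -90 mV (or -20 mV to inactivate the fast current) for 100 ms,
    test steps -80..+40 mV in 10 mV increments for 50 ms, sampled at
    20 kHz. A short holding segment is emitted first so baselines exist.
    """

    holding_mV: float = -60.0
    hold_ms: float = 20.0
    prepulse_mV: float = -90.0
    prepulse_ms: float = 100.0
    test_steps_mV: tuple[float, ...] = tuple(float(v) for v in range(-80, 50, 10))
    step_ms: float = 50.0
    sampling_hz: float = 20000.0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")
        steps = tuple(float(v) for v in self.test_steps_mV)
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("test steps must be strictly increasing")
        object.__setattr__(self, "test_steps_mV", steps)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_hz

    @property
    def prepulse_onset_ms(self) -> float:
        return self.hold_ms

    @property
    def test_onset_ms(self) -> float:
        return self.hold_ms + self.prepulse_ms

    @property
    def total_ms(self) -> float:
        return self.hold_ms + self.prepulse_ms + self.step_ms


@dataclass(frozen=True)
class CCProtocol:
    """Current-clamp protocol: depolarizing steps from a -60 mV membrane
    potential (1, 2, 4, 6, 8, 10 pA for 500 ms), sampled at 20 kHz."""

    currents_pA: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    duration_ms: float = 500.0
    v_init_mV: float = -60.0
    sampling_hz: float = 20000.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.currents_pA):
            raise ValueError("injected currents must be non-negative")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_hz


@dataclass(frozen=True)
class CellParams:
    """Ground-truth cell: passive properties, two K+ currents, optional
    spiking pair (Na + delayed rectifier) for current clamp."""

    C_pF: float = 5.0
    R_in_GOhm: float = 2.0            # leak reversal at -60 mV
    E_leak_mV: float = -60.0
    E_K_mV: float = -90.0
    R_access_MOhm: float = 10.0       # smooths the capacity transient

    g_Kfast_nS: float = 0.0           # fast-activating, inactivating
    fast_act_vhalf_mV: float = -30.0
    fast_act_k_mV: float = 10.0
    fast_inact_vhalf_mV: float = -60.0
    fast_inact_k_mV: float = -8.0     # negative slope: closes on depolarization
    tau_inact_ms: float = 10.0

    g_Kslow_nS: float = 0.0           # slow-activating, non-inactivating
    slow_act_vhalf_mV: float = -20.0
    slow_act_k_mV: float = 8.0
    tau_act_ms: float = 50.0

    g_Na_nS: float = 0.0              # spiking pair (current clamp only)
    E_Na_mV: float = 50.0
    na_act_vhalf_mV: float = -42.0
    na_act_k_mV: float = 4.0
    na_inact_vhalf_mV: float = -50.0
    na_inact_k_mV: float = -3.0       # deep inactivation: no plateau window
    tau_na_inact_ms: float = 1.0
    g_KDR_nS: float = 0.0
    kdr_vhalf_mV: float = -15.0
    kdr_k_mV: float = 5.0
    tau_kdr_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.C_pF <= 0:
            raise ValueError("capacitance must be > 0")
        if self.R_in_GOhm <= 0:
            raise ValueError("input resistance must be > 0")
        for name in ("g_Kfast_nS", "g_Kslow_nS", "g_Na_nS", "g_KDR_nS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_inact_ms <= 0 or self.tau_act_ms <= 0:
            raise ValueError("time constants must be > 0")

    @property
    def g_leak_nS(self) -> float:
        return 1.0 / self.R_in_GOhm

    def fast_act(self, v: float) -> float:
        return boltzmann(v, self.fast_act_vhalf_mV, self.fast_act_k_mV)

    def fast_inact(self, v: float) -> float:
        return boltzmann(v, self.fast_inact_vhalf_mV, self.fast_inact_k_mV)

    def slow_act(self, v: float) -> float:
        return boltzmann(v, self.slow_act_vhalf_mV, self.slow_act_k_mV)


@dataclass
class SweepSet:
    """A family of sweeps plus the protocol and (if synthetic) ground truth.

    ``data`` has one row per step: current in pA for voltage clamp,
    membrane voltage in mV for current clamp.
    """

    protocol: VCProtocol | CCProtocol
    time_ms: np.ndarray
    data: np.ndarray                  # (n_steps, n_samples)
    mode: str                         # "vc" or "cc"
    params: CellParams | None = None
    steps: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != self.time_ms.size:
            raise ValueError("data must be (n_steps, n_samples) matching time_ms")

    @property
    def n_steps(self) -> int:
        return int(self.data.shape[0])


# ---------------------------------------------------------------------------
# closed-form voltage clamp
# ---------------------------------------------------------------------------

def _bin_avg_exp(t0: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact average of exp(-t/tau) over bins [t0, t0+dt)."""
    return (tau / dt) * (np.exp(-t0 / tau) - np.exp(-(t0 + dt) / tau))


def _segment_current(params: CellParams, v: float, v_prev: float,
                     t0: np.ndarray, dt: float) -> np.ndarray:
    """Bin-averaged current during one constant-voltage segment.

    ``t0`` holds bin start times measured from the segment onset. The
    capacitive transient corresponds to the jump v_prev -> v smoothed by
    the access-resistance time constant; K+ gates start from the steady
    state at v_prev.
    """
    tau_a = params.R_access_MOhm * params.C_pF / 1000.0  # ms
    dv = v - v_prev
    cap = (1000.0 * dv / params.R_access_MOhm) * _bin_avg_exp(t0, dt, tau_a)
    leak = params.g_leak_nS * (v - params.E_leak_mV)
    drive = v - params.E_K_mV
    fast = (params.g_Kfast_nS * params.fast_act(v) * params.fast_inact(v_prev)
            * drive * _bin_avg_exp(t0, dt, params.tau_inact_ms))
    # slow activation restarts from zero at every voltage change (the gate is
    # taken to deactivate fully between segments), so the slow readout is
    # prepulse-independent by construction: s(t) = s_inf * (1 - exp(-t/tau))
    s_inf = params.slow_act(v)
    slow = params.g_Kslow_nS * drive * s_inf * (
        1.0 - _bin_avg_exp(t0, dt, params.tau_act_ms))
    return cap + leak + fast + slow


def _simulate_vc_step(params: CellParams, protocol: VCProtocol,
                      test_mV: float) -> tuple[np.ndarray, np.ndarray]:
    dt = protocol.dt_ms
    segments = [
        (protocol.holding_mV, protocol.holding_mV, protocol.hold_ms),
        (protocol.prepulse_mV, protocol.holding_mV, protocol.prepulse_ms),
        (test_mV, protocol.prepulse_mV, protocol.step_ms),
    ]
    times, currents = [], []
    offset = 0.0
    for v, v_prev, dur in segments:
        n = int(round(dur / dt))
        t0 = np.arange(n) * dt
        times.append(offset + t0)
        currents.append(_segment_current(params, v, v_prev, t0, dt))
        offset += n * dt
    return np.concatenate(times), np.concatenate(currents)


def simulate_voltage_clamp(params: CellParams, protocol: VCProtocol | None = None,
                           noise_sd_pA: float = 0.0,
                           seed: int | None = None) -> SweepSet:
    """Closed-form voltage-clamp sweep family (one sweep per test step)."""
    protocol = protocol or VCProtocol()
    sweeps = []
    time_ms = None
    for v in protocol.test_steps_mV:
        t, i = _simulate_vc_step(params, protocol, v)
        time_ms = t
        sweeps.append(i)
    data = np.vstack(sweeps)
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_pA, size=data.shape)
    return SweepSet(protocol=protocol, time_ms=time_ms, data=data, mode="vc",
                    params=params, steps=protocol.test_steps_mV)


def simulate_p4_subsweeps(params: CellParams, protocol: VCProtocol,
                          test_mV: float) -> SweepSet:
    """Four quarter-amplitude subsweeps for P/4 on-line leak subtraction.

    Each subsweep steps from holding to holding + (test - holding)/4 with
    the same segment durations as the main sweep (prepulse at a quarter of
    its excursion too, so every linear component scales by exactly 1/4).
    """
    quarter = replace(
        protocol,
        prepulse_mV=protocol.holding_mV + (protocol.prepulse_mV - protocol.holding_mV) / 4.0,
        test_steps_mV=(protocol.holding_mV + (test_mV - protocol.holding_mV) / 4.0,),
    )
    single = simulate_voltage_clamp(params, quarter)
    data = np.repeat(single.data, 4, axis=0)
    return SweepSet(protocol=quarter, time_ms=single.time_ms, data=data,
                    mode="vc", params=params, steps=(quarter.test_steps_mV[0],) * 4)


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

_CC_SUBSTEPS = 5  # forward-Euler substeps per 50 us sample


def simulate_current_clamp(params: CellParams, protocol: CCProtocol | None = None,
                           ) -> SweepSet:
    """Integrate the membrane equation for each injected-current step.

    Requires a spiking pair (g_Na > 0). Gates start at their steady state
    for the initial potential. Aborts with the parameter set echoed if the
    state ever becomes non-finite (stability check).
    """
    protocol = protocol or CCProtocol()
    if params.g_Na_nS <= 0:
        raise ValueError("current clamp requires g_Na_nS > 0")
    dt = protocol.dt_ms
    h = dt / _CC_SUBSTEPS
    n = int(round(protocol.duration_ms / dt))
    time_ms = np.arange(n) * dt
    v0 = protocol.v_init_mV

    sweeps = np.empty((len(protocol.currents_pA), n))
    for k, i_inj in enumerate(protocol.currents_pA):
        v = v0
        na_h = boltzmann(v0, params.na_inact_vhalf_mV, params.na_inact_k_mV)
        kdr_n = boltzmann(v0, params.kdr_vhalf_mV, params.kdr_k_mV)
        a_b = params.fast_inact(v0)
        s = params.slow_act(v0)
        for i in range(n):
            sweeps[k, i] = v
            for _ in range(_CC_SUBSTEPS):
                m = boltzmann(v, params.na_act_vhalf_mV, params.na_act_k_mV)
                i_na = params.g_Na_nS * m ** 3 * na_h * (v - params.E_Na_mV)
                i_kdr = params.g_KDR_nS * kdr_n * (v - params.E_K_mV)
                i_a = params.g_Kfast_nS * params.fast_act(v) * a_b * (v - params.E_K_mV)
                i_s = params.g_Kslow_nS * s * (v - params.E_K_mV)
                i_leak = params.g_leak_nS * (v - params.E_leak_mV)
                dv = (i_inj - i_na - i_kdr - i_a - i_s - i_leak) / params.C_pF
                v = v + h * dv
                na_h += h * (boltzmann(v, params.na_inact_vhalf_mV,
                                       params.na_inact_k_mV) - na_h) / params.tau_na_inact_ms
                kdr_n += h * (boltzmann(v, params.kdr_vhalf_mV,
                                        params.kdr_k_mV) - kdr_n) / params.tau_kdr_ms
                a_b += h * (params.fast_inact(v) - a_b) / params.tau_inact_ms
                s += h * (params.slow_act(v) - s) / params.tau_act_ms
            if not np.isfinite(v):
                raise RuntimeError(
                    f"current-clamp integration diverged at step {i_inj} pA; "
                    f"params: {params}")
    return SweepSet(protocol=protocol, time_ms=time_ms, data=sweeps, mode="cc",
                    params=params, steps=protocol.currents_pA)


# ---------------------------------------------------------------------------
# planting: choose conductances for target current densities
# ---------------------------------------------------------------------------

def params_for_target_densities(fast_density_pApF: float, slow_density_pApF: float,
                                base: CellParams | None = None,
                                at_mV: float = 40.0,
                                protocol: VCProtocol | None = None,
                                fast_peak_at_ms: float = 0.5) -> CellParams:
    """Conductances such that the analytic current components hit target
    densities at the reference test step (+40 mV, -90 mV prepulse).

    The fast target is the fast component's value at ``fast_peak_at_ms``
    after step onset — the earliest instant the extraction window can read
    (the measured peak of a decaying transient); the slow target is the
    mean of the slow component over the last 20% of the test step. The
    planting uses the analytic components only — never the measurement
    pipeline — so extraction accuracy remains a real test.
    """
    base = base or CellParams()
    protocol = protocol or VCProtocol()
    drive = at_mV - base.E_K_mV
    fast_gain = (base.fast_act(at_mV) * base.fast_inact(protocol.prepulse_mV)
                 * drive * np.exp(-fast_peak_at_ms / base.tau_inact_ms))
    g_fast = fast_density_pApF * base.C_pF / fast_gain

    T = protocol.step_ms
    t_lo = 0.8 * T
    s_inf = base.slow_act(at_mV)
    tau = base.tau_act_ms
    mean_exp = tau / (T - t_lo) * (np.exp(-t_lo / tau) - np.exp(-T / tau))
    late_mean_act = s_inf * (1.0 - mean_exp)
    g_slow = slow_density_pApF * base.C_pF / (late_mean_act * drive)
    return replace(base, g_Kfast_nS=float(g_fast), g_Kslow_nS=float(g_slow))


#: Spiking pair shared by the current-clamp presets; chosen once so the
#: model cell fires repetitively over the 1-10 pA step family with rates
#: in the tens per 500 ms at the top step.
_SPIKING = dict(g_Na_nS=400.0, g_KDR_nS=100.0)


def dmn_like(spiking: bool = False) -> CellParams:
    """Dorsal-motoneuron-like preset: large fast and slow K+ densities
    (60.1 / 49.0 pA/pF at +40 mV)."""
    p = params_for_target_densities(60.1, 49.0)
    return replace(p, **_SPIKING) if spiking else p


def vmn_like(spiking: bool = False) -> CellParams:
    """Ventral-motoneuron-like preset: smaller fast and slow K+ densities
    (42.6 / 33.3 pA/pF at +40 mV)."""
    p = params_for_target_densities(42.6, 33.3)
    return replace(p, **_SPIKING) if spiking else p
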