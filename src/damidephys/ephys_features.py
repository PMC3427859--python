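"""Measurement procedures for whole-cell K+ current recordings.

Implements the quantitative steps of the recording analysis: cell
capacitance from the area under the capacity transient of the -60 to
-90 mV step; input resistance from the steady leak of the same step (with
a > 1 GOhm acceptance criterion, strict); off-line leak subtraction for
neurons and P/4 on-line subtraction for muscle; extraction of the fast
transient (window max shortly after step onset) and the slow sustained
current (mean over the last 20% of the step), normalized to capacitance
as pA/pF densities; per-voltage group means +/- SEM with unpaired Welch
t-tests; and action-potential counting in current clamp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ephys_sim import CCProtocol, SweepSet, VCProtocol

__all__ = ["CellPassive", "DEFAULT_FAST_WINDOW_MS", "DEFAULT_SLOW_FRACTION",
           "estimate_capacitance", "estimate_input_resistance", "estimate_passive",
           "qc_input_resistance", "offline_leak_subtract", "p4_leak_subtract",
           "measure_features", "build_iv", "IVResults", "count_aps", "count_aps_sweeps"]

#: Window (ms after test-step onset) in which the fast transient peak is read.
#: Kept short so that, when the fast current is inactivated by a -20 mV
#: prepulse, the slowly activating sustained current has not yet risen into
#: the window. A config key, like the slow-window fraction.
DEFAULT_FAST_WINDOW_MS = (0.5, 5.0)
#: The slow current is averaged over this trailing fraction of the step.
DEFAULT_SLOW_FRACTION = 0.2

MIN_INPUT_RESISTANCE_GOHM = 1.0


@dataclass(frozen=True)
class CellPassive:
    """Passive properties estimated from the hyperpolarizing passive step."""

    capacitance_pF: float
    input_resistance_GOhm: float

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0 or self.input_resistance_GOhm <= 0:
            raise ValueError("passive properties must be positive")


def _segment_means(sweep: np.ndarray, time_ms: np.ndarray, lo: float, hi: float) -> float:
    sel = (time_ms >= lo) & (time_ms < hi)
    if not sel.any():
        raise ValueError("empty time window")
    return float(sweep[sel].mean())


def estimate_capacitance(sweeps: SweepSet, window_ms: float = 10.0,
                         min_peak_pA: float = 5.0) -> float:
    """Capacitance from the area under the -60 -> -90 mV capacity transient.

    The steady (leak) level late in the prepulse is subtracted as baseline,
    the remaining transient is integrated over ``window_ms`` after the
    jump, and C = |integral| / 30 mV. Raises if no transient is detectable
    (peak below ``min_peak_pA`` over baseline).
    """
    proto = sweeps.protocol
    if not isinstance(proto, VCProtocol):
        raise ValueError("capacitance estimation needs a voltage-clamp sweep set")
    dv = abs(proto.prepulse_mV - proto.holding_mV)
    if dv <= 0:
        raise ValueError("protocol has no passive voltage jump")
    t = sweeps.time_ms
    trace = sweeps.data[0]
    onset = proto.prepulse_onset_ms
    baseline = _segment_means(trace, t, onset + 0.75 * proto.prepulse_ms,
                              onset + proto.prepulse_ms)
    sel = (t >= onset) & (t < onset + window_ms)
    transient = trace[sel] - baseline
    if np.max(np.abs(transient)) < min_peak_pA:
        raise ValueError("no detectable capacity transient")
    area = float(np.sum(transient) * proto.dt_ms)   # pA*ms = fC... (pA*ms = 1e-15 C*1e3) -> pF*mV
    return abs(area) / dv                            # pA*ms / mV = pF


def estimate_input_resistance(sweeps: SweepSet) -> float:
    """Input resistance (GOhm) from the steady current of the passive step.

    R_in = |dV| / |dI| using the holding baseline and the late-prepulse
    steady level, where voltage-gated currents are closed.
    """
    proto = sweeps.protocol
    t = sweeps.time_ms
    trace = sweeps.data[0]
    i_hold = _segment_means(trace, t, 0.75 * proto.hold_ms, proto.hold_ms)
    onset = proto.prepulse_onset_ms
    i_pre = _segment_means(trace, t, onset + 0.75 * proto.prepulse_ms,
                           onset + proto.prepulse_ms)
    dv = abs(proto.prepulse_mV - proto.holding_mV)
    di = abs(i_pre - i_hold)
    if di <= 0:
        raise ValueError("no steady-state current change across the passive step")
    return dv / di  # mV / pA = GOhm


def estimate_passive(sweeps: SweepSet) -> CellPassive:
    return CellPassive(capacitance_pF=estimate_capacitance(sweeps),
                       input_resistance_GOhm=estimate_input_resistance(sweeps))


def qc_input_resistance(passive: CellPassive,
                        min_GOhm: float = MIN_INPUT_RESISTANCE_GOHM) -> bool:
    """Acceptance criterion: input resistance strictly above 1 GOhm."""
    return passive.input_resistance_GOhm > min_GOhm


def offline_leak_subtract(sweeps: SweepSet, passive: CellPassive) -> SweepSet:
    """Subtract the ohmic leak g_leak * (V(t) - V_hold) from every sweep.

    V(t) is the protocol's command voltage (holding / prepulse / test per
    segment); g_leak = 1 / R_in from the passive estimate. Capacitive
    transients are left in place — they are fast and lie before the
    measurement windows.
    """
    proto = sweeps.protocol
    g_leak = 1.0 / passive.input_resistance_GOhm  # nS
    t = sweeps.time_ms
    out = sweeps.data.copy()
    for k, v_test in enumerate(sweeps.steps):
        v_cmd = np.full_like(t, proto.holding_mV)
        v_cmd[(t >= proto.prepulse_onset_ms) & (t < proto.test_onset_ms)] = proto.prepulse_mV
        v_cmd[t >= proto.test_onset_ms] = v_test
        out[k] = sweeps.data[k] - g_leak * (v_cmd - proto.holding_mV)
    return SweepSet(protocol=proto, time_ms=t, data=out, mode=sweeps.mode,
                    params=sweeps.params, steps=sweeps.steps)


def p4_leak_subtract(main: np.ndarray, subsweeps: np.ndarray) -> np.ndarray:
    """P/4 on-line correction: main - 4 * mean(quarter-amplitude subsweeps).

    Exact for all linear (leak + capacitive) components; requires exactly
    four subsweeps sampled like the main sweep.
    """
    subsweeps = np.asarray(subsweeps)
    if subsweeps.ndim != 2 or subsweeps.shape[0] != 4:
        raise ValueError(f"P/4 requires exactly 4 subsweeps, got {subsweeps.shape}")
    if subsweeps.shape[1] != np.asarray(main).shape[0]:
        raise ValueError("subsweeps and main sweep differ in length")
    return np.asarray(main) - 4.0 * subsweeps.mean(axis=0)


def measure_features(sweeps: SweepSet, passive: CellPassive,
                     fast_window_ms: tuple[float, float] = DEFAULT_FAST_WINDOW_MS,
                     slow_fraction: float = DEFAULT_SLOW_FRACTION) -> pd.DataFrame:
    """Extract fast and slow K+ current amplitudes and densities per step.

    Expects leak-subtracted sweeps. The fast current is the maximum within
    ``fast_window_ms`` after test-step onset; the slow current is the mean
    over the trailing ``slow_fraction`` of the step. Densities divide by
    the estimated capacitance.
    """
    proto = sweeps.protocol
    if not isinstance(proto, VCProtocol):
        raise ValueError("feature extraction needs voltage-clamp sweeps")
    t = sweeps.time_ms
    onset = proto.test_onset_ms
    fast_sel = (t >= onset + fast_window_ms[0]) & (t < onset + fast_window_ms[1])
    slow_sel = (t >= onset + (1.0 - slow_fraction) * proto.step_ms) & \
               (t < onset + proto.step_ms)
    rows = []
    for k, v in enumerate(sweeps.steps):
        i_fast = float(sweeps.data[k, fast_sel].max())
        i_slow = float(sweeps.data[k, slow_sel].mean())
        rows.append({
            "step_mV": float(v),
            "I_Kfast_pA": i_fast,
            "I_Kslow_pA": i_slow,
            "I_Kfast_pApF": i_fast / passive.capacitance_pF,
            "I_Kslow_pApF": i_slow / passive.capacitance_pF,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group IV curves and statistics
# ---------------------------------------------------------------------------

@dataclass
class IVResults:
    """Group current-voltage results: mean +/- SEM per voltage per group,
    with an unpaired (Welch) t-test per voltage between two groups."""

    feature: str
    table: pd.DataFrame   # columns: step_mV, group, n, mean, sem
    tests: pd.DataFrame | None  # columns: step_mV, t, p (None if < 2 groups)

    def summary(self) -> str:
        lines = [f"IV comparison of {self.feature} (mean +/- SEM, pA/pF)"]
        wide = self.table.pivot(index="step_mV", columns="group")
        groups = sorted(self.table["group"].unique())
        header = "  V (mV)" + "".join(f"  {g:>20}" for g in groups)
        if self.tests is not None:
            header += "      Welch t        p"
        lines.append(header)
        for v in sorted(self.table["step_mV"].unique()):
            row = f"  {v:6.0f}"
            for g in groups:
                m = wide.loc[v, ("mean", g)]
                s = wide.loc[v, ("sem", g)]
                row += f"  {m:10.2f} +/- {s:5.2f}"
            if self.tests is not None:
                tr = self.tests[self.tests["step_mV"] == v].iloc[0]
                row += f"  {tr['t']:10.3f}  {tr['p']:8.3g}"
            lines.append(row)
        return "\n".join(lines)

    def plot(self, ax=None):
        """IV curves with SEM error bars, one line per group (needs
        matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for group, sub in self.table.groupby("group"):
            ax.errorbar(sub["step_mV"], sub["mean"], yerr=sub["sem"],
                        marker="o", capsize=3, label=str(group))
        ax.set_xlabel("test potential (mV)")
        ax.set_ylabel(f"{self.feature} (mean ± SEM)")
        ax.legend()
        return ax


def build_iv(features_per_cell: Sequence[pd.DataFrame], group_labels: Sequence[str],
             feature: str = "I_Kfast_pApF") -> IVResults:
    """Assemble per-group IV curves and per-voltage two-sample tests.

    Each element of ``features_per_cell`` is one cell's feature table from
    :func:`measure_features`; ``group_labels`` assigns each cell to a
    group. With exactly two groups an unpaired Welch t-test is computed at
    every voltage; groups of size one get means only (test skipped with a
    warning column absent).
    """
    if len(features_per_cell) != len(group_labels):
        raise ValueError("one group label per cell required")
    long = pd.concat(
        [df.assign(group=lab, cell=i) for i, (df, lab) in
         enumerate(zip(features_per_cell, group_labels))],
        ignore_index=True)
    agg = (long.groupby(["step_mV", "group"])[feature]
           .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
           .reset_index())
    agg["sem"] = agg["sd"] / np.sqrt(agg["n"])
    agg.loc[agg["n"] < 2, "sem"] = np.nan

    groups = sorted(set(group_labels))
    tests = None
    if len(groups) == 2 and all((np.array(group_labels) == g).sum() >= 2 for g in groups):
        rows = []
        for v in sorted(long["step_mV"].unique()):
            a = long[(long["step_mV"] == v) & (long["group"] == groups[0])][feature]
            b = long[(long["step_mV"] == v) & (long["group"] == groups[1])][feature]
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"step_mV": float(v), "t": float(t), "p": float(p)})
        tests = pd.DataFrame(rows)
    return IVResults(feature=feature,
                     table=agg[["step_mV", "group", "n", "mean", "sem"]],
                     tests=tests)


# ---------------------------------------------------------------------------
# action potentials
# ---------------------------------------------------------------------------

def count_aps(voltage: np.ndarray, sampling_hz: float,
              threshold_mV: float = 0.0, lockout_ms: float = 2.0) -> int:
    """Count action potentials as upward threshold crossings with a
    refractory lockout (crossings closer than ``lockout_ms`` to the
    previous accepted crossing are ignored)."""
    v = np.asarray(voltage, dtype=float)
    above = v >= threshold_mV
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        return 0
    lockout = lockout_ms * sampling_hz / 1000.0
    count, last = 0, -np.inf
    for c in crossings:
        if c - last >= lockout:
            count += 1
            last = c
    return count


def count_aps_sweeps(sweeps: SweepSet, threshold_mV: float = 0.0,
                     lockout_ms: float = 2.0) -> pd.DataFrame:
    """AP counts for every current step of a current-clamp sweep set."""
    if sweeps.mode != "cc":
        raise ValueError("AP counting needs current-clamp sweeps")
    fs = sweeps.protocol.sampling_hz
    rows = [{"current_pA": float(i_inj),
             "n_aps": count_aps(sweeps.data[k], fs, threshold_mV, lockout_ms)}
            for k, i_inj in enumerate(sweeps.steps)]
    return pd.DataFrame(rows)
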