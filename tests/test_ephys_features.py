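"""Measurement procedures: passive properties, leak subtraction, densities,
group statistics and AP counting."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from damidephys import ephys_features as ef
from damidephys import ephys_sim as es


def analyze(cell, proto=None, passive_from=None):
    proto = proto or es.VCProtocol()
    sw = es.simulate_voltage_clamp(cell, proto)
    passive = ef.estimate_passive(passive_from or sw)
    sub = ef.offline_leak_subtract(sw, passive)
    return ef.measure_features(sub, passive), passive


class TestCapacitance:
    def test_recovers_10pF_within_2_percent(self):
        cell = es.CellParams(C_pF=10.0, R_in_GOhm=2.0)
        sw = es.simulate_voltage_clamp(cell)
        assert ef.estimate_capacitance(sw) == pytest.approx(10.0, rel=0.02)

    def test_linear_in_transient_amplitude(self):
        """Doubling the transient amplitude at equal tau doubles the
        estimate (hand-built analytic RC trace)."""
        proto = es.VCProtocol()
        t = np.arange(0.0, proto.total_ms, proto.dt_ms)
        onset = proto.prepulse_onset_ms
        tau = 0.5
        estimates = []
        for amp in (600.0, 1200.0):
            trace = np.where(t >= onset, -amp * np.exp(-(t - onset) / tau), 0.0)
            sw = es.SweepSet(protocol=proto, time_ms=t,
                             data=trace[None, :], mode="vc", steps=(-80.0,))
            estimates.append(ef.estimate_capacitance(sw))
        assert estimates[1] == pytest.approx(2 * estimates[0], rel=1e-6)

    def test_flat_trace_raises(self):
        proto = es.VCProtocol()
        t = np.arange(0.0, proto.total_ms, proto.dt_ms)
        sw = es.SweepSet(protocol=proto, time_ms=t,
                         data=np.zeros((1, t.size)), mode="vc", steps=(-80.0,))
        with pytest.raises(ValueError, match="transient"):
            ef.estimate_capacitance(sw)


class TestInputResistanceQC:
    def test_recovers_planted_input_resistance(self):
        sw = es.simulate_voltage_clamp(es.CellParams(C_pF=5.0, R_in_GOhm=2.0))
        assert ef.estimate_input_resistance(sw) == pytest.approx(2.0, rel=0.1)

    @pytest.mark.parametrize("r,accepted", [(1.5, True), (0.9, False), (1.0, False)])
    def test_acceptance_strictly_above_1_GOhm(self, r, accepted):
        passive = ef.CellPassive(capacitance_pF=5.0, input_resistance_GOhm=r)
        assert ef.qc_input_resistance(passive) is accepted


class TestLeakSubtraction:
    def test_pure_leak_cell_maps_to_near_zero(self):
        cell = es.CellParams(C_pF=5.0, R_in_GOhm=1.0)
        proto = es.VCProtocol()
        sw = es.simulate_voltage_clamp(cell, proto)
        passive = ef.estimate_passive(sw)
        sub = ef.offline_leak_subtract(sw, passive)
        late = sub.time_ms >= proto.test_onset_ms + 20.0  # past the transient
        raw_late = sw.data[:, late]
        assert np.abs(sub.data[:, late]).max() <= 0.01 * np.abs(raw_late).max()

    def test_leak_plus_k_leaves_k_component(self):
        # with the true passive properties the subtraction must recover the
        # K-only analytic trace to 1%
        proto = es.VCProtocol()
        leaky = replace(es.dmn_like(), R_in_GOhm=1.0)
        k_only = replace(leaky, R_in_GOhm=1e9)
        sw = es.simulate_voltage_clamp(leaky, proto)
        passive = ef.CellPassive(capacitance_pF=leaky.C_pF,
                                 input_resistance_GOhm=leaky.R_in_GOhm)
        sub = ef.offline_leak_subtract(sw, passive)
        ref = es.simulate_voltage_clamp(k_only, proto)
        sel = sw.time_ms >= proto.test_onset_ms + 0.5
        scale = np.abs(ref.data[-1, sel]).max()
        assert np.abs(sub.data[-1, sel] - ref.data[-1, sel]).max() <= 0.01 * scale

    def test_p4_cancels_linear_cell_exactly(self):
        cell = es.CellParams(C_pF=5.0, R_in_GOhm=1.0)
        proto = es.VCProtocol()
        main = es.simulate_voltage_clamp(cell, proto)
        for k, v in enumerate(proto.test_steps_mV):
            subs = es.simulate_p4_subsweeps(cell, proto, v)
            corrected = ef.p4_leak_subtract(main.data[k], subs.data)
            assert np.abs(corrected).max() < 1e-9

    def test_p4_recovers_k_component_when_subpulses_subthreshold(self):
        # K currents activating only above ~ -40 mV: quarter pulses from
        # -60 toward +40 reach -35 mV where activation is ~0 for a steep gate
        cell = es.CellParams(C_pF=5.0, R_in_GOhm=1.0, g_Kfast_nS=5.0,
                             fast_act_vhalf_mV=-10.0, fast_act_k_mV=4.0)
        k_only = replace(cell, R_in_GOhm=1e9)
        proto = es.VCProtocol()
        main = es.simulate_voltage_clamp(cell, proto)
        ref = es.simulate_voltage_clamp(k_only, proto)
        k = proto.test_steps_mV.index(40.0)
        subs = es.simulate_p4_subsweeps(cell, proto, 40.0)
        corrected = ef.p4_leak_subtract(main.data[k], subs.data)
        sel = main.time_ms >= proto.test_onset_ms + 0.5
        scale = np.abs(ref.data[k, sel]).max()
        assert np.abs(corrected[sel] - ref.data[k, sel]).max() <= 0.02 * scale

    def test_p4_and_offline_agree_on_linear_cell(self):
        cell = es.CellParams(C_pF=5.0, R_in_GOhm=1.0)
        proto = es.VCProtocol()
        main = es.simulate_voltage_clamp(cell, proto)
        passive = ef.estimate_passive(main)
        offline = ef.offline_leak_subtract(main, passive)
        k = proto.test_steps_mV.index(40.0)
        subs = es.simulate_p4_subsweeps(cell, proto, 40.0)
        p4 = ef.p4_leak_subtract(main.data[k], subs.data)
        sel = main.time_ms >= proto.test_onset_ms + 5.0
        scale = np.abs(main.data[k, sel]).max()
        assert np.abs(p4[sel] - offline.data[k, sel]).max() <= 0.01 * scale

    def test_wrong_subsweep_count_rejected(self):
        with pytest.raises(ValueError, match="4 subsweeps"):
            ef.p4_leak_subtract(np.zeros(10), np.zeros((3, 10)))


class TestFeatureExtraction:
    @pytest.mark.parametrize("fast,slow", [(60.1, 49.0), (42.6, 33.3)])
    def test_planted_densities_recovered_within_5_percent(self, fast, slow):
        feats, _ = analyze(es.params_for_target_densities(fast, slow))
        row = feats[feats.step_mV == 40.0].iloc[0]
        assert row.I_Kfast_pApF == pytest.approx(fast, rel=0.05)
        assert row.I_Kslow_pApF == pytest.approx(slow, rel=0.05)

    def test_fast_approx_slow_for_fast_equilibrating_sustained_current(self):
        """A non-inactivating current that reaches steady state quickly is
        read identically by the early and late windows."""
        cell = es.CellParams(C_pF=5.0, R_in_GOhm=2.0, g_Kslow_nS=5.0,
                             tau_act_ms=0.5)
        feats, _ = analyze(cell)
        row = feats[feats.step_mV == 40.0].iloc[0]
        assert row.I_Kfast_pApF == pytest.approx(row.I_Kslow_pApF, rel=0.02)

    def test_prepulse_isolates_slow_component(self):
        cell = es.dmn_like()
        sw90 = es.simulate_voltage_clamp(cell, es.VCProtocol(prepulse_mV=-90.0))
        passive = ef.estimate_passive(sw90)
        f90 = ef.measure_features(ef.offline_leak_subtract(sw90, passive), passive)
        sw20 = es.simulate_voltage_clamp(cell, es.VCProtocol(prepulse_mV=-20.0))
        f20 = ef.measure_features(ef.offline_leak_subtract(sw20, passive), passive)
        a = f90[f90.step_mV == 40.0].iloc[0]
        b = f20[f20.step_mV == 40.0].iloc[0]
        assert b.I_Kfast_pApF < 0.2 * a.I_Kfast_pApF
        assert b.I_Kslow_pApF == pytest.approx(a.I_Kslow_pApF, rel=0.05)


class TestGroupStatistics:
    @staticmethod
    def features_from(values_by_voltage):
        return pd.DataFrame([{"step_mV": v, "I_Kfast_pApF": x,
                              "I_Kslow_pApF": x}
                             for v, x in values_by_voltage.items()])

    def test_identical_groups_give_null_test(self):
        cells = [self.features_from({0.0: 0.5 * x, 40.0: x}) for x in (1.0, 2.0, 3.0)]
        iv = ef.build_iv(cells * 2, ["a"] * 3 + ["b"] * 3)
        assert np.allclose(iv.tests["t"], 0.0)
        assert np.all(iv.tests["p"] > 0.99)

    def test_welch_t_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        cells = [self.features_from({40.0: x}) for x in a + b]
        iv = ef.build_iv(cells, ["a"] * 3 + ["b"] * 3)
        se = np.sqrt(np.var(a, ddof=1) / 3 + np.var(b, ddof=1) / 3)
        expected_t = (np.mean(a) - np.mean(b)) / se
        assert iv.tests["t"].iloc[0] == pytest.approx(expected_t)
        assert iv.tests["p"].iloc[0] == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue)

    def test_sem_is_sd_over_sqrt_n(self):
        cells = [self.features_from({40.0: x}) for x in (1.0, 1.0, 3.0, 3.0)]
        iv = ef.build_iv(cells, ["a"] * 4)
        row = iv.table.iloc[0]
        assert row["sem"] == pytest.approx(np.std([1, 1, 3, 3], ddof=1) / 2)

    def test_singleton_group_reports_mean_without_test(self):
        cells = [self.features_from({40.0: x}) for x in (1.0, 2.0, 5.0)]
        iv = ef.build_iv(cells, ["a", "a", "b"])
        assert iv.tests is None
        b_row = iv.table[iv.table.group == "b"].iloc[0]
        assert b_row["mean"] == 5.0 and np.isnan(b_row["sem"])

    def test_summary_renders(self):
        cells = [self.features_from({0.0: 1.0, 40.0: x}) for x in (1.0, 2.0, 3.0)]
        text = ef.build_iv(cells * 2, ["a"] * 3 + ["b"] * 3).summary()
        assert "Welch" in text and "40" in text


class TestApCounting:
    def test_flat_trace_counts_zero(self):
        assert ef.count_aps(np.full(10_000, -60.0), 20000.0) == 0

    def test_constructed_train_of_seven(self):
        fs = 20000.0
        t = np.arange(0, 0.5, 1 / fs)
        v = np.full(t.size, -60.0)
        for k in range(7):
            spike = (t > 0.05 + 0.06 * k) & (t < 0.051 + 0.06 * k)
            v[spike] = 20.0
        assert ef.count_aps(v, fs) == 7

    def test_sampling_rate_invariance(self):
        for fs in (20000.0, 40000.0):
            t = np.arange(0, 0.5, 1 / fs)
            v = -60 + 80 * np.maximum(0, np.sin(2 * np.pi * 10 * t))
            assert ef.count_aps(v, fs) == 5

    def test_lockout_suppresses_fast_double_crossings(self):
        fs = 20000.0
        v = np.full(200, -60.0)
        v[50:52] = 10.0
        v[60:62] = 10.0   # 0.5 ms later: within the 2 ms lockout
        v[150:152] = 10.0
        assert ef.count_aps(v, fs) == 2
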