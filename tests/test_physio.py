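import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import severinghaus_p_for_s
from qdcm.phantom import GasProtocol, make_protocol
from qdcm.physio import (
    AlignmentWarning,
    BloodConstants,
    EndTidalTrace,
    align_traces,
    cao2_from_state,
    derive_arterial,
    find_baseline_volumes,
    p50_from_ph,
    ph_from_paco2,
    severinghaus_pao2,
    severinghaus_sao2,
    t1_blood_from_oxygenation,
)


class TestSeveringhaus:
    def test_half_saturation_near_27_mmHg(self):
        # bisection on the closed form locates the dissociation midpoint
        p_half = severinghaus_p_for_s(0.5)
        assert p_half == pytest.approx(26.9, abs=0.15)
        assert severinghaus_sao2(p_half) == pytest.approx(0.5, abs=1e-9)

    def test_baseline_oxygenation(self):
        # at the group-mean baseline PETO2 of 116 mmHg
        assert severinghaus_sao2(116.0) == pytest.approx(0.98539, abs=2e-5)

    def test_asymptote(self):
        assert severinghaus_sao2(5000.0) > 0.999999
        assert severinghaus_sao2(1e5) < 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            severinghaus_sao2(0.0)
        with pytest.raises(ValueError):
            severinghaus_sao2(np.array([100.0, -1.0]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(min_value=30.0, max_value=600.0))
    def test_roundtrip_inverse(self, pao2):
        s = severinghaus_sao2(pao2)
        assert severinghaus_pao2(s) == pytest.approx(pao2, rel=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=600.0),
           st.floats(min_value=1.01, max_value=1.5))
    def test_monotone(self, p, factor):
        assert severinghaus_sao2(p * factor) > severinghaus_sao2(p)


class TestAcidBase:
    def test_henderson_hasselbalch_at_baseline(self):
        assert ph_from_paco2(41.6, 24.0) == pytest.approx(7.384, abs=0.001)

    def test_unit_ratio_gives_pk(self):
        assert ph_from_paco2(24.0 / 0.03, 24.0) == pytest.approx(6.1)

    def test_physiological_sanity(self):
        assert ph_from_paco2(40.0, 24.0) == pytest.approx(7.40, abs=0.005)

    def test_decreasing_in_paco2(self):
        assert ph_from_paco2(50.0) < ph_from_paco2(40.0)

    def test_p50_chain_reproduces_group_value(self):
        # PaCO2 41.6 -> pH -> P50 must land on the reported 27.1 mmHg
        p50 = p50_from_ph(ph_from_paco2(41.6, 24.0))
        assert p50 == pytest.approx(27.1, abs=0.1)

    def test_p50_line(self):
        assert p50_from_ph(7.40) == pytest.approx(26.73, abs=0.01)
        assert p50_from_ph(221.87 / 26.37) == pytest.approx(0.0, abs=1e-9)

    def test_p50_warns_outside_range(self):
        with pytest.warns(UserWarning):
            p50_from_ph(6.0)


class TestArterialContent:
    def test_saturation_only_term(self):
        assert cao2_from_state(0.0, 1.0, 0.143) == pytest.approx(1.34 * 0.143)

    def test_dissolved_only_term(self):
        assert cao2_from_state(100.0, 0.0, 0.143) == pytest.approx(0.0031)

    def test_full_value_at_baseline(self):
        s = severinghaus_sao2(116.0)
        assert cao2_from_state(116.0, s, 0.143) == pytest.approx(0.192, abs=0.001)

    def test_rejects_gdl_hb(self):
        with pytest.raises(ValueError):
            cao2_from_state(100.0, 0.98, 14.3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(min_value=50.0, max_value=400.0),
           st.floats(min_value=0.5, max_value=0.99),
           st.floats(min_value=0.08, max_value=0.2))
    def test_monotone_in_each_argument(self, pao2, sao2, hb):
        base = cao2_from_state(pao2, sao2, hb)
        assert cao2_from_state(pao2 * 1.1, sao2, hb) > base
        assert cao2_from_state(pao2, min(sao2 * 1.01, 1.0), hb) > base
        assert cao2_from_state(pao2, sao2, hb * 1.01) > base


class TestBloodT1:
    def test_fully_saturated_stationary_blood(self):
        assert t1_blood_from_oxygenation(1e-9, 1.0) == pytest.approx(
            1.0 / 0.5848, abs=1e-3)

    def test_baseline_value(self):
        assert t1_blood_from_oxygenation(116.0, 0.985) == pytest.approx(
            1.655, abs=0.005)

    def test_desaturation_shortens_t1(self):
        assert (t1_blood_from_oxygenation(100.0, 0.90)
                < t1_blood_from_oxygenation(100.0, 0.99))

    def test_range_over_physiological_grid(self):
        pao2, sao2 = np.meshgrid(np.linspace(60, 500, 20),
                                 np.linspace(0.8, 1.0, 10))
        t1 = t1_blood_from_oxygenation(pao2, sao2)
        assert np.all((t1 > 1.0) & (t1 < 2.2))


class TestBloodConstants:
    def test_rejects_gdl(self):
        with pytest.raises(ValueError):
            BloodConstants(hb=14.3)

    def test_from_gdl(self):
        assert BloodConstants.from_gdl(14.3).hb == pytest.approx(0.143)


class TestEndTidalTrace:
    def test_validation(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            EndTidalTrace(time=t[::-1], petco2=np.full(10, 40.0),
                          peto2=np.full(10, 110.0))
        with pytest.raises(ValueError):
            EndTidalTrace(time=t, petco2=np.full(10, 5.0),
                          peto2=np.full(10, 110.0))

    def test_from_file_single_and_split(self, tmp_path):
        t = np.arange(0.0, 30.0)
        co2 = 40.0 + np.sin(t / 5.0)
        o2 = 110.0 + 5.0 * np.cos(t / 7.0)
        one = tmp_path / "trace.tsv"
        pd.DataFrame({"time": t, "co2": co2, "o2": o2}).to_csv(
            one, sep="\t", index=False)
        tr = EndTidalTrace.from_file(one)
        assert np.allclose(tr.petco2, co2)
        co2f = tmp_path / "co2.tsv"
        o2f = tmp_path / "o2.tsv"
        pd.DataFrame({"time": t, "v": co2}).to_csv(co2f, sep="\t", index=False)
        pd.DataFrame({"time": t, "v": o2}).to_csv(o2f, sep="\t", index=False)
        tr2 = EndTidalTrace.from_file(co2f, o2f)
        assert np.allclose(tr2.peto2, o2)


class TestBaselineDetection:
    def test_flags_gas_blocks(self, acq):
        protocol = GasProtocol.default()
        trace = make_protocol(protocol)
        times = np.arange(244) * acq.tr
        co2, o2 = trace.sample(times)
        mask = find_baseline_volumes(co2, o2)
        # hypercapnic plateau volumes must be excluded
        hc = (times > 150) & (times < 260)
        assert not mask[hc].any()
        assert mask[:10].all()


class TestAlignTraces:
    def _asl_from_trace(self, trace, times, cbf0=60.0, cvr=2.4):
        co2, _ = trace.sample(times)
        return cbf0 * (1.0 + cvr / 100.0 * (co2 - co2[:5].mean()))

    def test_recovers_known_shift(self, constants, acq):
        trace = make_protocol(GasProtocol.default())
        times = np.arange(244) * acq.tr
        asl = self._asl_from_trace(trace, times)
        shifted = trace.shifted(-6.0)  # trace events appear 6 s later
        arterial = align_traces(shifted, asl, acq.tr, constants=constants,
                                volume_times=times)
        assert arterial.lag_s == pytest.approx(6.0, abs=trace.dt)

    def test_zero_shift(self, constants, acq):
        trace = make_protocol(GasProtocol.default())
        times = np.arange(244) * acq.tr
        asl = self._asl_from_trace(trace, times)
        arterial = align_traces(trace, asl, acq.tr, constants=constants,
                                volume_times=times)
        assert arterial.lag_s == pytest.approx(0.0, abs=trace.dt)

    def test_noise_triggers_warning(self, constants, acq):
        trace = make_protocol(GasProtocol.default())
        rng = np.random.default_rng(7)
        noise = rng.standard_normal(244)
        with pytest.warns(AlignmentWarning):
            align_traces(trace, noise, acq.tr, constants=constants,
                         volume_times=np.arange(244) * acq.tr)


class TestDeriveArterial:
    def test_baseline_scalars_and_table(self, constants, acq):
        trace = make_protocol(GasProtocol.default())
        arterial = derive_arterial(trace, np.arange(244) * acq.tr, constants)
        assert arterial.p50 == pytest.approx(27.1, abs=0.15)
        assert 7.3 < arterial.ph < 7.45
        assert arterial.cao2_0 == pytest.approx(0.192, abs=0.002)
        df = arterial.to_table()
        assert set(df.columns) >= {"time_s", "pao2_mmHg", "cao2_ml_per_ml"}
        assert len(df) == 244
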