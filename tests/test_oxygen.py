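import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import euler_oef
from qdcm.oxygen import (
    MOLAR_VOLUME_O2_STPD,
    OxygenLookupTable,
    OxygenModelParams,
    build_lookup,
    fick_cmro2,
    flow_volume_exponent,
    hill_pressure,
    invert_lookup_for_dc,
    ml_to_umol,
    oef_from_profile,
    solve_capillary_profile,
    umol_to_ml,
)

HB, P50 = 0.143, 27.1
MEAN = dict(dc=0.092, cbf=55.6, hb=HB, p50=P50)


class TestHillPressure:
    def test_half_saturation_returns_p50(self):
        assert hill_pressure(0.5 * 1.34 * HB, HB, P50) == pytest.approx(P50)

    def test_arterial_inlet_tension(self):
        # 0.95 of capacity: P = P50 * 19**(1/2.8)
        assert hill_pressure(0.95 * 1.34 * HB, HB, P50) == pytest.approx(
            77.56, abs=0.01)

    def test_low_content_asymptote(self):
        assert hill_pressure(1e-12, HB, P50) < 0.01

    def test_singularity_guard(self):
        with pytest.raises(ValueError):
            hill_pressure(1.34 * HB, HB, P50)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=0.9))
    def test_strictly_increasing(self, frac):
        cap = 1.34 * HB
        assert (hill_pressure(cap * (frac + 0.05), HB, P50)
                > hill_pressure(cap * frac, HB, P50))


class TestCapillaryProfile:
    def test_no_exchange_is_flat(self):
        prof = solve_capillary_profile(OxygenModelParams(dc=0.0, **{
            k: v for k, v in MEAN.items() if k != "dc"}))
        assert prof.ct[-1] == pytest.approx(prof.ct[0], rel=1e-12)
        assert oef_from_profile(prof) == pytest.approx(0.0, abs=1e-12)

    def test_mean_parameter_extraction(self):
        # group-mean physiology: the model's OEF matches the reported 0.38
        prof = solve_capillary_profile(OxygenModelParams(**MEAN))
        oef = oef_from_profile(prof)
        assert oef == pytest.approx(0.38333, abs=2e-4)
        assert oef == pytest.approx(euler_oef(**MEAN), abs=1e-4)

    def test_profile_monotone_nonincreasing(self):
        prof = solve_capillary_profile(OxygenModelParams(**MEAN))
        assert np.all(np.diff(prof.ct) <= 1e-12)

    def test_complete_extraction_asymptote(self):
        with pytest.warns(UserWarning):
            prof = solve_capillary_profile(OxygenModelParams(
                dc=10.0, cbf=55.6, hb=HB, p50=P50))
        assert oef_from_profile(prof) > 1.0 - 1e-6
        assert prof.floored

    def test_agrees_with_euler_oracle(self):
        rng = np.random.default_rng(42)
        dcs = rng.uniform(0.02, 0.25, 12)
        cbfs = rng.uniform(15.0, 130.0, 12)
        ours = np.array([
            oef_from_profile(solve_capillary_profile(
                OxygenModelParams(dc=d, cbf=c, hb=HB, p50=P50)))
            for d, c in zip(dcs, cbfs)])
        ref = euler_oef(dcs, cbfs, HB, P50)
        assert np.max(np.abs(ours - ref)) < 1e-4

    def test_mitochondrial_tension_reduces_extraction(self):
        oefs = [oef_from_profile(solve_capillary_profile(
            OxygenModelParams(pm=pm, **MEAN))) for pm in (0.0, 10.0, 20.0, 30.0)]
        assert np.all(np.diff(oefs) < 0)

    def test_oxygen_conservation(self):
        # flux balance: CBF*(Ct(0)-Ct(1)) == integral of Dc*(P - pm) dx
        p = OxygenModelParams(**MEAN)
        prof = solve_capillary_profile(p, n_points=4001)
        removed = p.cbf * (prof.ct[0] - prof.ct[-1])
        diffused = p.dc * np.trapezoid(prof.p - p.pm, prof.x)
        assert diffused == pytest.approx(removed, rel=1e-6)


class TestLookupTable:
    def test_monotone_in_both_axes(self, lut):
        unsat = lut.oef < 1 - 1e-6
        d_cbf = np.diff(lut.oef, axis=0)
        d_dc = np.diff(lut.oef, axis=1)
        assert np.all(d_cbf[unsat[:-1] & unsat[1:]] < 0)
        assert np.all(d_dc[unsat[:, :-1] & unsat[:, 1:]] > 0)

    def test_smallest_dc_column_is_minimal(self, lut):
        assert np.all(lut.oef[:, 0][:, None] <= lut.oef + 1e-15)

    def test_rebuild_is_bit_identical(self):
        grids = (np.geomspace(10, 100, 8), np.geomspace(0.02, 0.2, 8))
        a = build_lookup(*grids, hb=HB, p50=P50)
        b = build_lookup(*grids, hb=HB, p50=P50)
        assert np.array_equal(a.oef, b.oef)
        assert a.provenance == b.provenance

    def test_interpolation_matches_direct_solve(self, lut):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cbf = float(rng.uniform(10, 140))
            dc = float(rng.uniform(0.01, 0.3))
            direct = oef_from_profile(solve_capillary_profile(
                OxygenModelParams(dc=dc, cbf=cbf, hb=HB, p50=P50)))
            assert abs(lut.interp(cbf, dc) - direct) < 0.005

    def test_save_load_roundtrip(self, lut, tmp_path):
        path = tmp_path / "table.qlut.npz"
        lut.save(path)
        again = OxygenLookupTable.load(path)
        assert np.array_equal(again.oef, lut.oef)
        assert again.p50 == lut.p50 and again.provenance == lut.provenance

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            OxygenLookupTable(
                cbf_grid=np.array([2.0, 1.0]), dc_grid=np.array([0.1, 0.2]),
                oef=np.full((2, 2), 0.4), hb=HB, p50=P50)


class TestInversion:
    def test_grid_node_roundtrip(self, lut):
        worst = 0.0
        for ci in range(8, 248, 40):
            for di in range(8, 248, 40):
                oef = lut.oef[ci, di]
                if oef > 0.98:
                    continue
                dc = invert_lookup_for_dc(
                    float(oef), float(lut.cbf_grid[ci]), lut)
                worst = max(worst, abs(dc - lut.dc_grid[di]) / lut.dc_grid[di])
        assert worst < 1e-3

    def test_ode_oracle_roundtrip(self, lut):
        oef = oef_from_profile(solve_capillary_profile(
            OxygenModelParams(dc=0.05, cbf=40.0, hb=HB, p50=P50)))
        dc = invert_lookup_for_dc(oef, 40.0, lut)
        assert dc == pytest.approx(0.05, abs=5e-5)

    def test_out_of_range_returns_boundary(self, lut):
        with pytest.warns(UserWarning):
            lo = invert_lookup_for_dc(0.0, 60.0, lut)
        assert lo == pytest.approx(float(lut.dc_grid[0]))
        with pytest.warns(UserWarning):
            hi = invert_lookup_for_dc(0.99, 140.0, lut)
        assert hi == pytest.approx(float(lut.dc_grid[-1]))


class TestOxygenArithmetic:
    def test_diffusivity_unit_conversion(self):
        # the reported Dc of 0.092 ml/100g/mmHg/min in micromolar units
        assert ml_to_umol(0.092) == pytest.approx(3.62, abs=0.01)

    def test_unit_conversion_roundtrip_and_stpd(self):
        assert umol_to_ml(ml_to_umol(0.25)) == pytest.approx(0.25)
        assert ml_to_umol(1.0) == pytest.approx(39.3, abs=0.05)
        assert ml_to_umol(1.0, MOLAR_VOLUME_O2_STPD) == pytest.approx(
            44.615, abs=0.01)

    def test_fick_reproduces_group_cmro2(self):
        # product of the printed group means lands on 157.4 umol/100g/min
        assert fick_cmro2(55.6, 0.189, 0.38) == pytest.approx(157.4, rel=0.01)

    def test_fick_linearity_and_zero(self):
        assert fick_cmro2(55.6, 0.189, 1e-12) == pytest.approx(0.0, abs=1e-9)
        assert fick_cmro2(2 * 55.6, 0.189, 0.38) == pytest.approx(
            2 * fick_cmro2(55.6, 0.189, 0.38))

    def test_flow_volume_exponent_values(self):
        assert flow_volume_exponent(1.21, 1.125) == pytest.approx(0.62,
                                                                  abs=0.01)
        assert flow_volume_exponent(1.19, 1.067**2) == pytest.approx(0.75,
                                                                     abs=0.01)
        assert flow_volume_exponent(1.5, 1.0) == 0.0

    def test_flow_volume_exponent_errors(self):
        with pytest.raises(ValueError):
            flow_volume_exponent(1.0, 1.1)
        with pytest.raises(ValueError):
            flow_volume_exponent(-1.0, 1.1)
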