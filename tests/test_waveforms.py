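import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reboa_hemo.units import (LMIN_PER_M3S, M3S_PER_LMIN, MMHG_PER_PA,
                              PA_PER_MMHG, lmin_to_m3s, m3s_to_lmin,
                              mmhg_to_pa, pa_to_mmhg)
from reboa_hemo.waveforms import (CalibrationError, HemodynamicTargets,
                                  WaveformShape, calibrate_distal_pressure,
                                  couple_supra_outlets, make_inlet_flow,
                                  make_outlet_pressure)


class TestUnits:
    @given(x=st.floats(-1e6, 1e6, allow_nan=False))
    @settings(deadline=None)
    def test_round_trips_exact(self, x):
        assert pa_to_mmhg(mmhg_to_pa(x)) == pytest.approx(x, rel=1e-12, abs=1e-15)
        assert m3s_to_lmin(lmin_to_m3s(x)) == pytest.approx(x, rel=1e-12, abs=1e-15)

    def test_constants(self):
        assert PA_PER_MMHG == 133.322
        assert M3S_PER_LMIN == 1.0 / 60000.0


class TestInletFlow:
    @pytest.mark.parametrize("co, hr", [(6.5, 114), (4.5, 180), (4.8, 192),
                                        (6.0, 240)])
    def test_cycle_mean_is_cardiac_output(self, co, hr):
        wf = make_inlet_flow(HemodynamicTargets(co_l_min=co, hr_bpm=hr))
        assert wf.period == pytest.approx(60.0 / hr)
        assert wf.mean() * LMIN_PER_M3S == pytest.approx(co, rel=1e-9)

    def test_zero_output_is_identically_zero(self):
        wf = make_inlet_flow(HemodynamicTargets(co_l_min=0.0, hr_bpm=100))
        assert np.all(wf.values == 0.0)

    @settings(deadline=None, max_examples=60)
    @given(co=st.floats(0.5, 12), hr=st.floats(50, 260),
           s=st.floats(0.15, 0.6), ra=st.floats(0.0, 0.2))
    def test_mean_normalization_for_any_shape(self, co, hr, s, ra):
        shape = WaveformShape(systolic_fraction=s, reverse_amplitude=ra)
        wf = make_inlet_flow(HemodynamicTargets(co_l_min=co, hr_bpm=hr), shape)
        assert wf.mean() * LMIN_PER_M3S == pytest.approx(co, rel=1e-9)
        assert wf.values[0] == wf.values[-1]

    def test_invalid_systolic_fraction(self):
        with pytest.raises(ValueError):
            WaveformShape(systolic_fraction=1.2)


class TestOutletPressure:
    def test_exact_systolic_diastolic(self):
        wf = make_outlet_pressure(HemodynamicTargets(
            co_l_min=6.5, hr_bpm=114, systolic_mmhg=93, diastolic_mmhg=62))
        assert wf.values.max() * MMHG_PER_PA == pytest.approx(93)
        assert wf.values.min() * MMHG_PER_PA == pytest.approx(62)

    def test_flat_when_pulse_pressure_zero(self):
        wf = make_outlet_pressure(HemodynamicTargets(
            co_l_min=5, hr_bpm=100, systolic_mmhg=80, diastolic_mmhg=80))
        assert np.allclose(wf.values, 80 * PA_PER_MMHG)

    def test_map_only_pins_time_mean(self):
        wf = make_outlet_pressure(HemodynamicTargets(
            co_l_min=6.9, hr_bpm=126, map_mmhg=83))
        assert wf.mean() * MMHG_PER_PA == pytest.approx(83, rel=1e-9)

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicTargets(co_l_min=5, hr_bpm=100,
                               systolic_mmhg=60, diastolic_mmhg=90)

    def test_missing_pressures_rejected(self):
        with pytest.raises(ValueError):
            make_outlet_pressure(HemodynamicTargets(co_l_min=5, hr_bpm=100))


class TestSupraCoupling:
    def test_outlets_are_pointwise_identical_copies(self):
        wf = make_outlet_pressure(HemodynamicTargets(
            co_l_min=6.5, hr_bpm=114, systolic_mmhg=93, diastolic_mmhg=62))
        p1, p2 = couple_supra_outlets(wf)
        assert np.array_equal(p1.values, wf.values)
        assert np.array_equal(p2.values, wf.values)
        p1.values[0] = -1.0  # copies, not views
        assert wf.values[0] != -1.0

    def test_flow_waveform_rejected(self):
        q = make_inlet_flow(HemodynamicTargets(co_l_min=6.5, hr_bpm=114))
        with pytest.raises(ValueError):
            couple_supra_outlets(q)


class _Scenario:
    """Minimal scenario view for the calibration loop."""

    def __init__(self, co=6.5, hr=114):
        self.targets = HemodynamicTargets(co_l_min=co, hr_bpm=hr,
                                          systolic_mmhg=93, diastolic_mmhg=62)
        self.shape = WaveformShape()


def _mock_reference(q_mean, p_mean=75.0):
    """Synthetic recording with prescribed cycle means and no noise."""
    from reboa_hemo.synthetic import AnimalDraw, SyntheticRecording

    t = np.linspace(0, 4.0, 1000)
    return SyntheticRecording(
        animal_id=0, group="f_reboa", phase="baseline",
        draw=AnimalDraw(0, "f_reboa", "baseline", q_mean, 114, p_mean),
        time_s=t,
        subclavian_pressure_mmhg=np.full_like(t, p_mean),
        femoral_pressure_mmhg=np.full_like(t, p_mean - 3),
        descending_flow_l_min=np.full_like(t, q_mean),
        n_cycles=8, seed=0)


class _MockSolver:
    """Monotone linear flow-vs-distal-pressure response."""

    def __init__(self, q0=6.0, slope=0.09, p_probe=75.0):
        self.q0, self.slope, self.p_probe = q0, slope, p_probe
        self.calls = []

    def __call__(self, distal_wf):
        level = distal_wf.mean() * MMHG_PER_PA
        q = self.q0 - self.slope * level
        self.calls.append((level, q))
        return q, self.p_probe


class TestDistalCalibration:
    def test_recovers_reference_mean_within_tol(self):
        handle = _MockSolver()
        wf, history = calibrate_distal_pressure(
            _Scenario(), _mock_reference(q_mean=4.0), handle, tol=0.02)
        assert history[-1]["rel_err_flow"] <= 0.02
        assert history[-1]["rel_err_pressure"] <= 0.02

    def test_monotone_control_response(self):
        handle = _MockSolver()
        calibrate_distal_pressure(_Scenario(), _mock_reference(4.0), handle,
                                  tol=0.02)
        levels, flows = zip(*sorted(handle.calls))
        assert all(f2 <= f1 + 1e-9 for f1, f2 in zip(flows, flows[1:]))

    def test_infeasible_reference_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_distal_pressure(_Scenario(co=6.5),
                                      _mock_reference(q_mean=9.9),
                                      _MockSolver(), tol=0.05)

    def test_nonconvergence_reports_history(self):
        stuck = lambda wf: (0.5, 75.0)  # unresponsive plant
        with pytest.raises(CalibrationError) as err:
            calibrate_distal_pressure(_Scenario(), _mock_reference(6.0),
                                      stuck, tol=0.01, max_iter=4)
        assert len(err.value.history) == 4
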