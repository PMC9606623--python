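import numpy as np
import pytest

from reboa_hemo.geometry import build_channel, sample_walls
from reboa_hemo.metrics import (WallMetricSeries, extract_sys_dia, osi,
                                percent_change, tawss, tawsr,
                                wall_shear_series)
from reboa_hemo.rheology import FluidProperties


def make_series(wss_fn, n_t=201, period=1.0, n_s=1):
    """WallMetricSeries from an analytic signed-shear signal."""
    t = np.linspace(0.0, period, n_t)
    wss = np.tile(wss_fn(t), (n_s, 1))
    return WallMetricSeries(
        x=np.zeros(n_s), y=np.zeros(n_s),
        region=np.array(["descending_proximal"] * n_s, dtype=object),
        times=t, wss=wss, wsr=np.abs(wss) / 0.0035,
        flagged=np.zeros(n_s, dtype=bool), period=period)


class TestTimeAverages:
    @pytest.mark.parametrize("fn, expected, rtol", [
        (lambda t: np.full_like(t, 2.0), 2.0, 1e-12),          # constant
        (lambda t: np.sin(2 * np.pi * t), 2 / np.pi, 1e-3),    # mean of |sin|
        (lambda t: np.where(t % 1.0 < 0.5, 3.0, -3.0), 3.0, 1e-2),  # square
    ])
    def test_tawss_closed_forms(self, fn, expected, rtol):
        assert tawss(make_series(fn))[0] == pytest.approx(expected, rel=rtol)

    def test_tawsr_scales_like_tawss(self):
        s = make_series(lambda t: np.sin(2 * np.pi * t) * 0.0035 * 500)
        assert tawsr(s)[0] == pytest.approx(500 * 2 / np.pi, rel=1e-3)

    def test_quadrature_refinement_below_one_percent(self):
        fn = lambda t: np.sin(2 * np.pi * t) + 0.4
        coarse = tawss(make_series(fn, n_t=25))[0]
        fine = tawss(make_series(fn, n_t=49))[0]
        assert abs(fine - coarse) / fine < 0.01

    def test_nonuniform_sampling_rejected(self):
        s = make_series(lambda t: np.full_like(t, 1.0))
        s.times = s.times ** 2
        with pytest.raises(ValueError):
            tawss(s)


class TestOSI:
    @pytest.mark.parametrize("fn, expected", [
        (lambda t: np.full_like(t, 1.5), 0.0),                 # unidirectional
        (lambda t: np.sin(2 * np.pi * t), 0.5),                # zero-mean
        # 1 for T/2, -1/2 for T/2: 0.5 (1 - 0.25/0.75) = 1/3
        (lambda t: np.where(t % 1.0 < 0.5, 1.0, -0.5), 1.0 / 3.0),
    ])
    def test_hand_computed_values(self, fn, expected):
        val, flag = osi(make_series(fn, n_t=2001))
        assert val[0] == pytest.approx(expected, abs=2e-3)
        assert not flag[0]

    def test_identically_zero_shear_flagged_as_zero(self):
        val, flag = osi(make_series(lambda t: np.zeros_like(t)))
        assert val[0] == 0.0 and flag[0]

    def test_bounds_for_random_signals(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            coef = rng.standard_normal(4)
            fn = lambda t: (coef[0] + coef[1] * np.sin(2 * np.pi * t)
                            + coef[2] * np.cos(4 * np.pi * t)
                            + coef[3] * np.sin(6 * np.pi * t))
            val, _ = osi(make_series(fn))
            assert 0.0 <= val[0] <= 0.5


class TestSysDia:
    def test_sinusoid(self):
        t = np.linspace(0, 1, 500)
        s, d, m = extract_sys_dia(100 + 20 * np.sin(2 * np.pi * t), t)
        assert (s, d) == (pytest.approx(120, abs=0.01), pytest.approx(80, abs=0.01))
        assert m == pytest.approx(100, abs=0.1)

    def test_constant(self):
        assert extract_sys_dia(np.full(10, 80.0)) == (80, 80, 80)

    def test_prescribed_outlet_waveform_extrema(self):
        from reboa_hemo.units import pa_to_mmhg
        from reboa_hemo.waveforms import HemodynamicTargets, make_outlet_pressure

        wf = make_outlet_pressure(HemodynamicTargets(
            co_l_min=6.5, hr_bpm=114, systolic_mmhg=93, diastolic_mmhg=62))
        s, d, _ = extract_sys_dia(pa_to_mmhg(wf.values), wf.times)
        assert s == pytest.approx(93) and d == pytest.approx(62)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            extract_sys_dia(np.array([]))


class TestWallShearFromFields:
    @pytest.fixture(scope="class")
    def poiseuille_series(self):
        from reboa_hemo.solver import run_until_steady

        class Const:
            period = 0.2
            values = np.array([0.02 * 0.01])

            def __call__(self, t):
                return 0.02 * 0.01

        geom = build_channel(0.02, 0.01, 0.01 / 16)
        geom.wall_samples = sample_walls(geom)
        props = FluidProperties(newtonian_override=0.056)
        sol = run_until_steady(geom, props,
                               {"inlet": Const(), "right": ConstZero()},
                               t_max=3.0, tol=1e-8)
        snaps = {"times": np.linspace(0, 0.2, 25, endpoint=False),
                 "u": [sol.state.u] * 25, "v": [sol.state.v] * 25,
                 "p": [sol.state.p] * 25, "mu": [sol.state.mu] * 25}
        return geom, props, wall_shear_series(snaps, geom, props)

    def test_poiseuille_wall_shear_is_six_mu_u_over_h(self, poiseuille_series):
        geom, props, series = poiseuille_series
        expected = 6 * 0.056 * 0.02 / 0.01
        # away from the ports the wall shear matches the analytic value
        sel = (~series.flagged) & (series.x > 0.005) & (series.x < 0.015)
        vals = tawss(series)[sel]
        assert np.median(vals) == pytest.approx(expected, rel=0.05)

    def test_newtonian_tawss_equals_mu_times_tawsr(self, poiseuille_series):
        geom, props, series = poiseuille_series
        np.testing.assert_allclose(tawss(series),
                                   0.056 * tawsr(series), rtol=1e-9)

    def test_zero_flow_gives_zero_shear(self, poiseuille_series):
        geom, props, _ = poiseuille_series
        zeros_u = np.zeros((geom.nx + 1, geom.ny))
        zeros_v = np.zeros((geom.nx, geom.ny + 1))
        snaps = {"times": np.linspace(0, 0.2, 25, endpoint=False),
                 "u": [zeros_u] * 25, "v": [zeros_v] * 25,
                 "p": [np.zeros((geom.nx, geom.ny))] * 25,
                 "mu": [np.zeros((geom.nx, geom.ny))] * 25}
        series = wall_shear_series(snaps, geom, props)
        assert np.all(series.wss == 0) and np.all(series.wsr == 0)

    def test_too_few_instants_rejected(self, poiseuille_series):
        geom, props, _ = poiseuille_series
        snaps = {"times": np.linspace(0, 0.2, 5),
                 "u": [], "v": [], "p": [], "mu": []}
        with pytest.raises(ValueError):
            wall_shear_series(snaps, geom, props)


class ConstZero:
    period = 0.2
    values = np.array([0.0])

    def __call__(self, t):
        return 0.0


class TestPercentChange:
    def test_identity_and_direction(self):
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(6.0, 5.0) == pytest.approx(20.0)
        assert np.isnan(percent_change(1.0, 0.0))
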