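import numpy as np
import pytest

from reboa_hemo.synthetic import (GROUP_STATS, AnimalDraw, CohortSpec,
                                  SyntheticRecording, draw_cohort,
                                  reference_means, render_traces)


def zero_sd_stats():
    return {g: {ph: {k: (v[0], 0.0) for k, v in d.items()}
                for ph, d in phases.items()}
            for g, phases in GROUP_STATS.items()}


class TestCohortDraws:
    def test_zero_sd_reproduces_phase_means_exactly(self):
        spec = CohortSpec(group="p_reboa", n_animals=5, seed=9,
                          stats=zero_sd_stats())
        for d in draw_cohort(spec):
            st = GROUP_STATS["p_reboa"][d.phase]
            assert (d.co_l_min, d.hr_bpm, d.map_mmhg) == (
                st["co"][0], st["hr"][0], st["map"][0])

    def test_same_seed_is_reproducible(self):
        spec = CohortSpec(group="f_reboa", n_animals=6, seed=123)
        a, b = draw_cohort(spec), draw_cohort(spec)
        assert a == b

    def test_default_cohort_sizes_match_study_arms(self):
        assert CohortSpec(group="f_reboa").size == 4
        assert CohortSpec(group="p_reboa").size == 6

    @pytest.mark.parametrize("group", ["f_reboa", "p_reboa"])
    @pytest.mark.parametrize("phase", ["baseline", "hemorrhage", "occlusion"])
    def test_distributional_recovery_within_two_percent(self, group, phase):
        spec = CohortSpec(group=group, phases=(phase,), n_animals=10000,
                          seed=2)
        draws = draw_cohort(spec)
        st = GROUP_STATS[group][phase]
        for key, attr in (("co", "co_l_min"), ("hr", "hr_bpm"),
                          ("map", "map_mmhg")):
            vals = np.array([getattr(d, attr) for d in draws])
            mean, sd = st[key]
            assert vals.mean() == pytest.approx(mean, rel=0.02)
            assert vals.std(ddof=1) == pytest.approx(sd, rel=0.05)

    def test_physiologic_floors_enforced(self):
        stats = {"f_reboa": {"baseline": {"co": (0.6, 2.0), "hr": (45, 30),
                                          "map": (25, 20)}}}
        spec = CohortSpec(group="f_reboa", phases=("baseline",),
                          n_animals=500, seed=4, stats=stats)
        for d in draw_cohort(spec):
            assert d.co_l_min > 0.5 and d.hr_bpm > 40 and d.map_mmhg > 20


def noiseless_spec(**kw):
    return CohortSpec(beat_noise_cv=0.0, pressure_noise_mmhg=0.0,
                      flow_noise_l_min=0.0, **kw)


class TestTraceRendering:
    def test_noise_free_flow_mean_equals_cardiac_output(self):
        spec = noiseless_spec(group="f_reboa", phases=("baseline",),
                              n_animals=2, seed=3)
        for rec in render_traces(draw_cohort(spec), spec=spec, n_cycles=6):
            assert rec.descending_flow_l_min.mean() == pytest.approx(
                rec.draw.co_l_min, rel=1e-12)
            assert rec.subclavian_pressure_mmhg.mean() == pytest.approx(
                rec.draw.map_mmhg, rel=1e-12)

    def test_full_occlusion_phase_flow_reads_zero(self):
        spec = noiseless_spec(group="f_reboa", phases=("occlusion",),
                              n_animals=1, seed=3)
        rec = render_traces(draw_cohort(spec), spec=spec, n_cycles=4)[0]
        assert np.all(rec.descending_flow_l_min == 0.0)

    def test_rendering_is_bit_reproducible(self):
        spec = CohortSpec(group="p_reboa", phases=("baseline",), n_animals=1,
                          seed=7)
        a = render_traces(draw_cohort(spec), spec=spec, n_cycles=10)[0]
        b = render_traces(draw_cohort(spec), spec=spec, n_cycles=10)[0]
        assert np.array_equal(a.subclavian_pressure_mmhg,
                              b.subclavian_pressure_mmhg)
        assert np.array_equal(a.descending_flow_l_min, b.descending_flow_l_min)

    def test_requires_two_cycles(self):
        spec = CohortSpec(n_animals=1)
        with pytest.raises(ValueError):
            render_traces(draw_cohort(spec), spec=spec, n_cycles=1)


class TestReferenceMeans:
    def _const_recording(self, value=80.0, n_cycles=8):
        t = np.linspace(0, 4, 1000)
        return SyntheticRecording(
            animal_id=0, group="f_reboa", phase="baseline",
            draw=AnimalDraw(0, "f_reboa", "baseline", 6.5, 114, 83),
            time_s=t, subclavian_pressure_mmhg=np.full_like(t, value),
            femoral_pressure_mmhg=np.full_like(t, value),
            descending_flow_l_min=np.full_like(t, 6.5),
            n_cycles=n_cycles, seed=0)

    def test_constant_trace_mean_and_zero_se(self):
        out = reference_means(self._const_recording())
        assert out["subclavian_pressure_mmhg"]["mean"] == 80.0
        assert out["subclavian_pressure_mmhg"]["se"] == 0.0

    def test_standard_error_shrinks_like_root_n_cycles(self):
        # noise-dominated regime; averaged over seeds because the
        # jackknife SE from ~10 beats is itself a noisy estimate
        ses = {10: [], 40: []}
        for seed in range(8):
            for nc in (10, 40):
                spec = CohortSpec(group="f_reboa", phases=("baseline",),
                                  n_animals=1, seed=100 + seed,
                                  beat_noise_cv=0.0, flow_noise_l_min=1.0)
                rec = render_traces(draw_cohort(spec), spec=spec,
                                    n_cycles=nc)[0]
                ses[nc].append(
                    reference_means(rec)["descending_flow_l_min"]["se"])
        ratio = np.mean(ses[10]) / np.mean(ses[40])
        assert ratio == pytest.approx(2.0, rel=0.45)

    def test_short_recording_rejected(self):
        rec = self._const_recording(n_cycles=1)
        with pytest.raises(ValueError):
            reference_means(rec)
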