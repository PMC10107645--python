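"""Synthetic data generators: inversion correctness and design properties."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mplcox import SimConfig, invert_event_time, make_preset
from mplcox.simulate import (BASELINES, gen_study1, gen_study2_scenario1,
                             gen_study2_scenario2, generate,
                             invert_event_time_continuous)
from mplcox.study import run_simulation_study


class TestInversion:
    def test_weibull_closed_form_without_covariates(self):
        base = BASELINES["weibull"]            # H0(t) = t^3
        for u in [0.1, 0.5, 0.9]:
            T = invert_event_time(base, [0.0], [0.0], [[0.0]], [0.0], [0.0], u)
            assert T == pytest.approx((-math.log(u)) ** (1 / 3), rel=1e-12)

    def test_gompertz_closed_form(self):
        base = BASELINES["gompertz"]           # H0(t) = 2.5 (e^{0.2t} - 1)
        u = math.exp(-2.5)
        T = invert_event_time(base, [0.0], [0.0], [[0.0]], [0.0], [0.0], u)
        assert T == pytest.approx(5.0 * math.log(1 + 2.5 / 2.5), rel=1e-12)

    @pytest.mark.parametrize("name", sorted(BASELINES))
    def test_plugback_residual_with_segments(self, name):
        base = BASELINES[name]
        rng = np.random.default_rng(7)
        beta, gamma = [0.8, -0.4], [-0.9]
        for _ in range(50):
            x = [rng.integers(0, 2), rng.uniform()]
            ct = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 2.0, 2))])
            zv = rng.normal(scale=0.7, size=(3, 1))
            u = rng.uniform(1e-4, 1 - 1e-4)
            T = invert_event_time(base, x, ct, zv, beta, gamma, u)
            # independent residual: quadrature of the generated hazard
            def h(s):
                a = int(np.searchsorted(ct, s, side="right")) - 1
                return float(base.h0(s) * math.exp(
                    np.dot(x, beta) + zv[a] @ np.asarray(gamma)))
            Hq, _ = quad(h, 0.0, T, limit=400, points=list(ct[1:]))
            assert abs(Hq + math.log(u)) < 1e-8

    def test_continuous_covariate_matches_piecewise_free_case(self):
        base = BASELINES["weibull"]
        for u in [0.2, 0.7]:
            T = invert_event_time_continuous(base, [0.0], lambda t: 0.0,
                                             [0.0], [1.0], u)
            assert T == pytest.approx((-math.log(u)) ** (1 / 3), rel=1e-9)

    def test_invalid_uniform_deviate_rejected(self):
        with pytest.raises(ValueError):
            invert_event_time(BASELINES["weibull"], [0.0], [0.0], [[0.0]],
                              [0.0], [0.0], 1.5)


class TestStudy1:
    def test_only_event_and_right_types(self):
        ds = gen_study1(make_preset("study1-gompertz", n=300), seed=4)
        types = set(s.censor_type for s in ds.subjects)
        assert types <= {"event", "right"}

    def test_event_proportion_near_configured(self):
        cfg = make_preset("study1-gompertz", n=6000, pi_E=0.7)
        ds = gen_study1(cfg, seed=10)
        frac = np.mean([s.censor_type == "event" for s in ds.subjects])
        assert abs(frac - 0.7) < 0.02

    def test_unbounded_censoring_window_gives_all_events(self):
        cfg = SimConfig(scenario="study1", baseline="gompertz",
                        beta_true=(1.0, -0.5), gamma_true=(-1.0,),
                        n=200, pi_E=0.7, b1=0.0, b2=1e6)
        ds = gen_study1(cfg, seed=1)
        assert all(s.censor_type == "event" for s in ds.subjects)

    def test_covariate_jump_lowers_risk(self):
        # gamma1 = -1: among large-n subjects, post-jump exposure time
        # should be longer than under gamma1 = 0 (hazard halts after jump)
        lo = gen_study1(SimConfig(scenario="study1", baseline="gompertz",
                                  beta_true=(0.0, 0.0), gamma_true=(-2.0,),
                                  n=4000, b2=1e6), seed=5)
        none = gen_study1(SimConfig(scenario="study1", baseline="gompertz",
                                    beta_true=(0.0, 0.0), gamma_true=(0.0,),
                                    n=4000, b2=1e6), seed=5)
        assert (np.mean([s.y for s in lo.subjects])
                > np.mean([s.y for s in none.subjects]))


class TestScenario1:
    def test_event_fraction_matches_pi_e(self):
        cfg = make_preset("s2s1-weibull", n=20000, pi_E=0.3)
        ds = gen_study2_scenario1(cfg, seed=2)
        frac = np.mean([s.censor_type == "event" for s in ds.subjects])
        assert abs(frac - 0.3) < 0.01

    def test_all_four_types_occur(self):
        cfg = make_preset("s2s1-weibull", n=2000, pi_E=0.5)
        counts = gen_study2_scenario1(cfg, seed=3).censor_counts()
        assert all(counts[k] > 0 for k in counts)

    def test_certain_event_probability_collapses_types(self):
        cfg = make_preset("s2s1-weibull", n=100, pi_E=1 - 1e-12)
        ds = gen_study2_scenario1(cfg, seed=3)
        assert all(s.censor_type == "event" for s in ds.subjects)


class TestScenario2:
    @pytest.mark.parametrize("cond", [1, 2, 3])
    def test_no_exact_events_and_valid_grid_classification(self, cond):
        cfg = make_preset(f"s2s2-cond{cond}", n=150)
        ds = gen_study2_scenario2(cfg, seed=6)
        types = set(s.censor_type for s in ds.subjects)
        assert "event" not in types
        assert types <= {"left", "interval", "right"}
        for s in ds.subjects:
            if s.censor_type == "left":
                assert s.yL == 0.0
            # recorded covariate change times never pass the horizon
            assert s.change_times[-1] < s.y or s.ni == 1

    def test_condition2_has_two_time_varying_covariates(self):
        ds = gen_study2_scenario2(make_preset("s2s2-cond2", n=50), seed=8)
        assert ds.q == 2

    def test_condition3_records_sinusoid_at_assessments(self):
        ds = gen_study2_scenario2(make_preset("s2s2-cond3", n=80), seed=9)
        assert ds.p == 1 and ds.q == 1
        # every recorded z lies within the |tau_i| amplitude of sin(2t)
        for s in ds.subjects:
            amp = np.max(np.abs(s.z_values))
            assert np.isfinite(amp)


def test_seeded_generation_is_reproducible():
    cfg = make_preset("s2s1-weibull", n=80, pi_E=0.7)
    a = generate(cfg, seed=42).to_frame()
    b = generate(cfg, seed=42).to_frame()
    assert a.equals(b)


def test_study_harness_self_test_with_injected_truth():
    cfg = make_preset("s2s1-weibull", n=50, pi_E=0.7)
    res = run_simulation_study(cfg, n_reps=20, seed=1, inject_truth=True)
    assert np.allclose(res.table["bias"], 0.0)
    assert np.allclose(res.table["cp"], 1.0)
    assert res.n_excluded == 0
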