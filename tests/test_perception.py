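"""The quadratic heat-perception model: fitting, vertex, tolerance,
sensitivity and the perception threshold."""
import datetime as dt

import numpy as np
import pytest

from conftest import make_temps
from heatlens.perception import (
    NO_INTERSECTION,
    NON_CONVEX,
    PerceptionFit,
    build_observations,
    derive_statistics,
    fit_perception_model,
    heat_perception_threshold,
    heat_sensitivity,
    heat_tolerance,
    vertex_temperature,
)
from heatlens.records import AttentionRecord, PostRecord
from oracles import bisect_right_root


def _fit(a0, a1, a2, mean_attention=0.0):
    return PerceptionFit(
        region="R", a0=a0, a1=a1, a2=a2, n_obs=0, r2=1.0,
        mean_attention=mean_attention,
    )


class TestQuadraticFit:
    def test_noiseless_data_recovered_exactly(self):
        w = np.linspace(20, 40, 62)
        t = 1.0 + 2.0 * w + 3.0 * w * w
        fit = fit_perception_model(omega=w, t_attn=t)
        assert fit.a0 == pytest.approx(1.0, abs=1e-8)
        assert fit.a1 == pytest.approx(2.0, abs=1e-8)
        assert fit.a2 == pytest.approx(3.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        w = np.array([25.0, 30.0, 35.0, 28.0])
        fit = fit_perception_model(omega=w, t_attn=np.full(4, 7.5))
        assert fit.a0 == pytest.approx(7.5, abs=1e-9)
        assert fit.a1 == pytest.approx(0.0, abs=1e-9)
        assert fit.a2 == pytest.approx(0.0, abs=1e-9)

    def test_noise_study_bias_within_monte_carlo_se(self):
        """200 replicates of Gaussian-noise data: OLS coefficient bias stays
        below 3 Monte-Carlo standard errors."""
        true = np.array([905.0, -60.0, 1.0])
        w = np.linspace(24, 36, 62)
        X = np.column_stack([np.ones_like(w), w, w * w])
        signal = X @ true
        rng = np.random.default_rng(0)
        coefs = np.empty((200, 3))
        for r in range(200):
            t = signal + rng.normal(0, 2.0, size=len(w))
            f = fit_perception_model(omega=w, t_attn=t)
            coefs[r] = (f.a0, f.a1, f.a2)
        bias = coefs.mean(axis=0) - true
        se = coefs.std(axis=0, ddof=1) / np.sqrt(200)
        assert (np.abs(bias) < 3 * se).all(), (bias, se)

    def test_too_few_distinct_temperatures(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_perception_model(omega=[30.0, 30.0, 30.0, 31.0], t_attn=[1, 2, 3, 4])

    def test_mean_attention_is_arithmetic_mean(self):
        w = [25.0, 30.0, 35.0]
        t = [2.0, 4.0, 9.0]
        fit = fit_perception_model(omega=w, t_attn=t)
        assert fit.mean_attention == pytest.approx(5.0)


class TestVertex:
    def test_simple(self):
        assert vertex_temperature(_fit(0, -60.0, 1.0)) == pytest.approx(30.0)

    def test_turning_point_form(self):
        assert vertex_temperature(_fit(0, -65.0, 1.0)) == pytest.approx(32.5)

    def test_non_convex_undefined(self):
        assert vertex_temperature(_fit(0, -60.0, -1.0)) is None
        derived = derive_statistics(_fit(0, -60.0, -1.0))
        assert NON_CONVEX in derived.flags


class TestSensitivity:
    @pytest.mark.parametrize("a2", [1.007, 0.0, 0.002, -0.4])
    def test_returns_a2_verbatim(self, a2):
        assert heat_sensitivity(_fit(0, 0, a2)) == a2


class TestTolerance:
    def test_worked_example_right_root(self):
        # T = (ω − 30)² + 5 with mean attention 9: roots 28 and 32
        fit = _fit(905.0, -60.0, 1.0, mean_attention=9.0)
        assert heat_tolerance(fit) == pytest.approx(32.0, abs=1e-12)

    def test_mean_at_minimum_gives_vertex(self):
        fit = _fit(905.0, -60.0, 1.0, mean_attention=5.0)  # minimum value is 5
        assert heat_tolerance(fit) == pytest.approx(vertex_temperature(fit))

    def test_mean_below_minimum_undefined(self):
        fit = _fit(905.0, -60.0, 1.0, mean_attention=4.0)
        assert heat_tolerance(fit) is None
        assert NO_INTERSECTION in derive_statistics(fit).flags

    def test_non_convex_undefined(self):
        assert heat_tolerance(_fit(1.0, 1.0, -2.0, mean_attention=0.0)) is None

    def test_matches_bisection_oracle_on_random_convex_fits(self):
        """50 random convex fits: the closed-form right root agrees with a
        numeric bisection of T(ω) − M to 1e-9."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            a2 = float(rng.uniform(0.05, 3.0))
            vx = float(rng.uniform(20, 35))
            a1 = -2 * a2 * vx
            a0 = a2 * vx * vx + float(rng.uniform(0, 10))
            minimum = a0 - a1 * a1 / (4 * a2)
            m = minimum + float(rng.uniform(0.1, 20.0))
            fit = _fit(a0, a1, a2, mean_attention=m)
            root = heat_tolerance(fit)
            oracle = bisect_right_root(a0, a1, a2, m, lo=vx, hi=vx + 1000.0)
            assert root == pytest.approx(oracle, abs=1e-9)
            checked += 1

    def test_tolerance_at_least_vertex_on_grid(self):
        for a2 in np.linspace(0.05, 2.0, 8):
            for vx in np.linspace(22, 36, 8):
                for lift in np.linspace(0.5, 15.0, 6):
                    a1 = -2 * a2 * vx
                    a0 = a2 * vx * vx + 1.0
                    fit = _fit(a0, a1, a2, mean_attention=1.0 + lift)
                    tol = heat_tolerance(fit)
                    assert tol is not None
                    assert tol >= vertex_temperature(fit) - 1e-12

    def test_tolerance_nondecreasing_in_mean_attention(self):
        for a2 in (0.1, 0.5, 1.5):
            fit_lo = _fit(a2 * 900, -60 * a2, a2, mean_attention=2.0)
            prev = None
            for m in np.linspace(2.0, 30.0, 20):
                fit = _fit(fit_lo.a0, fit_lo.a1, fit_lo.a2, mean_attention=float(m))
                tol = heat_tolerance(fit)
                if prev is not None:
                    assert tol >= prev
                prev = tol


class TestThreshold:
    def _posts(self, day_regions):
        return [
            PostRecord(f"p{i}", date, region, "hot")
            for i, (date, region) in enumerate(day_regions)
        ]

    def test_constant_temperature(self):
        temps = make_temps("RA", dt.date(2023, 7, 1), [30.0] * 5)
        posts = self._posts([(dt.date(2023, 7, 1 + i), "RA") for i in range(5)])
        assert heat_perception_threshold(posts, temps, "RA") == pytest.approx(30.0)

    def test_post_weighted_mean(self):
        temps = make_temps("RA", dt.date(2023, 7, 1), [28.0, 32.0])
        posts = self._posts(
            [(dt.date(2023, 7, 1), "RA")] + [(dt.date(2023, 7, 2), "RA")] * 3
        )
        assert heat_perception_threshold(posts, temps, "RA") == pytest.approx(31.0)

    def test_matches_brute_force_per_post_average(self):
        rng = np.random.default_rng(6)
        values = list(rng.uniform(24, 38, 10))
        temps = make_temps("RA", dt.date(2023, 7, 1), values)
        days = [int(d) for d in rng.integers(0, 10, size=40)]
        posts = self._posts(
            [(dt.date(2023, 7, 1) + dt.timedelta(days=d), "RA") for d in days]
        )
        brute = sum(values[d] for d in days) / len(days)
        assert heat_perception_threshold(posts, temps, "RA") == pytest.approx(brute)

    def test_no_matching_posts_is_error(self):
        temps = make_temps("RA", dt.date(2023, 7, 1), [30.0])
        with pytest.raises(ValueError, match="RB"):
            heat_perception_threshold([], temps, "RB")


class TestBuildObservations:
    def test_joins_on_region_day(self):
        temps = make_temps("RA", dt.date(2023, 7, 1), [30.0, 31.0])
        recs = [
            AttentionRecord("RA", dt.date(2023, 7, 1), 3, 1.5, 2.0),
            AttentionRecord("RA", dt.date(2023, 7, 9), 1, 1.5, 2 / 3),  # no temp
            AttentionRecord("RA", None, 4, 1.5, 8 / 3),  # period row ignored
        ]
        obs = build_observations(recs, temps)
        assert len(obs) == 1
        assert obs[0].omega == 30.0 and obs[0].t_attn == 2.0
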