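import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2oflux import (
    Scenario,
    attached_uptake,
    concentration_at,
    single_sphere_release,
    solve_image_series,
    solve_scenario,
    uptake_analytic,
)
from n2oflux.analytic import ConvergenceError


def mutual_charge_closed_form(R, r, L):
    """Independent oracle: Maxwell's sinh series for the mutual capacitance
    coefficient of two spheres (producer at potential 1, consumer grounded)."""
    u = math.acosh((L * L - R * R - r * r) / (2.0 * R * r))
    total, n = 0.0, 1
    while True:
        term = 1.0 / math.sinh(n * u)
        total += term
        if term < 1e-16 * total or n > 10**6:
            break
        n += 1
    return -(R * r / L) * math.sinh(u) * total


def uptake(R, r, d, **kw):
    return solve_scenario(Scenario(R, r, d), **kw).absolute_uptake


class TestImageSeries:
    def test_hand_iterated_equal_spheres(self):
        # R = r = 1, d = 2: images -1/4, -1/56, -0.0012821, ... sum -0.26924
        s = Scenario(1.0, 1.0, 2.0)
        series = solve_image_series(s)
        assert series.converged
        first = [c.magnitude for c in series.consumer_charges[:3]]
        assert first[0] == pytest.approx(-0.25)
        assert first[1] == pytest.approx(-1.0 / 56.0, rel=1e-9)
        assert first[2] == pytest.approx(-0.0012821, rel=1e-4)
        assert series.total_consumer_charge == pytest.approx(-0.26924, rel=1e-4)
        res = uptake_analytic(series, s)
        assert res.absolute_uptake == pytest.approx(4 * math.pi * 0.26924, rel=1e-4)
        assert res.volume_normalized_uptake == pytest.approx(
            res.absolute_uptake / (4 * math.pi / 3), rel=1e-12
        )

    def test_far_field_limit(self):
        # L >> R + r: U -> 4*pi*D*r*R/L
        s = Scenario(1.0, 1.0, 98.0, domain_side=210.0)
        U = solve_scenario(s).absolute_uptake
        assert U == pytest.approx(4 * math.pi * 0.01, rel=0.01)

    @pytest.mark.parametrize(
        "R,r,d",
        [(1.0, 1.0, 2.0), (1.0, 0.25, 0.5), (1.5, 0.05, 0.1), (0.5, 0.5, 0.01)],
    )
    def test_matches_closed_form_capacitance(self, R, r, d):
        series = solve_image_series(Scenario(R, r, d))
        expected = mutual_charge_closed_form(R, r, R + r + d)
        assert series.total_consumer_charge == pytest.approx(expected, rel=1e-8)

    def test_charge_positions_inside_spheres(self):
        series = solve_image_series(Scenario(1.0, 0.35, 0.1))
        L = series.center_distance
        for q, x in series.producer_charges:
            assert abs(x) < 1.0
        for q, x in series.consumer_charges:
            assert abs(x - L) < 0.35

    def test_charge_signs(self):
        series = solve_image_series(Scenario(1.0, 0.35, 0.5))
        assert series.total_producer_charge > 0
        assert series.total_consumer_charge < 0

    def test_non_convergence_flagged_not_silent(self):
        series = solve_image_series(Scenario(1.0, 1.0, 0.001), max_iterations=3)
        assert not series.converged
        with pytest.raises(ConvergenceError):
            uptake_analytic(series, Scenario(1.0, 1.0, 0.001))

    @given(
        R=st.floats(min_value=0.1, max_value=2.0),
        r=st.floats(min_value=0.1, max_value=2.0),
        d=st.floats(min_value=0.05, max_value=3.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_reciprocity_under_radius_exchange(self, R, r, d):
        # mutual capacitance is symmetric: swapping producer and consumer
        # radii leaves the uptake magnitude unchanged
        side = 2 * (R + r + d + max(R, r)) + 1.0
        u1 = solve_scenario(Scenario(R, r, d, domain_side=side)).absolute_uptake
        u2 = solve_scenario(Scenario(r, R, d, domain_side=side)).absolute_uptake
        assert u1 == pytest.approx(u2, rel=1e-8)


class TestScalingLaws:
    @pytest.mark.parametrize("k", [0.1, 3.0])
    def test_scale_invariance(self, k):
        # lengths x k => absolute uptake x k, volume-normalized x k^-2
        base = Scenario(1.0, 0.35, 0.5)
        scaled = Scenario(k * 1.0, k * 0.35, k * 0.5, domain_side=max(20.0, 20.0 * k))
        u0 = solve_scenario(base)
        u1 = solve_scenario(scaled)
        assert u1.absolute_uptake == pytest.approx(k * u0.absolute_uptake, rel=1e-9)
        assert u1.volume_normalized_uptake == pytest.approx(
            u0.volume_normalized_uptake / k**2, rel=1e-9
        )

    def test_doubling_diffusivity_doubles_uptake(self):
        u1 = solve_scenario(Scenario(1.0, 1.0, 2.0, diffusivity=1.0))
        u2 = solve_scenario(Scenario(1.0, 1.0, 2.0, diffusivity=2.0))
        assert u2.absolute_uptake == pytest.approx(2 * u1.absolute_uptake, rel=1e-12)

    def test_uptake_strictly_decreases_with_gap(self):
        gaps = [0.0, 0.05, 0.1, 0.5, 1.0, 2.0]
        ups = [uptake(1.0, 0.35, d) for d in gaps]
        assert all(a > b for a, b in zip(ups, ups[1:]))

    def test_convergence_stable_under_more_iterations(self):
        s = Scenario(1.0, 1.0, 0.01)
        u1 = uptake_analytic(solve_image_series(s, max_iterations=10**5), s)
        u2 = uptake_analytic(solve_image_series(s, max_iterations=2 * 10**5), s)
        assert u2.absolute_uptake == pytest.approx(u1.absolute_uptake, rel=1e-9)


class TestAttachedLimit:
    def test_extrapolated_value_exceeds_regularized_values(self):
        s = Scenario(1.0, 0.1, 0.0)
        res = attached_uptake(s)
        regs = res.meta["regularized_uptakes"]
        assert all(a < b for a, b in zip(regs, regs[1:]))  # grows as eps shrinks
        assert res.absolute_uptake > regs[-1]

    def test_deterministic_and_dispatched(self):
        s = Scenario(1.0, 0.1, 0.0)
        a = solve_scenario(s)
        b = solve_scenario(s)
        assert a.absolute_uptake == b.absolute_uptake
        assert a.absolute_uptake == attached_uptake(s).absolute_uptake

    def test_attached_exceeds_small_gap(self):
        assert uptake(1.0, 0.35, 0.0) > uptake(1.0, 0.35, 0.1)


@pytest.fixture(scope="module")
def series():
    return solve_image_series(Scenario(1.0, 1.0, 2.0))


class TestConcentrationField:
    def test_producer_surface_at_one(self, series):
        for p in [(0.0, 1.0, 0.0), (-1.0, 0.0, 0.0), (0.6, 0.8, 0.0)]:
            assert concentration_at(series, p) == pytest.approx(1.0, abs=1e-6)

    def test_consumer_surface_at_zero(self, series):
        L = series.center_distance
        for p in [(L, 0.0, 1.0), (L + 1.0, 0.0, 0.0), (L - 0.6, -0.8, 0.0)]:
            assert concentration_at(series, p) == pytest.approx(0.0, abs=1e-6)

    def test_decays_to_zero_far_away(self, series):
        assert concentration_at(series, (0.0, 500.0, 0.0)) == pytest.approx(0.0, abs=0.01)

    def test_bounded_between_surface_values(self, series):
        rng = np.random.default_rng(0)
        L = series.center_distance
        count = 0
        while count < 200:
            p = rng.uniform(-5, 5, size=3) + np.array([L / 2, 0, 0])
            if np.linalg.norm(p) <= 1.0 or np.linalg.norm(p - [L, 0, 0]) <= 1.0:
                continue
            c = concentration_at(series, p)
            assert -1e-9 <= c <= 1.0 + 1e-9
            count += 1

    def test_rejects_interior_points(self, series):
        with pytest.raises(ValueError, match="producer"):
            concentration_at(series, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="consumer"):
            concentration_at(series, (series.center_distance, 0.0, 0.1))


def test_single_sphere_release_closed_form():
    assert single_sphere_release(1.0) == pytest.approx(4 * math.pi, rel=1e-12)
    assert single_sphere_release(2.0, diffusivity=3.0) == pytest.approx(
        4 * math.pi * 6.0, rel=1e-12
    )
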