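"""Desirability transforms, grid+polish optimization, and threshold regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aavdoe import (
    DesirabilitySpec,
    MixtureBounds,
    SimplexRegion,
    SquareRegion,
    desirability_one,
    desirability_overall,
    equal_weight_thresholds,
    optimize_desirability,
    threshold_region,
)
from aavdoe.synthetic import RSMSurface, ScheffeSurface


class TestIndividualDesirability:
    def test_piecewise_closed_forms(self):
        assert desirability_one(-1.0, 0, 10) == 0.0
        assert desirability_one(11.0, 0, 10) == 1.0
        assert desirability_one(5.0, 0, 10, r=1) == pytest.approx(0.5)
        assert desirability_one(5.0, 0, 10, r=0.5) == pytest.approx(np.sqrt(0.5))

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError, match="L"):
            desirability_one(1.0, 5, 5)
        with pytest.raises(ValueError, match="r"):
            desirability_one(1.0, 0, 1, r=1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        L=st.floats(-10, 10),
        width=st.floats(0.1, 20),
        r=st.floats(0.05, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_monotone_and_bounded(self, L, width, r, seed):
        y = np.sort(np.random.default_rng(seed).uniform(L - 5, L + width + 5, 50))
        d = desirability_one(y, L, L + width, r)
        assert np.all((0 <= d) & (d <= 1))
        assert np.all(np.diff(d) >= -1e-12)


class TestOverallDesirability:
    def test_identities(self):
        assert desirability_overall([1.0, 1.0, 1.0]) == 1.0
        assert desirability_overall([0.9, 0.0, 1.0]) == 0.0
        assert desirability_overall([0.25, 0.25, 0.25], k=3) == pytest.approx(0.25)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            desirability_overall([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_geometric_mean_sandwich(self, d):
        D = desirability_overall(d)
        assert min(d) - 1e-12 <= D <= max(d) + 1e-12


class TestOptimizer:
    def test_quadratic_interior_optimum(self):
        # y = 5 - (x1 - 0.2)^2 - (x2 + 0.4)^2 on the coded square
        coef = np.array([5 - 0.04 - 0.16, 0.4, -0.8, -1.0, -1.0, 0.0])
        models = {"y": RSMSurface(coef)}
        spec = DesirabilitySpec({"y": (0.0, 5.0, 1.0)})
        res = optimize_desirability(models, SquareRegion(0.05), spec=spec)
        np.testing.assert_allclose(res.best.point, [0.2, -0.4], atol=0.05 * np.sqrt(2))

    def test_monotone_mixture_surface_hits_boundary(self):
        # Scheffe surface increasing in pRepCap only -> optimum at its 0.6 cap
        surf = ScheffeSurface(np.array([0.0, 1.0, 0.0, 0, 0, 0]))
        region = SimplexRegion(MixtureBounds(), 0.02)
        res = optimize_desirability({"y": surf}, region)
        assert res.best.point[1] == pytest.approx(0.6, abs=0.03)

    def test_saturated_targets_plateau(self):
        surf = RSMSurface(np.array([10.0, 0.1, 0, 0, 0, 0]))
        spec = DesirabilitySpec({"y": (0.0, 5.0, 1.0)})  # T below all y
        res = optimize_desirability({"y": surf}, SquareRegion(0.1), spec=spec)
        assert res.plateau
        assert res.best.D == 1.0

    def test_overall_d_is_geometric_mean_of_individuals(self, archetypes):
        arch = archetypes["egfp_like"]
        res = optimize_desirability(
            arch.scheffe_surfaces(), SimplexRegion(arch.bounds, 0.02)
        )
        d = np.array(list(res.best.d_individual.values()))
        assert res.best.D == pytest.approx(float(np.prod(d ** (1 / 3))), abs=1e-12)

    def test_zero_everywhere_flagged_not_raised(self):
        surf = RSMSurface(np.array([-5.0, 0.1, 0, 0, 0, 0]))
        spec = DesirabilitySpec({"y": (0.0, 5.0, 1.0)})  # all y < L
        res = optimize_desirability({"y": surf}, SquareRegion(0.1), spec=spec)
        assert res.all_zero

    def test_optimizer_matches_fine_grid_oracle(self, rng):
        # random concave quadratics: coarse grid+polish vs 10x finer scan
        for _ in range(5):
            a = rng.uniform(-1.5, -0.5, 2)
            b = rng.uniform(-1, 1, 2)
            c = rng.uniform(-0.5, 0.5)
            coef = np.array([0.0, b[0], b[1], a[0], a[1], c])
            surf = RSMSurface(coef)
            spec_region = SquareRegion(0.1)
            fine = SquareRegion(0.01).grid()
            spec = DesirabilitySpec.from_models({"y": surf}, spec_region)
            res = optimize_desirability({"y": surf}, spec_region, spec=spec)
            oracle = fine[np.argmax(surf.predict(fine))]
            assert np.linalg.norm(res.best.point - oracle) <= 0.1 * np.sqrt(2) + 1e-9


class TestThresholds:
    def test_minus_inf_threshold_keeps_full_grid(self, archetypes):
        arch = archetypes["egfp_like"]
        models = arch.scheffe_surfaces()
        thr = {name: -np.inf for name in models}
        mask = threshold_region(models, thr, SimplexRegion(arch.bounds, 0.05))
        assert mask.combined.all()

    def test_unreachable_threshold_empties_region(self, archetypes):
        arch = archetypes["egfp_like"]
        models = arch.scheffe_surfaces()
        region = SimplexRegion(arch.bounds, 0.05)
        grid = region.grid()
        thr = {name: -np.inf for name in models}
        thr["log_vp"] = float(models["log_vp"].predict(grid).max()) + 1.0
        mask = threshold_region(models, thr, region)
        assert not mask.combined.any()

    def test_passing_points_satisfy_inequalities_on_recheck(self, archetypes):
        arch = archetypes["bdnf_like"]
        models = arch.scheffe_surfaces()
        region = SimplexRegion(arch.bounds, 0.05)
        thr = equal_weight_thresholds(models, region, level=0.2)
        mask = threshold_region(models, thr, region)
        assert mask.combined.any()
        white = mask.points[mask.combined]
        for name, model in models.items():
            assert np.all(model.predict(white) >= thr[name] - 1e-9)

    def test_combined_is_conjunction(self, archetypes):
        arch = archetypes["msh2_like"]
        models = arch.scheffe_surfaces()
        mask = threshold_region(
            models,
            equal_weight_thresholds(models, SimplexRegion(arch.bounds, 0.05), 0.7),
            SimplexRegion(arch.bounds, 0.05),
        )
        expected = np.logical_and.reduce(list(mask.passes.values()))
        np.testing.assert_array_equal(mask.combined, expected)

    def test_equal_weight_threshold_inversion(self, archetypes):
        arch = archetypes["egfp_like"]
        models = arch.scheffe_surfaces()
        region = SimplexRegion(arch.bounds, 0.05)
        spec_half = DesirabilitySpec.from_models(models, region, r=1.0)
        thr = equal_weight_thresholds(models, region, 0.5, spec=spec_half)
        for name in models:
            L, T, _ = spec_half[name]
            assert thr[name] == pytest.approx((L + T) / 2)
        thr_top = equal_weight_thresholds(models, region, 1.0, spec=spec_half)
        for name in models:
            assert thr_top[name] == pytest.approx(spec_half[name][1])
        spec_r = DesirabilitySpec.from_models(models, region, r=0.5)
        thr_r = equal_weight_thresholds(models, region, 0.25, spec=spec_r)
        for name in models:
            L, T, _ = spec_r[name]
            assert thr_r[name] == pytest.approx(L + 0.0625 * (T - L))

    def test_argmax_lies_in_its_own_threshold_region(self, archetypes):
        arch = archetypes["egfp_like"]
        models = arch.scheffe_surfaces()
        region = SimplexRegion(arch.bounds, 0.02)
        res = optimize_desirability(models, region)
        # thresholds at the optimum's own desirability levels
        thr = {}
        for name in models:
            L, T, r = res.spec[name]
            thr[name] = L + (T - L) * res.best.d_individual[name] ** (1 / r)
        for name, model in models.items():
            assert float(model.predict(res.best.point[None, :])[0]) >= thr[name] - 1e-6
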