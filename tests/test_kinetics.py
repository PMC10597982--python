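"""Forward-model tests: macro-rates, analytic vs ODE tissue curves, voxel
mixing, frame integration, and the vectorised simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkin import kinetics
from petkin.types import BloodInput, KineticParams


def params(fv=0.0, K1=0.1, k2=0.1, k3=0.05, k4=0.0):
    return KineticParams(fv, K1, k2, k3, k4)


GRID = np.arange(0.0, 65.0001, 0.05)


class TestMacroRates:
    def test_irreversible_closed_form(self):
        # k4 = 0: discriminant collapses to k2+k3, so alpha1 = 0 exactly
        mr = kinetics.macro_rates(params(K1=0.1, k2=0.1, k3=0.05, k4=0.0))
        assert mr.alpha1 == 0.0
        assert mr.alpha2 == pytest.approx(0.15)
        assert mr.a == pytest.approx(0.1 * 0.05 / 0.15)
        assert mr.b == pytest.approx(0.1 * 0.1 / 0.15)

    def test_amplitudes_scale_with_k1(self):
        mr = kinetics.macro_rates(params(K1=0.0, k2=0.4, k3=0.1, k4=0.05))
        assert mr.a == 0.0 and mr.b == 0.0

    def test_eigenvalues_match_polynomial_roots(self, rng):
        # oracle: numerically solve s^2 + (k2+k3+k4) s + k2 k4 = 0
        for _ in range(20):
            K1, k2, k3, k4 = rng.uniform(0.01, 1.5, 4)
            mr = kinetics.macro_rates(params(K1=K1, k2=k2, k3=k3, k4=k4))
            roots = np.sort(np.roots([1.0, k2 + k3 + k4, k2 * k4]))
            assert mr.alpha2 == pytest.approx(-roots[0], abs=1e-10)
            assert mr.alpha1 == pytest.approx(-roots[1], abs=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(k2=st.floats(0.0, 2.0), k3=st.floats(0.0, 2.0),
           k4=st.floats(0.0, 2.0))
    def test_vieta_and_ordering(self, k2, k3, k4):
        mr = kinetics.macro_rates(params(K1=0.5, k2=k2, k3=k3, k4=k4))
        assert mr.alpha1 <= mr.alpha2 + 1e-15
        assert mr.alpha1 >= -1e-15
        assert mr.alpha1 * mr.alpha2 == pytest.approx(k2 * k4, abs=1e-10)
        assert mr.alpha1 + mr.alpha2 == pytest.approx(k2 + k3 + k4, abs=1e-10)
        if k4 == 0.0:
            assert mr.alpha1 == 0.0


class TestTissueConcentration:
    def test_zero_input_gives_zero_tissue(self, blood):
        zero = BloodInput(blood.times, np.zeros_like(blood.values))
        tc = kinetics.tissue_concentration(params(), zero, GRID)
        assert np.all(tc.ct == 0)

    def test_pure_trapping_integrates_the_input(self, blood):
        # k2 = k3 = k4 = 0 exercises the repeated-eigenvalue guard:
        # ct(t) = K1 * integral of C0
        tc = kinetics.tissue_concentration(
            params(K1=0.5, k2=0.0, k3=0.0, k4=0.0), blood, GRID)
        expect = 0.5 * blood.cumulative_integral(GRID)
        assert np.max(np.abs(tc.ct - expect)) < 1e-3 * expect.max()

    def test_compartments_sum_to_tissue(self, blood):
        tc = kinetics.tissue_concentration(
            params(fv=0.05, K1=0.5, k2=0.3, k3=0.05, k4=0.01), blood, GRID)
        np.testing.assert_allclose(tc.ct, tc.c1 + tc.c2, atol=1e-10)

    def test_matches_ode_oracle(self, blood):
        p = params(fv=0.05, K1=0.5, k2=0.3, k3=0.05, k4=0.01)
        tc = kinetics.tissue_concentration(p, blood, GRID)
        oc = kinetics.ode_oracle(p, blood, GRID)
        rel = np.linalg.norm(tc.ct - oc.ct) / np.linalg.norm(oc.ct)
        assert rel < 1e-3

    def test_rejects_negative_time_grid(self, blood):
        with pytest.raises(ValueError, match="precedes time 0"):
            kinetics.tissue_concentration(params(), blood,
                                          np.array([-1.0, 0.0, 1.0]))

    def test_linear_in_k1(self, blood):
        p1 = params(K1=0.3, k2=0.4, k3=0.1, k4=0.02)
        p2 = params(K1=0.6, k2=0.4, k3=0.1, k4=0.02)
        c1 = kinetics.tissue_concentration(p1, blood, GRID).ct
        c2 = kinetics.tissue_concentration(p2, blood, GRID).ct
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_positivity(self, blood, rng):
        for _ in range(5):
            K1, k2, k3, k4 = rng.uniform(0.0, 1.5, 4)
            tc = kinetics.tissue_concentration(
                params(K1=K1, k2=k2, k3=k3, k4=k4), blood, GRID)
            assert tc.ct.min() >= -1e-12

    def test_irreversible_asymptotic_ratio(self, blood):
        # with k4=0 and fast, strongly trapping kinetics the non-trapped
        # distribution term is negligible by 60 min and
        # ct / int(Cp) -> K1 k3/(k2+k3)
        p = params(K1=0.5, k2=0.3, k3=0.3, k4=0.0)
        tc = kinetics.tissue_concentration(p, blood, GRID)
        i60 = np.searchsorted(GRID, 60.0)
        ratio = tc.ct[i60] / blood.cumulative_integral(np.array([60.0]))[0]
        ki = 0.5 * 0.3 / 0.6
        assert abs(ratio - ki) / ki < 0.05


class TestOdeOracle:
    def test_no_influx_stays_zero(self, blood):
        oc = kinetics.ode_oracle(params(K1=0.0, k2=0.3, k3=0.1, k4=0.05),
                                 blood, GRID)
        assert np.all(oc.c1 == 0) and np.all(oc.c2 == 0)

    def test_one_tissue_reduction(self, blood):
        # k3 = 0: C2 stays 0 and C1 solves the one-compartment model whose
        # closed form is K1 * C0 conv exp(-k2 t)
        p = params(K1=0.4, k2=0.3, k3=0.0, k4=0.0)
        oc = kinetics.ode_oracle(p, blood, GRID)
        assert np.max(np.abs(oc.c2)) == 0.0
        # closed form evaluated on the blood's own (finer) grid so both
        # sides integrate the identical piecewise-linear input
        g = kinetics.exp_conv(blood.times, blood.values,
                              np.array([0.3]))[:, 0]
        ref = 0.4 * np.interp(GRID, blood.times, g)
        assert np.max(np.abs(oc.c1 - ref)) < 1e-4 * ref.max()

    def test_cross_validates_analytic_solution(self, blood, rng):
        for _ in range(5):
            fv = 0.0
            K1, k2 = rng.uniform(0.05, 1.2, 2)
            k3 = rng.uniform(0.005, 0.4)
            k4 = rng.uniform(0.0, 0.15)
            p = params(fv, K1, k2, k3, k4)
            tc = kinetics.tissue_concentration(p, blood, GRID)
            oc = kinetics.ode_oracle(p, blood, GRID)
            rel = np.linalg.norm(tc.ct - oc.ct) / np.linalg.norm(oc.ct)
            assert rel < 1e-3

    def test_step_size_check(self, blood):
        p = params(K1=0.5, k2=0.3, k3=0.05, k4=0.01)
        with pytest.raises(RuntimeError, match="step size"):
            kinetics.ode_oracle(p, blood, GRID, step=2.0, check_step=True,
                                step_tol=1e-10)


class TestVoxelConcentration:
    def test_mixture_endpoints_and_midpoint(self, blood):
        tc = kinetics.tissue_concentration(
            params(K1=0.5, k2=0.3, k3=0.05), blood, GRID)
        v0 = kinetics.voxel_concentration(tc, blood, 0.0)
        np.testing.assert_array_equal(v0.cpet, tc.ct)
        v1 = kinetics.voxel_concentration(tc, blood, 1.0)
        np.testing.assert_allclose(v1.cpet, blood(GRID))
        # affine mixture: fv=0.25 of constants 4 (tissue) and 8 (blood)
        const = kinetics.TissueCurve(GRID, np.zeros_like(GRID),
                                     np.zeros_like(GRID),
                                     np.full_like(GRID, 4.0))
        b8 = BloodInput(blood.times, np.full_like(blood.values, 8.0))
        vm = kinetics.voxel_concentration(const, b8, 0.25)
        assert np.allclose(vm.cpet[GRID > 0], 5.0)

    def test_rejects_out_of_range_fraction(self, blood):
        tc = kinetics.tissue_concentration(params(), blood, GRID)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            kinetics.voxel_concentration(tc, blood, 1.5)


class TestFrameActivity:
    @staticmethod
    def _const_curve(value, grid=GRID):
        z = np.zeros_like(grid)
        return kinetics.TissueCurve(grid, z, z, np.full_like(grid, value))

    def test_constant_integrand(self):
        from petkin.types import FrameSchedule
        sched = FrameSchedule(np.array([0.0]), np.array([5.0]),
                              decay_lambda=0.0)
        ds = kinetics.frame_activity(self._const_curve(1.0), sched,
                                     mode="integral")
        assert ds.frames[0, 0, 0] == pytest.approx(5.0, abs=1e-10)

    def test_decay_weighted_constant(self):
        from petkin.types import FrameSchedule
        lam, c, ts, te = 0.00631, 3.0, 10.0, 15.0
        sched = FrameSchedule(np.array([ts]), np.array([te]),
                              decay_lambda=lam, decay_corrected_input=False)
        ds = kinetics.frame_activity(self._const_curve(c), sched,
                                     mode="integral")
        expect = c * (np.exp(-lam * ts) - np.exp(-lam * te)) / lam
        assert ds.frames[0, 0, 0] == pytest.approx(expect, rel=1e-5)

    def test_average_mode_divides_by_duration(self):
        from petkin.types import FrameSchedule
        sched = FrameSchedule(np.array([0.0]), np.array([5.0]),
                              decay_lambda=0.0)
        ds = kinetics.frame_activity(self._const_curve(7.0), sched,
                                     mode="average")
        assert ds.frames[0, 0, 0] == pytest.approx(7.0, abs=1e-10)

    def test_matches_fine_grid_riemann_oracle(self, blood, schedule):
        tc = kinetics.tissue_concentration(
            params(K1=0.5, k2=0.3, k3=0.05), blood, GRID)
        ds = kinetics.frame_activity(tc, schedule, mode="integral")
        for m in range(schedule.n_frames):
            fine = np.linspace(schedule.starts[m], schedule.ends[m], 4001)
            oracle = np.trapezoid(np.interp(fine, GRID, tc.ct), fine)
            assert ds.frames[m, 0, 0] == pytest.approx(oracle, rel=1e-5)

    def test_schedule_outside_grid(self, schedule):
        short = np.arange(0.0, 30.0, 0.05)
        tc = self._const_curve(1.0, grid=short)
        with pytest.raises(ValueError, match="outside the time grid"):
            kinetics.frame_activity(tc, schedule)


class TestSimulator:
    def test_identical_params_identical_tacs(self, blood, schedule):
        pm = np.tile(np.array([0.05, 0.5, 0.3, 0.05, 0.0])[:, None, None],
                     (1, 2, 2))
        ds = kinetics.simulate_dynamic_frames(pm, blood, schedule)
        for i in range(2):
            for j in range(2):
                np.testing.assert_array_equal(ds.frames[:, i, j],
                                              ds.frames[:, 0, 0])

    def test_dead_voxel_is_zero(self, blood, schedule):
        pm = np.tile(np.array([0.05, 0.5, 0.3, 0.05, 0.0])[:, None, None],
                     (1, 2, 2))
        pm[:, 0, 0] = 0.0  # K1 = 0, fv = 0
        ds = kinetics.simulate_dynamic_frames(pm, blood, schedule)
        assert np.all(ds.frames[:, 0, 0] == 0)
        assert np.all(ds.frames[:, 1, 1] > 0)

    def test_matches_scalar_chain(self, blood, schedule, rng):
        shape = (3, 3)
        pm = np.stack([
            rng.uniform(0.0, 0.3, shape), rng.uniform(0.05, 1.2, shape),
            rng.uniform(0.05, 1.2, shape), rng.uniform(0.005, 0.4, shape),
            rng.uniform(0.0, 0.15, shape)])
        ds = kinetics.simulate_dynamic_frames(pm, blood, schedule)
        for i in range(shape[0]):
            for j in range(shape[1]):
                p = KineticParams(*pm[:, i, j])
                tc = kinetics.tissue_concentration(p, blood, GRID)
                vc = kinetics.voxel_concentration(tc, blood, p.fv)
                fa = kinetics.frame_activity(vc, schedule)
                np.testing.assert_allclose(ds.frames[:, i, j],
                                           fa.frames[:, 0, 0], atol=1e-10)

    def test_rejects_invalid_maps(self, blood, schedule):
        pm = np.zeros((5, 2, 2))
        pm[1, 0, 1] = np.nan
        with pytest.raises(ValueError, match=r"non-finite.*\[0, 1\]"):
            kinetics.simulate_dynamic_frames(pm, blood, schedule)
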