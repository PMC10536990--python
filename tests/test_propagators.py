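"""Sub-step maps, flow composition, and oracle comparisons for MInt/SL/DE."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from mmstdyn import (
    PhaseSpacePoint,
    StepPlan,
    adiabatize,
    build_model,
    de_h2_halfstep,
    electronic_halfstep,
    mmst_energy,
    nuclear_halfstep_mint,
    potential,
    propagate,
    reference_propagate,
    sl_h2_halfstep,
    step_h1,
)
from mmstdyn.propagators import _ef_kernels

from conftest import random_state


def _frame(model, x):
    dm = potential(model, x)
    return dm, adiabatize(dm)


class TestH1:
    def test_zero_momentum_fixed_point(self, models, state):
        st0 = PhaseSpacePoint(state.x, 0.0, state.X, state.P)
        out = step_h1(st0, models[1], 0.7)
        assert out.x == st0.x

    def test_dt_zero_identity(self, models, state):
        out = step_h1(state, models[1], 0.0)
        np.testing.assert_array_equal(out.z, state.z)

    def test_halfstep_composition_exact(self, models, state):
        m = models[2]
        one = step_h1(state, m, 0.3)
        two = step_h1(step_h1(state, m, 0.15), m, 0.15)
        np.testing.assert_array_equal(one.z, two.z)

    def test_mapping_variables_untouched(self, models, state):
        out = step_h1(state, models[3], 0.5)
        np.testing.assert_array_equal(out.X, state.X)
        np.testing.assert_array_equal(out.P, state.P)
        np.testing.assert_array_equal(out.p, state.p)


class TestElectronicHalfstep:
    def test_zero_duration_identity(self, models, state):
        _, fr = _frame(models[1], state.x)
        out = electronic_halfstep(state, fr, 0.0)
        np.testing.assert_array_equal(out.z, state.z)

    def test_vt_zero_leaves_mapping_unchanged(self, state):
        m = build_model(alpha=0.0, delta=0.0, kappa=0.0)
        _, fr = _frame(m, state.x)
        out = electronic_halfstep(state, fr, 0.4)
        np.testing.assert_array_equal(out.X, state.X)
        np.testing.assert_array_equal(out.P, state.P)

    def test_matches_matrix_exponential_oracle(self, models, rng):
        # exact linear EOM: d/dt (X; P) = [[0, Vt], [-Vt, 0]] (X; P)
        m = models[3]
        for _ in range(5):
            st = random_state(rng)
            dm, fr = _frame(m, st.x)
            tau = 0.35
            A = np.block([[np.zeros((2, 2)), dm.Vt],
                          [-dm.Vt, np.zeros((2, 2))]])
            v = expm(A * tau) @ np.concatenate([st.X, st.P])
            out = electronic_halfstep(st, fr, tau)
            np.testing.assert_allclose(np.concatenate([out.X, out.P]), v,
                                       atol=1e-12)

    def test_preserves_electronic_probability(self, models, rng):
        m = models[1]
        st = random_state(rng)
        _, fr = _frame(m, st.x)
        out = electronic_halfstep(st, fr, 0.9)
        before = np.sum(st.X**2 + st.P**2)
        after = np.sum(out.X**2 + out.P**2)
        assert abs(after - before) < 1e-12


def _mint_kick_quadrature(model, st, tau):
    """Numerical-quadrature oracle for the MInt momentum integral."""
    dm, fr = _frame(model, st.x)
    Xb = fr.S.T @ st.X
    Pb = fr.S.T @ st.P

    def integrand(t):
        c, s = np.cos(fr.Lam * t), np.sin(fr.Lam * t)
        Xt = c * Xb + s * Pb
        Pt = -s * Xb + c * Pb
        return dm.dU + 0.5 * (Xt @ fr.G @ Xt + Pt @ fr.G @ Pt)

    val, err = quad(integrand, 0.0, tau, epsabs=1e-13, epsrel=1e-13)
    return st.p - val


class TestMIntHalfstep:
    def test_zero_force_leaves_p(self):
        # constant Vt (kappa = 0) at the minimum of U: no force at all
        m = build_model(alpha=0.3, delta=2.0, kappa=0.0)
        st = PhaseSpacePoint(x=0.0, p=1.1, X=[0.4, -0.2], P=[0.3, 0.9])
        dm, fr = _frame(m, st.x)
        assert nuclear_halfstep_mint(st, fr, dm, 0.5) == pytest.approx(st.p,
                                                                      abs=0)

    @pytest.mark.parametrize("preset", [1, 2, 3])
    def test_matches_quadrature_oracle(self, models, preset, rng):
        m = models[preset]
        for _ in range(5):
            st = random_state(rng)
            dm, fr = _frame(m, st.x)
            pn = nuclear_halfstep_mint(st, fr, dm, 0.05)
            assert abs(pn - _mint_kick_quadrature(m, st, 0.05)) < 1e-10

    def test_degenerate_gap_series_limit(self, rng):
        # lam_nm*tau far below the series cutoff: kernels from the Taylor
        # branch must still match direct quadrature of the momentum integral
        m = build_model(alpha=0.0, delta=1e-8, kappa=1e-8)
        st = random_state(rng)
        dm, fr = _frame(m, st.x)
        assert abs(fr.lamdiff).max() * 0.05 < 1e-6
        pn = nuclear_halfstep_mint(st, fr, dm, 0.05)
        assert abs(pn - _mint_kick_quadrature(m, st, 0.05)) < 1e-10

    def test_ef_kernel_symmetries(self, models):
        dm, fr = _frame(models[2], 0.7)
        E, F, _, _ = _ef_kernels(fr.lamdiff, 0.05)
        np.testing.assert_allclose(E, E.T, atol=0)
        np.testing.assert_allclose(F, -F.T, atol=0)
        assert F[0, 0] == 0.0 and F[1, 1] == 0.0


class TestSLHalfstep:
    def test_force_free_limit_equals_mint(self, rng):
        # kappa = 0 and x at the U minimum: p untouched, mapping rotates
        m = build_model(alpha=0.5, delta=1.5, kappa=0.0)
        st = random_state(rng)
        st = PhaseSpacePoint(0.0, st.p, st.X, st.P)
        dm, fr = _frame(m, st.x)
        out = sl_h2_halfstep(st, fr, dm, 0.3, "a")
        assert out.p == pytest.approx(float(st.p), abs=1e-15)
        pm = nuclear_halfstep_mint(st, fr, dm, 0.3)
        assert pm == pytest.approx(float(st.p), abs=1e-15)
        rot = electronic_halfstep(st, fr, 0.3)
        np.testing.assert_allclose(out.X, rot.X, atol=1e-15)

    def test_sl_approaches_mint_at_third_order(self, models, rng):
        # one full step: |SL - MInt| ~ O(dt^3), so halving dt gains ~8x
        m = models[2]
        st = random_state(rng)
        diffs = []
        for dt in (0.2, 0.1, 0.05):
            sl = propagate(st, m, StepPlan("sl", dt), 1).states[-1]
            mi = propagate(st, m, StepPlan("mint", dt), 1).states[-1]
            diffs.append(np.linalg.norm(sl.z - mi.z))
        ratios = np.array(diffs[:-1]) / np.array(diffs[1:])
        assert np.all(ratios > 5.5) and np.all(ratios < 10.5)

    def test_symmetric_composition_reversible(self, models, rng):
        m = models[3]
        st = random_state(rng)
        plan = StepPlan("sl", 0.1)
        fwd = propagate(st, m, plan, 50).states[-1]
        back = propagate(fwd, m, plan.reversed(), 50).states[-1]
        assert np.abs(back.z - st.z).max() < 1e-11

    def test_invalid_variant(self, models, state):
        dm, fr = _frame(models[1], state.x)
        with pytest.raises(ValueError):
            sl_h2_halfstep(state, fr, dm, 0.1, "c")


class TestDEHalfstep:
    def test_degenerate_vt_all_algorithms_identical(self, rng):
        m = build_model(alpha=0.0, delta=0.0, kappa=0.0)
        st = random_state(rng)
        outs = [propagate(st, m, StepPlan(a, 0.1), 20).states[-1].z
                for a in ("mint", "sl", "de")]
        np.testing.assert_array_equal(outs[0], outs[1])
        np.testing.assert_array_equal(outs[0], outs[2])

    def test_zero_derivative_leaves_p(self):
        m = build_model(alpha=0.3, delta=2.0, kappa=0.0)
        st = PhaseSpacePoint(x=0.0, p=0.4, X=[1.0, 0.1], P=[0.2, 0.5])
        dm, fr = _frame(m, st.x)
        out = de_h2_halfstep(st, fr, dm, 0.3)
        assert out.p == pytest.approx(0.4, abs=1e-15)

    def test_de_less_accurate_than_mint(self, models, rng):
        m = models[2]
        st = random_state(rng)
        T = 100 * 0.1
        ref = reference_propagate(st, m, T, 1e-12)
        de = propagate(st, m, StepPlan("de", 0.1), 100).states[-1]
        mi = propagate(st, m, StepPlan("mint", 0.1), 100).states[-1]
        err_de = np.linalg.norm(de.z - ref.z)
        err_mi = np.linalg.norm(mi.z - ref.z)
        assert err_de > err_mi


class TestPropagate:
    def test_zero_steps_returns_initial(self, models, state):
        traj = propagate(state, models[1], StepPlan("mint", 0.1), 0)
        assert len(traj) == 1
        np.testing.assert_array_equal(traj.states[0].z, state.z)

    def test_mint_forward_backward_reversible(self, models, rng):
        m = models[1]
        st = random_state(rng)
        plan = StepPlan("mint", 0.1)
        fwd = propagate(st, m, plan, 100).states[-1]
        back = propagate(fwd, m, plan.reversed(), 100).states[-1]
        assert np.abs(back.z - st.z).max() < 1e-11

    @pytest.mark.parametrize("alg", ["mint", "sl"])
    def test_global_error_second_order(self, models, alg, rng):
        m = models[3]
        st = random_state(rng)
        T = 5.0
        ref = reference_propagate(st, m, T, 1e-12)
        dts = np.array([0.1, 0.05, 0.025])
        errs = [np.linalg.norm(
            propagate(st, m, StepPlan(alg, dt), int(round(T / dt)))
            .states[-1].z - ref.z) for dt in dts]
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_deterministic_bit_identical(self, models, state):
        m = models[2]
        plan = StepPlan("sl", 0.1)
        z1 = propagate(state, m, plan, 50).states[-1].z
        z2 = propagate(state, m, plan, 50).states[-1].z
        np.testing.assert_array_equal(z1, z2)

    @pytest.mark.parametrize("alg", ["mint", "sl", "de"])
    def test_electronic_probability_conserved(self, models, alg, rng):
        m = models[2]
        st = random_state(rng)
        traj = propagate(st, m, StepPlan(alg, 0.1), 2000)
        probs = [np.sum(s.X**2 + s.P**2) / 2 for s in traj.states]
        assert np.abs(np.asarray(probs) - probs[0]).max() < 1e-10

    def test_h1_outer_order_close_to_default(self, models, rng):
        # swapping the sandwich order changes results only at O(dt^2)
        m = models[1]
        st = random_state(rng)
        a = propagate(st, m, StepPlan("mint", 0.05), 40).states[-1]
        b = propagate(st, m,
                      StepPlan("mint", 0.05, sandwich_order="h1h2h1"),
                      40).states[-1]
        assert np.abs(a.z - b.z).max() < 0.05 * 0.05

    def test_batched_matches_scalar(self, models, rng):
        m = models[2]
        singles = [random_state(rng) for _ in range(4)]
        batch = PhaseSpacePoint(
            x=np.array([s.x for s in singles]),
            p=np.array([s.p for s in singles]),
            X=np.stack([s.X for s in singles]),
            P=np.stack([s.P for s in singles]))
        plan = StepPlan("de", 0.1)
        zb = propagate(batch, m, plan, 30).states[-1].z
        for i, s in enumerate(singles):
            zi = propagate(s, m, plan, 30).states[-1].z
            np.testing.assert_array_equal(zb[i], zi)

    def test_nonfinite_initial_state_aborts(self, models):
        bad = PhaseSpacePoint(x=np.nan, p=0.0, X=[0, 0], P=[0, 0])
        with pytest.raises(FloatingPointError):
            propagate(bad, models[1], StepPlan("mint", 0.1), 1)


class TestReferenceOracle:
    def test_identity_at_t_zero(self, models, state):
        out = reference_propagate(state, models[1], 0.0)
        np.testing.assert_array_equal(out.z, state.z)

    def test_conserves_energy_and_probability(self, models, rng):
        m = models[3]
        st = random_state(rng)
        tol = 1e-12
        out = reference_propagate(st, m, 8.0, tol)
        e0, e1 = mmst_energy(m, st), mmst_energy(m, out)
        assert abs(e1 - e0) < 1e-9
        pr0 = np.sum(st.X**2 + st.P**2) / 2
        pr1 = np.sum(out.X**2 + out.P**2) / 2
        assert abs(pr1 - pr0) < 1e-9

    def test_rejects_loose_tolerance(self, models, state):
        with pytest.raises(ValueError):
            reference_propagate(state, models[1], 1.0, 1e-6)
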