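"""Forward-model tests: elementary forces, integration, trajectory
extraction and the oscillation filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from sixmm.model import (
    CM,
    MM,
    PhysicalConfig,
    RestPositionGrid,
    ScalingVector,
    SimState,
    SimulationUnstableError,
    TrajectorySet,
    anchor_force_lateral,
    collision_force,
    coupling_lateral_force,
    driving_force,
    extract_trajectories,
    is_oscillating,
    rk4_step,
    simulate,
    simulate_batch,
    spring_force,
    total_acceleration,
    trajectory_std,
)
from sixmm.model import _effective_params, _params_of, _smooth_sign

CFG = PhysicalConfig()


# ---------------------------------------------------------------------------
# Elementary forces
# ---------------------------------------------------------------------------

class TestSpringForce:
    @pytest.mark.parametrize(
        "s, v, k, r, ell, expected",
        [
            # at free length with no velocity the force vanishes
            ((0.7, 0, 0), (0, 0, 0), 3.0, 0.5, 0.7, (0, 0, 0)),
            # doubled free length, pure elastic: -k*(2l-l) along the axis
            ((2.0, 0, 0), (0, 0, 0), 1.0, 0.0, 1.0, (-1.0, 0, 0)),
            # at free length, radial velocity v: pure damping -r*v
            ((1.0, 0, 0), (0.3, 0, 0), 5.0, 2.0, 1.0, (-0.6, 0, 0)),
        ],
    )
    def test_point_examples(self, s, v, k, r, ell, expected):
        np.testing.assert_allclose(
            spring_force(np.array(s), np.array(v), k, r, ell), expected, atol=1e-12
        )

    @given(
        s=st.tuples(*[st.floats(-2, 2) for _ in range(3)]).filter(
            lambda t: np.linalg.norm(t) > 1e-3
        ),
        v=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        k=st.floats(0.1, 100),
        r=st.floats(0, 10),
        ell=st.floats(0, 2),
    )
    @settings(deadline=None, max_examples=80)
    def test_antisymmetry(self, s, v, k, r, ell):
        s, v = np.array(s), np.array(v)
        f1 = spring_force(s, v, k, r, ell)
        f2 = spring_force(-s, -v, k, r, ell)
        np.testing.assert_allclose(f1, -f2, rtol=1e-10, atol=1e-12)

    @given(k=st.floats(0.1, 100), r=st.floats(0, 10), ell=st.floats(0.01, 2))
    @settings(deadline=None, max_examples=40)
    def test_free_length_nullity(self, k, r, ell):
        direction = np.array([0.6, 0.8, 0.0])
        f = spring_force(direction * ell, np.zeros(3), k, r, ell)
        np.testing.assert_allclose(f, 0, atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            spring_force(np.array([np.nan, 0, 0]), np.zeros(3), 1, 0, 0)


class TestAnchorForce:
    def test_zero_at_rest(self):
        assert anchor_force_lateral(0.5, 0.0, 0.5, 10.0, 1.0, 100.0) == 0

    def test_linear_limit(self):
        f = anchor_force_lateral(0.7, 0.0, 0.5, 10.0, 0.0, 0.0)
        assert f == pytest.approx(-10.0 * 0.2)

    def test_cubic_hand_value(self):
        # -k*dx*(1 + eta*dx^2) = -1*0.1*(1 + 100*0.01) = -0.2
        f = anchor_force_lateral(0.1, 0.0, 0.0, 1.0, 0.0, 100.0)
        assert f == pytest.approx(-0.2)


class TestCouplingForce:
    def test_zero_at_origin(self):
        assert coupling_lateral_force(0.0, 2.0, 3.0) == 0

    def test_345_triangle_magnitude(self):
        # k=2, ell=3, dx=4: magnitude 2*(5-3) = 4, restoring direction
        f = coupling_lateral_force(4.0, 2.0, 3.0, eps=1e-6)
        assert f == pytest.approx(-4.0, rel=1e-6)

    def test_asymptotic_linear(self):
        ell = 0.01
        f = coupling_lateral_force(100 * ell, 1.0, ell, eps=1e-6)
        assert abs(f) == pytest.approx(1.0 * (100 * ell - ell), rel=0.01)

    @given(dx=st.floats(-0.01, 0.01), k=st.floats(0.1, 50), ell=st.floats(0, 0.01))
    @settings(deadline=None, max_examples=60)
    def test_odd_and_restoring(self, dx, k, ell):
        f = coupling_lateral_force(dx, k, ell)
        f_neg = coupling_lateral_force(-dx, k, ell)
        assert f == pytest.approx(-f_neg, abs=1e-15)
        assert f * dx <= 0  # always restores toward zero


class TestCollisionForce:
    def _state(self, x):
        return SimState(x=np.asarray(x, float), v=np.zeros((2, 3, 2)))

    def test_open_glottis_zero(self):
        x = np.zeros((2, 3, 2))
        x[0] = -1e-3
        x[1] = 1e-3
        p = _params_of(ScalingVector.identity(), np.zeros(6), CFG)
        f = collision_force(self._state(x), p)
        np.testing.assert_array_equal(f, 0)

    def test_symmetric_overlap_antisymmetric(self):
        d = 0.1 * MM
        x = np.zeros((2, 3, 2))
        x[0, 0, 0] = d  # left posterior lower crosses the midline
        x[1, 0, 0] = -d
        p = _params_of(ScalingVector.identity(), np.zeros(6), CFG)
        f = collision_force(self._state(x), p)
        # only that pair is loaded, with equal magnitude and opposite sign
        k_c = 3.0 * CFG.default_xi_c * CFG.default_k_a_bottom
        expected = k_c * (2 * d) / 2
        assert f[0, 0, 0] == pytest.approx(-expected)
        assert f[1, 0, 0] == pytest.approx(expected)
        f[0, 0, 0] = f[1, 0, 0] = 0
        np.testing.assert_array_equal(f, 0)

    def test_continuous_at_contact(self):
        p = _params_of(ScalingVector.identity(), np.zeros(6), CFG)
        for pen in (1e-9, 1e-12):
            x = np.zeros((2, 3, 2))
            x[0, :, :] = pen / 2
            x[1, :, :] = -pen / 2
            f = collision_force(self._state(x), p)
            assert np.abs(f).max() <= 3 * CFG.default_k_a_bottom * pen


class TestDrivingForce:
    def _open_state(self):
        x = np.zeros((2, 3, 2))
        x[0, :, 0], x[1, :, 0] = -1.0 * MM, 1.0 * MM  # wide lower gap
        x[0, :, 1], x[1, :, 1] = -0.5 * MM, 0.5 * MM  # narrower upper gap
        return SimState(x=x, v=np.zeros_like(x))

    def test_zero_pressure(self):
        f = driving_force(self._open_state(), 0.0, CFG)
        np.testing.assert_array_equal(f, 0)

    def test_linear_in_pressure(self):
        f1 = driving_force(self._open_state(), 800.0, CFG)
        f2 = driving_force(self._open_state(), 1600.0, CFG)
        np.testing.assert_allclose(f2, 2 * f1)

    def test_outward_on_lower_open_columns(self):
        f = driving_force(self._open_state(), 800.0, CFG)
        assert np.all(f[0, :, 0] < 0) and np.all(f[1, :, 0] > 0)
        np.testing.assert_array_equal(f[:, :, 1], 0)  # nothing above the minimum

    def test_closed_column_zero_everywhere(self):
        x = np.zeros((2, 3, 2))
        x[0, :, 0], x[1, :, 0] = 0.1 * MM, -0.1 * MM  # lower masses in contact
        x[0, :, 1], x[1, :, 1] = -0.5 * MM, 0.5 * MM
        f = driving_force(SimState(x=x, v=np.zeros_like(x)), 800.0, CFG)
        np.testing.assert_array_equal(f[:, :, 1], 0)

    def test_divergent_column_carries_no_pressure(self):
        # jet separation at the narrow lower entry: no pressure recovery
        x = np.zeros((2, 3, 2))
        x[0, :, 0], x[1, :, 0] = -0.2 * MM, 0.2 * MM
        x[0, :, 1], x[1, :, 1] = -1.0 * MM, 1.0 * MM
        f = driving_force(SimState(x=x, v=np.zeros_like(x)), 800.0, CFG)
        np.testing.assert_array_equal(f, 0)


# ---------------------------------------------------------------------------
# Acceleration assembly
# ---------------------------------------------------------------------------

class TestTotalAcceleration:
    def test_equilibrium_is_exact_with_matched_geometry(self):
        # all rest positions equal to the anchor ends and no pressure:
        # every spring sits at its free configuration
        cfg = PhysicalConfig(
            anchor_lateral_posterior=0.0, initial_lower_deflection=1.0
        )
        rest = np.zeros(6)
        q = ScalingVector.identity().to_array().copy()
        q[12] = 1e-12  # no driving
        x = np.zeros((2, 3, 2))
        state = SimState(x=x, v=np.zeros_like(x))
        a = total_acceleration(state, q, rest, cfg)
        np.testing.assert_allclose(a, 0, atol=1e-9)

    def test_inv_mass_scaling_doubles_acceleration(self):
        rest = np.array([-0.3, -0.3, -0.3, 0.3, 0.3, 0.3])
        x = np.zeros((2, 3, 2))
        x[0], x[1] = -1.0 * MM, 1.0 * MM
        state = SimState(x=x, v=np.zeros_like(x))
        q1 = ScalingVector.identity().to_array()
        q2 = q1.copy()
        q2[0] = 2.0  # left posterior pair: half the mass
        a1 = total_acceleration(state, q1, rest, CFG)
        a2 = total_acceleration(state, q2, rest, CFG)
        np.testing.assert_allclose(a2[0, 0, :], 2 * a1[0, 0, :], rtol=1e-12)
        np.testing.assert_allclose(a2[1], a1[1], rtol=1e-12)

    def test_reports_non_finite_forces(self):
        rest = np.zeros(6)
        x = np.full((2, 3, 2), np.nan)
        state = SimState.__new__(SimState)
        state.x, state.v, state.t = x, np.zeros_like(x), 0.0
        with pytest.raises(SimulationUnstableError):
            total_acceleration(state, ScalingVector.identity(), rest, CFG)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

class TestRK4:
    def test_zero_force_linear_drift(self):
        x = np.linspace(-1, 1, 12).reshape(2, 3, 2)
        v = np.linspace(1, 2, 12).reshape(2, 3, 2)
        out = rk4_step(SimState(x, v), 0.5, lambda X, V: np.zeros_like(X))
        np.testing.assert_allclose(out.x, x + 0.5 * v, rtol=1e-15)
        np.testing.assert_array_equal(out.v, v)

    def test_harmonic_oscillator_energy_drift(self):
        # unit mass and stiffness; 1e4 steps at dt = period/100.  RK4's
        # dissipative O(h^4) energy error accumulates to ~8.5e-6 relative
        # over these 100 periods (verified against the closed form), so
        # the bound is one order above that.
        dt = 2 * np.pi / 100
        x = np.zeros((2, 3, 2))
        x[0, 0, 0] = 1.0
        state = SimState(x, np.zeros_like(x))
        for _ in range(10_000):
            state = rk4_step(state, dt, lambda X, V: -X)
        energy = 0.5 * (state.x[0, 0, 0] ** 2 + state.v[0, 0, 0] ** 2)
        assert abs(energy - 0.5) / 0.5 < 1e-5
        # and the trajectory still matches the closed form to phase level
        assert state.x[0, 0, 0] == pytest.approx(np.cos(10_000 * dt), abs=1e-3)

    def test_richardson_convergence_order(self):
        def endpoint(dt, n):
            x = np.zeros((2, 3, 2))
            x[0, 0, 0] = 1.0
            s = SimState(x, np.zeros_like(x))
            for _ in range(n):
                s = rk4_step(s, dt, lambda X, V: -X)
            return s.x[0, 0, 0]

        exact = np.cos(1.0)
        e1 = abs(endpoint(0.01, 100) - exact)
        e2 = abs(endpoint(0.005, 200) - exact)
        assert e1 / e2 == pytest.approx(16, rel=0.2)

    def test_rejects_non_positive_dt(self):
        s = SimState(np.zeros((2, 3, 2)), np.zeros((2, 3, 2)))
        with pytest.raises(ValueError):
            rk4_step(s, 0.0, lambda X, V: X)


class TestSimulate:
    def test_duration_is_250_ms(self):
        assert CFG.n_steps * CFG.dt == pytest.approx(250.0)

    def test_default_q_oscillates(self, rng):
        from sixmm.sampling import CopulaSpec, DEFAULT_MARGINALS, sample_rest_positions

        rest = sample_rest_positions(DEFAULT_MARGINALS, CopulaSpec(), 3, rng)
        for r in rest:
            T = extract_trajectories(simulate(ScalingVector.identity(), r, CFG), CFG)
            assert is_oscillating(T)

    def test_vanishing_pressure_decays(self, rng):
        from sixmm.sampling import CopulaSpec, DEFAULT_MARGINALS, sample_rest_positions

        rest = sample_rest_positions(DEFAULT_MARGINALS, CopulaSpec(), 1, rng)[0]
        q = ScalingVector.identity().to_array().copy()
        q[12] = 1e-9
        T = extract_trajectories(simulate(q, rest, CFG), CFG)
        first = T.values[:, :200].std(axis=1)
        last = T.values[:, -200:].std(axis=1)
        assert np.all(last < first)

    def test_determinism_bit_identical(self):
        rest = np.array([-0.4, -0.3, -0.2, 0.4, 0.3, 0.2])
        h1 = simulate(ScalingVector.identity(), rest, CFG)
        h2 = simulate(ScalingVector.identity(), rest, CFG)
        np.testing.assert_array_equal(h1, h2)

    def test_mirror_symmetry(self):
        rest = np.array([-0.42, -0.33, -0.21, 0.38, 0.29, 0.24])
        q = np.array([1.2, 0.8, 1.5, 0.6, 1.1, 0.9,
                      1.3, 0.7, 1.4, 0.5, 1.0, 2.0, 1.5, 0.8])
        h = simulate(q, rest, CFG)
        # swap sides in parameters and rest positions
        q_m = q.copy()
        q_m[:6] = np.concatenate([q[3:6], q[:3]])
        q_m[6:12] = np.concatenate([q[9:12], q[6:9]])
        rest_m = -np.concatenate([rest[3:], rest[:3]])
        h_m = simulate(q_m, rest_m, CFG)
        np.testing.assert_allclose(h_m[:, ::-1, :, :], -h, atol=1e-15)

    def test_coupled_system_convergence_order(self):
        # smooth, collision-free setting: wide rest gap, no pressure, and
        # gentle coupling-direction smoothing so the force field is
        # resolved by the step sizes tested
        rest = np.array([-2.0, -2.0, -2.0, 2.0, 2.0, 2.0])
        q = ScalingVector.identity().to_array().copy()
        q[12] = 1e-12

        def endpoint(refine):
            # state at the common physical time 16 * 0.25 ms = 4 ms
            cfg = PhysicalConfig(
                dt=CFG.dt / refine, n_steps=16 * refine + 1, sign_smoothing_eps=1.0
            )
            return simulate(q, rest, cfg)[16 * refine]

        ref = endpoint(16)
        e1 = np.abs(endpoint(1) - ref).max()
        e2 = np.abs(endpoint(2) - ref).max()
        order = np.log2(e1 / e2)
        assert order >= 3.5

    def test_energy_conservation_and_dissipation(self):
        # undamped, undriven, collision-free: energy constant to < 1e-4
        rest = np.array([-2.0, -2.0, -2.0, 2.0, 2.0, 2.0])
        q = ScalingVector.identity().to_array().copy()
        q[12] = 1e-15

        def total_energy(cfg, history, velocity_history):
            p = _effective_params(q[None], rest[None], cfg)
            kin = 0.5 * (p.m[0] * velocity_history**2).sum(axis=(1, 2, 3))
            eta = cfg.eta_si
            k_a = p.k_a[0]
            dx = history - p.x_rest[0][..., None]
            v_anchor = (0.5 * k_a * dx**2 + 0.25 * k_a * eta * dx**4).sum(
                axis=(1, 2, 3)
            )
            eps = cfg.sign_smoothing_eps * MM

            def vpot(dxs, k, ell):
                # numeric potential of the coupling force on a grid
                grid = np.linspace(0, np.abs(dxs).max() + 1e-6, 4001)
                mag = np.sqrt(grid**2 + ell**2) - ell
                integrand = mag * np.tanh(grid / (2 * eps))
                cum = np.concatenate(
                    [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2 * np.diff(grid))]
                )
                return k * np.interp(np.abs(dxs), grid, cum)

            dxv = history[..., 1] - history[..., 0]
            v_vert = vpot(dxv, cfg.k_v, cfg.ell_v * CM).sum(axis=(1, 2))
            ends = cfg.anchor_end_positions()
            n_t = history.shape[0]
            xe = np.concatenate(
                [
                    np.broadcast_to(ends[None, :, 0, None, None], (n_t, 2, 1, 2)),
                    history,
                    np.broadcast_to(ends[None, :, 1, None, None], (n_t, 2, 1, 2)),
                ],
                axis=2,
            )
            ka = p.k_a[0]
            k_seg = np.stack(
                [2 * ka[:, 0], ka[:, 0] + ka[:, 1], ka[:, 1] + ka[:, 2], 2 * ka[:, 2]],
                axis=1,
            ) * cfg.xi_l
            dxl = xe[:, :, 1:, :] - xe[:, :, :-1, :]
            v_long = np.zeros(history.shape[0])
            for s in range(2):
                for seg in range(4):
                    for vert in range(2):
                        v_long += vpot(
                            dxl[:, s, seg, vert], k_seg[s, seg, vert], cfg.ell_l * CM
                        )
            return kin + v_anchor + v_vert + v_long

        def run(cfg):
            p = _effective_params(q[None], rest[None], cfg)
            from sixmm.model import _acceleration, _initial_state

            state = _initial_state(p, (1,))
            xs, vs = [state.x[0].copy()], [state.v[0].copy()]
            x, v = state.x, state.v
            for _ in range(cfg.n_steps):
                nxt = rk4_step(
                    SimState(x, v), cfg.dt_s, lambda X, V: _acceleration(X, V, p)
                )
                x, v = nxt.x, nxt.v
                xs.append(x[0].copy())
                vs.append(v[0].copy())
            return total_energy(cfg, np.array(xs), np.array(vs))

        # undamped: the forces are exactly conservative, so the drift is
        # pure integrator error and vanishes at fourth order; at the
        # operating step the stiffest mode has omega*dt ~ 0.3 and RK4's
        # dissipative error dominates, so the tight bound is checked at a
        # refined step
        E_coarse = run(PhysicalConfig(r_a=0.0, n_steps=200))  # dt 0.25, 50 ms
        drift_coarse = np.abs(E_coarse - E_coarse[0]).max() / E_coarse[0]
        assert drift_coarse < 1e-2
        E_fine = run(PhysicalConfig(r_a=0.0, dt=0.0025, n_steps=2000))  # 5 ms
        drift_fine = np.abs(E_fine - E_fine[0]).max() / E_fine[0]
        assert drift_fine < 1e-6
        # damped: energy decreases monotonically at the refined step
        E_damped = run(PhysicalConfig(r_a=CFG.r_a, dt=0.0025, n_steps=2000))
        assert E_damped[-1] < E_damped[0]
        assert np.all(np.diff(E_damped) < E_damped[0] * 1e-7)


class TestTrajectories:
    def test_minimal_member_and_tiebreak(self):
        h = np.zeros((2, 2, 3, 2))
        h[:, 0, 0, 0] = -2.0 * MM  # lower
        h[:, 0, 0, 1] = -3.0 * MM  # upper
        T = extract_trajectories(h, CFG)
        assert T.values[0, 0] == pytest.approx(-2.0)
        # straddling pair: +0.5 is closer than -1
        h[:, 0, 1, 0] = -1.0 * MM
        h[:, 0, 1, 1] = 0.5 * MM
        T = extract_trajectories(h, CFG)
        assert T.values[1, 0] == pytest.approx(0.5)
        # exact tie goes to the lower mass
        h[:, 0, 2, 0] = -0.7 * MM
        h[:, 0, 2, 1] = 0.7 * MM
        T = extract_trajectories(h, CFG)
        assert T.values[2, 0] == pytest.approx(-0.7)

    def test_row_ordering_stable(self):
        h = np.arange(2 * 2 * 3 * 2, dtype=float).reshape(2, 2, 3, 2) * MM
        T1 = extract_trajectories(h, CFG)
        T2 = extract_trajectories(h, CFG)
        np.testing.assert_array_equal(T1.values, T2.values)
        assert T1.labels[0] == ("left", "posterior")
        assert T1.labels[5] == ("right", "anterior")

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            extract_trajectories(np.empty((0, 2, 3, 2)), CFG)


class TestOscillationFilter:
    def test_constant_false(self):
        T = TrajectorySet(np.full((6, 1000), 0.3), dt=0.25)
        assert not is_oscillating(T)

    def test_sinusoid_true(self):
        t = np.arange(1000) * 0.25e-3
        T = TrajectorySet(
            np.tile(np.sin(2 * np.pi * 150 * t), (6, 1)), dt=0.25
        )
        assert is_oscillating(T)

    def test_boundary_inclusive(self):
        vals = np.zeros((6, 1000))
        # build rows whose post-transient std (cm) is exactly the threshold
        target = 1e-3  # cm
        vals[:, 300::2] = 0.0
        vals[:, 301::2] = 2 * target * 10  # mm amplitude for std = target cm
        T = TrajectorySet(vals, dt=0.25)
        stds = trajectory_std(T.values, T.dt)
        assert is_oscillating(T, threshold=float(stds.mean()))

    def test_min_aggregation_stricter(self):
        vals = np.zeros((6, 1000))
        vals[0, 300:] = np.sin(np.arange(700))
        T = TrajectorySet(vals, dt=0.25)
        assert is_oscillating(T, agg="mean")
        assert not is_oscillating(T, agg="min")


class TestValidation:
    def test_scaling_vector_positivity(self):
        with pytest.raises(ValueError):
            ScalingVector.from_array(np.zeros(14))

    def test_rest_grid_sign_convention(self):
        with pytest.raises(ValueError):
            RestPositionGrid(np.array([0.5, -0.3, -0.2, 0.4, 0.3, 0.2]))
        # small midline crossings within the documented tolerance pass
        RestPositionGrid(np.array([0.1, -0.3, -0.2, 0.4, 0.3, 0.2]))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            PhysicalConfig(dt=-1.0)
        with pytest.raises(ValueError):
            PhysicalConfig(vf_length=3.0)  # must equal 4 * ell_l

    def test_identity_reproduces_defaults(self):
        q = ScalingVector.identity()
        p = _params_of(q, np.zeros(6), CFG)
        assert p.m[0, 0, 0] == pytest.approx(CFG.default_mass_bottom * 1e-3)
        assert p.k_a[0, 0, 1] == pytest.approx(CFG.default_k_a_top)
        assert p.P_S == pytest.approx(CFG.default_P_S)
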