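import numpy as np
import pytest

from ablaheat import fem, make_oracle_fixture
from ablaheat.electric import solve_terminal
from ablaheat.materials import BODY_TEMP_K
from ablaheat.runner import SimulationConfig, SimulationContext
from ablaheat.thermal import BoundarySet, ThermalProblem, ThermalState


@pytest.fixture(scope="module")
def protected_context():
    return SimulationContext(
        SimulationConfig(study=2, protected=True, power=30.0, T_water=5.0, target_elements=1500)
    )


def make_problem(ctx, T_water=None):
    return ThermalProblem(ctx.space, boundaries=BoundarySet(T_water=T_water))


class TestSlabOracle:
    def test_transient_matches_fourier_series(self):
        """1D slab with clamped faces follows the plane-wall series solution."""
        fx = make_oracle_fixture("slab_1d")
        space = fem.build_space(fx["mesh"])
        problem = ThermalProblem(
            space,
            extra_dirichlet=(fx["face_nodes"], np.full(len(fx["face_nodes"]), BODY_TEMP_K)),
        )
        T0 = np.full(fx["mesh"].n_nodes, BODY_TEMP_K + 1.0)
        T0[fx["face_nodes"]] = BODY_TEMP_K
        state = ThermalState(T=T0, time=0.0)
        dt = 0.05
        for _ in range(100):
            state = problem.step(state, None, dt)
        z = fx["mesh"].nodes[:, 1]
        ref = fx["reference"](z, 5.0)
        interior = (z > 0.1 * fx["length"]) & (z < 0.9 * fx["length"])
        err = np.abs((state.T - BODY_TEMP_K) - ref)[interior].max()
        assert err < 0.01  # 1% of the 1 K initial amplitude


class TestStepProperties:
    def test_uniform_body_temperature_is_steady(self, coarse_context):
        problem = make_problem(coarse_context)
        state = problem.initial_state(False)
        new = problem.step(state, None, 0.5)
        np.testing.assert_allclose(new.T, state.T, atol=1e-9)

    def test_discrete_max_principle_source_free(self, coarse_context):
        rng = np.random.default_rng(42)
        problem = make_problem(coarse_context)
        T = rng.uniform(305.0, 315.0, coarse_context.mesh.n_nodes)
        state = ThermalState(T=T, time=0.0)
        for _ in range(5):
            state = problem.step(state, None, 0.2)
            assert state.T.min() >= 305.0 - 0.1
            assert state.T.max() <= 315.0 + 0.1

    def test_discrete_energy_balance_is_exact(self, coarse_context, body_T):
        """Enthalpy change per implicit step equals boundary + source terms."""
        ctx = coarse_context
        problem = make_problem(ctx)
        sol = solve_terminal(ctx.space, ctx.sigma_complex(body_T, 500e3), ctx.terminal_nodes, ctx.ground_nodes, 30.0)
        state = problem.initial_state(False)
        dt = 0.1
        new = problem.step(state, sol.Q_rh, dt)
        k_e, rhocp_e = problem.element_properties(state.T)
        K = fem.assemble_stiffness(ctx.space, k_e, problem.active)
        M = fem.lumped_mass(ctx.space, rhocp_e, problem.active)
        F = fem.element_load(ctx.space, sol.Q_rh, problem.active)
        lhs = M * (new.T - state.T) / dt
        rhs = -K @ new.T - problem._robin_diag * new.T + problem._robin_rhs + F
        free = np.setdiff1d(np.arange(ctx.mesh.n_nodes), problem.fixed_nodes)
        scale = np.abs(F[free]).sum() + 1.0
        assert np.abs(lhs[free] - rhs[free]).sum() / scale < 1e-8

    def test_nonpositive_dt_rejected(self, coarse_context):
        problem = make_problem(coarse_context)
        with pytest.raises(ValueError, match="dt"):
            problem.step(problem.initial_state(False), None, 0.0)


class TestPrecooling:
    def test_body_temperature_coolant_leaves_field_uniform(self, protected_context):
        problem = make_problem(protected_context, T_water=310.15)
        state = problem.run_precooling(problem.initial_state(True))
        assert state.time == 0.0
        assert np.abs(state.T - 310.15).max() < 0.2

    def test_cold_coolant_bounds_and_monotonicity(self, protected_context):
        ctx = protected_context
        problem = make_problem(ctx, T_water=5.0 + 273.15)
        state = problem.initial_state(True)
        eso = ctx.mesh.subdomain_nodes("esophagus")
        prev = state.T[eso].copy()
        for _ in range(10):
            state = problem.step(state, None, 5.0)
            assert np.all(state.T[eso] <= prev + 1e-9)
            prev = state.T[eso].copy()
        final = problem.run_precooling(state)
        inner_wall = state.T[eso].min()
        assert 278.15 < inner_wall < 310.15
        assert 278.15 < final.T[eso].min() < 310.15

    def test_precool_step_size_insensitive(self, protected_context):
        problem = make_problem(protected_context, T_water=5.0 + 273.15)
        a = problem.run_precooling(problem.initial_state(True), dt=5.0)
        b = problem.run_precooling(problem.initial_state(True), dt=10.0)
        eso = protected_context.mesh.subdomain_nodes("esophagus")
        assert np.abs(a.T[eso] - b.T[eso]).max() < 0.2

    def test_precool_on_control_geometry_rejected(self, coarse_context):
        problem = make_problem(coarse_context)
        with pytest.raises(ValueError, match="protected"):
            problem.run_precooling(ThermalState(T=np.full(coarse_context.mesh.n_nodes, 310.15), time=-300.0))


class TestInitialState:
    def test_control_initial_state(self, coarse_context):
        problem = make_problem(coarse_context)
        state = problem.initial_state(False)
        assert state.time == 0.0
        assert np.all(state.T == 310.15)
        assert len(state.T) == coarse_context.mesh.n_nodes

    def test_protected_initial_state(self, protected_context):
        problem = make_problem(protected_context, T_water=278.15)
        state = problem.initial_state(True)
        assert state.time == -300.0
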