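"""The two mass-balance models against closed forms and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprayroom import (WHOLE_ROOM, EmissionEvent, FlowParameters,
                       cv_over_time, mass_balance_residual, simulate_model1,
                       simulate_model2, solve_matrix_exponential)


class TestWellMixedModel:
    def test_instantaneous_release_decays_exponentially(self, chamber):
        times = np.linspace(0.0, 0.5, 200)
        out = simulate_model1(chamber, EmissionEvent(mass=795.0), times)
        expected = 795.0 / 30.0 * np.exp(-times)
        np.testing.assert_allclose(out.values[:, 0], expected, rtol=1e-7)

    def test_constant_rate_reaches_the_steady_state(self, chamber):
        # R_em / Q after many residence times
        emission = EmissionEvent(source=WHOLE_ROOM, mass=3000.0,
                                 mode="constant_rate", duration=100.0)
        out = simulate_model1(chamber, emission, np.linspace(0.0, 30.0, 50))
        c_ss = emission.rate / chamber.q
        assert out.values[-1, 0] == pytest.approx(c_ss, rel=1e-6)

    def test_rejects_invalid_inputs(self, chamber):
        with pytest.raises(ValueError):
            EmissionEvent(mass=-1.0)
        with pytest.raises(ValueError):
            simulate_model1(chamber, EmissionEvent(mass=1.0),
                            np.array([0.0, 0.2, 0.1]))
        with pytest.raises(ValueError):
            simulate_model1(chamber, EmissionEvent(source="111", mass=1.0),
                            np.linspace(0, 1, 10))


class TestEightCompartmentModel:
    def test_zero_exchange_closed_forms(self, grid):
        # with lambda_ex = 0 each column is a two-stage cascade at rate
        # 2*lambda: y=1 decays as e^(-2 lt), y=2 as e^(-2 lt)(1 + 2 lt)
        lam = 1.0
        params = FlowParameters(30.0, lam, 0.0)
        times = np.linspace(0.0, 0.33, 67)
        c0 = np.full(8, 5.0)
        for solver in (simulate_model2, solve_matrix_exponential):
            out = solver(grid, params, EmissionEvent(source="111", mass=0.0),
                         times, initial=c0)
            for j, lab in enumerate(grid.labels):
                decay = 5.0 * np.exp(-2 * lam * times)
                expected = decay * (1 + 2 * lam * times) if lab[1] == "2" else decay
                np.testing.assert_allclose(out.values[:, j], expected,
                                           atol=1e-8)

    @pytest.mark.parametrize("lambda_ex", [0.0, 1.0, 4.64, 10.0])
    @pytest.mark.parametrize("mode,duration", [("instantaneous", None),
                                               ("constant_rate", 0.05)])
    def test_integrator_matches_matrix_exponential_oracle(
            self, grid, lambda_ex, mode, duration):
        params = FlowParameters(30.0, 1.0, lambda_ex)
        emission = EmissionEvent(source="111", mass=795.0, mode=mode,
                                 duration=duration)
        times = np.linspace(0.0, 0.33, 241)
        ivp = simulate_model2(grid, params, emission, times)
        ref = solve_matrix_exponential(grid, params, emission, times)
        scale = np.max(np.abs(ref.values))
        assert np.max(np.abs(ivp.values - ref.values)) / scale < 1e-6

    def test_matrix_exponential_returns_initial_state_at_t0(self, grid,
                                                            chamber):
        c0 = np.arange(1.0, 9.0)
        out = solve_matrix_exponential(grid, chamber,
                                       EmissionEvent(source="111", mass=0.0),
                                       np.array([0.0, 0.1]), initial=c0)
        np.testing.assert_array_equal(out.values[0], c0)

    @pytest.mark.parametrize("lambda_ex", [0.0, 1.0, 4.64, 10.0])
    @pytest.mark.parametrize("mode,duration", [("instantaneous", None),
                                               ("constant_rate", 0.05)])
    def test_mass_balance_closes_on_every_interval(self, grid, lambda_ex,
                                                   mode, duration):
        # summed over compartments, exchange cancels pairwise and the mass
        # budget is d(total)/dt = emission - outlet removal
        params = FlowParameters(30.0, 1.0, lambda_ex)
        emission = EmissionEvent(source="111", mass=795.0, mode=mode,
                                 duration=duration)
        times = np.linspace(0.0, 1.0 / 3.0, 1201)
        for solver in (simulate_model2, solve_matrix_exponential):
            out = solver(grid, params, emission, times)
            residual = mass_balance_residual(out, grid, params, emission)
            assert np.max(np.abs(residual)) / emission.mass < 1e-6

    def test_perfect_mixing_limit_recovers_the_well_mixed_model(
            self, grid, source_release):
        params = FlowParameters(30.0, 1.0, 1000.0)
        times = np.linspace(0.0, 1.0 / 3.0, 121)
        m2 = solve_matrix_exponential(grid, params, source_release, times)
        m1 = simulate_model1(FlowParameters(30.0, 1.0, 0.0),
                             EmissionEvent(mass=source_release.mass), times,
                             exact=True)
        late = times >= 0.02
        rel = np.abs(m2.values[late] - m1.values[late]) / m1.values[late]
        assert np.max(rel) < 0.005

    def test_cv_decreases_monotonically_with_exchange_rate(self, grid,
                                                           source_release):
        # faster inter-compartment mixing means less spatial heterogeneity
        t_eval = np.array([0.0, 0.1])
        cvs = []
        for ratio in (0.5, 1.0, 2.0, 5.0, 10.0, 100.0):
            params = FlowParameters(30.0, 1.0, ratio * 1.0)
            out = solve_matrix_exponential(grid, params, source_release,
                                           t_eval)
            cvs.append(float(cv_over_time(out)["cv"].iloc[-1]))
        assert all(a > b for a, b in zip(cvs, cvs[1:]))
        assert cvs[-1] < 0.05

    def test_rejects_unknown_source_and_negative_exchange(self, grid,
                                                          chamber):
        with pytest.raises(ValueError):
            simulate_model2(grid, chamber,
                            EmissionEvent(source="333", mass=1.0),
                            np.linspace(0, 0.1, 5))
        with pytest.raises(ValueError):
            FlowParameters(30.0, 1.0, -0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lambda_ex=st.floats(0.0, 50.0),
           mass=st.floats(0.0, 5000.0),
           seed=st.integers(0, 2**16))
    def test_concentrations_stay_non_negative(self, grid, lambda_ex, mass,
                                              seed):
        # Metzler rate matrix: the non-negative orthant is invariant
        rng = np.random.default_rng(seed)
        params = FlowParameters(30.0, 1.0, lambda_ex)
        out = solve_matrix_exponential(
            grid, params, EmissionEvent(source="111", mass=mass),
            np.linspace(0.0, 0.5, 40), initial=rng.uniform(0, 30, 8))
        assert np.min(out.values) >= -1e-12
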