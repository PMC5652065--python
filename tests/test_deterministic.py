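"""Deterministic model: response function, equilibria, stability, RK4."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochemostat import (
    ChemostatParams,
    NoInteriorMaximum,
    State,
    classify_equilibrium,
    drift,
    growth_rate,
    growth_rate_peak,
    integrate_ode,
    interior_equilibria,
    jacobian,
    washout_equilibrium,
)


class TestGrowthRate:
    def test_known_value_at_input_concentration(self, ergodic_low):
        # mu(2) = 2*2 / (0.2 + 2 + 0.3*4) = 4/3.4
        assert growth_rate(2.0, ergodic_low.params) == pytest.approx(1.1765, abs=5e-5)

    def test_zero_substrate_gives_zero_rate(self, ergodic_low):
        assert growth_rate(0.0, ergodic_low.params) == 0.0

    def test_negative_substrate_rejected(self, ergodic_low):
        with pytest.raises(ValueError):
            growth_rate(-0.1, ergodic_low.params)

    def test_vanishes_at_large_substrate(self, ergodic_low):
        assert growth_rate(1e8, ergodic_low.params) < 1e-6

    def test_peak_matches_dense_grid_oracle(self, ergodic_low):
        p = ergodic_low.params
        grid = np.arange(1e-4, 10.0 + 1e-9, 1e-4)
        vals = growth_rate(grid, p)
        k = int(np.argmax(vals))
        S_peak, mu_peak = growth_rate_peak(p)
        assert S_peak == pytest.approx(grid[k], abs=2e-4)
        assert mu_peak == pytest.approx(vals[k], abs=1e-6)
        assert S_peak == pytest.approx(math.sqrt(0.2 / 0.3), rel=1e-12)

    def test_peak_below_maximal_rate(self, bistable):
        _, mu_peak = growth_rate_peak(bistable.params)
        assert mu_peak < bistable.params.m

    def test_peak_hand_value_symmetric_params(self):
        p = ChemostatParams(Q=0.5, S0=5.0, m=1.0, a=1.0, K=1.0, delta=1.0)
        S_peak, mu_peak = growth_rate_peak(p)
        assert S_peak == pytest.approx(1.0)
        assert mu_peak == pytest.approx(1.0 / 3.0)

    def test_monod_limit_signals_no_interior_maximum(self):
        p = ChemostatParams(Q=1.0, S0=2.0, m=2.0, a=0.2, K=0.0, delta=1.6)
        with pytest.raises(NoInteriorMaximum):
            growth_rate_peak(p)

    @settings(derandomize=True, max_examples=200)
    @given(
        S=st.floats(0.0, 1e3),
        m=st.floats(0.1, 10.0),
        a=st.floats(0.01, 5.0),
        K=st.floats(0.001, 5.0),
    )
    def test_response_bounded_by_its_peak(self, S, m, a, K):
        """0 <= mu(S) <= m/(1 + 2 sqrt(aK)) < m for every S >= 0."""
        p = ChemostatParams(Q=1.0, S0=1.0, m=m, a=a, K=K, delta=1.0)
        mu = growth_rate(S, p)
        _, peak = growth_rate_peak(p)
        assert 0.0 <= mu <= peak * (1 + 1e-12)
        assert peak < m


class TestDrift:
    def test_washout_state_is_stationary(self, ergodic_low):
        p = ergodic_low.params
        f = drift(State(p.S0, 0.0), p)
        assert f == (0.0, 0.0)

    def test_hand_arithmetic_value(self, ergodic_low):
        # mu(2) = 4/3.4; dS = -mu*0.8/1.6, dx = (mu - 1)*0.8
        fS, fx = drift(State(2.0, 0.8), ergodic_low.params)
        assert fS == pytest.approx(-0.58824, abs=5e-6)
        assert fx == pytest.approx(0.14118, abs=5e-6)

    @pytest.mark.parametrize(
        "preset_name", ["stationary-low-noise", "noise-induced-extinction", "bistable"]
    )
    def test_vanishes_at_interior_equilibria(self, preset_name):
        from stochemostat import preset

        p = preset(preset_name).params
        for eq in interior_equilibria(p):
            fS, fx = drift(State(eq.S, eq.x), p)
            assert max(abs(fS), abs(fx)) < 1e-9


class TestEquilibria:
    def test_bistable_case_has_two_interior_equilibria(self, bistable):
        eqs = interior_equilibria(bistable.params)
        assert len(eqs) == 2
        assert eqs[0].S == pytest.approx(0.3255, abs=5e-5)
        assert eqs[0].x == pytest.approx(2.0745, abs=5e-5)
        assert eqs[1].S == pytest.approx(1.7281, abs=5e-5)
        assert eqs[1].x == pytest.approx(0.6719, abs=5e-5)

    def test_unique_equilibrium_when_second_root_exceeds_input(self, noise_extinction):
        # the larger quadratic root (~2.4558) exceeds S0=2 and is rejected
        eqs = interior_equilibria(noise_extinction.params)
        assert len(eqs) == 1
        assert eqs[0].S == pytest.approx(0.2715, abs=5e-5)
        assert eqs[0].x == pytest.approx(2.7657, abs=5e-5)

    def test_empty_when_dilution_exceeds_max_growth(self, washout):
        assert interior_equilibria(washout.params) == []

    def test_monod_degenerate_case_linear_break_even(self):
        p = ChemostatParams(Q=1.0, S0=2.0, m=2.0, a=0.2, K=0.0, delta=1.6)
        eqs = interior_equilibria(p)
        assert len(eqs) == 1
        assert eqs[0].S == pytest.approx(0.2)  # Qa/(m-Q)
        assert eqs[0].x == pytest.approx(1.6 * 1.8)

    @pytest.mark.parametrize(
        "preset_name",
        ["stationary-low-noise", "noise-induced-extinction", "bistable",
         "extinction-moderate-dilution"],
    )
    def test_roots_agree_with_bisection_scan(self, preset_name):
        """Independent oracle: sign-change bisection of the equilibrium
        quadratic over (0, S0]."""
        from stochemostat import preset

        p = preset(preset_name).params

        def poly(S):
            return p.Q * p.K * S * S + (p.Q - p.m) * S + p.Q * p.a

        grid = np.linspace(1e-9, p.S0, 20001)
        vals = poly(grid)
        roots = []
        for i in range(len(grid) - 1):
            if vals[i] == 0.0:
                roots.append(grid[i])
            elif vals[i] * vals[i + 1] < 0:
                lo, hi = grid[i], grid[i + 1]
                for _ in range(100):
                    mid = 0.5 * (lo + hi)
                    if poly(lo) * poly(mid) <= 0:
                        hi = mid
                    else:
                        lo = mid
                roots.append(0.5 * (lo + hi))
        roots = [r for r in roots if r < p.S0 - 1e-12]
        eqs = interior_equilibria(p)
        assert len(eqs) == len(roots)
        for eq, r in zip(eqs, sorted(roots)):
            assert eq.S == pytest.approx(r, abs=1e-8)

    def test_washout_stability_by_dilution_regime(self, washout, noise_extinction, bistable):
        assert washout_equilibrium(washout.params).stability == "stable node"
        assert washout_equilibrium(noise_extinction.params).stability == "saddle"
        assert washout_equilibrium(bistable.params).stability == "stable node"

    def test_equilibrium_drift_residual(self, bistable):
        p = bistable.params
        for eq in [washout_equilibrium(p)] + interior_equilibria(p):
            fS, fx = drift(State(eq.S, eq.x), p)
            assert max(abs(fS), abs(fx)) < 1e-9


class TestJacobianAndClassification:
    def test_washout_corner_entry_is_growth_minus_dilution(self, ergodic_low):
        p = ergodic_low.params
        J = jacobian(State(p.S0, 0.0), p)
        assert J[1, 1] == pytest.approx(growth_rate(p.S0, p) - p.Q)
        assert J[1, 0] == 0.0

    @pytest.mark.parametrize(
        "S,x", [(0.5, 1.0), (2.0, 0.8), (1.7281, 0.6719), (0.05, 3.0)]
    )
    def test_matches_central_differences(self, bistable, S, x):
        p = bistable.params
        h = 1e-6
        J = jacobian(State(S, x), p)
        num = np.empty((2, 2))
        for j, (dS, dx) in enumerate([(h, 0.0), (0.0, h)]):
            fp = drift(State(S + dS, x + dx), p)
            fm = drift(State(S - dS, x - dx), p)
            num[0, j] = (fp[0] - fm[0]) / (2 * h)
            num[1, j] = (fp[1] - fm[1]) / (2 * h)
        assert np.allclose(J, num, rtol=1e-6, atol=1e-6)

    def test_bistable_interior_labels(self, bistable):
        eqs = interior_equilibria(bistable.params)
        assert eqs[0].stability == "stable node"
        assert eqs[1].stability == "saddle"
        ev = eqs[1].eigenvalues
        assert ev[0].real < 0 < ev[1].real

    def test_unique_equilibrium_is_attracting(self, noise_extinction):
        (eq,) = interior_equilibria(noise_extinction.params)
        label = classify_equilibrium(eq.S, eq.x, noise_extinction.params)
        assert label in ("stable node", "stable spiral")

    def test_non_steady_point_rejected_with_residual(self, ergodic_low):
        with pytest.raises(ValueError, match="residual"):
            classify_equilibrium(1.0, 1.0, ergodic_low.params)


class TestRk4Integration:
    def test_equilibrium_is_invariant(self, noise_extinction):
        p = noise_extinction.params
        (eq,) = interior_equilibria(p)
        traj = integrate_ode(p, State(eq.S, eq.x), t_end=20.0, dt=0.01)
        assert np.max(np.abs(traj.S_path - eq.S)) < 1e-6
        assert np.max(np.abs(traj.x_path - eq.x)) < 1e-6

    def test_converges_to_interior_equilibrium(self, ergodic_low):
        p = ergodic_low.params
        traj = integrate_ode(p, State(1.2, 0.8), t_end=100.0, dt=0.01)
        eqs = interior_equilibria(p)
        end = traj.final_state()
        dists = [abs(end.S - eq.S) + abs(end.x - eq.x) for eq in eqs]
        assert min(dists) < 1e-4

    def test_conserved_quantity_decays_exponentially(self, ergodic_low):
        """z = S + x/delta obeys dz/dt = Q (S0 - z) exactly, so
        |z(t) - S0| <= |z(0) - S0| exp(-Q t)."""
        p = ergodic_low.params
        traj = integrate_ode(p, State(1.2, 0.8), t_end=20.0, dt=0.01)
        z = traj.S_path + traj.x_path / p.delta
        bound = abs(z[0] - p.S0) * np.exp(-p.Q * traj.times) + 1e-6
        assert np.all(np.abs(z - p.S0) <= bound)

    def test_fourth_order_self_convergence(self, ergodic_low):
        p = ergodic_low.params
        init = State(1.2, 0.8)
        ref = integrate_ode(p, init, t_end=5.0, dt=0.0005).final_state()

        def err(dt):
            end = integrate_ode(p, init, t_end=5.0, dt=dt).final_state()
            return abs(end.S - ref.S) + abs(end.x - ref.x)

        ratio = err(0.04) / err(0.02)
        assert 10 < ratio < 22  # ~16 for a 4th-order method

    def test_invalid_steps_rejected(self, ergodic_low):
        with pytest.raises(ValueError):
            integrate_ode(ergodic_low.params, State(1, 1), t_end=1.0, dt=0.0)
        with pytest.raises(ValueError):
            integrate_ode(ergodic_low.params, State(1, 1), t_end=0.005, dt=0.01)
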