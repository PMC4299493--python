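"""Circuit-model checks: rates, Jacobian, steady states, bifurcations."""

import numpy as np
import pytest

from bistflux.circuit import (
    CircuitParams,
    apply_perturbation,
    bifurcation_scan,
    cra_response,
    fbp_nullcline,
    fbp_rate,
    find_steady_states,
    flux,
    fold_points_exact,
    integrate,
    jacobian,
    rhs,
    watershed,
)
from conftest import rk4_endpoints

P = CircuitParams.reference()
S_MID = 1.0  # well inside the bistable substrate window


class TestElementaryRates:
    def test_flux_zeros_and_half_saturation(self):
        assert flux(0.0, 1.0, P) == 0.0
        assert flux(2.0, 0.0, P) == 0.0
        sat = P.k_E * P.u * 2.0  # s -> infinity limit at E = 2
        assert flux(2.0, P.K_s, P) == pytest.approx(0.5 * sat)

    def test_fbp_rate_limits(self):
        assert fbp_rate(1.0, 0.0, P) == 0.0
        assert fbp_rate(1e9, 1e9, P) == pytest.approx(P.f_fbp * P.V_f, rel=1e-6)
        assert fbp_rate(P.K_F, P.K_J, P) == pytest.approx(P.f_fbp * P.V_f / 4)

    def test_cra_response(self):
        assert cra_response(0.0, P) == 1.0
        assert cra_response(P.K_I, P) == pytest.approx(0.5)
        assert cra_response(2 * P.K_I, P) < cra_response(P.K_I, P)

    def test_origin_escapes(self):
        dE, dF = rhs((0.0, 0.0), 1.0, P)
        assert dE == pytest.approx(P.beta0 + P.beta1)
        assert dE > 0


class TestJacobian:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            E = float(10 ** rng.uniform(-2, 1))
            F = float(10 ** rng.uniform(-2, 0.7))
            s = float(10 ** rng.uniform(-1, 0.6))
            J_an = jacobian((E, F), s, P)
            J_fd = np.zeros((2, 2))
            for j, x in enumerate((E, F)):
                hstep = 1e-6 * max(abs(x), 1e-3)
                up = [E, F]; dn = [E, F]
                up[j] += hstep; dn[j] -= hstep
                J_fd[:, j] = (rhs(up, s, P) - rhs(dn, s, P)) / (2 * hstep)
            np.testing.assert_allclose(J_an, J_fd, atol=1e-5, rtol=1e-5)


class TestSteadyStates:
    def test_no_substrate_single_state(self):
        states = find_steady_states(0.0, P)
        assert len(states) == 1
        assert states[0].J == 0.0

    def test_residual_norm_at_fixed_points(self):
        for s in (0.2, S_MID, 2.0, 3.0):
            for st in find_steady_states(s, P):
                d = rhs((st.state.E, st.state.F), s, P)
                assert np.max(np.abs(d)) < 1e-9

    def test_mid_window_bistability(self):
        states = find_steady_states(S_MID, P)
        assert len(states) == 3
        assert sum(st.stable for st in states) == 2
        assert sum(not st.stable for st in states) == 1
        # the unstable state lies between the stable ones in E and J
        Es = [st.state.E for st in states]
        assert Es == sorted(Es)
        assert not states[1].stable

    def test_brute_force_basin_agreement(self):
        # every random initial condition must settle onto one of the two
        # stable states under an independent fixed-step integration
        states = find_steady_states(S_MID, P)
        stable = [st for st in states if st.stable]
        rng = np.random.default_rng(11)
        n = 10000
        E0 = 10 ** rng.uniform(-3, 1.5, n)
        F0 = 10 ** rng.uniform(-3, 0.8, n)
        E_end, F_end = rk4_endpoints(E0, F0, S_MID, P, t_end=400.0)
        targets = np.array([[st.state.E, st.state.F] for st in stable])
        d = np.hypot(E_end[:, None] - targets[None, :, 0],
                     F_end[:, None] - targets[None, :, 1])
        nearest = d.min(axis=1)
        assert np.all(nearest < 1e-4)

    def test_positivity_preserved(self):
        rng = np.random.default_rng(3)
        n = 100
        E0 = 10 ** rng.uniform(-3, 1.5, n)
        F0 = 10 ** rng.uniform(-3, 0.8, n)
        _, _, min_E, min_F = rk4_endpoints(E0, F0, S_MID, P, t_end=100.0,
                                           track_min=True)
        assert min_E.min() > -1e-9
        assert min_F.min() > -1e-9

    def test_high_branch_has_lower_fbp(self):
        # the positive-loop sign condition: FBP drops with rising flux
        for s in (1.0, 2.0):
            stable = [st for st in find_steady_states(s, P) if st.stable]
            high = max(stable, key=lambda st: st.J)
            low = min(stable, key=lambda st: st.J)
            assert high.state.F < low.state.F


class TestWatershed:
    def test_monostable_returns_none(self):
        assert watershed(0.25, P) is None
        assert watershed(3.5, P) is None

    def test_separatrix_by_integration(self):
        ws = watershed(S_MID, P)
        stable = [st for st in find_steady_states(S_MID, P) if st.stable]
        high = max(stable, key=lambda st: st.J)
        low = min(stable, key=lambda st: st.J)
        for fac, target in [(1.01, high), (0.99, low)]:
            E0 = fac * ws
            F0 = fbp_nullcline(E0, S_MID, P)
            sol = integrate((E0, F0), S_MID, P, t_end=400.0)
            assert abs(sol.y[0, -1] - target.state.E) < 1e-4

    def test_threshold_decreasing_in_transport_capacity(self):
        thresholds = [watershed(S_MID, P.replace(u=u))
                      for u in (0.9, 1.0, 1.2, 1.4)]
        assert all(t is not None for t in thresholds)
        assert np.all(np.diff(thresholds) < 0)


@pytest.fixture(scope="module")
def diagram():
    grid = np.geomspace(0.05, 4.0, 40)
    return bifurcation_scan("substrate", grid, P)


class TestBifurcationScan:

    def test_state_counts(self, diagram):
        for states in diagram.branches:
            n_stable = sum(st.stable for st in states)
            n_unstable = sum(not st.stable for st in states)
            assert n_stable in (1, 2)
            assert n_unstable == (1 if n_stable == 2 else 0)

    def test_single_bistable_interval_with_two_folds(self, diagram):
        assert len(diagram.fold_points) == 2
        lo, hi = sorted(diagram.fold_points)
        assert 0.1 < lo < 1.0
        assert 2.0 < hi < 3.5
        for s, states in zip(diagram.grid, diagram.branches):
            if lo < s < hi:
                assert len(states) == 3
            elif s < lo * 0.99 or s > hi * 1.01:
                assert len(states) == 1

    def test_fold_agreement_with_degeneracy_condition(self, diagram):
        # cross-check: a fold solves g = 0 and dg/dE = 0 simultaneously
        lo, hi = sorted(diagram.fold_points)
        i_lo = int(np.searchsorted(diagram.grid, lo))
        saddle_E = next(st.state.E for st in diagram.branches[i_lo]
                        if not st.stable)
        s_exact, _ = fold_points_exact("substrate", lo, P, E_guess=saddle_E)
        assert abs(s_exact - lo) / lo < 1e-4

    def test_beta1_reduction_moves_lower_fold_right(self):
        grid = np.geomspace(0.2, 1.5, 25)
        d1 = bifurcation_scan("substrate", grid, P)
        d2 = bifurcation_scan("substrate", grid, P.replace(beta1=0.7 * P.beta1))
        lo1 = min(d1.fold_points)
        lo2 = min(d2.fold_points)
        assert lo2 > lo1
        # high-branch flux at a fixed mid-window substrate barely moves
        J1 = max(st.J for st in find_steady_states(2.0, P) if st.stable)
        J2 = max(st.J for st in
                 find_steady_states(2.0, P.replace(beta1=0.7 * P.beta1))
                 if st.stable)
        assert abs(J2 - J1) / J1 < 0.10

    def test_monostable_sweep_has_no_folds(self):
        grid = np.linspace(3.0, 4.0, 21)
        d = bifurcation_scan("substrate", grid, P)
        assert d.fold_points == []

    def test_dataframe_export(self, diagram):
        df = diagram.to_dataframe()
        assert set(df.columns) == {"parameter", "branch_id", "E", "F", "J",
                                   "stable"}
        assert len(df) == sum(len(b) for b in diagram.branches)


class TestHighBranchGrowth:
    def test_mu_increasing_and_saturating(self):
        ss = [0.8, 1.2, 1.6, 2.0, 2.4]
        mus = []
        for s in ss:
            stable = [st for st in find_steady_states(s, P) if st.stable]
            mus.append(P.Y * max(st.J for st in stable))
        assert np.all(np.diff(mus) > 0)
        # hyperbolic-like: increments shrink with s
        inc = np.diff(mus)
        assert inc[-1] < inc[0]

    def test_reference_growth_rate_at_2gl(self):
        stable = [st for st in find_steady_states(2.0, P) if st.stable]
        mu = P.Y * max(st.J for st in stable)
        assert mu == pytest.approx(0.272, rel=1e-3)


class TestPerturbations:
    def test_identity(self):
        assert apply_perturbation(P, "transporter", 1.0) == P

    def test_fbp_inverse_composition(self):
        q = apply_perturbation(apply_perturbation(P, "fbp_oe", 2.0),
                               "dg6p", 0.5)
        assert q.f_fbp == pytest.approx(P.f_fbp)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            apply_perturbation(P, "unknown", 2.0)

    def test_transporter_widens_window_leftward(self):
        grid = np.geomspace(0.1, 1.2, 25)
        base = bifurcation_scan("substrate", grid, P)
        boosted = bifurcation_scan("substrate", grid,
                                   apply_perturbation(P, "transporter", 2.0))
        assert min(boosted.fold_points) < min(base.fold_points)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            CircuitParams(K_I=-1.0)
        with pytest.raises(ValueError):
            CircuitParams(h=0.5)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "params.yaml"
        P.to_yaml(path)
        assert CircuitParams.from_yaml(path) == P
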