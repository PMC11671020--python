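"""QSS reduction, nullclines, and the reduced-plane portrait."""

import numpy as np
import pytest

import triosc
from triosc.phaseplane import _gk_root, compute_nullcline, qss_reduce


class TestGoldbeterKoshlandRoot:
    def test_matches_bisection_on_random_rates(self):
        from scipy.optimize import brentq
        rng = np.random.default_rng(1)
        for _ in range(300):
            act, inact = rng.uniform(0.01, 3.0, 2)
            ja, ji = rng.uniform(0.005, 0.5, 2)
            total = rng.uniform(0.3, 2.0)
            v = float(_gk_root(act, inact, ja, ji, total))
            g = lambda x: act * (total - x) / (ja + total - x) - inact * x / (ji + x)
            if g(0) <= 0:
                ref = 0.0
            elif g(total) >= 0:
                ref = total
            else:
                ref = brentq(g, 0.0, total, xtol=1e-15)
            assert v == pytest.approx(ref, abs=1e-12)

    def test_degenerate_rates(self):
        assert _gk_root(0.0, 1.0, 0.1, 0.1, 1.0) == 0.0
        assert _gk_root(1.0, 0.0, 0.1, 0.1, 1.0) == 1.0


class TestReduction:
    def test_reduced_rhs_zero_at_full_fixed_point(self, reduced_stressed,
                                                  stressed_fixed_points):
        fp = stressed_fixed_points[0]
        d = reduced_stressed.rhs(fp.activity("AMPK"), fp.activity("ULK1"))
        assert np.max(np.abs(d)) < 1e-8

    def test_inner_mtorc1_decreases_with_ampk(self, reduced_stressed):
        m_lo = reduced_stressed.inner_state(0.2, 0.3)
        m_hi = reduced_stressed.inner_state(0.6, 0.3)
        i = reduced_stressed.model.index("mTORC1")
        assert m_hi[i] < m_lo[i]

    def test_grid_and_scalar_paths_agree(self, reduced_stressed):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1, 20)
        U = rng.uniform(0, 1, 20)
        dA, dU = reduced_stressed.rhs_grid(A, U)
        for i in range(20):
            d = reduced_stressed.rhs(A[i], U[i])
            assert d[0] == pytest.approx(dA[i], abs=1e-10)
            assert d[1] == pytest.approx(dU[i], abs=1e-10)

    def test_reduced_attractor_matches_full_projection(self, reduced_stressed,
                                                       stressed_model, rest_fp):
        # both routes must classify the stressed cell as oscillatory with
        # comparable ULK1 excursion
        from scipy.integrate import solve_ivp
        tc = triosc.integrate(stressed_model, t_end=200.0, x0=rest_fp.state)
        u_full = tc.activity("ULK1")[1000:]
        fun = lambda t, x: reduced_stressed.rhs(x[0], x[1])
        x0 = [rest_fp.activity("AMPK"), rest_fp.activity("ULK1")]
        sol = solve_ivp(fun, (0, 200.0), x0, method="LSODA", rtol=1e-8,
                        atol=1e-10, t_eval=np.linspace(0, 200, 2000))
        u_red = sol.y[1][1000:]
        assert u_full.max() - u_full.min() > 0.5
        assert u_red.max() - u_red.min() > 0.5


class TestNullclines:
    def test_points_satisfy_residual_invariant(self, reduced_stressed,
                                               portrait_stressed):
        for var in ("AMPK", "ULK1"):
            pts = portrait_stressed.nullclines[var].points
            assert len(pts) > 50
            k = 0 if var == "AMPK" else 1
            sample = pts[:: max(len(pts) // 25, 1)]
            for a, u in sample:
                assert abs(reduced_stressed.rhs(a, u)[k]) < 1e-8

    def test_logistic_test_system_nullcline_closed_form(self):
        # a 1D dx/dt = x(1-x) embedded via a custom scalar scan
        import types
        red = types.SimpleNamespace(
            rhs=lambda a, u: np.array([a * (1 - a), -u]),
            rhs_grid=lambda A, U: (A * (1 - A), -U),
        )
        ncl = compute_nullcline(red, "AMPK", grid_n=41)
        vals = sorted(set(np.round(ncl.points[:, 0], 6)))
        assert vals == [0.0, 1.0]

    def test_grid_too_coarse_rejected(self, reduced_stressed):
        with pytest.raises(ValueError):
            compute_nullcline(reduced_stressed, "AMPK", grid_n=8)


class TestPortrait:
    def test_single_unstable_intersection(self, portrait_stressed):
        fps = portrait_stressed.fixed_points
        assert len(fps) == 1
        x, ev, stable = fps[0]
        assert not stable
        assert ev.real.max() > 0

    def test_fixed_point_lies_on_both_nullclines(self, portrait_stressed,
                                                 reduced_stressed):
        x, _, _ = portrait_stressed.fixed_points[0]
        d = reduced_stressed.rhs(x[0], x[1])
        assert np.max(np.abs(d)) < 1e-8

    def test_fixed_point_equals_full_system_projection(self, portrait_stressed,
                                                       stressed_fixed_points):
        x, _, _ = portrait_stressed.fixed_points[0]
        fp = stressed_fixed_points[0]
        assert abs(x[0] - fp.activity("AMPK")) < 1e-6
        assert abs(x[1] - fp.activity("ULK1")) < 1e-6

    def test_variant_B_orbit_smaller_than_A(self, stressed_model):
        params = stressed_model.parameters
        pb = triosc.portrait(triosc.build_model("B", params), t_end=250.0, seed=0)
        area = lambda tr: ((tr[:, 0].max() - tr[:, 0].min())
                           * (tr[:, 1].max() - tr[:, 1].min()))
        pa = triosc.portrait(stressed_model, t_end=250.0, seed=0)
        tail = lambda p: p.trajectories[0][len(p.trajectories[0]) // 2:]
        assert area(tail(pb)) < area(tail(pa))
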