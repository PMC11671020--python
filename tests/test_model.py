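"""Model core: topology variants, rate-law structure, Jacobian."""

import numpy as np
import pytest

import triosc
from triosc.model import (
    AMPK_ACTIVATES_ULK1,
    AMPK_INHIBITS_ULK1,
    ConfigurationError,
    MANDATORY_EDGES,
    build_model,
    jacobian,
    rhs,
)


@pytest.fixture(scope="module")
def params():
    return triosc.reference_parameters()


def edge_keys(model):
    return {e.key for e in model.edges}


class TestBuildModel:
    def test_variant_A_has_amplifying_edge_only(self, params):
        m = build_model("A", params)
        assert AMPK_INHIBITS_ULK1 in edge_keys(m)
        assert AMPK_ACTIVATES_ULK1 not in edge_keys(m)

    def test_variant_B_is_A_without_double_negative(self, params):
        a, b = build_model("A", params), build_model("B", params)
        assert edge_keys(a) - edge_keys(b) == {AMPK_INHIBITS_ULK1}

    def test_custom_empty_equals_mandatory_set(self, params):
        m = build_model(triosc.TopologyVariant("custom"), params)
        assert edge_keys(m) == {e.key for e in MANDATORY_EDGES}
        assert edge_keys(m) == edge_keys(build_model("B", params))

    def test_variant_algebra(self, params):
        a, b, c = (edge_keys(build_model(v, params)) for v in "ABC")
        assert b < a < c
        fw, fs = build_model("F_weak", params), build_model("F_strong", params)
        assert edge_keys(fw) == edge_keys(fs)
        w_weak = fw.variant.weight_overrides["k_ampk_ulk1_act"]
        w_strong = fs.variant.weight_overrides["k_ampk_ulk1_act"]
        assert w_strong == pytest.approx(100 * w_weak)

    def test_unknown_variant_rejected(self, params):
        with pytest.raises(ConfigurationError):
            build_model("Z", params)

    def test_missing_weight_param_named_in_error(self):
        bad = triosc.ParameterSet(rate_constants={}, michaelis_constants={"J": 1.0})
        with pytest.raises(ConfigurationError, match="k_ampk_mtorc1"):
            build_model("A", bad)


class TestRhs:
    def test_all_zero_state_never_points_outward(self, params):
        m = build_model("A", params)
        d = rhs(m, np.zeros(5))
        assert np.all(d >= 0)

    def test_forward_invariance_on_random_boundary_states(self, params):
        m = build_model("A", params.with_updates(stress=0.75, stress1=0.25))
        rng = np.random.default_rng(42)
        totals = m.totals
        for _ in range(1000):
            x = rng.uniform(0, 1, 5) * totals
            j = rng.integers(0, 5)
            x[j] = totals[j] if rng.random() < 0.5 else 0.0
            d = rhs(m, x)
            if x[j] == 0.0:
                assert d[j] >= 0
            else:
                assert d[j] <= 0

    def test_edge_sign_consistency_at_random_interior_states(self, params):
        m = build_model("A", params.with_updates(stress=0.3, stress1=0.1))
        rng = np.random.default_rng(7)
        eps = 1e-6
        for _ in range(1000):
            x = rng.uniform(0.05, 0.95, 5) * m.totals
            e = m.edges[rng.integers(0, len(m.edges))]
            src = m.index(e.sources[0])
            tgt = m.index(e.target)
            xp = x.copy()
            xp[src] += eps
            delta = rhs(m, xp)[tgt] - rhs(m, x)[tgt]
            if e.sign == "positive":
                assert delta >= 0
            else:
                assert delta <= 0

    def test_higher_ampk_lowers_mtorc1_derivative(self, params):
        m = build_model("A", params)
        x = np.array([0.5, 0.3, 0.2, 0.1, 0.05])
        x_hi = x.copy()
        x_hi[1] = 0.6
        assert rhs(m, x_hi)[0] < rhs(m, x)[0]

    def test_dimension_and_domain_errors(self, params):
        m = build_model("A", params)
        with pytest.raises(ValueError):
            rhs(m, np.zeros(4))
        with pytest.raises(ValueError):
            rhs(m, np.array([2.0, 0, 0, 0, 0]))

    def test_rhs_vanishes_at_root_finder_fixed_point(self, params, rest_fp):
        m = build_model("A", params)
        assert np.max(np.abs(rhs(m, rest_fp.state))) < 1e-9


class TestJacobian:
    def test_sign_of_ampk_on_mtorc1_entry(self, params):
        m = build_model("A", params)
        x = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        J = jacobian(m, x)
        assert J[m.index("mTORC1"), m.index("AMPK")] <= 0

    def test_matches_independent_finite_difference(self, params):
        m = build_model("A", params.with_updates(stress=0.75, stress1=0.25))
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.uniform(0.1, 0.9, 5)
            J = jacobian(m, x)
            # independent oracle: one-sided differences, different step
            h = 2e-7
            J2 = np.empty((5, 5))
            for j in range(5):
                xp = x.copy()
                xp[j] += h
                J2[:, j] = (rhs(m, xp) - rhs(m, x)) / h
            assert np.max(np.abs(J - J2)) < 1e-5

    def test_linear_decay_closed_form(self):
        # one effectively decoupled species: dPROT/dt ~ -k*PROT near 0 drive
        params = triosc.reference_parameters()
        m = build_model("A", params)
        x = np.array([0.0, 0.0, 0.0, 0.5, 0.0])
        ka = params.get("k_act_PROT")
        ja = params.get("J_act_PROT")
        k = params.get("k_inact_PROT")
        ji = params.get("J_inact_PROT")
        J = jacobian(m, x)
        i = m.index("PROT")
        # closed form: with AMPK = 0 the PROT row is autonomous
        expected = -ka * ja / (ja + 0.5) ** 2 - k * ji / (ji + 0.5) ** 2
        assert J[i, i] == pytest.approx(expected, rel=1e-4)


class TestFingerprint:
    def test_fingerprint_changes_with_parameters(self, params):
        m1 = build_model("A", params)
        m2 = build_model("A", params.with_updates(stress=0.1))
        assert m1.fingerprint() != m2.fingerprint()
        assert m1.fingerprint() == build_model("A", params).fingerprint()
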