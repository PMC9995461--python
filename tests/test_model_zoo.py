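"""Model-zoo constructors and their model-specific sensitivity metrics."""

import math

import numpy as np
import pytest

import schemesens as ss


class TestIndependentSites:
    def test_one_site_occupancy_closed_form(self):
        sch = ss.make_independent_sites(1, [1.0])
        for x in (0.2, 1.0, 8.0):
            pi = ss.steady_state_linear(sch, x)
            assert pi[sch.index("1")] == pytest.approx(x / (1 + x), rel=1e-12)

    def test_two_site_mean_occupancy(self):
        sch = ss.make_independent_sites(2, (1.0, 1.0))
        nb = ss.Observable.from_mapping(sch, sch.n_bound)
        for x in (0.5, 2.0):
            pi = ss.steady_state_linear(sch, x)
            assert ss.observable_average(pi, nb) == pytest.approx(2 * x / (1 + x))

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_construction_is_detailed_balanced(self, n):
        sch = ss.make_independent_sites(n, [0.5 + i for i in range(n)])
        assert ss.is_detailed_balanced(sch, 1.7)[0]

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError):
            ss.make_independent_sites(13)


class TestMwc:
    @pytest.mark.parametrize("n,expected", [(2, 4), (5, 10), (11, 22)])
    def test_support_size_is_2n(self, n, expected):
        sch = ss.make_mwc_noneq(n, ss.mwc_equilibrium_rates(n))
        assert ss.support_size(sch) == expected
        # every state with a binding exit is in the support
        with_binding_exit = {
            e.src for e in sch.edges if e.x_power == 1
        }
        assert len(with_binding_exit) == expected

    def test_incomplete_rate_table_rejected(self):
        rates = ss.mwc_equilibrium_rates(2)
        del rates["flip"]
        with pytest.raises(ValueError, match="incomplete"):
            ss.make_mwc_noneq(2, rates)

    def test_equilibrium_parameterization_is_balanced_and_hill_below_n(self):
        n = 2
        sch = ss.make_mwc_noneq(n, ss.mwc_equilibrium_rates(n))
        assert ss.is_detailed_balanced(sch, 1.3)[0]
        curve = ss.ResponseCurve.from_scheme_partition(
            sch, ss.StatePartition(sch.set_states("CW"))
        )
        assert ss.hill_s90s10(curve).value <= n + 1e-6
        for x in (0.3, 1.0, 3.0):
            assert ss.hill_binding(sch, x).value <= n + 1e-9

    def test_saturating_family_pushes_hill_toward_2n(self):
        for n in (2, 3):
            sch = ss.make_mwc_noneq(n, ss.mwc_saturating_rates(n, 1e6))
            curve = ss.ResponseCurve.from_scheme_partition(
                sch, ss.StatePartition(sch.set_states("CW")), exact=True
            )
            h = ss.hill_s90s10(curve).value
            assert n < h <= 2 * n + 1e-6
            assert h > 0.98 * 2 * n


class TestHopfield:
    def test_support_is_the_two_bound_states(self, hopfield_eq):
        assert set(ss.support(hopfield_eq)) == {"EW", "EW*"}
        assert ss.support_size(hopfield_eq) == 2

    def test_equilibrium_discrimination_is_boltzmann(self, hopfield_eq):
        for delta in (0.0, 0.7, -1.2):
            assert ss.discriminatory_index(hopfield_eq, delta=delta) == pytest.approx(
                1.0, abs=1e-10
            )

    def test_any_parameterization_bounded_by_two(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            rates = 10.0 ** rng.uniform(-3, 3, size=6)
            nu = ss.discriminatory_index(ss.make_hopfield_kp(rates))
            assert nu <= 2.0 + 1e-9

    def test_saturating_family_approaches_two(self):
        nus = [
            ss.discriminatory_index(ss.make_hopfield_kp(ss.hopfield_saturating_rates(lam)))
            for lam in (10.0, 100.0, 1000.0)
        ]
        assert nus[0] < nus[1] < nus[2] <= 2.0
        assert nus[1] > 1.9


class TestFence:
    def _hopfield_as_fence(self, rates):
        a, b, c, d, e, f = rates
        crossings = [
            ("X0", "Y0", a, 0),  # E -> EW
            ("Y0", "X0", b, 1),  # EW -> E (discard, carries x)
            ("Y1", "X0", e, 1),  # EW* -> E (discard, carries x)
            ("X0", "Y1", f, 0),  # E -> EW*
        ]
        internal = [("Y0", "Y1", c, 0), ("Y1", "Y0", d, 0)]
        return ss.make_fence_scheme(1, 2, crossings, internal)

    def test_hopfield_is_a_fence_special_case(self):
        rates = (1.0, 2.0, 0.5, 3.0, 4.0, 0.25)
        hop = ss.make_hopfield_kp(rates)
        fence = self._hopfield_as_fence(rates)
        for x in (0.3, 1.0, 2.5):
            p1 = ss.steady_state_linear(hop, x)
            p2 = ss.steady_state_linear(fence, x)
            # states: E,EW,EW* <-> X0,Y0,Y1
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_misdirected_x_edge_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            ss.make_fence_scheme(1, 1, [("X0", "Y0", 1.0, 1)], [])

    def test_discriminatory_index_bounded_by_boundary_states(self):
        # ladder: 3 Y states, each with one crossing exit -> m = 3
        crossings = [(f"Y{i}", f"X{i}", 1.0, 1) for i in range(3)] + [
            (f"X{i}", f"Y{i}", 1.0, 0) for i in range(3)
        ]
        internal = []
        for side in ("X", "Y"):
            for i in range(3):
                j = (i + 1) % 3
                internal += [(f"{side}{i}", f"{side}{j}", 1.0 + i, 0),
                             (f"{side}{j}", f"{side}{i}", 0.7, 0)]
        sch = ss.make_fence_scheme(3, 3, crossings, internal)
        m = ss.support_size(sch)
        assert m == 3
        nu = ss.discriminatory_index(sch, bound_state="Y0", free_state="X0")
        assert abs(nu) <= m + 1e-9

    def test_single_crossing_limits_nu_to_one(self):
        crossings = [("Y0", "X0", 2.0, 1), ("X0", "Y0", 1.0, 0)]
        sch = ss.make_fence_scheme(1, 1, crossings, [])
        nu = ss.discriminatory_index(sch, bound_state="Y0", free_state="X0")
        assert abs(nu) <= 1 + 1e-9


class TestSensing:
    def test_two_state_receptor_closed_form(self):
        sch = ss.KineticScheme(
            ["X0", "Y0"], [ss.Edge("X0", "Y0", 1.0, x_power=1), ss.Edge("Y0", "X0", 1.0)]
        )
        setup = ss.SensingSetup(sch, frozenset(["Y0"]), R_T=1000, c=0.7)
        eps2, bound = ss.sensing_error(setup)
        pi_Y = 0.7 / 1.7
        assert eps2 == pytest.approx(1 / (1000 * pi_Y * (1 - pi_Y)), rel=1e-12)
        assert eps2 == pytest.approx(bound, rel=1e-12)  # m = 1 receptor saturates

    def test_random_receptors_obey_both_inequalities(self):
        for seed in range(100):
            setup = ss.random_receptor(seed)
            eps2, bound = ss.sensing_error(setup)
            m = ss.support_size(setup.scheme)
            assert eps2 >= bound * (1 - 1e-9)
            assert bound >= 4.0 / (setup.R_T * m**2) * (1 - 1e-12)

    def test_non_crossing_x_edge_rejected(self):
        sch = ss.KineticScheme(
            ["X0", "X1", "Y0"],
            [
                ss.Edge("X0", "X1", 1.0, x_power=1),
                ss.Edge("X1", "X0", 1.0),
                ss.Edge("X1", "Y0", 1.0),
                ss.Edge("Y0", "X0", 1.0),
            ],
        )
        with pytest.raises(ValueError, match="boundary"):
            ss.SensingSetup(sch, frozenset(["Y0"]), 100, 1.0)


class TestNestedHysteresis:
    def test_single_site_reduces_to_simple_binding(self):
        for s, q in [(10.0, 1.0), (1e4, 0.01)]:
            sch = ss.make_nested_hysteresis(n=1, s=s, q=q)
            for x in (0.5, 2.0):
                pi = ss.steady_state_linear(sch, x)
                assert pi[sch.index("1")] == pytest.approx(x / (1 + x), rel=1e-12)

    def test_fig_parameters_give_usable_scheme(self):
        sch = ss.make_nested_hysteresis(n=3, s=10.0)
        assert sch.is_strongly_connected()
        assert ss.validate_scheme(sch).is_valid
        ss.steady_state_linear(sch, 2.0)

    def test_site2_marginal_converges_to_squared_hill(self):
        sch = ss.make_nested_hysteresis(n=2, s=1e4, q=1.0)
        for x in (0.5, 1.0, 2.0):
            pi = ss.steady_state_linear(sch, x)
            marg = sum(p for st, p in zip(sch.states, pi) if st[1] == "1")
            assert marg == pytest.approx(x**2 / (1 + x**2), rel=1e-2)

    def test_exact_limit_at_unit_concentration(self):
        for n in (1, 2, 4):
            _, pi_all = ss.nested_hysteresis_exact(n, 1.0, 1.0)
            assert pi_all == pytest.approx(2.0**-n, rel=1e-12)

    def test_exact_limit_geometric_sum_value(self):
        _, pi_all = ss.nested_hysteresis_exact(3, 2.0, 1.0)
        assert pi_all == pytest.approx(128.0 / 255.0, rel=1e-14)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_scheme_converges_to_exact_limit(self, n):
        sch = ss.make_nested_hysteresis(n=n, s=1e4, q=1.0)
        for x in (0.5, 1.0, 2.0):
            pi = ss.steady_state_linear(sch, x)
            marg, pi_all = ss.nested_hysteresis_exact(n, x, 1.0)
            assert pi[sch.index("1" * n)] == pytest.approx(pi_all, rel=1e-2)
            for i in range(n):
                sim = sum(p for st, p in zip(sch.states, pi) if st[i] == "1")
                assert sim == pytest.approx(marg[i], abs=1e-2)

    def test_stabilized_limit_approaches_hill(self):
        # q -> 0: pi_all(x) -> x^7/(K^7 + x^7) with K = 1
        n, q = 3, 1e-8
        for x in (0.5, 0.9, 1.1, 2.0):
            _, pi_all = ss.nested_hysteresis_exact(n, x, q)
            hill = x**7 / (1 + x**7)
            assert pi_all == pytest.approx(hill, rel=1e-4)

    def test_binding_definition_exceeds_one_for_gated_scheme(self):
        sch = ss.make_nested_hysteresis(n=2, s=1e4, q=1.0)
        assert ss.hill_binding(sch, 0.5).value > 1.0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ss.NestedHysteresisSpec(0, 10.0)
        with pytest.raises(ValueError):
            ss.NestedHysteresisSpec(2, 0.5)
        with pytest.raises(ValueError):
            ss.NestedHysteresisSpec(2, 10.0, q=0.0)


class TestFamilyTable:
    def test_support_sizes_by_family(self):
        for n in (1, 2, 3):
            sizes = ss.family_support_sizes(n)
            assert sizes == {"kp_ladder": n, "mwc": 2 * n, "unordered": 2**n - 1}
        # structural counts from actual constructors
        assert ss.support_size(ss.make_mwc_noneq(3, ss.mwc_equilibrium_rates(3))) == 6
        assert ss.support_size(ss.make_hypercube(3)) == 7
        assert ss.support_size(ss.make_hopfield_kp([1] * 6)) == 2

    def test_equilibrium_families_respect_equilibrium_bounds(self):
        # KP at equilibrium: nu = 1; MWC/unordered at equilibrium: H <= n
        assert ss.discriminatory_index(
            ss.make_hopfield_kp(ss.hopfield_equilibrium_rates())
        ) == pytest.approx(1.0, abs=1e-10)
        n = 2
        mwc = ss.make_mwc_noneq(n, ss.mwc_equilibrium_rates(n))
        assert ss.hill_binding(mwc, 1.0).value <= n + 1e-9
        db = ss.random_db_binding(n, seed=4)
        assert ss.hill_binding(db, 1.0).value <= n + 1e-9

    def test_constructors_round_trip_through_json(self, tmp_path):
        zoo = [
            ss.make_independent_sites(2),
            ss.make_hypercube(2),
            ss.make_mwc_noneq(2, ss.mwc_equilibrium_rates(2)),
            ss.make_hopfield_kp((1, 2, 3, 4, 5, 6)),
            ss.make_nested_hysteresis(n=2, s=10.0, q=0.5),
        ]
        for i, sch in enumerate(zoo):
            assert ss.validate_scheme(sch).is_valid
            p = tmp_path / f"zoo{i}.json"
            ss.write_scheme(sch, p)
            back = ss.read_scheme(p)
            assert back.states == sch.states
            assert [
                (e.src, e.dst, e.base_rate, e.x_power) for e in back.edges
            ] == [(e.src, e.dst, e.base_rate, e.x_power) for e in sch.edges]
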