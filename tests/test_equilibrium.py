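"""Closed-form mass-action algebra against examples and a bisection oracle."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from eqshift import (
    InconsistentMeasurementError,
    InfeasibilityError,
    InvalidInputError,
    ReactionSystem,
    conversion_after_hydrolysis,
    equilibrium_state,
    estimate_K_from_equilibrium,
    hydrolyzed_amount,
    hydrolyzed_amount_joint,
    max_shift,
    solve_equilibrium_conversion,
)
from _oracles import bisect_conversion

systems = st.tuples(
    st.floats(0.1, 10.0),  # N0 (mM)
    st.floats(1.0, 20.0),  # phosphate equivalents P0/N0
    st.floats(0.01, 1.0),  # K
).map(lambda t: ReactionSystem(N0=t[0], P0=t[1] * t[0], K=t[2]))


class TestSolveEquilibriumConversion:
    @pytest.mark.parametrize(
        "N0, P0, K, expected",
        [
            (2.0, 8.0, 0.15, 0.5077803414648046),  # 50 % conversion, ~1 mM each
            (1.0, 2.5, 0.15, 0.42367114149483953),
            (2.0, 8.0, 1e-12, 0.0),  # products infinitely disfavored
        ],
    )
    def test_examples(self, N0, P0, K, expected):
        c1 = solve_equilibrium_conversion(ReactionSystem(N0, P0, K))
        assert c1 == pytest.approx(expected, abs=1e-5)

    def test_demonstration_system_generates_one_mM(self, uridine_system):
        c1 = solve_equilibrium_conversion(uridine_system)
        assert round(c1 * uridine_system.N0, 1) == 1.0

    def test_k_equal_one_linear_degeneracy(self):
        system = ReactionSystem(N0=1.0, P0=4.0, K=1.0)
        c = solve_equilibrium_conversion(system)
        assert equilibrium_state(system).mass_action_ratio() == pytest.approx(
            1.0, rel=1e-9
        )
        assert c == pytest.approx(bisect_conversion(1.0, 4.0, 1.0), abs=1e-10)

    @pytest.mark.parametrize("N0,P0,K", [(-1, 8, 0.15), (2, 0, 0.15), (2, 8, -0.1)])
    def test_invalid_inputs(self, N0, P0, K):
        with pytest.raises(InvalidInputError):
            ReactionSystem(N0, P0, K)


class TestEstimateK:
    def test_half_conversion_closed_form(self):
        # c1=0.5, N0=2, P0=8: K = (0.25*2)/(0.5*7) = 1/7
        assert estimate_K_from_equilibrium(0.5, 2.0, 8.0) == pytest.approx(1 / 7)

    def test_round_trip_with_solver(self, uridine_system):
        c1 = solve_equilibrium_conversion(uridine_system)
        assert estimate_K_from_equilibrium(c1, 2.0, 8.0) == pytest.approx(
            0.15, rel=1e-9
        )

    def test_zero_conversion_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_K_from_equilibrium(0.0, 2.0, 8.0) == 0.0

    def test_phosphate_exhaustion_is_infeasible(self):
        with pytest.raises(InfeasibilityError):
            estimate_K_from_equilibrium(0.9, 2.0, 1.0)

    def test_full_conversion_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_K_from_equilibrium(1.0, 2.0, 8.0)


class TestHydrolyzedAmount:
    def test_ceiling_means_full_hydrolysis(self, uridine_system):
        # 72 % conversion corresponds to full hydrolysis of the ~1 mM
        # sugar phosphate generated in the first equilibrium
        assert hydrolyzed_amount(0.72, uridine_system) == pytest.approx(
            1.0, abs=2e-3
        )

    def test_unshifted_equilibrium_means_no_loss(self, uridine_system):
        c1 = solve_equilibrium_conversion(uridine_system)
        assert hydrolyzed_amount(c1, uridine_system) == 0.0

    def test_intermediate_conversion(self, uridine_system):
        assert hydrolyzed_amount(0.60, uridine_system) == pytest.approx(
            0.4727272727, rel=1e-9
        )

    def test_below_equilibrium_beyond_tolerance_errors(self, uridine_system):
        with pytest.raises(InconsistentMeasurementError):
            hydrolyzed_amount(0.40, uridine_system)

    def test_slightly_below_equilibrium_clamps_to_zero(self, uridine_system):
        c1 = solve_equilibrium_conversion(uridine_system)
        assert hydrolyzed_amount(c1 - 1e-5, uridine_system) == 0.0

    def test_out_of_range_conversion(self, uridine_system):
        with pytest.raises(InvalidInputError):
            hydrolyzed_amount(1.0, uridine_system)


class TestJointDetermination:
    def test_both_equilibria_recover_K_and_full_hydrolysis(self):
        K, h = hydrolyzed_amount_joint(0.5078, 0.7202, 2.0, 8.0)
        assert K == pytest.approx(0.150, abs=5e-4)
        assert h == pytest.approx(1.0, abs=2e-3)

    def test_no_shift_means_no_hydrolysis(self):
        K, h = hydrolyzed_amount_joint(0.4, 0.4, 2.0, 8.0)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert K == pytest.approx(estimate_K_from_equilibrium(0.4, 2.0, 8.0))

    def test_full_hydrolysis_at_low_ratio(self):
        c1 = 0.42367114149483953
        K, h = hydrolyzed_amount_joint(c1, 0.6278214164626775, 1.0, 2.5)
        assert h == pytest.approx(c1, rel=1e-6)  # h = c1*N0 with N0 = 1

    def test_shift_below_first_equilibrium_errors(self):
        with pytest.raises(InconsistentMeasurementError):
            hydrolyzed_amount_joint(0.6, 0.5, 2.0, 8.0)


class TestMaxShift:
    def test_paper_ceiling_72_percent(self, uridine_system):
        window = max_shift(0.50, uridine_system)
        assert round(window.c2_max * 100) == 72
        assert window.delta_c_max == window.c2_max - 0.50

    def test_full_hydrolysis_round_trip(self, uridine_system):
        c1 = solve_equilibrium_conversion(uridine_system)
        window = max_shift(c1, uridine_system)
        h = hydrolyzed_amount(window.c2_max, uridine_system)
        assert h == pytest.approx(c1 * uridine_system.N0, rel=1e-9)

    def test_no_generated_sugar_phosphate_leaves_equilibrium(self, uridine_system):
        window = max_shift(0.0, uridine_system)
        assert window.c2_max == pytest.approx(
            solve_equilibrium_conversion(uridine_system), rel=1e-12
        )
        assert window.delta_c_max == pytest.approx(window.c2_max)

    def test_low_ratio_shift(self):
        system = ReactionSystem(1.0, 2.5, 0.15)
        c1 = solve_equilibrium_conversion(system)
        window = max_shift(c1, system)
        oracle = bisect_conversion(1.0, 2.5, 0.15, h=c1 * 1.0) - c1
        assert window.delta_c_max == pytest.approx(oracle, abs=1e-10)
        assert window.delta_c_max == pytest.approx(0.204, abs=5e-4)

    def test_invalid_c1(self, uridine_system):
        with pytest.raises(InvalidInputError):
            max_shift(1.0, uridine_system)


class TestConversionAfterHydrolysis:
    def test_zero_hydrolysis_returns_first_equilibrium(self, uridine_system):
        assert conversion_after_hydrolysis(0.0, uridine_system) == pytest.approx(
            solve_equilibrium_conversion(uridine_system), rel=1e-12
        )

    def test_one_millimolar_gives_72_percent(self, uridine_system):
        assert conversion_after_hydrolysis(1.0, uridine_system) == pytest.approx(
            0.7202, abs=5e-5
        )

    def test_round_trip_of_intermediate_amount(self, uridine_system):
        c2 = conversion_after_hydrolysis(0.4727272727, uridine_system)
        assert c2 == pytest.approx(0.600, abs=1e-9)

    def test_negative_amount_rejected(self, uridine_system):
        with pytest.raises(InvalidInputError):
            conversion_after_hydrolysis(-0.1, uridine_system)

    def test_beyond_full_hydrolysis_infeasible(self, uridine_system):
        with pytest.raises(InfeasibilityError):
            conversion_after_hydrolysis(1.5, uridine_system)


class TestProperties:
    @given(system=systems, frac=st.floats(0.0, 1.0))
    def test_round_trip_identity_and_mass_action(self, system, frac):
        """hydrolyzed_amount inverts conversion_after_hydrolysis, and every
        produced state satisfies the mass-action law."""
        c1 = solve_equilibrium_conversion(system)
        h = frac * c1 * system.N0
        c2 = conversion_after_hydrolysis(h, system)
        tiny = 1e-12 * system.N0  # roundoff head-room only
        assert hydrolyzed_amount(c2, system, clamp_tol=tiny) == pytest.approx(
            h, rel=1e-9, abs=1e-9 * system.N0
        )
        state = equilibrium_state(system, h=h)
        if min(state.P1P, state.B, state.N, state.P) > 1e-12 * system.N0:
            assert state.mass_action_ratio() == pytest.approx(
                system.K, rel=1e-9
            )

    @given(system=systems, frac=st.floats(0.0, 1.0))
    def test_conservation(self, system, frac):
        """B + N = N0 and P + B - h = P0 exactly at every state."""
        c1 = solve_equilibrium_conversion(system)
        h = frac * c1 * system.N0
        state = equilibrium_state(system, h=h)
        assert state.B + state.N == pytest.approx(system.N0, rel=1e-12)
        assert state.P + state.B - state.h == pytest.approx(
            system.P0, rel=1e-12
        )

    @given(system=systems)
    def test_monotonicity(self, system):
        """h(c2) strictly increases on (c1, c2_max]; c2(h) on [0, c1*N0]."""
        c1 = solve_equilibrium_conversion(system)
        window = max_shift(c1, system)
        n = 9
        hs = [i / (n - 1) * c1 * system.N0 for i in range(n)]
        c2s = [conversion_after_hydrolysis(h, system) for h in hs]
        assert all(b > a for a, b in zip(c2s, c2s[1:]))
        grid = [
            c1 + (window.c2_max - c1) * (i + 1) / n for i in range(n)
        ]
        hs_back = [
            hydrolyzed_amount(c, system, clamp_tol=1e-12 * system.N0)
            for c in grid
        ]
        assert all(b > a for a, b in zip(hs_back, hs_back[1:]))

    @given(system=systems)
    def test_K_round_trip(self, system):
        c1 = solve_equilibrium_conversion(system)
        K = estimate_K_from_equilibrium(c1, system.N0, system.P0)
        assert K == pytest.approx(system.K, rel=1e-9)

    @given(system=systems, frac=st.floats(0.0, 1.0))
    def test_oracle_equivalence(self, system, frac):
        """Closed-form roots agree with bisection on the mass-action
        residual to 1e-8."""
        c1 = solve_equilibrium_conversion(system)
        assert c1 == pytest.approx(
            bisect_conversion(system.N0, system.P0, system.K), abs=1e-8
        )
        h = frac * c1 * system.N0
        assert conversion_after_hydrolysis(h, system) == pytest.approx(
            bisect_conversion(system.N0, system.P0, system.K, h=h), abs=1e-8
        )
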