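"""Closed-form steady state: frozen oracle values, special cases, thresholds.

The independent oracle used to freeze the expected values solves the
steady-state balance equations of the reaction scheme directly — a
sympy exact-rational linear solve of the chain equations plus the
binding quadratic — without ever forming the cumulative-product
recursion that the implementation uses.  See ``_exact_steady_state``.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kprchain import (
    CellContext,
    basic_kpr_cn,
    constant_schedule,
    koff_mckeithan,
    ligand_threshold,
    mckeithan_cn,
    steady_state_solve,
)
from kprchain.experiments import foreign_schedule, self_schedule
from kprchain.schedules import RateSchedule

from conftest import random_schedule


def _exact_steady_state(koff, kp, T_T, P_T, k_on):
    """Independent oracle: solve the chain balance equations by matrix solve.

    Works in exact rationals via sympy: for the bound subsystem with
    C_0 = 1, solve the full linear system  A x = b  assembled directly
    from the reaction scheme (no recursion), then impose the binding
    balance  k_on (P_T - S C_0)(T_T - S C_0) = (koff0 + kp0) C_0  where
    S = sum_i x_i, and take the physical root.
    """
    import sympy as sp

    N = len(kp)
    koff = [sp.Rational(Fraction(v).limit_denominator(10**12)) for v in koff]
    kp = [sp.Rational(Fraction(v).limit_denominator(10**12)) for v in kp]
    # unknowns x_1..x_N are C_i / C_0
    A = sp.zeros(N, N)
    b = sp.zeros(N, 1)
    for i in range(1, N + 1):
        row = i - 1
        drain = koff[i] + (kp[i] if i < N else 0)
        A[row, row] = drain
        if i >= 2:
            A[row, i - 2] = -kp[i - 1]
        else:
            b[row] = kp[0]
    x = A.LUsolve(b)
    S = 1 + sum(x)  # C_T / C_0
    c0 = sp.symbols("c0", positive=True)
    eq = sp.Eq(k_on * (P_T - S * c0) * (T_T - S * c0), (koff[0] + kp[0]) * c0)
    roots = sp.solve(eq, c0)
    phys = [r for r in roots if 0 < S * r <= min(T_T, P_T)]
    C0 = min(phys)
    return np.array([float(C0)] + [float(C0 * xi) for xi in x])


def test_foreign_chain_matches_exact_rational_oracle(foreign_n4, ctx_saturating):
    C_exact = _exact_steady_state(
        foreign_n4.koff, foreign_n4.kp, 20000, 10**7, Fraction(5, 100000)
    )
    sol = steady_state_solve(foreign_n4, ctx_saturating)
    assert np.allclose(sol.C, C_exact, rtol=1e-9)


class TestForeignN4Intermediates:
    """Frozen high-precision values for the N=4 foreign chain."""

    @pytest.fixture(autouse=True)
    def _solve(self, foreign_n4, ctx_saturating):
        self.sol = steady_state_solve(foreign_n4, ctx_saturating)

    def test_step_ratios_and_cumulative_products(self):
        assert self.sol.alpha[0] == pytest.approx(0.617647058824, rel=1e-9)
        assert self.sol.gamma[-1] == pytest.approx(0.384615384615, rel=1e-9)

    def test_aggregates(self):
        assert self.sol.mu == pytest.approx(5.18054298643, rel=1e-9)
        assert self.sol.delta == pytest.approx(0.522665734999, rel=1e-9)
        assert self.sol.epsilon == pytest.approx(5790.89876845, rel=1e-9)
        assert self.sol.C_T == pytest.approx(19988.4017358, rel=1e-9)
        assert self.sol.C_N == pytest.approx(10447.2526847, rel=1e-9)


def test_self_chain_n4(self_n4, ctx_saturating):
    assert steady_state_solve(self_n4, ctx_saturating).C_N == pytest.approx(
        681.693021124, rel=1e-9
    )


def test_conservation_and_structure(foreign_n4, ctx_saturating):
    sol = steady_state_solve(foreign_n4, ctx_saturating)
    assert np.all(sol.C >= 0)
    assert sol.C.sum() == pytest.approx(sol.C_T, rel=1e-9)
    assert sol.C[0] == pytest.approx(sol.C_T / sol.mu, rel=1e-12)
    assert sol.C_N == pytest.approx(sol.delta * sol.C_T, rel=1e-12)
    assert 0 <= sol.C_T <= min(ctx_saturating.T_T, ctx_saturating.P_T)


def test_printed_recursion_differs_unless_kp_constant(foreign_n4, ctx_saturating):
    ma = steady_state_solve(foreign_n4, ctx_saturating, recursion="mass_action")
    pr = steady_state_solve(foreign_n4, ctx_saturating, recursion="printed")
    assert abs(pr.C_N - ma.C_N) / ma.C_N > 0.05  # genuinely different solutions
    const = constant_schedule(0.5, 1.0, 6)
    ma = steady_state_solve(const, ctx_saturating, recursion="mass_action")
    pr = steady_state_solve(const, ctx_saturating, recursion="printed")
    assert ma.C_N == pytest.approx(pr.C_N, rel=1e-12)


class TestClassicLimit:
    """Constant-rate chains collapse to the classic proofreading formulas."""

    def test_alpha_and_epsilon(self, ctx_saturating):
        sched = constant_schedule(0.5, 1.0, 8)
        sol = steady_state_solve(sched, ctx_saturating)
        assert np.allclose(sol.alpha, 1.0 / (1.0 + 0.5))
        assert sol.epsilon == pytest.approx(0.5 / ctx_saturating.k_on, rel=1e-12)

    @pytest.mark.parametrize("N, expected", [(4, 3946.7), (10, 346.5)])
    def test_closed_form_values(self, ctx_saturating, N, expected):
        assert basic_kpr_cn(0.5, 1.0, N, ctx_saturating) == pytest.approx(expected, abs=0.05)

    def test_closed_form_equals_general_solver(self, ctx_saturating):
        for N in (1, 3, 10):
            sched = constant_schedule(0.5, 1.0, N)
            for rec in ("mass_action", "printed"):
                sol = steady_state_solve(sched, ctx_saturating, recursion=rec)
                assert basic_kpr_cn(0.5, 1.0, N, ctx_saturating) == pytest.approx(
                    sol.C_N, rel=1e-9
                )

    def test_zero_steps_degenerates_to_occupancy(self, ctx_saturating):
        cn = basic_kpr_cn(0.5, 1.0, 0, ctx_saturating)
        sol = steady_state_solve(constant_schedule(0.5, 1.0, 1), ctx_saturating)
        assert cn == pytest.approx(sol.C_T, rel=1e-6)  # alpha^0 * C_T


class TestMcKeithan:
    def test_c_equal_one_is_classic(self, ctx_saturating):
        assert mckeithan_cn(0.5, 1.0, 1.0, 12, ctx_saturating) == pytest.approx(
            basic_kpr_cn(0.5, 1.0, 12, ctx_saturating), rel=1e-12
        )

    def test_c_to_zero_limit_accumulates_everything(self, ctx_saturating):
        cn = mckeithan_cn(0.5, 1.0, 1e-12, 12, ctx_saturating)
        sched = RateSchedule(koff=koff_mckeithan(0.5, 1e-12, 12), kp=np.ones(12))
        sol = steady_state_solve(sched, ctx_saturating)
        assert cn == pytest.approx(sol.C_T, rel=1e-6)

    def test_frozen_value_n20(self, ctx_saturating):
        assert mckeithan_cn(0.5, 1.0, 0.2, 20, ctx_saturating) == pytest.approx(
            30.0067037019, rel=1e-9
        )

    def test_equals_general_solver_on_step_schedule(self, ctx_saturating):
        sched = RateSchedule(koff=koff_mckeithan(0.5, 0.2, 20), kp=np.ones(20))
        sol = steady_state_solve(sched, ctx_saturating)
        assert mckeithan_cn(0.5, 1.0, 0.2, 20, ctx_saturating) == pytest.approx(
            sol.C_N, rel=1e-9
        )


class TestLigandThreshold:
    @pytest.mark.parametrize(
        "schedule_factory, expected",
        [
            (lambda: foreign_schedule(tau=2.0, N=10, constant_kp=True), 9.240803931),
            (lambda: self_schedule(tau=2.0, N=10, constant_kp=True), 819.752139),
            (lambda: foreign_schedule(tau=2.0, N=10), 4.751881188),
            (lambda: self_schedule(tau=4.0, N=10), 758.221975),
        ],
    )
    def test_frozen_threshold_values(self, schedule_factory, expected):
        res = ligand_threshold(schedule_factory())
        assert res.reachable
        assert res.P_T_min == pytest.approx(expected, rel=1e-8)

    def test_broken_chain_is_unreachable(self):
        res = ligand_threshold(self_schedule(tau=2.0, N=10))
        assert not res.reachable and res.P_T_min is None
        assert str(res) == ">10^9"

    def test_round_trip_forward_evaluation(self):
        """Solving at P_T = P_T_min must give back exactly the target C_N."""
        for sched in (foreign_schedule(), self_schedule(tau=4.0),
                      foreign_schedule(constant_kp=True)):
            res = ligand_threshold(sched, target_CN=1.0)
            sol = steady_state_solve(sched, CellContext(P_T=res.P_T_min))
            assert sol.C_N == pytest.approx(1.0, rel=1e-6)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            ligand_threshold(foreign_schedule(), target_CN=0.0)


def test_terminal_response_decreases_with_chain_length(ctx_saturating):
    values = [basic_kpr_cn(0.5, 1.0, N, ctx_saturating) for N in range(1, 15)]
    assert np.all(np.diff(values) < 0)


def test_terminal_response_decreases_with_koff(ctx_saturating):
    values = [basic_kpr_cn(k, 1.0, 8, ctx_saturating) for k in (0.1, 0.3, 0.5, 1.0, 2.0)]
    assert np.all(np.diff(values) < 0)


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_random_chain_conservation_and_bounds(seed):
    """Sum rule, positivity and occupancy bound hold for arbitrary chains."""
    rng = np.random.default_rng(seed)
    sched = random_schedule(rng, int(rng.integers(1, 7)))
    ctx = CellContext(T_T=1000.0, P_T=float(rng.uniform(1, 5000)), k_on=1e-3)
    sol = steady_state_solve(sched, ctx)
    assert np.all(sol.C >= 0)
    assert sol.C.sum() == pytest.approx(sol.C_T, rel=1e-9)
    assert sol.C_T <= min(ctx.T_T, ctx.P_T) * (1 + 1e-12)
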