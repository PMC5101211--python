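"""Closed-form steady state of the generalized proofreading chain.

At steady state the chain obeys a backward recursion: writing
``alpha_i = kp(i-1) / (kp(i) + koff(i))`` for the intermediate complexes
(each ``C_i`` with ``1 <= i <= N-1`` drains both by dissociation and by
propagation to ``C_{i+1}``), the complex abundances are

    C_i  = gamma_i * C_0,      gamma_i = alpha_1 * ... * alpha_i
    C_N  = delta * C_T
    mu   = C_T / C_0 = 1 + (kp[N-1]/koff[N]) * gamma_{N-1} + sum_i gamma_i
    eps  = (koff[0] + kp[0]) / (kon * mu)

and the total occupancy ``C_T`` is the physical (smaller) root of the
receptor-ligand binding quadratic

    C_T^2 - (T_T + P_T + eps) C_T + T_T P_T = 0.

An alternative recursion with denominator ``kp(i-1) + koff(i)``
(``recursion="printed"``) is retained for comparison; the two coincide
whenever ``kp`` is constant along the chain.  The mass-action form is the
default: it is the steady state of the chain's rate equations and is the
one consistent with the reference response tables.

Special cases: with constant rates the solution collapses to the classic
proofreading result ``C_N = alpha^N C_T`` with ``alpha = kp/(kp+koff)``
and ``eps = K_D = koff/kon``; with a single stabilized terminal complex
(``koff(N) = c*koff``) it collapses to McKeithan's modification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .schedules import RateSchedule

__all__ = [
    "CellContext",
    "SteadyStateSolution",
    "ThresholdResult",
    "steady_state_solve",
    "basic_kpr_cn",
    "mckeithan_cn",
    "ligand_threshold",
]


@dataclass(frozen=True)
class CellContext:
    """Per-cell molecular totals and the binding rate constant.

    Parameters
    ----------
    T_T : float
        Total number of receptors per cell.
    P_T : float
        Total number of pMHC ligands per cell.
    k_on : float
        Association rate constant, (molecule * s)^-1.  All amounts are
        molecule counts per cell, so no volume conversion is involved.
    """

    T_T: float = 2.0e4
    P_T: float = 1.0e7
    k_on: float = 5.0e-5

    def __post_init__(self) -> None:
        if not (self.T_T > 0 and math.isfinite(self.T_T)):
            raise ValueError("T_T must be positive")
        if not (self.P_T >= 0 and math.isfinite(self.P_T)):
            raise ValueError("P_T must be non-negative")
        if not (self.k_on > 0 and math.isfinite(self.k_on)):
            raise ValueError("k_on must be positive")

    def K_D(self, koff0: float) -> float:
        """Dissociation constant of the initial complex, ``koff(0)/k_on``."""
        return koff0 / self.k_on


def _chain_factors(schedule: RateSchedule, recursion: str):
    """alpha, gamma, mu, delta for a schedule; P_T-independent."""
    koff, kp, N = schedule.koff, schedule.kp, schedule.N
    if recursion == "mass_action":
        denom = kp[1:N] + koff[1:N]
    elif recursion == "printed":
        denom = kp[0 : N - 1] + koff[1:N]
    else:
        raise ValueError(f"recursion must be 'mass_action' or 'printed', got {recursion!r}")
    alpha = kp[0 : N - 1] / denom  # alpha_1 .. alpha_{N-1}
    gamma = np.cumprod(alpha)  # gamma_1 .. gamma_{N-1}
    g_last = gamma[-1] if N > 1 else 1.0  # empty product for N = 1
    tail = (kp[N - 1] / koff[N]) * g_last
    mu = 1.0 + tail + gamma.sum()
    delta = tail / mu
    return alpha, gamma, mu, delta


def _occupancy_root(T_T: float, P_T: float, eps: float) -> float:
    """Smaller root of ``x^2 - (T_T+P_T+eps) x + T_T P_T = 0``.

    Evaluated as ``2*T_T*P_T / (S + sqrt(S^2 - 4*T_T*P_T))`` which avoids
    the catastrophic cancellation of the textbook form when
    ``eps << T_T + P_T``.
    """
    S = T_T + P_T + eps
    disc = S * S - 4.0 * P_T * T_T
    # disc = (T_T - P_T)^2 + eps^2 + 2*eps*(T_T + P_T) >= 0 always
    assert disc >= 0.0, "binding quadratic has no real root (invalid inputs)"
    if P_T == 0.0:
        return 0.0
    return 2.0 * P_T * T_T / (S + math.sqrt(disc))


@dataclass(frozen=True)
class SteadyStateSolution:
    """All steady-state quantities of one chain in one cellular context."""

    schedule: RateSchedule
    context: CellContext
    recursion: str
    alpha: np.ndarray  # step ratios alpha_1 .. alpha_{N-1}
    gamma: np.ndarray  # cumulative products gamma_1 .. gamma_{N-1}
    mu: float  # C_T / C_0
    delta: float  # C_N / C_T
    epsilon: float  # effective dissociation scale in the binding quadratic
    C_T: float  # total bound complexes
    C: np.ndarray  # abundances C_0 .. C_N

    @property
    def C_N(self) -> float:
        """Abundance of the terminal (productive) complex."""
        return float(self.C[-1])

    @property
    def fraction_bound(self) -> float:
        """Steady-state productive fraction ``C_N / P_T``."""
        return self.C_N / self.context.P_T

    def summary(self) -> str:
        lines = [
            "Generalized proofreading chain - steady state",
            f"  N = {self.schedule.N}, recursion = {self.recursion}",
            f"  T_T = {self.context.T_T:g}, P_T = {self.context.P_T:g}, "
            f"k_on = {self.context.k_on:g}",
            f"  mu = {self.mu:.6g}   delta = {self.delta:.6g}   "
            f"epsilon = {self.epsilon:.6g}",
            f"  C_T = {self.C_T:.6g}   C_N = {self.C_N:.6g}",
        ]
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"i": np.arange(len(self.C)), "C_i": self.C})

    def to_json(self) -> str:
        return json.dumps(
            {
                "recursion": self.recursion,
                "alpha": self.alpha.tolist(),
                "gamma": self.gamma.tolist(),
                "mu": self.mu,
                "delta": self.delta,
                "epsilon": self.epsilon,
                "C_T": self.C_T,
                "C": self.C.tolist(),
            }
        )


def steady_state_solve(
    schedule: RateSchedule,
    ctx: CellContext,
    recursion: str = "mass_action",
) -> SteadyStateSolution:
    """Solve the chain at steady state in closed form.

    Parameters
    ----------
    schedule : RateSchedule
        Per-step rate constants.
    ctx : CellContext
        Receptor/ligand totals and binding rate constant.
    recursion : {"mass_action", "printed"}
        Step-ratio convention for the intermediate complexes (see module
        docstring).  ``mass_action`` is the steady state of the chain's
        rate equations and the default.

    Returns
    -------
    SteadyStateSolution
    """
    alpha, gamma, mu, delta = _chain_factors(schedule, recursion)
    eps = (schedule.koff[0] + schedule.kp[0]) / (ctx.k_on * mu)
    C_T = _occupancy_root(ctx.T_T, ctx.P_T, eps)
    C0 = C_T / mu
    C = np.concatenate(([C0], gamma * C0, [delta * C_T]))
    return SteadyStateSolution(
        schedule=schedule,
        context=ctx,
        recursion=recursion,
        alpha=alpha,
        gamma=gamma,
        mu=mu,
        delta=delta,
        epsilon=eps,
        C_T=C_T,
        C=C,
    )


def basic_kpr_cn(koff: float, kp: float, N: int, ctx: CellContext) -> float:
    """Terminal response of the constant-rate chain, ``C_N = alpha^N C_T``.

    ``alpha = kp/(kp+koff)`` and ``C_T`` solves the binding quadratic with
    ``eps = K_D = koff/k_on``.  ``N = 0`` degenerates to plain receptor
    occupancy (``C_N = C_T``).
    """
    if koff <= 0 or kp <= 0:
        raise ValueError("koff and kp must be positive")
    if N < 0:
        raise ValueError("N must be >= 0")
    alpha = kp / (kp + koff)
    C_T = _occupancy_root(ctx.T_T, ctx.P_T, ctx.K_D(koff))
    return alpha**N * C_T


def mckeithan_cn(koff: float, kp: float, c: float, N: int, ctx: CellContext) -> float:
    """Terminal response with a ``c``-fold stabilized productive complex.

    The chain is constant except ``koff(N) = c*koff`` with ``0 < c <= 1``.
    The closed form is ``C_N = alpha^N C_T / (alpha^N + c (1 - alpha^N))``
    with the occupancy quadratic driven by
    ``eps = c K_D / (alpha^N + c (1 - alpha^N))``.  ``c = 1`` recovers the
    constant chain; as ``c -> 0`` the whole bound pool accumulates in the
    terminal complex (``C_N -> C_T``).
    """
    if koff <= 0 or kp <= 0:
        raise ValueError("koff and kp must be positive")
    if not (0.0 < c <= 1.0):
        raise ValueError(f"c must satisfy 0 < c <= 1, got {c!r}")
    if N < 1:
        raise ValueError("N must be >= 1")
    alpha = kp / (kp + koff)
    aN = alpha**N
    share = aN + c * (1.0 - aN)
    eps = c * ctx.K_D(koff) / share
    C_T = _occupancy_root(ctx.T_T, ctx.P_T, eps)
    return aN * C_T / share


@dataclass(frozen=True)
class ThresholdResult:
    """Minimum ligand count for a productive response, or unreachable.

    ``reachable`` is False when even full receptor saturation cannot put
    ``target_CN`` complexes into the terminal state (``target_CN/delta >=
    T_T``); the chain is then said to be broken for that ligand.
    """

    P_T_min: float | None
    target_CN: float
    reachable: bool

    def __str__(self) -> str:
        if not self.reachable:
            return ">10^9"
        return f"{self.P_T_min:.6g}"


def ligand_threshold(
    schedule: RateSchedule,
    T_T: float = 2.0e4,
    k_on: float = 5.0e-5,
    target_CN: float = 1.0,
    recursion: str = "mass_action",
) -> ThresholdResult:
    """Minimum ``P_T`` at which the steady state reaches ``C_N = target_CN``.

    ``delta``, ``mu`` and ``eps`` do not depend on ``P_T``, so the binding
    quadratic can be inverted exactly: with ``C_T* = target_CN/delta``,

        P_T_min = C_T* (T_T + eps - C_T*) / (T_T - C_T*).

    Returns an unreachable result when ``C_T* >= T_T``.
    """
    if target_CN <= 0:
        raise ValueError("target_CN must be positive")
    _, _, mu, delta = _chain_factors(schedule, recursion)
    eps = (schedule.koff[0] + schedule.kp[0]) / (k_on * mu)
    C_T_star = target_CN / delta
    if C_T_star >= T_T:
        return ThresholdResult(P_T_min=None, target_CN=target_CN, reachable=False)
    P_T_min = C_T_star * (T_T + eps - C_T_star) / (T_T - C_T_star)
    return ThresholdResult(P_T_min=float(P_T_min), target_CN=target_CN, reachable=True)
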