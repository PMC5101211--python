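"""Convenience model object tying a schedule to a cellular context."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinetics import TimeCourse, simulate
from .schedules import RateSchedule, ScheduleSpec, build_schedule
from .steady_state import (
    CellContext,
    SteadyStateSolution,
    ThresholdResult,
    ligand_threshold,
    steady_state_solve,
)

__all__ = ["ProofreadingChain"]


@dataclass(frozen=True)
class ProofreadingChain:
    """A proofreading chain embedded in one cell.

    Thin object wrapper over the functional layers: holds a
    :class:`RateSchedule` plus a :class:`CellContext` and exposes the
    steady-state solution, ODE time course and ligand-threshold solvers
    as methods.

    Examples
    --------
    >>> from kprchain import ProofreadingChain, ScheduleSpec
    >>> chain = ProofreadingChain.from_spec(
    ...     ScheduleSpec(N=10, tau=2.0, koff_family="hyperbolic", r_koff=2.5,
    ...                  kp_family="hyperbolic", r_kp=0.5))
    >>> round(chain.steady_state().C_N, 1)
    5391.1
    """

    schedule: RateSchedule
    context: CellContext = CellContext()

    @classmethod
    def from_spec(cls, spec: ScheduleSpec, context: CellContext | None = None):
        return cls(schedule=build_schedule(spec), context=context or CellContext())

    def with_context(self, **kwargs) -> "ProofreadingChain":
        """Copy of this chain with updated context fields (T_T, P_T, k_on)."""
        return ProofreadingChain(self.schedule, replace(self.context, **kwargs))

    @property
    def N(self) -> int:
        return self.schedule.N

    def steady_state(self, recursion: str = "mass_action") -> SteadyStateSolution:
        return steady_state_solve(self.schedule, self.context, recursion=recursion)

    def simulate(self, t_end: float, output_times: np.ndarray | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> TimeCourse:
        return simulate(self.schedule, self.context, t_end, output_times, rtol=rtol, atol=atol)

    def ligand_threshold(self, target_CN: float = 1.0,
                         recursion: str = "mass_action") -> ThresholdResult:
        return ligand_threshold(
            self.schedule,
            T_T=self.context.T_T,
            k_on=self.context.k_on,
            target_CN=target_CN,
            recursion=recursion,
        )
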