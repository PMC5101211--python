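"""Reference analyses: response tables, sensitivity and specificity grids.

Everything here is a deterministic function of model parameters.  The
canonical ligand pair used throughout the discrimination analyses shares
a dissociation time (``tau = 2 s`` unless stated): the foreign ligand
stabilizes its complexes (hyperbolic ``koff`` profile, shape ``r = 2.5``)
while accelerating propagation (hyperbolic ``kp``, ``r = 0.5``); the
self ligand is the mirror image (``r = 0.5`` / ``r = 2.5``).  Setting
``constant_kp=True`` removes the propagation modulation and isolates the
effect of the dissociation profile alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import discrimination_ratio, fraction_bound, simulate
from .rebinding import build_default_rho_profile, rebinding_effective_schedule
from .schedules import (
    RateSchedule,
    constant_schedule,
    koff_geometric,
    koff_hyperbolic,
    koff_mckeithan,
    kp_geometric,
    kp_hyperbolic,
)
from .steady_state import CellContext, ligand_threshold, steady_state_solve

__all__ = [
    "foreign_schedule",
    "self_schedule",
    "model_schedule",
    "run_table2",
    "run_table1",
    "run_sensitivity_curve",
    "run_specificity_curve",
]

UNREACHABLE_LABEL = ">10^9"
UNREACHABLE_CUTOFF = 1.0e9

# shape parameters of the canonical foreign/self pair (hyperbolic profiles)
R_KOFF_FOREIGN, R_KP_FOREIGN = 2.5, 0.5
R_KOFF_SELF, R_KP_SELF = 0.5, 2.5
# geometric-profile pair used in the model-comparison analyses
R_GEO_KOFF_FOREIGN, R_GEO_KP_FOREIGN = 0.95, 1.05
R_GEO_KOFF_SELF, R_GEO_KP_SELF = 1.05, 0.95


def foreign_schedule(tau: float = 2.0, N: int = 10, kp0: float = 1.0,
                     constant_kp: bool = False) -> RateSchedule:
    """Canonical foreign-ligand chain (stabilizing koff, accelerating kp)."""
    koff = koff_hyperbolic(1.0 / tau, R_KOFF_FOREIGN, N)
    kp = np.full(N, kp0) if constant_kp else kp_hyperbolic(kp0, R_KP_FOREIGN, N)
    return RateSchedule(koff=koff, kp=kp)


def self_schedule(tau: float = 2.0, N: int = 10, kp0: float = 1.0,
                  constant_kp: bool = False) -> RateSchedule:
    """Canonical self-ligand chain (destabilizing koff, decelerating kp)."""
    koff = koff_hyperbolic(1.0 / tau, R_KOFF_SELF, N)
    kp = np.full(N, kp0) if constant_kp else kp_hyperbolic(kp0, R_KP_SELF, N)
    return RateSchedule(koff=koff, kp=kp)


def model_schedule(model: str, tau: float, N: int | None = None, kp0: float = 1.0,
                   c: float = 0.2) -> RateSchedule:
    """Schedule for one of the comparison models at dissociation time ``tau``.

    ``model`` is one of ``kpr`` (constant rates), ``mckeithan`` (terminal
    complex stabilized ``c``-fold), ``rebinding`` / ``rebinding25``
    (constant chain with the default rebinding profile folded into
    effective off-rates; N defaults to 20 and 25 respectively),
    ``general-foreign`` / ``general-self`` (geometric koff with
    hyperbolic kp, the position-dependent chains of the comparison
    figures).
    """
    koff0 = 1.0 / tau
    if model == "kpr":
        return constant_schedule(koff0, kp0, N or 20)
    if model == "mckeithan":
        n = N or 20
        return RateSchedule(koff=koff_mckeithan(koff0, c, n), kp=np.full(n, kp0))
    if model in ("rebinding", "rebinding25"):
        n = N or (25 if model == "rebinding25" else 20)
        base = constant_schedule(koff0, kp0, n)
        return rebinding_effective_schedule(base, build_default_rho_profile(n))
    if model == "general-foreign":
        n = N or 20
        return RateSchedule(koff=koff_geometric(koff0, R_GEO_KOFF_FOREIGN, n),
                            kp=kp_geometric(kp0, R_GEO_KP_FOREIGN, n))
    if model == "general-self":
        n = N or 20
        return RateSchedule(koff=koff_geometric(koff0, R_GEO_KOFF_SELF, n),
                            kp=kp_geometric(kp0, R_GEO_KP_SELF, n))
    raise ValueError(f"unknown model {model!r}")


def run_table2(N_values=range(4, 21, 2), tau: float = 2.0,
               ctx: CellContext | None = None) -> pd.DataFrame:
    """Steady-state terminal response versus chain length.

    Columns: foreign and self chains of the canonical hyperbolic pair and
    the constant-rate baseline, all at saturating ligand numbers
    (``P_T = 1e7`` by default) so the differences reflect the
    transmission power of the chain rather than ligand scarcity.
    """
    ctx = ctx or CellContext()
    rows = []
    for N in N_values:
        cn_f = steady_state_solve(foreign_schedule(tau, N), ctx).C_N
        cn_s = steady_state_solve(self_schedule(tau, N), ctx).C_N
        cn_k = steady_state_solve(constant_schedule(1.0 / tau, 1.0, N), ctx).C_N
        rows.append({"N": N, "CN_foreign": cn_f, "CN_self": cn_s, "CN_kpr": cn_k})
    return pd.DataFrame(rows)


def _threshold_field(schedule: RateSchedule, T_T: float, k_on: float):
    res = ligand_threshold(schedule, T_T=T_T, k_on=k_on)
    if not res.reachable or res.P_T_min > UNREACHABLE_CUTOFF:
        return np.inf
    return res.P_T_min


def run_table1(tau_pairs=((2.0, 2.0), (2.0, 4.0), (4.0, 2.0)), N: int = 10,
               t: float = 10.0, T_T: float = 2.0e4, k_on: float = 5.0e-5,
               P_T_ratio: float = 100.0) -> pd.DataFrame:
    """Discrimination ratios at a threshold time plus ligand thresholds.

    For each (tau_foreign, tau_self) pair: the fold difference of
    productive fractions ``C_N/P_T`` at ``t`` seconds (ODE time courses in
    the low-occupancy regime) and the minimum ligand number for a
    productive steady-state response of each ligand (``inf`` when the
    chain cannot reach one complex at any ligand number; rendered as
    ``>10^9`` by the CLI).
    """
    rows = []
    ctx = CellContext(T_T=T_T, P_T=P_T_ratio, k_on=k_on)
    for tau_f, tau_s in tau_pairs:
        sf, ss = foreign_schedule(tau_f, N), self_schedule(tau_s, N)
        ratio = discrimination_ratio(sf, ss, ctx, t=t)
        rows.append({
            "tau_foreign": tau_f,
            "tau_self": tau_s,
            "ratio_10s": ratio,
            "PT_min_foreign": _threshold_field(sf, T_T, k_on),
            "PT_min_self": _threshold_field(ss, T_T, k_on),
        })
    return pd.DataFrame(rows)


def run_sensitivity_curve(model: str, tau_grid=None, target_CN: float = 1.0,
                          N: int | None = None, T_T: float = 2.0e4,
                          k_on: float = 5.0e-5, c: float = 0.2) -> pd.DataFrame:
    """Minimum ligand number for a productive response versus tau.

    Unreachable entries are reported as ``inf``.
    """
    if tau_grid is None:
        tau_grid = np.linspace(1.0, 20.0, 39)
    rows = []
    for tau in np.asarray(tau_grid, dtype=float):
        sched = model_schedule(model, tau, N=N, c=c)
        res = ligand_threshold(sched, T_T=T_T, k_on=k_on, target_CN=target_CN)
        rows.append({"tau": tau,
                     "PT_min": res.P_T_min if res.reachable else np.inf})
    return pd.DataFrame(rows)


def run_specificity_curve(model: str, taus=(1.0, 2.0, 3.0, 5.0, 10.0, 20.0),
                          t_grid=None, N: int | None = None,
                          ctx: CellContext | None = None, c: float = 0.2) -> pd.DataFrame:
    """Productive fraction ``C_N(t)/P_T`` over time for a set of tau values.

    One column per dissociation time, evaluated in the low-occupancy
    regime.  Within a model, longer-lived ligands bind more productively
    at every time point.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 50.0, 101)
    t_grid = np.asarray(t_grid, dtype=float)
    ctx = ctx or CellContext(P_T=100.0)
    out = {"t": t_grid}
    for tau in taus:
        sched = model_schedule(model, tau, N=N, c=c)
        tc = simulate(sched, ctx, t_end=float(t_grid[-1]), output_times=t_grid)
        out[f"tau_{tau:g}"] = tc.C_N / ctx.P_T
    return pd.DataFrame(out)
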