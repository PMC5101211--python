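"""Induced-rebinding comparison baseline.

In the induced-rebinding picture a ligand that has just dissociated from
``C_i`` stays close to the receptor cluster and may rebind at rate
``rho_i`` before its signaling-competent state decays at rate ``lam``.
The probability that the ligand actually escapes is ``lam/(lam+rho_i)``,
so rebinding is folded into an effective dissociation rate

    koff_eff(i) = koff(i) * lam / (lam + rho_i).

This effective-rate reduction is an approximation used only for the
model-comparison analyses: it reproduces both limiting regimes (rho <<
lam: essentially the plain chain; rho >> lam: ligands trapped, terminal
dissociation suppressed by orders of magnitude) without re-deriving the
full rebinding state space.

The default rebinding profile is flat at 1e3 s^-1 up to position 21 and
ramps to 1e7 s^-1 at position 25; the ramp is log-linear because the
rates span four decades.  The signaling decay rate defaults to 1e4 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedules import RateSchedule

__all__ = ["RebindingProfile", "build_default_rho_profile", "rebinding_effective_schedule"]

RHO_LOW = 1.0e3
RHO_HIGH = 1.0e7
RAMP_START = 21  # last position with the low plateau
RAMP_END = 25  # first position at the high plateau
LAMBDA_DEFAULT = 1.0e4


@dataclass(frozen=True)
class RebindingProfile:
    """Per-position rebinding rates ``rho_i`` and signaling decay ``lam``."""

    rho: np.ndarray
    lam: float = LAMBDA_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        if np.any(self.rho < 0) or not np.all(np.isfinite(self.rho)):
            raise ValueError("all rho entries must be finite and >= 0")
        if not self.lam > 0:
            raise ValueError("lam must be positive")


def build_default_rho_profile(N: int, lam: float = LAMBDA_DEFAULT) -> RebindingProfile:
    """Default rebinding profile for a chain of length ``N``.

    ``rho_i = 1e3`` for ``i <= 21``; log-linear ramp from 1e3 to 1e7 over
    positions 21..25; constant 1e7 beyond.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    i = np.arange(N + 1, dtype=float)
    frac = np.clip((i - RAMP_START) / (RAMP_END - RAMP_START), 0.0, 1.0)
    rho = 10.0 ** (np.log10(RHO_LOW) + frac * (np.log10(RHO_HIGH) - np.log10(RHO_LOW)))
    return RebindingProfile(rho=rho, lam=lam)


def rebinding_effective_schedule(
    base: RateSchedule, profile: RebindingProfile
) -> RateSchedule:
    """Fold rebinding into effective dissociation rates.

    Returns a schedule with ``koff_eff[i] = koff[i]*lam/(lam+rho_i)`` and
    the propagation rates unchanged.  Feeding the result into the
    steady-state or kinetics layer yields the rebinding baseline.
    """
    if len(profile.rho) != base.N + 1:
        raise ValueError(
            f"rho profile length {len(profile.rho)} does not match chain length N+1 = {base.N + 1}"
        )
    attenuation = profile.lam / (profile.lam + profile.rho)
    return RateSchedule(koff=base.koff * attenuation, kp=base.kp.copy())
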