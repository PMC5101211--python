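"""Position-dependent rate-constant profiles along the proofreading chain.

A kinetic-proofreading chain of length ``N`` is parameterized by the
dissociation rate constants ``koff[0..N]`` (each intermediate complex
``C_i`` can release its ligand) and the propagation rate constants
``kp[0..N-1]`` (``kp[i]`` drives the modification ``C_i -> C_{i+1}``).
``koff[0] = 1/tau`` where ``tau`` is the mean lifetime of the initial
receptor-ligand complex ``C_0``.

Profiles are materialized as explicit finite sequences so that the
steady-state and kinetics layers consume one uniform representation;
measured or otherwise custom profiles are therefore first-class citizens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RateSchedule",
    "ScheduleSpec",
    "koff_hyperbolic",
    "kp_hyperbolic",
    "koff_geometric",
    "kp_geometric",
    "koff_mckeithan",
    "constant_schedule",
    "build_schedule",
]

_FAMILIES = ("constant", "hyperbolic", "geometric", "mckeithan", "custom")


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class RateSchedule:
    """Per-step rate constants of one proofreading chain.

    Parameters
    ----------
    koff : sequence of float
        Dissociation rate constants, one per complex ``C_0 .. C_N`` (s^-1).
    kp : sequence of float
        Propagation rate constants, one per step ``C_i -> C_{i+1}``,
        ``i = 0 .. N-1`` (s^-1).
    """

    koff: np.ndarray
    kp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "koff", np.asarray(self.koff, dtype=float))
        object.__setattr__(self, "kp", np.asarray(self.kp, dtype=float))
        if self.koff.ndim != 1 or self.kp.ndim != 1:
            raise ValueError("koff and kp must be one-dimensional sequences")
        if len(self.koff) != len(self.kp) + 1:
            raise ValueError(
                f"length mismatch: need len(koff) == len(kp) + 1, got "
                f"{len(self.koff)} and {len(self.kp)}"
            )
        if len(self.kp) < 1:
            raise ValueError("chain length N must be >= 1")
        if not (np.all(np.isfinite(self.koff)) and np.all(self.koff > 0)):
            raise ValueError("all koff entries must be strictly positive and finite")
        if not (np.all(np.isfinite(self.kp)) and np.all(self.kp > 0)):
            raise ValueError("all kp entries must be strictly positive and finite")

    @property
    def N(self) -> int:
        """Chain length (number of proofreading steps)."""
        return len(self.kp)

    @property
    def tau(self) -> float:
        """Dissociation time of the initial complex, ``1/koff[0]`` (s)."""
        return 1.0 / self.koff[0]

    # -- serialization -------------------------------------------------

    def to_frame(self):
        """Flat tabular form: one row per index ``i`` with ``koff_i, kp_i``.

        ``kp`` has no entry at ``i = N``; that cell is NaN.
        """
        import pandas as pd

        kp = np.append(self.kp, np.nan)
        return pd.DataFrame({"i": np.arange(self.N + 1), "koff_i": self.koff, "kp_i": kp})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateSchedule":
        import pandas as pd

        df = pd.read_csv(path).sort_values("i")
        kp = df["kp_i"].to_numpy()
        return cls(koff=df["koff_i"].to_numpy(), kp=kp[~np.isnan(kp)])

    def to_json(self) -> str:
        return json.dumps({"koff": self.koff.tolist(), "kp": self.kp.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RateSchedule":
        d = json.loads(text)
        return cls(koff=d["koff"], kp=d["kp"])


def koff_hyperbolic(base_koff: float, r: float, N: int) -> np.ndarray:
    """Hyperbolic dissociation profile ``koff(i) = base*(1+i)/(1+r*i)``.

    For ``r > 1`` the profile decreases monotonically from ``base`` toward
    ``base/r`` (complex stabilization, the foreign-ligand regime); for
    ``r < 1`` it increases toward ``base/r`` (destabilization, self-ligand
    regime); ``r = 1`` leaves it constant.
    """
    _check_positive("base_koff", base_koff)
    _check_positive("r", r)
    if N < 1:
        raise ValueError("N must be >= 1")
    i = np.arange(N + 1)
    return base_koff * (1.0 + i) / (1.0 + r * i)


def kp_hyperbolic(base_kp: float, r: float, N: int) -> np.ndarray:
    """Hyperbolic propagation profile ``kp(i) = base*(1+i)/(1+r*i)``.

    Increasing for ``r < 1`` (foreign), decreasing for ``r > 1`` (self).
    Indexed ``i = 0 .. N-1``.
    """
    _check_positive("base_kp", base_kp)
    _check_positive("r", r)
    if N < 1:
        raise ValueError("N must be >= 1")
    i = np.arange(N)
    return base_kp * (1.0 + i) / (1.0 + r * i)


def koff_geometric(base_koff: float, r: float, N: int) -> np.ndarray:
    """Geometric dissociation profile ``koff(i) = base * r**i``.

    For ``r < 1`` rates vanish as the chain progresses (strong
    stabilization); for ``r > 1`` they grow without bound.
    """
    _check_positive("base_koff", base_koff)
    _check_positive("r", r)
    if N < 1:
        raise ValueError("N must be >= 1")
    return base_koff * r ** np.arange(N + 1, dtype=float)


def kp_geometric(base_kp: float, r: float, N: int) -> np.ndarray:
    """Geometric propagation profile ``kp(i) = base * r**i``, ``i = 0..N-1``."""
    _check_positive("base_kp", base_kp)
    _check_positive("r", r)
    if N < 1:
        raise ValueError("N must be >= 1")
    return base_kp * r ** np.arange(N, dtype=float)


def koff_mckeithan(base_koff: float, c: float, N: int) -> np.ndarray:
    """Step profile: constant ``base_koff`` except the terminal complex.

    The productive complex ``C_N`` dissociates at ``c * base_koff`` with
    ``0 < c <= 1``; every upstream complex keeps the base rate.  ``c = 1``
    recovers the plain constant profile.
    """
    _check_positive("base_koff", base_koff)
    if not (0.0 < c <= 1.0):
        raise ValueError(f"c must satisfy 0 < c <= 1, got {c!r}")
    if N < 1:
        raise ValueError("N must be >= 1")
    out = np.full(N + 1, base_koff, dtype=float)
    out[N] = c * base_koff
    return out


def constant_schedule(koff: float, kp: float, N: int) -> RateSchedule:
    """Constant-rate chain: the classic proofreading baseline."""
    _check_positive("koff", koff)
    _check_positive("kp", kp)
    if N < 1:
        raise ValueError("N must be >= 1")
    return RateSchedule(koff=np.full(N + 1, float(koff)), kp=np.full(N, float(kp)))


@dataclass(frozen=True)
class ScheduleSpec:
    """Declarative description of a schedule, e.g. from a config file.

    ``koff_family`` and ``kp_family`` may differ (the specificity analyses
    pair a hyperbolic dissociation profile with either a hyperbolic or a
    constant propagation profile).  ``tau`` may be given instead of
    ``base_koff``; internally only rates are stored.
    """

    N: int
    base_koff: float | None = None
    tau: float | None = None
    base_kp: float = 1.0
    koff_family: str = "constant"
    kp_family: str = "constant"
    r_koff: float = 1.0
    r_kp: float = 1.0
    c: float = 1.0
    custom_koff: Sequence[float] | None = field(default=None, repr=False)
    custom_kp: Sequence[float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.base_koff is None) == (self.tau is None):
            raise ValueError("give exactly one of base_koff or tau")
        for fam in (self.koff_family, self.kp_family):
            if fam not in _FAMILIES:
                raise ValueError(f"unknown family {fam!r}; choose from {_FAMILIES}")

    @property
    def koff0(self) -> float:
        return self.base_koff if self.base_koff is not None else 1.0 / self.tau

    def build(self) -> RateSchedule:
        return build_schedule(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScheduleSpec":
        return cls(**d)


def build_schedule(spec: ScheduleSpec) -> RateSchedule:
    """Materialize a :class:`ScheduleSpec` into explicit rate sequences."""
    N, k0, p0 = spec.N, spec.koff0, spec.base_kp
    if spec.koff_family == "constant":
        koff = np.full(N + 1, float(k0))
    elif spec.koff_family == "hyperbolic":
        koff = koff_hyperbolic(k0, spec.r_koff, N)
    elif spec.koff_family == "geometric":
        koff = koff_geometric(k0, spec.r_koff, N)
    elif spec.koff_family == "mckeithan":
        koff = koff_mckeithan(k0, spec.c, N)
    else:
        if spec.custom_koff is None:
            raise ValueError("custom koff family requires custom_koff values")
        koff = np.asarray(spec.custom_koff, dtype=float)
    if spec.kp_family == "constant":
        kp = np.full(N, float(p0))
    elif spec.kp_family == "hyperbolic":
        kp = kp_hyperbolic(p0, spec.r_kp, N)
    elif spec.kp_family == "geometric":
        kp = kp_geometric(p0, spec.r_kp, N)
    elif spec.kp_family == "mckeithan":
        raise ValueError("the mckeithan step applies to koff, not kp")
    else:
        if spec.custom_kp is None:
            raise ValueError("custom kp family requires custom_kp values")
        kp = np.asarray(spec.custom_kp, dtype=float)
    return RateSchedule(koff=koff, kp=kp)
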