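"""λ-coupling schedules and a toy hybrid-potential evaluator.

An alchemical transformation interpolates between ligand L1 (λ=0) and
ligand L2 (λ=1).  The hybrid potential is

    V(λ, x) = (1 − λ) V1(λ, x) + λ V2(λ, x)

and the free-energy change is ΔG = ∫₀¹ ⟨∂V/∂λ⟩_λ dλ.  Van der Waals
interactions of the alchemical regions scale linearly over the full λ range
(through a soft-core form so nothing diverges as atoms (de)materialize),
while electrostatics are switched over partial windows: the disappearing
region's charges ramp linearly from full strength at λ=0 to zero at λ=0.55,
and the appearing region's charges ramp from zero at λ=0.45 to full
strength at λ=1.  The overlap of the two windows keeps the net change in
charged interactions gradual through mid-schedule.

The :class:`ToyAlchemicalSystem` evaluator exists to exercise the estimator
end to end on closed-form potentials; it computes no molecular energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "LambdaSchedule",
    "CouplingState",
    "ToyAlchemicalSystem",
    "default_schedule",
    "elec_scale",
    "vdw_scale",
    "coupling_state",
    "softcore_pair_energy",
    "hybrid_potential",
    "dvdl",
]

#: λ grid used by the ensemble TI protocol: dense near the endpoints where
#: the integrand varies fastest, coarser through the middle.
DEFAULT_LAMBDAS = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0)

APPEARING = "appearing"
DISAPPEARING = "disappearing"
_REGIONS = (APPEARING, DISAPPEARING)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered λ grid with the electrostatic switching windows.

    ``elec_off_end`` is the λ at which the disappearing region's
    electrostatics reach zero; ``elec_on_start`` the λ at which the
    appearing region's electrostatics begin to ramp in.  The windows may
    overlap (and do, by default: 0.45–0.55).
    """

    values: tuple[float, ...] = DEFAULT_LAMBDAS
    elec_off_end: float = 0.55
    elec_on_start: float = 0.45

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("schedule needs at least the two endpoints")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("lambda values must be strictly increasing")
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if not 0.0 < self.elec_off_end <= 1.0:
            raise ValueError("elec_off_end must lie in (0, 1]")
        if not 0.0 <= self.elec_on_start < 1.0:
            raise ValueError("elec_on_start must lie in [0, 1)")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass(frozen=True)
class CouplingState:
    """The four interaction scale factors at one λ."""

    lambda_value: float
    vdw_appearing: float
    vdw_disappearing: float
    elec_appearing: float
    elec_disappearing: float


def default_schedule() -> LambdaSchedule:
    """The 13-window production schedule with 0.45/0.55 electrostatic windows."""
    return LambdaSchedule()


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return lam


def elec_scale(lam: float, region: str, s: LambdaSchedule | None = None) -> float:
    """Electrostatic scale factor for an alchemical region at λ.

    Disappearing charges decay linearly from 1 at λ=0 to 0 at
    ``s.elec_off_end`` and stay off beyond; appearing charges are off until
    ``s.elec_on_start`` then grow linearly to 1 at λ=1.
    """
    lam = _check_lambda(lam)
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {_REGIONS}, got {region!r}")
    if s is None:
        s = default_schedule()
    if region == DISAPPEARING:
        if lam >= s.elec_off_end:
            return 0.0
        return 1.0 - lam / s.elec_off_end
    if lam <= s.elec_on_start:
        return 0.0
    return (lam - s.elec_on_start) / (1.0 - s.elec_on_start)


def vdw_scale(lam: float, region: str) -> float:
    """Van der Waals scale factor: linear in λ over the full range."""
    lam = _check_lambda(lam)
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {_REGIONS}, got {region!r}")
    return lam if region == APPEARING else 1.0 - lam


def coupling_state(lam: float, s: LambdaSchedule | None = None) -> CouplingState:
    """All four scale factors at one λ."""
    if s is None:
        s = default_schedule()
    return CouplingState(
        lambda_value=float(lam),
        vdw_appearing=vdw_scale(lam, APPEARING),
        vdw_disappearing=vdw_scale(lam, DISAPPEARING),
        elec_appearing=elec_scale(lam, APPEARING, s),
        elec_disappearing=elec_scale(lam, DISAPPEARING, s),
    )


def softcore_pair_energy(
    r: float,
    lam_scale: float,
    eps: float = 0.1,
    sigma: float = 3.4,
    alpha: float = 0.5,
) -> float:
    """Separation-shifted (Beutler-style) soft-core Lennard-Jones energy.

    With ρ = (r/σ)² + α(1−λs),

        U(r; λs) = 4 ε λs (ρ⁻⁶ − ρ⁻³)     [kcal/mol]

    which reduces to plain Lennard-Jones at λs=1, vanishes at λs=0, and is
    finite as r → 0 for any λs < 1 — the property that removes the endpoint
    catastrophe when alchemical atoms (de)materialize.

    Parameters: ``r`` separation (Å, > 0); ``lam_scale`` the vdW coupling
    factor in [0, 1]; ``eps`` well depth (kcal/mol); ``sigma`` LJ diameter
    (Å); ``alpha`` dimensionless shift strength (default 0.5).
    """
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    if not 0.0 <= lam_scale <= 1.0:
        raise ValueError(f"lam_scale must lie in [0, 1], got {lam_scale}")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rho = (r / sigma) ** 2 + alpha * (1.0 - lam_scale)
    return 4.0 * eps * lam_scale * (rho**-6 - rho**-3)


@dataclass
class ToyAlchemicalSystem:
    """Closed-form two-state system for exercising the TI estimator.

    ``v1`` and ``v2`` are the endpoint potentials (kcal/mol) as callables of
    a configuration ``x``; with ``lambda_dependent=True`` they are called as
    ``v(lam, x)`` and ∂V/∂λ falls back to a finite difference.
    """

    v1: Callable
    v2: Callable
    lambda_dependent: bool = False
    fd_step: float = 1e-5

    def _eval(self, v: Callable, lam: float, x) -> float:
        return float(v(lam, x)) if self.lambda_dependent else float(v(x))


def hybrid_potential(sys: ToyAlchemicalSystem, lam: float, x) -> float:
    """V(λ, x) = (1 − λ) V1 + λ V2."""
    lam = _check_lambda(lam)
    return (1.0 - lam) * sys._eval(sys.v1, lam, x) + lam * sys._eval(sys.v2, lam, x)


def dvdl(sys: ToyAlchemicalSystem, lam: float, x) -> float:
    """∂V/∂λ of the hybrid potential.

    For λ-independent endpoint potentials this is exactly V2(x) − V1(x) at
    every λ; otherwise a central finite difference (clipped to [0, 1]) with
    step ``sys.fd_step`` is used.
    """
    lam = _check_lambda(lam)
    if not sys.lambda_dependent:
        return sys._eval(sys.v2, lam, x) - sys._eval(sys.v1, lam, x)
    lo = max(0.0, lam - sys.fd_step)
    hi = min(1.0, lam + sys.fd_step)
    return (hybrid_potential(sys, hi, x) - hybrid_potential(sys, lo, x)) / (hi - lo)
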