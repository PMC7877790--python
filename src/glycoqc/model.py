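"""Mass-action model of the ER glycoprotein quality-control cycle.

Newly made glycoproteins carry a single glucose on one glycan branch.  The
tag lets them bind the lectin chaperones calnexin/calreticulin; glucosidase
II trims the tag to end the interaction; UGGT re-adds it to proteins that
have not yet reached the native fold, closing a cycle.  Untagged proteins
are vulnerable to ERAD-mediated degradation.  This module defines the
dimensionless state, rate constants, pathway-architecture variants, the
mass-action right-hand sides, and the three steady-state performance
metrics (folding fraction, total unfolded protein, cycle driving energy).

Non-dimensionalization: times are scaled by the chaperone-release
(glucose-trimming) rate, so ``kr = 1``; concentrations by total chaperone,
so ``Ctot = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RATE_BOUNDS",
    "ADJUSTABLE_RATES",
    "STATE_FIELDS",
    "Conditions",
    "RateSet",
    "ModelVariant",
    "VARIANTS",
    "StateVector",
    "assemble_rates",
    "dynamics_rhs",
    "available_chaperone",
    "cycle_energy",
    "folding_fraction",
    "total_unfolded",
]

#: Default search interval for every adjustable rate constant.
RATE_BOUNDS = (1e-3, 1e3)

#: Rate constants a pathway architecture may tune (kr and Ctot are fixed by
#: the non-dimensionalization; kf, kp, kps, Pb are external conditions).
ADJUSTABLE_RATES = ("kc", "kmc", "kmr", "kg", "kmg", "kd")

#: Canonical ordering of the eight concentrations.
STATE_FIELDS = ("Pg", "Pc", "Pcf", "P", "Pgs", "Pcs", "Ps", "Pcb")


@dataclass(frozen=True)
class Conditions:
    """External inputs of the quality-control system.

    Parameters
    ----------
    kpt : float
        Total protein production rate (foldable + unfoldable), in units of
        the chaperone-release rate.
    mf : float
        Fraction of produced proteins that are terminally misfolded
        (cycle with normal rates but cannot fold), in [0, 1].
    kf : float
        Folding rate constant of chaperone-bound foldable proteins.
    Pb : float
        Concentration of background proteins (outside the tag cycle) that
        can occupy chaperones through untagged binding, in units of Ctot.
    """

    kpt: float
    mf: float
    kf: float
    Pb: float

    def __post_init__(self) -> None:
        if not self.kpt > 0:
            raise ValueError(f"kpt must be positive, got {self.kpt}")
        if not 0.0 <= self.mf <= 1.0:
            raise ValueError(f"mf must lie in [0, 1], got {self.mf}")
        if self.kf < 0:
            raise ValueError(f"kf must be nonnegative, got {self.kf}")
        if self.Pb < 0:
            raise ValueError(f"Pb must be nonnegative, got {self.Pb}")

    @property
    def kp(self) -> float:
        """Production rate of foldable proteins, (1 - mf) * kpt."""
        return (1.0 - self.mf) * self.kpt

    @property
    def kps(self) -> float:
        """Production rate of terminally misfolded proteins, mf * kpt."""
        return self.mf * self.kpt


@dataclass(frozen=True)
class RateSet:
    """Complete dimensionless rate constants for one model instance.

    ``kc``: tagged chaperone binding; ``kmc``: unbinding retaining the tag;
    ``kr``: unbinding with tag trimming (1 by non-dimensionalization, 0 in
    the no-tag-memory variant); ``kmr``: untagged (re)binding; ``kg``:
    reglucosylation; ``kmg``: deglucosylation of free tagged proteins (the
    "safety valve"); ``kd``: degradation of untagged proteins; ``kf``:
    folding; ``kp``/``kps``: foldable/misfolded production; ``Pb``:
    background protein reservoir; ``Ctot``: total chaperone (1).
    """

    kc: float
    kmc: float
    kmr: float
    kg: float
    kmg: float
    kd: float
    kf: float
    kp: float
    kps: float
    Pb: float
    kr: float = 1.0
    Ctot: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kc", "kmc", "kmr", "kg", "kmg", "kd", "kf",
                     "kp", "kps", "Pb", "kr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
        if not self.kd > 0:
            raise ValueError("kd must be strictly positive")
        if self.kr not in (0.0, 1.0):
            raise ValueError(f"kr is fixed by non-dimensionalization to 0 or 1, got {self.kr}")
        if self.Ctot != 1.0:
            raise ValueError("Ctot is fixed to 1 by non-dimensionalization")

    @property
    def kpt(self) -> float:
        return self.kp + self.kps

    def with_(self, **changes: float) -> "RateSet":
        """Return a copy with the given rates replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelVariant:
    """A pathway architecture: which adjustable rates exist and are free.

    ``free_rates``, ``fixed_zero`` and the keys of ``fixed_other``
    partition :data:`ADJUSTABLE_RATES`.  ``kr`` is 1 except in the
    no-tag-memory variant, where chaperone release never trims the tag.
    """

    name: str
    free_rates: tuple[str, ...]
    fixed_zero: tuple[str, ...] = ()
    fixed_other: dict[str, float] = field(default_factory=dict)
    kr: float = 1.0

    def __post_init__(self) -> None:
        names = (*self.free_rates, *self.fixed_zero, *self.fixed_other)
        if sorted(names) != sorted(ADJUSTABLE_RATES):
            raise ValueError(
                f"variant {self.name}: free/zero/other must partition "
                f"{ADJUSTABLE_RATES}, got {names}"
            )

    def pin(self, **values: float) -> "ModelVariant":
        """Move free rates into ``fixed_other`` at the given values.

        Used for single-rate sweeps where one cycle rate is held at a
        prescribed value while the others remain free to optimize.
        """
        unknown = set(values) - set(self.free_rates)
        if unknown:
            raise ValueError(f"cannot pin non-free rates {sorted(unknown)} in {self.name}")
        return ModelVariant(
            name=f"{self.name}[" + ",".join(f"{k}={v:g}" for k, v in values.items()) + "]",
            free_rates=tuple(r for r in self.free_rates if r not in values),
            fixed_zero=self.fixed_zero,
            fixed_other={**self.fixed_other, **values},
            kr=self.kr,
        )


def _variant(name, free, zero=(), other=None, kr=1.0):
    return ModelVariant(name, tuple(free), tuple(zero), dict(other or {}), kr)


#: The seven pathway architectures compared in the analysis.
#:
#: FULL  -- every cycle transition reversible (finite driving energy).
#: PHYS  -- consensus physiological cycle: no untagged binding (kmr = 0),
#:          no release without trimming (kmc = 0).
#: WB    -- weak binding: reversible chaperone binding only; once the tag
#:          is trimmed the protein is committed to degradation.
#: WBSV  -- weak binding plus the safety-valve deglucosylation route.
#: OS    -- one shot: irreversible binding and trimming, no reglucosylation.
#: NTM   -- no tag memory: release (kmc = 1) never trims the tag, so
#:          trimming and chaperone binding are independent processes.
#: CNSV  -- the physiological cycle without the safety valve.
VARIANTS: dict[str, ModelVariant] = {
    "FULL": _variant("FULL", ("kc", "kmc", "kmr", "kg", "kmg", "kd")),
    "PHYS": _variant("PHYS", ("kc", "kg", "kmg", "kd"), ("kmc", "kmr")),
    "WB": _variant("WB", ("kc", "kmc", "kd"), ("kmr", "kg", "kmg")),
    "WBSV": _variant("WBSV", ("kc", "kmc", "kmg", "kd"), ("kmr", "kg")),
    "OS": _variant("OS", ("kc", "kd"), ("kmc", "kmr", "kg", "kmg")),
    "NTM": _variant("NTM", ("kc", "kg", "kmg", "kd"), ("kmr",), {"kmc": 1.0}, kr=0.0),
    "CNSV": _variant("CNSV", ("kc", "kg", "kd"), ("kmc", "kmr", "kmg")),
}


@dataclass(frozen=True)
class StateVector:
    """The eight protein concentrations, in units of total chaperone.

    Foldable pool: ``Pg`` (tagged, free), ``Pc`` (chaperone-bound,
    unfolded), ``Pcf`` (chaperone-bound, folded), ``P`` (untagged,
    degradation-vulnerable).  Misfolded pool: ``Pgs``, ``Pcs``, ``Ps``
    (the starred analogues; no folded state).  ``Pcb``: chaperone-bound
    background proteins.
    """

    Pg: float
    Pc: float
    Pcf: float
    P: float
    Pgs: float = 0.0
    Pcs: float = 0.0
    Ps: float = 0.0
    Pcb: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    @classmethod
    def zero(cls) -> "StateVector":
        return cls(0.0, 0.0, 0.0, 0.0)


def assemble_rates(
    variant: ModelVariant,
    conditions: Conditions,
    free_values: dict[str, float],
    bounds: tuple[float, float] = RATE_BOUNDS,
) -> RateSet:
    """Build a full :class:`RateSet` by applying a variant's mask.

    ``free_values`` must name exactly the variant's free rates; each value
    must lie within ``bounds``.  Masked rates are set to zero (or their
    pinned values), production splits into ``kp = (1-mf)*kpt`` and
    ``kps = mf*kpt``, and ``kr``/``Ctot`` follow the non-dimensionalization.
    """
    if set(free_values) != set(variant.free_rates):
        missing = set(variant.free_rates) - set(free_values)
        extra = set(free_values) - set(variant.free_rates)
        raise ValueError(
            f"variant {variant.name}: free rates mismatch"
            + (f"; missing {sorted(missing)}" if missing else "")
            + (f"; not free {sorted(extra)}" if extra else "")
        )
    lo, hi = bounds
    for name, v in free_values.items():
        if not lo <= v <= hi:
            raise ValueError(f"rate {name}={v} outside bounds [{lo}, {hi}]")
    rates = {r: 0.0 for r in variant.fixed_zero}
    rates.update(variant.fixed_other)
    rates.update(free_values)
    return RateSet(
        kf=conditions.kf,
        kp=conditions.kp,
        kps=conditions.kps,
        Pb=conditions.Pb,
        kr=variant.kr,
        Ctot=1.0,
        **rates,
    )


def _rhs(y: np.ndarray, r: RateSet) -> np.ndarray:
    """Mass-action right-hand side on the raw concentration array.

    Degradation is a loss term (-kd*P, -kd*Ps): the steady-state flux
    balance kp = kf*Pc + kd*P requires it.  The background reservoir Pb is
    held constant (no dPb/dt); only its chaperone-bound form Pcb evolves.
    """
    Pg, Pc, Pcf, P, Pgs, Pcs, Ps, Pcb = y
    CA = r.Ctot - Pc - Pcf - Pcs - Pcb
    dPg = r.kg * P + r.kmc * Pc - (r.kc * CA + r.kmg) * Pg + r.kp
    dPc = (r.kc * Pg + r.kmr * P) * CA - (r.kr + r.kmc + r.kf) * Pc
    dP = r.kr * Pc + r.kmg * Pg - (r.kg + r.kmr * CA + r.kd) * P
    dPcf = r.kf * Pc - (r.kr + r.kmc) * Pcf
    dPgs = r.kg * Ps + r.kmc * Pcs - (r.kc * CA + r.kmg) * Pgs + r.kps
    dPcs = (r.kc * Pgs + r.kmr * Ps) * CA - (r.kr + r.kmc) * Pcs
    dPs = r.kr * Pcs + r.kmg * Pgs - (r.kg + r.kmr * CA + r.kd) * Ps
    dPcb = r.kmr * CA * r.Pb - r.kr * Pcb
    return np.array([dPg, dPc, dPcf, dP, dPgs, dPcs, dPs, dPcb])


def dynamics_rhs(state: StateVector, rates: RateSet) -> np.ndarray:
    """Time derivatives of the eight concentrations under mass action.

    Returns an array ordered as :data:`STATE_FIELDS`.  Raises
    ``ValueError`` for negative concentrations.
    """
    y = state.to_array()
    if np.any(y < 0):
        raise ValueError("concentrations must be nonnegative")
    return _rhs(y, rates)


def available_chaperone(state: StateVector) -> float:
    """Free chaperone CA = 1 - Pc - Pcf - Pcs - Pcb.

    May be negative for an infeasible state; callers filter.
    """
    return 1.0 - state.Pc - state.Pcf - state.Pcs - state.Pcb


def cycle_energy(rates: RateSet) -> float:
    """Free energy (units of kBT) driving the cycle per turn.

    E = log[(kc*kr*kg) / (kmc*kmr*kmg)].  When any reverse rate is zero
    the cycle is irreversibly driven and the energy is unbounded; this is
    signalled by returning ``math.inf``.  A zero forward rate is a domain
    error (the cycle does not turn).
    """
    if rates.kc <= 0 or rates.kr <= 0 or rates.kg <= 0:
        raise ValueError("cycle energy requires positive forward rates kc, kr, kg")
    if rates.kmc <= 0 or rates.kmr <= 0 or rates.kmg <= 0:
        return math.inf
    return math.log((rates.kc * rates.kr * rates.kg) / (rates.kmc * rates.kmr * rates.kmg))


def folding_fraction(state: StateVector, rates: RateSet) -> float:
    """Fraction of foldable proteins that fold rather than degrade.

    f = kf * Pc / kp.  Meaningful at steady state, where the flux balance
    kp = kf*Pc + kd*P bounds it by 1.
    """
    if rates.kp <= 0:
        raise ValueError("folding fraction undefined for kp = 0")
    return rates.kf * state.Pc / rates.kp


def total_unfolded(state: StateVector) -> float:
    """Total unfolded protein, Pg + Pg* + Pc + Pc* + P + P*.

    Excludes folded (Pcf) and background-bound (Pcb) proteins.
    """
    return state.Pg + state.Pgs + state.Pc + state.Pcs + state.P + state.Ps
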