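"""Reproducible sweep drivers composing the steady-state and optimization layers.

Each driver regenerates the data behind one family of results as a tidy
:class:`pandas.DataFrame` (one row per grid point, failures flagged in-row,
never dropped), with run metadata attached in ``DataFrame.attrs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .model import Conditions, ModelVariant, RateSet, VARIANTS, assemble_rates, \
    folding_fraction, total_unfolded
from .optimize import (
    OptimizationProblem,
    adjust_kd,
    energy_constrained_efficiency,
    folding_efficiency,
)
from .steady_state import solve_steady_state

__all__ = [
    "SweepSpec",
    "sweep_optimal",
    "compare_variants",
    "robustness",
    "energy_curves",
    "population_sweep_kmc",
]

logger = logging.getLogger(__name__)

SWEEPABLE = ("kpt", "kf", "mf", "kmr", "kmc", "E")
MODES = ("optimize", "fixed-rates", "fixed-rates-adaptive-kd")


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a base problem, the swept quantity, its grid, and a mode.

    ``kpt``/``kf``/``mf`` sweep the external conditions; ``kmr``/``kmc``
    pin one cycle rate per grid point (the rest stay free); ``E`` sweeps
    the cycle driving energy under the energy-constrained protocol.
    """

    problem: OptimizationProblem
    swept: str
    grid: np.ndarray
    mode: str = "optimize"

    def __post_init__(self) -> None:
        if self.swept not in SWEEPABLE:
            raise ValueError(f"swept must be one of {SWEEPABLE}, got {self.swept}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode}")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        if self.swept in ("kmr", "kmc", "E") and self.mode != "optimize":
            raise ValueError(f"swept {self.swept} requires mode 'optimize'")


def _attrs(problem: OptimizationProblem, **extra) -> dict:
    c = problem.conditions
    return {
        "variant": problem.variant.name,
        "conditions": {"kpt": c.kpt, "mf": c.mf, "kf": c.kf, "Pb": c.Pb},
        "bounds": list(problem.bounds),
        "starts": problem.starts,
        "seed": problem.seed,
        "version": __version__,
        **extra,
    }


def _point_problem(spec: SweepSpec, value: float) -> OptimizationProblem:
    p, c = spec.problem, spec.problem.conditions
    if spec.swept == "kpt":
        cond = Conditions(value, c.mf, c.kf, c.Pb)
        return OptimizationProblem(p.variant, cond, p.bounds, p.starts, p.seed)
    if spec.swept == "kf":
        cond = Conditions(c.kpt, c.mf, value, c.Pb)
        return OptimizationProblem(p.variant, cond, p.bounds, p.starts, p.seed)
    if spec.swept == "mf":
        cond = Conditions(c.kpt, value, c.kf, c.Pb)
        return OptimizationProblem(p.variant, cond, p.bounds, p.starts, p.seed)
    if spec.swept in ("kmr", "kmc"):
        return OptimizationProblem(p.variant.pin(**{spec.swept: value}),
                                   c, p.bounds, p.starts, p.seed)
    raise AssertionError(spec.swept)


def sweep_optimal(spec: SweepSpec) -> pd.DataFrame:
    """Folding efficiency f*max (and optimal rates) along a grid.

    Per-point optimization failures are recorded in the row (``exists``
    False) and the sweep continues.
    """
    if spec.mode != "optimize":
        raise ValueError("sweep_optimal requires mode 'optimize'")
    rows = []
    for v in np.asarray(spec.grid, dtype=float):
        try:
            if spec.swept == "E":
                res = energy_constrained_efficiency(spec.problem, float(v))
            else:
                res = folding_efficiency(_point_problem(spec, float(v)))
            rows.append({
                spec.swept: v, "fstar": res.objective,
                "punfolded": res.extras.get("punfolded", np.nan),
                "exists": res.success,
                **{f"opt_{k}": val for k, val in res.best_rates.items()},
            })
        except RuntimeError as err:  # no start converged
            logger.warning("sweep point %s=%g failed: %s", spec.swept, v, err)
            rows.append({spec.swept: v, "fstar": np.nan, "punfolded": np.nan,
                         "exists": False})
    df = pd.DataFrame(rows)
    df.attrs = _attrs(spec.problem, swept=spec.swept, mode=spec.mode)
    return df


def compare_variants(
    kpt_grid: np.ndarray,
    variants: list[str | ModelVariant],
    kf: float = 1.0,
    mf: float = 0.001,
    Pb: float = 1.0,
    starts: int = 20,
    seed: int = 0,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> pd.DataFrame:
    """f*max per variant per production rate, with ratios to PHYS.

    The physiological model must be among the variants (it is the
    reference).  Non-existent steady states / infeasible optimizations are
    flagged with NaN efficiency.
    """
    vs = [VARIANTS[v] if isinstance(v, str) else v for v in variants]
    if not any(v.name == "PHYS" for v in vs):
        raise ValueError("PHYS must be included as the reference variant")
    rows = []
    for kpt in np.asarray(kpt_grid, dtype=float):
        cond = Conditions(float(kpt), mf, kf, Pb)
        row: dict = {"kpt": kpt}
        for v in vs:
            try:
                res = folding_efficiency(OptimizationProblem(v, cond, bounds, starts, seed))
                row[f"fstar_{v.name}"] = res.objective if res.success else np.nan
            except RuntimeError:
                row[f"fstar_{v.name}"] = np.nan
        for v in vs:
            if v.name != "PHYS":
                row[f"ratio_{v.name}"] = row[f"fstar_{v.name}"] / row["fstar_PHYS"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs = {"kf": kf, "mf": mf, "Pb": Pb, "starts": starts, "seed": seed,
                "bounds": list(bounds), "version": __version__}
    return df


def robustness(
    fixed_from_kpt: list[float],
    eval_grid: np.ndarray,
    adapt_kd: bool = False,
    kf: float = 1.0,
    mf: float = 0.001,
    Pb: float = 1.0,
    starts: int = 20,
    seed: int = 0,
    bounds: tuple[float, float] = (1e-3, 1e3),
    compute_reference: bool = True,
) -> pd.DataFrame:
    """Performance of frozen rate sets across changing production rates.

    For each anchor production rate, the physiological rates are optimized
    (f*max at P_unfolded = 1), then frozen and evaluated over ``eval_grid``
    — optionally re-fitting only the degradation rate to hold the load at
    1.  The per-point optimal reference f*max is recomputed once per eval
    point and shared across anchors.
    """
    eval_grid = np.asarray(eval_grid, dtype=float)
    variant = VARIANTS["PHYS"]
    refs: dict[float, float] = {}
    if compute_reference:
        for kpt in eval_grid:
            cond = Conditions(float(kpt), mf, kf, Pb)
            res = folding_efficiency(OptimizationProblem(variant, cond, bounds, starts, seed))
            refs[float(kpt)] = res.objective if res.success else np.nan
    rows = []
    for anchor in fixed_from_kpt:
        cond_a = Conditions(float(anchor), mf, kf, Pb)
        opt = folding_efficiency(OptimizationProblem(variant, cond_a, bounds, starts, seed))
        base = assemble_rates(variant, cond_a, opt.best_rates, bounds)
        for kpt in eval_grid:
            cond = Conditions(float(kpt), mf, kf, Pb)
            rates = base.with_(kp=cond.kp, kps=cond.kps)
            kd_used = base.kd
            if adapt_kd:
                kd_used, ss = adjust_kd(rates, bounds)
                rates = rates.with_(kd=kd_used)
            else:
                ss = solve_steady_state(rates)
            row = {
                "anchor_kpt": float(anchor), "kpt": float(kpt),
                "exists": ss.exists, "kd": kd_used,
                "f": folding_fraction(ss.state, rates) if ss.exists else np.nan,
                "punfolded": total_unfolded(ss.state) if ss.exists else np.inf,
            }
            if compute_reference:
                row["fstar_ref"] = refs[float(kpt)]
                row["f_over_fmax"] = row["f"] / refs[float(kpt)]
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs = {"kf": kf, "mf": mf, "Pb": Pb, "adapt_kd": adapt_kd,
                "starts": starts, "seed": seed, "bounds": list(bounds),
                "version": __version__}
    return df


def energy_curves(
    conditions: list[Conditions],
    E_grid: np.ndarray,
    starts: int = 20,
    seed: int = 0,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> pd.DataFrame:
    """Energy-constrained folding efficiency curves (full reversible model).

    One curve per condition set (keyed by its kpt/kf/mf/Pb values), one
    row per driving-energy value.
    """
    rows = []
    for i, cond in enumerate(conditions):
        problem = OptimizationProblem(VARIANTS["FULL"], cond, bounds, starts, seed)
        for E in np.asarray(E_grid, dtype=float):
            res = energy_constrained_efficiency(problem, float(E))
            rows.append({
                "curve": i, "kpt": cond.kpt, "kf": cond.kf, "mf": cond.mf,
                "Pb": cond.Pb, "E": float(E),
                "fstar": res.objective if res.success else np.nan,
                "success": res.success,
            })
    df = pd.DataFrame(rows)
    df.attrs = {"starts": starts, "seed": seed, "bounds": list(bounds),
                "version": __version__}
    return df


def population_sweep_kmc(rates: RateSet, kmc_grid: np.ndarray) -> pd.DataFrame:
    """Steady-state chaperone-bound populations Pc and Pcf versus kmc.

    Holds every other rate fixed; used to examine when already-folded
    proteins occupy a significant fraction of the chaperones (fast
    folding, high production, slow release).
    """
    rows = []
    for kmc in np.asarray(kmc_grid, dtype=float):
        ss = solve_steady_state(rates.with_(kmc=float(kmc)))
        rows.append({
            "kmc": float(kmc), "exists": ss.exists,
            "Pc": ss.state.Pc if ss.exists else np.nan,
            "Pcf": ss.state.Pcf if ss.exists else np.nan,
            "CA": ss.CA if ss.exists else np.nan,
        })
    df = pd.DataFrame(rows)
    df.attrs = {"version": __version__}
    return df
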