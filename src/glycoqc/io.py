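"""Scenario parsing, result serialization, and the seeded fixture generator."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    RATE_BOUNDS,
    Conditions,
    ModelVariant,
    RateSet,
    VARIANTS,
    assemble_rates,
)

__all__ = ["Scenario", "load_scenario", "random_rate_fixture", "write_results"]

#: Significant digits for all serialized floats (bit-stable output).
_SIGDIGITS = 12


@dataclass(frozen=True)
class Scenario:
    """A validated run description: variant, conditions, rates, settings."""

    variant: ModelVariant
    conditions: Conditions
    rates: dict[str, float] | None = None
    bounds: tuple[float, float] = RATE_BOUNDS
    starts: int = 20
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def rate_set(self) -> RateSet:
        """Assemble the full RateSet (requires explicit free-rate values)."""
        if self.rates is None:
            raise ValueError("scenario gives no explicit rates (optimization scenario?)")
        return assemble_rates(self.variant, self.conditions, self.rates, self.bounds)


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a YAML or JSON scenario file.

    Required keys: ``variant`` (name) and ``conditions`` with kpt, mf, kf,
    Pb.  Optional: ``rates`` (values for the variant's free rates),
    ``bounds`` {lo, hi}, ``starts``, ``seed``.  Defaults are filled and
    recorded; every violation is reported with the offending field name.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario must be a mapping")
    try:
        vname = data["variant"]
    except KeyError:
        raise ValueError(f"{path}: missing field 'variant'") from None
    if vname not in VARIANTS:
        raise ValueError(f"{path}: unknown variant {vname!r}; expected one of {sorted(VARIANTS)}")
    variant = VARIANTS[vname]
    cond_raw = data.get("conditions")
    if not isinstance(cond_raw, dict):
        raise ValueError(f"{path}: missing or malformed field 'conditions'")
    missing = {"kpt", "mf", "kf", "Pb"} - set(cond_raw)
    if missing:
        raise ValueError(f"{path}: conditions missing {sorted(missing)}")
    try:
        conditions = Conditions(**{k: float(cond_raw[k]) for k in ("kpt", "mf", "kf", "Pb")})
    except ValueError as err:
        raise ValueError(f"{path}: invalid conditions: {err}") from None
    bounds_raw = data.get("bounds", {})
    bounds = (float(bounds_raw.get("lo", RATE_BOUNDS[0])),
              float(bounds_raw.get("hi", RATE_BOUNDS[1])))
    if not 0 < bounds[0] < bounds[1]:
        raise ValueError(f"{path}: bounds must satisfy 0 < lo < hi, got {bounds}")
    rates = data.get("rates")
    if rates is not None:
        if set(rates) != set(variant.free_rates):
            raise ValueError(
                f"{path}: rates must name exactly the free rates of {vname} "
                f"({sorted(variant.free_rates)}), got {sorted(rates)}"
            )
        for k, v in rates.items():
            v = float(v)
            if not bounds[0] <= v <= bounds[1]:
                raise ValueError(f"{path}: rate {k}={v} outside bounds {bounds}")
        rates = {k: float(v) for k, v in rates.items()}
    known = {"variant", "conditions", "rates", "bounds", "starts", "seed"}
    return Scenario(
        variant=variant, conditions=conditions, rates=rates, bounds=bounds,
        starts=int(data.get("starts", 20)), seed=int(data.get("seed", 0)),
        extra={k: v for k, v in data.items() if k not in known},
    )


def random_rate_fixture(
    variant: ModelVariant,
    seed: int,
    n: int,
    bounds: tuple[float, float] = RATE_BOUNDS,
) -> list[RateSet]:
    """Deterministic random rate sets for a variant, paired with conditions.

    Free rates are log-uniform within ``bounds``; conditions are drawn as
    kpt log-uniform in [0.01, 10], mf from {1e-3, 0.4}, kf log-uniform in
    [0.03, 3], Pb from {0, 1, 10} — spanning the regimes the analysis
    explores (low to overwhelming production, clean to heavily misfolded
    input, absent to dominant background competition).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    llo, lhi = math.log10(bounds[0]), math.log10(bounds[1])
    out = []
    for _ in range(n):
        cond = Conditions(
            kpt=float(10.0 ** rng.uniform(-2, 1)),
            mf=float(rng.choice([1e-3, 0.4])),
            kf=float(10.0 ** rng.uniform(math.log10(0.03), math.log10(3.0))),
            Pb=float(rng.choice([0.0, 1.0, 10.0])),
        )
        free = {r: float(10.0 ** rng.uniform(llo, lhi)) for r in variant.free_rates}
        out.append(assemble_rates(variant, cond, free, bounds))
    return out


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return v if not math.isfinite(v) else float(f"{v:.{_SIGDIGITS}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_results(
    data: pd.DataFrame | dict,
    path: str | Path,
    format: str | None = None,
    manifest: dict | None = None,
) -> None:
    """Serialize a table (CSV) or record (JSON) with fixed float formatting.

    Output is bit-stable for identical inputs: floats carry 12 significant
    digits.  JSON records gain a ``manifest`` block (version plus caller
    metadata such as seed, bounds, tolerances).  An empty table produces a
    header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or ("csv" if isinstance(data, pd.DataFrame) else "json")
    if fmt not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {fmt}")
    if fmt == "csv":
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        data.to_csv(path, index=False, float_format=f"%.{_SIGDIGITS}g")
        if manifest is not None or data.attrs:
            m = {"version": __version__, **(data.attrs or {}), **(manifest or {})}
            path.with_suffix(".manifest.json").write_text(
                json.dumps(_round_floats(m), indent=2, sort_keys=True) + "\n")
    else:
        record = dict(data) if isinstance(data, dict) else data.to_dict(orient="list")
        record["manifest"] = {"version": __version__, **(manifest or {})}
        path.write_text(json.dumps(_round_floats(record), indent=2, sort_keys=True) + "\n")
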