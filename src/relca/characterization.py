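"""GWP characterization factors with uncertainty.

Factors convert inventory totals (kg of each greenhouse gas) into kg
CO2-equivalents.  The CO2 factor is 1 by definition and carries no
uncertainty — every other GWP is a ratio normalized by CO2's absolute GWP,
so under dependent sampling of the underlying radiative-forcing models the
CO2 factor is a point value while CH4, N2O, ... have distributions.
Uncertainty is taken at the GWP level: a normal distribution whose sigma is
back-calculated from the published 90% range, truncated at zero.

The bundled default table carries the IPCC AR5 GWP100 values for CO2, CH4
and N2O with their 90% uncertainty ranges (+/-40% for CH4, +/-30% for N2O);
users may override it with their own factor table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import _MAX_REJECTIONS, back_calc_sigma

__all__ = [
    "CO2_FLOW_IDS",
    "CharacterizationFactor",
    "CharacterizationSet",
    "default_factors",
    "load_factors",
    "sample_factors",
]

#: flow ids recognized as carbon dioxide (case-insensitive)
CO2_FLOW_IDS = frozenset({"co2", "carbon dioxide", "carbon-dioxide"})


def is_co2(flow_id: str) -> bool:
    return flow_id.lower() in CO2_FLOW_IDS


@dataclass(frozen=True)
class CharacterizationFactor:
    """GWP of one greenhouse gas, kg CO2-eq per kg."""

    flow_id: str
    gwp: float
    sigma: float = 0.0
    kind: str = "normal"  # "point" | "normal"

    def __post_init__(self) -> None:
        if self.kind not in ("point", "normal"):
            raise ValueError(f"factor kind must be point/normal, got {self.kind!r}")
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")
        if self.gwp < 0.0:
            raise ValueError(f"negative central GWP for {self.flow_id!r}")
        if is_co2(self.flow_id) and (self.gwp != 1.0 or self.sigma != 0.0):
            raise ValueError("the CO2 factor is fixed at (1, 0) by definition")


@dataclass
class CharacterizationSet:
    """An ordered set of factors for one time horizon."""

    factors: list[CharacterizationFactor]
    horizon: str = "GWP100"

    def __post_init__(self) -> None:
        ids = [f.flow_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate characterization factor")
        if not any(is_co2(f.flow_id) for f in self.factors):
            raise ValueError("characterization set must contain a CO2 factor")

    def central(self) -> dict[str, float]:
        return {f.flow_id: f.gwp for f in self.factors}

    def __iter__(self):
        return iter(self.factors)


def load_factors(records, horizon: str = "GWP100") -> CharacterizationSet:
    """Build a characterization set from factor records.

    Each record is a mapping with ``flow_id``, ``gwp`` and either ``sigma``
    or a 90% range ``(p05, p95)`` (sigma wins when both are present; the
    range is converted with sigma = (P95 - P05) / (2 * 1.645)).  Any CO2
    record is forced to (1, 0) regardless of its input values.
    """
    factors: list[CharacterizationFactor] = []
    seen: set[str] = set()
    for rec in records:
        fid = rec["flow_id"]
        if fid in seen:
            raise ValueError(f"duplicate factor for flow {fid!r}")
        seen.add(fid)
        if is_co2(fid):
            factors.append(CharacterizationFactor(fid, 1.0, 0.0, "point"))
            continue
        gwp = float(rec["gwp"])
        sigma = rec.get("sigma")
        if sigma is None or (isinstance(sigma, float) and np.isnan(sigma)):
            p05, p95 = rec.get("p05"), rec.get("p95")
            if p05 is None or p95 is None:
                sigma = 0.0
            else:
                sigma = back_calc_sigma(float(p05), float(p95))
        sigma = float(sigma)
        kind = "point" if sigma == 0.0 else "normal"
        factors.append(CharacterizationFactor(fid, gwp, sigma, kind))
    return CharacterizationSet(factors, horizon=horizon)


def default_factors() -> CharacterizationSet:
    """IPCC AR5 GWP100 defaults for CO2, CH4 (fossil) and N2O."""
    return load_factors(
        [
            {"flow_id": "co2", "gwp": 1.0},
            # 90% ranges: +/-40% for CH4, +/-30% for N2O
            {"flow_id": "ch4", "gwp": 28.0, "p05": 16.8, "p95": 39.2},
            {"flow_id": "n2o", "gwp": 265.0, "p05": 185.5, "p95": 344.5},
        ]
    )


def sample_factors(
    cset: CharacterizationSet, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one characterization vector (as a flow_id -> value mapping).

    The CO2 entry is exactly 1 in every draw.  Uncertain factors are drawn
    from normal(gwp, sigma) truncated at > 0 by rejection.  In dependent
    mode the caller applies one such vector to every alternative of a run.
    """
    out: dict[str, float] = {}
    for fac in cset:
        if is_co2(fac.flow_id):
            out[fac.flow_id] = 1.0
        elif fac.kind == "point" or fac.sigma == 0.0:
            out[fac.flow_id] = fac.gwp
        else:
            for _ in range(_MAX_REJECTIONS):
                v = rng.normal(fac.gwp, fac.sigma)
                if v > 0.0:
                    out[fac.flow_id] = float(v)
                    break
            else:
                raise RuntimeError(
                    f"rejection limit exceeded sampling GWP of {fac.flow_id!r}"
                )
    return out
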