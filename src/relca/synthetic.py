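"""Synthetic comparative aquaculture case.

Generates product systems with the statistical structure of a two-farm-type
catfish study: a shared background supply chain (electricity, commercial and
farm-made feed milling, transport) consumed in different quantities by each
farm type, plus farm-type-specific direct pond emissions (CH4, N2O) that are
*not* shared.  Background emission-factor parameters carry identical
parameter ids across alternatives, so dependent sampling reuses one draw per
run for all farm types; pond parameters carry per-alternative ids and are
sampled independently, mirroring how on-farm measurements differ between
groups while the upstream inventory is literally the same data.

Family farms rely on commercial feed for 69% of their feed input (the rest
farm-made), corporate farms for 94%.  All technosphere amounts are point
values (survey quantities, horizontally averaged); uncertainty sits in the
emission intensities — the farm-to-farm spread of the observed groups is
folded into the pond-emission dispersions — and in the GWPs.  A controllable
``true_effect`` adds electricity demand to the higher-footprint alternatives
so that the central-value footprint difference between the extreme
alternatives equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .characterization import CharacterizationSet, default_factors
from .distributions import lognormal_from_mean
from .inventory import (
    Exchange,
    Flow,
    ProductSystem,
    UnitProcess,
    build_system,
    footprint,
    solve_inventory,
)
from .io import write_comparison_config, write_factors, write_system_dir
from .montecarlo import SharedParameterRegistry, build_registry

__all__ = ["CaseConfig", "SyntheticCase", "generate_case", "write_fixture"]

# flows (units are labels; elementary flows in kg)
ELECTRICITY = Flow("electricity", "electricity, medium voltage", "product", "kWh")
TRANSPORT = Flow("transport", "lorry transport", "product", "tkm")
FEED_COMMERCIAL = Flow("feed_commercial", "commercial pelleted feed", "product", "tonne")
FEED_FARMMADE = Flow("feed_farmmade", "farm-made feed", "product", "tonne")
FISH = Flow("fish", "live fish at farm gate", "product", "tonne")
CO2 = Flow("co2", "carbon dioxide, fossil", "elementary", "kg", "air")
CH4 = Flow("ch4", "methane", "elementary", "kg", "air")
N2O = Flow("n2o", "dinitrogen monoxide", "elementary", "kg", "air")


@dataclass
class CaseConfig:
    """Study conditions for the synthetic comparison.

    Defaults encode two farm types sharing one background supply chain,
    with a 824 kg CO2-eq central footprint difference (family minus
    corporate) injected through extra background electricity demand.
    """

    n_alternatives: int = 2
    alternative_ids: tuple[str, ...] | None = None
    #: commercial share of the 1.8 t feed input per tonne of fish
    commercial_feed_share: tuple[float, ...] | None = None
    feed_per_tonne_fish: float = 1.8  # tonne feed / tonne fish
    electricity_kwh: tuple[float, ...] | None = None  # on-farm pumping etc.
    transport_tkm: tuple[float, ...] | None = None

    # background emission intensities: (arithmetic mean, geometric sd)
    electricity_co2: tuple[float, float] = (0.6, 1.2)  # kg/kWh
    transport_co2: tuple[float, float] = (0.12, 1.3)  # kg/tkm
    feed_commercial_co2: tuple[float, float] = (450.0, 1.5)  # kg/tonne feed
    feed_commercial_n2o: tuple[float, float] = (0.8, 1.4)
    feed_farmmade_co2: tuple[float, float] = (300.0, 1.5)
    feed_farmmade_n2o: tuple[float, float] = (1.1, 1.4)

    # direct pond emissions, kg per tonne fish, identical across farm types
    pond_ch4: tuple[float, float] = (60.0, 1.2)
    pond_n2o: tuple[float, float] = (2.0, 1.2)

    #: target central-value footprint difference between the first and last
    #: alternative, kg CO2-eq per tonne of fish
    true_effect: float = 824.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_alternatives
        if k < 2:
            raise ValueError("need at least 2 alternatives")
        if self.alternative_ids is None:
            if k == 2:
                self.alternative_ids = ("small-farm", "large-farm")
            else:
                self.alternative_ids = tuple(f"farm-{i + 1}" for i in range(k))
        if len(self.alternative_ids) != k:
            raise ValueError("alternative_ids length must equal n_alternatives")
        if self.commercial_feed_share is None:
            self.commercial_feed_share = tuple(np.linspace(0.69, 0.94, k))
        if self.electricity_kwh is None:
            self.electricity_kwh = tuple(np.linspace(300.0, 280.0, k))
        if self.transport_tkm is None:
            self.transport_tkm = tuple(np.linspace(100.0, 150.0, k))
        for name in ("commercial_feed_share", "electricity_kwh", "transport_tkm"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length must equal n_alternatives")
        for s in self.commercial_feed_share:
            if not 0.0 <= s <= 1.0:
                raise ValueError("feed shares must lie in [0, 1]")


@dataclass
class SyntheticCase:
    """Generated systems plus everything needed to run the comparison."""

    config: CaseConfig
    systems: list[ProductSystem]
    processes: dict[str, list[UnitProcess]]  # per alternative id
    demand: tuple[str, float]
    registry: SharedParameterRegistry
    characterization: CharacterizationSet = field(default_factory=default_factors)


def _background_processes(cfg: CaseConfig) -> list[UnitProcess]:
    def emission(flow: Flow, pid: str, mean_gsd: tuple[float, float]) -> Exchange:
        mean, gsd = mean_gsd
        spec = lognormal_from_mean(mean, gsd)
        return Exchange(flow, spec.mean, pid, spec)

    def point(flow: Flow, amount: float, pid: str) -> Exchange:
        return Exchange(flow, amount, pid)

    return [
        UnitProcess(
            "electricity", "electricity supply",
            Exchange(ELECTRICITY, 1.0, "prod.electricity"),
            (emission(CO2, "bg.electricity.co2", cfg.electricity_co2),),
        ),
        UnitProcess(
            "transport", "lorry transport",
            Exchange(TRANSPORT, 1.0, "prod.transport"),
            (emission(CO2, "bg.transport.co2", cfg.transport_co2),),
        ),
        UnitProcess(
            "feed_commercial", "commercial feed milling",
            Exchange(FEED_COMMERCIAL, 1.0, "prod.feed_commercial"),
            (
                point(ELECTRICITY, -120.0, "bg.feed_commercial.electricity"),
                point(TRANSPORT, -50.0, "bg.feed_commercial.transport"),
                emission(CO2, "bg.feed_commercial.co2", cfg.feed_commercial_co2),
                emission(N2O, "bg.feed_commercial.n2o", cfg.feed_commercial_n2o),
            ),
        ),
        UnitProcess(
            "feed_farmmade", "farm-made feed preparation",
            Exchange(FEED_FARMMADE, 1.0, "prod.feed_farmmade"),
            (
                point(ELECTRICITY, -40.0, "bg.feed_farmmade.electricity"),
                emission(CO2, "bg.feed_farmmade.co2", cfg.feed_farmmade_co2),
                emission(N2O, "bg.feed_farmmade.n2o", cfg.feed_farmmade_n2o),
            ),
        ),
    ]


def _farming_process(cfg: CaseConfig, i: int, extra_kwh: float) -> UnitProcess:
    aid = cfg.alternative_ids[i]
    share = cfg.commercial_feed_share[i]
    feed = cfg.feed_per_tonne_fish
    ch4 = lognormal_from_mean(*cfg.pond_ch4)
    n2o = lognormal_from_mean(*cfg.pond_n2o)
    exchanges = [
        Exchange(FEED_COMMERCIAL, -share * feed, f"fg.{aid}.feed_commercial"),
        Exchange(FEED_FARMMADE, -(1.0 - share) * feed, f"fg.{aid}.feed_farmmade"),
        Exchange(
            ELECTRICITY,
            -(cfg.electricity_kwh[i] + extra_kwh),
            f"fg.{aid}.electricity",
        ),
        Exchange(TRANSPORT, -cfg.transport_tkm[i], f"fg.{aid}.transport"),
        Exchange(CH4, ch4.mean, f"pond.{aid}.ch4", ch4),
        Exchange(N2O, n2o.mean, f"pond.{aid}.n2o", n2o),
    ]
    return UnitProcess(
        "farming", f"grow-out farming ({aid})",
        Exchange(FISH, 1.0, "prod.farming"),
        tuple(exchanges),
    )


def generate_case(config: CaseConfig | None = None) -> SyntheticCase:
    """Build the alternatives and their shared-parameter registry.

    Background parameter ids are identical across alternatives (shared under
    dependent sampling); pond parameter ids appear in exactly one
    alternative.  The central-value footprint of alternative ``i`` exceeds
    the last alternative's by ``true_effect * (k-1-i)/(k-1)`` exactly, the
    shift being injected as extra point-valued electricity demand.
    """
    cfg = config if config is not None else CaseConfig()
    cset = default_factors()
    central_cf = cset.central()
    demand = ("fish", 1.0)
    k = cfg.n_alternatives

    def assemble(i: int, extra: float) -> tuple[list[UnitProcess], ProductSystem]:
        procs = _background_processes(cfg) + [_farming_process(cfg, i, extra)]
        return procs, build_system(cfg.alternative_ids[i], procs, demand)

    # central footprints before the effect shift
    base = np.empty(k)
    for i in range(k):
        _, system = assemble(i, 0.0)
        base[i] = footprint(solve_inventory(system), central_cf)
    # central footprint of one kWh of background electricity
    fp_kwh = cfg.electricity_co2[0] * central_cf["co2"]
    targets = base[k - 1] + cfg.true_effect * (k - 1 - np.arange(k)) / (k - 1)
    extras = (targets - base) / fp_kwh
    extras[k - 1] = 0.0

    processes: dict[str, list[UnitProcess]] = {}
    systems: list[ProductSystem] = []
    for i in range(k):
        procs, system = assemble(i, float(extras[i]))
        processes[cfg.alternative_ids[i]] = procs
        systems.append(system)

    return SyntheticCase(
        config=cfg,
        systems=systems,
        processes=processes,
        demand=demand,
        registry=build_registry(systems),
        characterization=cset,
    )


def write_fixture(case: SyntheticCase, path) -> Path:
    """Write the case in the CSV dialect plus factors.csv and comparison.yaml.

    Deterministic: regenerating the same config writes identical bytes, and
    reading the files back reproduces the matrices bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for aid in case.config.alternative_ids:
        write_system_dir(path / aid, case.processes[aid], case.demand)
    write_factors(path / "factors.csv", case.characterization)
    write_comparison_config(
        path / "comparison.yaml",
        {aid: aid for aid in case.config.alternative_ids},
        factors="factors.csv",
        n_runs=1000,
        mode="dependent",
        seed=case.config.seed,
    )
    return path
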