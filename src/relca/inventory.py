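"""Matrix-based life-cycle inventory.

A product system is a set of single-output unit processes linked through
product flows.  The technology matrix ``A`` (product flow x process) holds
production entries (positive) and consumption entries (negative); the
intervention matrix ``B`` (elementary flow x process) holds emissions per
unit of process activity.  Given a demand vector ``f`` encoding the
functional unit, the scaling vector solves ``A s = f`` and the inventory is
``g = B s``; the carbon footprint is the dot product of ``g`` with a vector
of characterization factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import DistributionSpec

__all__ = [
    "AmbiguityError",
    "Exchange",
    "Flow",
    "InventoryResult",
    "LinkageError",
    "ProductSystem",
    "SingularSystemError",
    "StochasticCell",
    "UnitProcess",
    "build_system",
    "footprint",
    "solve_inventory",
]

COND_LIMIT = 1e12


class LinkageError(ValueError):
    """A consumed product flow has no producer in the system."""


class AmbiguityError(ValueError):
    """A product flow is produced by more than one process."""


class SingularSystemError(ValueError):
    """The technology matrix is singular or numerically unusable."""


@dataclass(frozen=True)
class Flow:
    """A product or elementary flow.

    Product flows have no compartment; elementary flows name the environmental
    compartment they enter (e.g. ``air``).  Units are labels carried for
    consistency checking, never converted.
    """

    id: str
    name: str
    kind: str  # "product" | "elementary"
    unit: str
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("product", "elementary"):
            raise ValueError(f"flow kind must be product/elementary, got {self.kind!r}")
        if self.kind == "product" and self.compartment:
            raise ValueError(f"product flow {self.id!r} must not have a compartment")


@dataclass(frozen=True)
class Exchange:
    """One matrix entry: a flow exchanged by a process.

    Sign convention: production positive, consumption negative (product
    flows); emissions positive (elementary flows).  ``amount`` is the
    central value — the arithmetic mean of ``distribution`` when one is
    attached.  ``parameter_id`` keys dependent sampling: exchanges sharing a
    parameter id receive the same drawn value in each Monte Carlo run.
    """

    flow: Flow
    amount: float
    parameter_id: str
    distribution: DistributionSpec | None = None

    def __post_init__(self) -> None:
        if not self.parameter_id:
            raise ValueError("parameter_id must be non-empty")
        if self.distribution is not None and self.distribution.kind != "point":
            mean = self.distribution.mean
            tol = 1e-6 * max(abs(mean), abs(self.amount), 1e-30)
            if abs(mean - self.amount) > tol:
                raise ValueError(
                    f"exchange amount {self.amount} for parameter "
                    f"{self.parameter_id!r} differs from its distribution's "
                    f"central value {mean}"
                )

    @property
    def is_stochastic(self) -> bool:
        return self.distribution is not None and self.distribution.kind != "point"


@dataclass(frozen=True)
class UnitProcess:
    """A single-output unit process: one production exchange plus inputs and
    emissions."""

    id: str
    name: str
    production: Exchange
    exchanges: tuple[Exchange, ...] = ()

    def __post_init__(self) -> None:
        if self.production.flow.kind != "product":
            raise ValueError(f"process {self.id!r} must produce a product flow")
        if self.production.amount <= 0:
            raise ValueError(f"process {self.id!r} production amount must be > 0")


@dataclass(frozen=True)
class StochasticCell:
    """A distribution-annotated matrix cell, the unit of Monte Carlo sampling."""

    parameter_id: str
    matrix: str  # "A" | "B"
    row: int
    col: int
    spec: DistributionSpec


@dataclass
class ProductSystem:
    """One product alternative as matrices plus index maps."""

    alternative_id: str
    processes: list[str]
    product_flows: list[Flow]
    elementary_flows: list[Flow]
    A: np.ndarray
    B: np.ndarray
    f: np.ndarray
    stochastic_cells: list[StochasticCell] = field(default_factory=list)

    @property
    def n_processes(self) -> int:
        return len(self.processes)


@dataclass
class InventoryResult:
    """Scaling vector and elementary-flow totals for one functional unit."""

    s: np.ndarray
    g: np.ndarray
    elementary_flows: list[Flow]


def build_system(
    alternative_id: str,
    processes: list[UnitProcess],
    demand: tuple[str, float],
) -> ProductSystem:
    """Assemble A, B and f from unit-process records.

    Index maps follow insertion order: row/column ``j`` of ``A`` belongs to
    the ``j``-th process and its product flow; ``B`` rows follow first
    appearance of each elementary flow.  Every consumed product flow must be
    produced by exactly one process, and the demand flow must be produced.
    """
    if not processes:
        raise ValueError("at least one process required")
    ids = [p.id for p in processes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate process ids in {alternative_id!r}")

    # flow registry with consistency check
    flows: dict[str, Flow] = {}

    def register(flow: Flow) -> None:
        seen = flows.get(flow.id)
        if seen is None:
            flows[flow.id] = flow
        elif seen != flow:
            raise ValueError(
                f"flow {flow.id!r} declared inconsistently "
                f"({seen.kind}/{seen.unit}/{seen.compartment} vs "
                f"{flow.kind}/{flow.unit}/{flow.compartment})"
            )

    producers: dict[str, int] = {}
    for j, proc in enumerate(processes):
        register(proc.production.flow)
        fid = proc.production.flow.id
        if fid in producers:
            raise AmbiguityError(
                f"product flow {fid!r} produced by both "
                f"{processes[producers[fid]].id!r} and {proc.id!r}"
            )
        producers[fid] = j
        for ex in proc.exchanges:
            register(ex.flow)

    product_flows = [p.production.flow for p in processes]
    row_of_product = {fl.id: i for i, fl in enumerate(product_flows)}

    elementary_flows: list[Flow] = []
    row_of_elem: dict[str, int] = {}
    for proc in processes:
        for ex in proc.exchanges:
            if ex.flow.kind == "elementary" and ex.flow.id not in row_of_elem:
                row_of_elem[ex.flow.id] = len(elementary_flows)
                elementary_flows.append(ex.flow)

    n = len(processes)
    A = np.zeros((n, n))
    B = np.zeros((len(elementary_flows), n))
    cells: list[StochasticCell] = []

    for j, proc in enumerate(processes):
        seen_pairs: set[str] = set()
        i = row_of_product[proc.production.flow.id]
        A[i, j] = proc.production.amount
        if proc.production.is_stochastic:
            cells.append(
                StochasticCell(
                    proc.production.parameter_id, "A", i, j, proc.production.distribution
                )
            )
        seen_pairs.add(proc.production.flow.id)
        for ex in proc.exchanges:
            if ex.flow.id in seen_pairs:
                raise ValueError(
                    f"process {proc.id!r} exchanges flow {ex.flow.id!r} twice"
                )
            seen_pairs.add(ex.flow.id)
            if ex.flow.kind == "product":
                if ex.flow.id not in row_of_product:
                    raise LinkageError(
                        f"process {proc.id!r} consumes product flow "
                        f"{ex.flow.id!r} which no process produces"
                    )
                i = row_of_product[ex.flow.id]
                A[i, j] = ex.amount
                if ex.is_stochastic:
                    cells.append(
                        StochasticCell(ex.parameter_id, "A", i, j, ex.distribution)
                    )
            else:
                i = row_of_elem[ex.flow.id]
                B[i, j] = ex.amount
                if ex.is_stochastic:
                    cells.append(
                        StochasticCell(ex.parameter_id, "B", i, j, ex.distribution)
                    )

    demand_flow, demand_amount = demand
    if demand_flow not in row_of_product:
        raise LinkageError(
            f"demand flow {demand_flow!r} is not produced by any process"
        )
    f = np.zeros(n)
    f[row_of_product[demand_flow]] = demand_amount

    return ProductSystem(
        alternative_id=alternative_id,
        processes=ids,
        product_flows=product_flows,
        elementary_flows=elementary_flows,
        A=A,
        B=B,
        f=f,
        stochastic_cells=cells,
    )


def solve_inventory(
    system: ProductSystem,
    A: np.ndarray | None = None,
    B: np.ndarray | None = None,
) -> InventoryResult:
    """Solve ``A s = f`` and form ``g = B s``.

    ``A``/``B`` override the system's central matrices (used per Monte Carlo
    run).  Raises :class:`SingularSystemError` when the technology matrix is
    singular or its condition estimate exceeds 1e12.
    """
    A = system.A if A is None else A
    B = system.B if B is None else B
    try:
        cond = np.linalg.cond(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularSystemError(str(exc)) from exc
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise SingularSystemError(
            f"technology matrix of {system.alternative_id!r} is singular or "
            f"ill-conditioned (condition estimate {cond:.3e} > {COND_LIMIT:.0e})"
        )
    s = np.linalg.solve(A, system.f)
    return InventoryResult(s=s, g=B @ s, elementary_flows=system.elementary_flows)


def footprint(result: InventoryResult, cf) -> float:
    """Characterize an inventory into kg CO2-eq.

    ``cf`` is either an array aligned with the result's elementary flows or a
    mapping ``flow_id -> factor``; flows without a factor contribute zero.
    """
    if isinstance(cf, dict):
        vec = np.array(
            [cf.get(fl.id, 0.0) for fl in result.elementary_flows], dtype=float
        )
    else:
        vec = np.asarray(cf, dtype=float)
        if vec.shape != result.g.shape:
            raise ValueError(
                f"characterization vector length {vec.shape} does not match "
                f"{result.g.shape} elementary flows"
            )
    return float(vec @ result.g)
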