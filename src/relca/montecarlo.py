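"""Dependent and independent Monte Carlo propagation across alternatives.

In a comparative study the alternatives share most of their supply chain.
Under *dependent* sampling each shared uncertain parameter is drawn once per
run and the value is written to every matrix cell that carries it, in every
alternative, and a single GWP vector is applied to all alternatives of the
run.  Only the per-run differences ("relative results") are then meaningful,
and the shared part of the uncertainty cancels out of them.  Under
*independent* sampling every alternative gets fresh draws, yielding absolute
but incomparable results.

RNG contract: the draw for parameter ``p`` in run ``k`` comes from a
dedicated substream seeded by ``(master_seed, hash(p), k)`` (plus the
alternative index in independent mode), so dependent sharing is exact,
results are order-independent, and extending ``n_runs`` never changes
earlier draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .characterization import CharacterizationSet, sample_factors
from .distributions import DistributionSpec, sample
from .inventory import ProductSystem, SingularSystemError, footprint, solve_inventory

__all__ = [
    "ComparisonDesign",
    "MCResultSet",
    "RegisteredParameter",
    "SharedParameterRegistry",
    "build_registry",
    "relative_results",
    "run_comparison",
    "substream",
]

DISCARD_LIMIT = 0.05


def _param_words(parameter_id: str) -> tuple[int, int]:
    digest = hashlib.blake2b(parameter_id.encode("utf-8"), digest_size=8).digest()
    word = int.from_bytes(digest, "big")
    return word >> 32, word & 0xFFFFFFFF


def substream(
    master_seed: int,
    parameter_id: str,
    run_index: int,
    alt_index: int | None = None,
) -> np.random.Generator:
    """Dedicated generator for one (parameter, run[, alternative]) cell."""
    hi, lo = _param_words(parameter_id)
    entropy = [int(master_seed), hi, lo, int(run_index)]
    if alt_index is not None:
        entropy.append(int(alt_index))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class RegisteredParameter:
    """One sampled parameter and every matrix cell it feeds."""

    parameter_id: str
    spec: DistributionSpec
    #: (alternative index, "A"|"B", row, col)
    sites: list[tuple[int, str, int, int]] = field(default_factory=list)

    @property
    def alternatives(self) -> list[int]:
        return sorted({s[0] for s in self.sites})


@dataclass
class SharedParameterRegistry:
    """Maps parameter ids to the matrix cells (across alternatives) that
    reuse them; a parameter appearing in several alternatives is *shared*."""

    params: dict[str, RegisteredParameter] = field(default_factory=dict)

    def shared_ids(self) -> list[str]:
        return [p for p, reg in self.params.items() if len(reg.alternatives) > 1]

    def unshared_ids(self) -> list[str]:
        return [p for p, reg in self.params.items() if len(reg.alternatives) == 1]


def build_registry(alternatives: list[ProductSystem]) -> SharedParameterRegistry:
    """Register every distribution-annotated cell of every alternative.

    A parameter id must carry the same distribution wherever it appears —
    one id means one draw per run.
    """
    reg = SharedParameterRegistry()
    for ai, system in enumerate(alternatives):
        seen_cells: set[tuple[str, int, int]] = set()
        for cell in system.stochastic_cells:
            key = (cell.matrix, cell.row, cell.col)
            if key in seen_cells:
                raise ValueError(
                    f"cell {key} of {system.alternative_id!r} registered twice"
                )
            seen_cells.add(key)
            entry = reg.params.get(cell.parameter_id)
            if entry is None:
                entry = RegisteredParameter(cell.parameter_id, cell.spec)
                reg.params[cell.parameter_id] = entry
            elif entry.spec != cell.spec:
                raise ValueError(
                    f"parameter {cell.parameter_id!r} carries conflicting "
                    f"distributions across its sites"
                )
            entry.sites.append((ai, cell.matrix, cell.row, cell.col))
    return reg


@dataclass
class ComparisonDesign:
    """A comparative Monte Carlo experiment over >= 2 product systems."""

    alternatives: list[ProductSystem]
    characterization: CharacterizationSet
    n_runs: int = 1000
    mode: str = "dependent"
    master_seed: int = 0
    registry: SharedParameterRegistry | None = None

    def __post_init__(self) -> None:
        if len(self.alternatives) < 2:
            raise ValueError("a comparison needs at least 2 alternatives")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.mode not in ("dependent", "independent"):
            raise ValueError(f"mode must be dependent/independent, got {self.mode!r}")
        ids = [a.alternative_id for a in self.alternatives]
        if len(set(ids)) != len(ids):
            raise ValueError("alternative ids must be unique")
        if self.registry is None:
            self.registry = build_registry(self.alternatives)


@dataclass
class MCResultSet:
    """Characterized footprints, runs x alternatives, plus run metadata."""

    results: np.ndarray
    alternative_ids: list[str]
    mode: str
    master_seed: int
    n_runs: int
    discarded: list[tuple[int, str]] = field(default_factory=list)

    def column(self, alternative_id: str) -> np.ndarray:
        return self.results[:, self.alternative_ids.index(alternative_id)]

    def to_dataframe(self):
        import pandas as pd

        n = self.results.shape[0]
        kept = [k for k in range(self.n_runs) if k not in {d[0] for d in self.discarded}]
        return pd.DataFrame(
            {
                "run": np.repeat(kept, len(self.alternative_ids)),
                "alternative": np.tile(self.alternative_ids, n),
                "footprint": self.results.ravel(),
            }
        )


def run_comparison(design: ComparisonDesign) -> MCResultSet:
    """Propagate uncertainty through every alternative over ``n_runs`` runs.

    Runs whose sampled technology matrix is singular are discarded and
    logged; more than 5% discarded runs aborts with an error (pathological
    distributions should be fixed, not silently averaged over).
    """
    alts = design.alternatives
    registry = design.registry
    cset = design.characterization
    # fail early if the central systems are not solvable
    central = [solve_inventory(a) for a in alts]

    a_stochastic = [
        any(s[0] == ai and s[1] == "A" for p in registry.params.values() for s in p.sites)
        for ai in range(len(alts))
    ]
    central_s = [res.s for res in central]

    param_ids = sorted(registry.params)
    rows: list[np.ndarray] = []
    discarded: list[tuple[int, str]] = []

    for k in range(design.n_runs):
        # 1. draw every registered parameter for this run
        values: dict[tuple[str, int], float] = {}
        for pid in param_ids:
            entry = registry.params[pid]
            if design.mode == "dependent":
                v = sample(entry.spec, substream(design.master_seed, pid, k))
                for ai in entry.alternatives:
                    values[(pid, ai)] = v
            else:
                for ai in entry.alternatives:
                    values[(pid, ai)] = sample(
                        entry.spec, substream(design.master_seed, pid, k, ai)
                    )
        # 2. draw characterization vectors
        if design.mode == "dependent":
            shared_cf = sample_factors(
                cset, substream(design.master_seed, "__cf__", k)
            )
            cfs = [shared_cf] * len(alts)
        else:
            cfs = [
                sample_factors(cset, substream(design.master_seed, "__cf__", k, ai))
                for ai in range(len(alts))
            ]
        # 3. rebuild, solve and characterize each alternative
        row = np.empty(len(alts))
        failed: str | None = None
        for ai, system in enumerate(alts):
            A = system.A.copy() if a_stochastic[ai] else None
            B = system.B.copy()
            for pid in param_ids:
                entry = registry.params[pid]
                for site_ai, matrix, i, j in entry.sites:
                    if site_ai != ai:
                        continue
                    if matrix == "A":
                        A[i, j] = values[(pid, ai)]
                    else:
                        B[i, j] = values[(pid, ai)]
            try:
                if A is None:
                    g = B @ central_s[ai]
                    res_flows = system.elementary_flows
                    h = sum(
                        cfs[ai].get(fl.id, 0.0) * g[i]
                        for i, fl in enumerate(res_flows)
                    )
                else:
                    res = solve_inventory(system, A=A, B=B)
                    h = footprint(res, cfs[ai])
            except (SingularSystemError, np.linalg.LinAlgError) as exc:
                failed = f"{system.alternative_id}: {exc}"
                break
            if not np.isfinite(h):
                failed = f"{system.alternative_id}: non-finite footprint"
                break
            row[ai] = h
        if failed is not None:
            discarded.append((k, failed))
        else:
            rows.append(row)

    if len(discarded) > DISCARD_LIMIT * design.n_runs:
        raise RuntimeError(
            f"{len(discarded)}/{design.n_runs} runs discarded (> "
            f"{DISCARD_LIMIT:.0%}); the parameter distributions are "
            f"pathological for this system"
        )

    return MCResultSet(
        results=np.array(rows) if rows else np.empty((0, len(alts))),
        alternative_ids=[a.alternative_id for a in alts],
        mode=design.mode,
        master_seed=design.master_seed,
        n_runs=design.n_runs,
        discarded=discarded,
    )


def relative_results(res: MCResultSet, a: str, b: str) -> np.ndarray:
    """Per-run differences h_a - h_b, the basis of all paired testing.

    Only dependent-mode results are comparable run by run; independent-mode
    results are refused.
    """
    if res.mode != "dependent":
        raise ValueError(
            "relative results require dependent sampling; independent-mode "
            "footprints are completely stochastic and incomparable run by run"
        )
    return res.column(a) - res.column(b)
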