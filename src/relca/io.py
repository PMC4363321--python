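"""Plain-text interchange formats.

A product system is stored as three UTF-8 CSV files in one directory:

``processes.csv``
    process_id, name, product_flow, unit, amount — one single-output unit
    process per row (the production entry of the technology matrix).
``exchanges.csv``
    process_id, flow_id, kind, compartment, amount, dist_kind, dist_p1,
    dist_p2, dist_p3, parameter_id — consumption entries (kind ``product``,
    negative amounts) and emissions (kind ``elementary``, kg, positive).
``demand.csv``
    flow_id, amount — the functional unit.

Characterization factors live in ``factors.csv`` (flow_id, gwp, p05, p95,
sigma; sigma wins when both are given), observation samples for fitting in
``samples.csv`` (parameter_id, value), and a comparison is declared in a
``comparison.yaml`` listing the alternative directories, the factor table,
n_runs, sampling mode and master seed.

Floats are written with ``repr`` so a write/read round trip reproduces the
matrices bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import yaml

from .characterization import CharacterizationSet, default_factors, load_factors
from .distributions import DistributionSpec
from .inventory import Exchange, Flow, UnitProcess, build_system

__all__ = [
    "load_comparison_config",
    "read_factors",
    "read_samples",
    "read_system_dir",
    "write_comparison_config",
    "write_factors",
    "write_system_dir",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _spec_columns(spec: DistributionSpec | None) -> list[str]:
    if spec is None:
        return ["point", "", "", ""]
    return [spec.kind, _fmt(spec.p1), _fmt(spec.p2), _fmt(spec.p3)]


def _spec_from_columns(kind: str, p1: str, p2: str, p3: str, amount: float):
    kind = (kind or "point").strip()
    if kind == "point":
        return None
    return DistributionSpec(
        kind,
        float(p1),
        float(p2) if p2 else None,
        float(p3) if p3 else None,
    )


def write_system_dir(
    path, processes: list[UnitProcess], demand: tuple[str, float]
) -> None:
    """Write one alternative's unit processes in the CSV dialect."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "processes.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["process_id", "name", "product_flow", "unit", "amount"])
        for p in processes:
            if p.production.is_stochastic:
                raise ValueError(
                    f"the CSV dialect stores point-valued production entries; "
                    f"process {p.id!r} has a stochastic one"
                )
            w.writerow(
                [p.id, p.name, p.production.flow.id, p.production.flow.unit,
                 _fmt(p.production.amount)]
            )
    with open(path / "exchanges.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["process_id", "flow_id", "kind", "compartment", "amount",
             "dist_kind", "dist_p1", "dist_p2", "dist_p3", "parameter_id"]
        )
        for p in processes:
            for ex in p.exchanges:
                w.writerow(
                    [p.id, ex.flow.id, ex.flow.kind, ex.flow.compartment or "",
                     _fmt(ex.amount), *_spec_columns(ex.distribution),
                     ex.parameter_id]
                )
    with open(path / "demand.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["flow_id", "amount"])
        w.writerow([demand[0], _fmt(demand[1])])


def read_system_dir(path) -> tuple[list[UnitProcess], tuple[str, float]]:
    """Read one alternative back from the CSV dialect."""
    path = Path(path)
    for name in ("processes.csv", "exchanges.csv", "demand.csv"):
        if not (path / name).exists():
            raise FileNotFoundError(f"missing {name} in {path}")

    product_flows: dict[str, Flow] = {}
    proc_rows: list[dict] = []
    with open(path / "processes.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            proc_rows.append(row)
            fid = row["product_flow"]
            product_flows[fid] = Flow(fid, fid, "product", row["unit"])

    exchanges: dict[str, list[Exchange]] = {r["process_id"]: [] for r in proc_rows}
    with open(path / "exchanges.csv", newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            pid = row["process_id"]
            if pid not in exchanges:
                raise ValueError(
                    f"exchanges.csv line {i}: unknown process {pid!r}"
                )
            amount = float(row["amount"])
            kind = row["kind"]
            if kind == "product":
                flow = product_flows.get(row["flow_id"])
                if flow is None:
                    # keep the reference; build_system reports the linkage error
                    flow = Flow(row["flow_id"], row["flow_id"], "product", "unknown")
            elif kind == "elementary":
                flow = Flow(
                    row["flow_id"], row["flow_id"], "elementary", "kg",
                    row["compartment"] or None,
                )
            else:
                raise ValueError(
                    f"exchanges.csv line {i}: kind must be product/elementary"
                )
            spec = _spec_from_columns(
                row["dist_kind"], row["dist_p1"], row["dist_p2"], row["dist_p3"],
                amount,
            )
            exchanges[pid].append(
                Exchange(flow, amount, row["parameter_id"], spec)
            )

    processes = [
        UnitProcess(
            id=row["process_id"],
            name=row["name"],
            production=Exchange(
                product_flows[row["product_flow"]],
                float(row["amount"]),
                f"prod.{row['process_id']}",
            ),
            exchanges=tuple(exchanges[row["process_id"]]),
        )
        for row in proc_rows
    ]

    with open(path / "demand.csv", newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if len(rows) != 1:
        raise ValueError(f"demand.csv must have exactly one row, got {len(rows)}")
    demand = (rows[0]["flow_id"], float(rows[0]["amount"]))
    return processes, demand


def write_factors(path, cset: CharacterizationSet) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["flow_id", "gwp", "p05", "p95", "sigma"])
        for fac in cset:
            w.writerow([fac.flow_id, _fmt(fac.gwp), "", "", _fmt(fac.sigma)])


def read_factors(path) -> CharacterizationSet:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                {
                    "flow_id": row["flow_id"],
                    "gwp": float(row["gwp"]),
                    "p05": float(row["p05"]) if row.get("p05") else None,
                    "p95": float(row["p95"]) if row.get("p95") else None,
                    "sigma": float(row["sigma"]) if row.get("sigma") else None,
                }
            )
    return load_factors(records)


def read_samples(path) -> dict[str, list[float]]:
    """Observation samples per parameter id, for distribution fitting."""
    out: dict[str, list[float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "parameter_id", "value"
        } <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected header with parameter_id,value columns"
            )
        for i, row in enumerate(reader, start=2):
            try:
                out.setdefault(row["parameter_id"], []).append(float(row["value"]))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} line {i}: malformed row ({exc})") from exc
    if not out:
        raise ValueError(f"{path}: no samples found")
    return out


def write_comparison_config(
    path,
    alternative_dirs: dict[str, str],
    factors: str | None = "factors.csv",
    n_runs: int = 1000,
    mode: str = "dependent",
    seed: int = 0,
) -> None:
    cfg = {
        "alternatives": [
            {"id": aid, "path": str(p)} for aid, p in alternative_dirs.items()
        ],
        "n_runs": int(n_runs),
        "mode": mode,
        "seed": int(seed),
    }
    if factors:
        cfg["factors"] = str(factors)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_comparison_config(path):
    """Read a comparison.yaml and assemble the systems and factor set.

    Returns ``(systems, cset, n_runs, mode, seed)``; alternative paths are
    resolved relative to the config file.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "alternatives" not in cfg:
        raise ValueError(f"{path}: not a comparison config (no alternatives key)")
    base = path.parent
    systems = []
    for alt in cfg["alternatives"]:
        processes, demand = read_system_dir(base / alt["path"])
        systems.append(build_system(alt["id"], processes, demand))
    if cfg.get("factors"):
        cset = read_factors(base / cfg["factors"])
    else:
        cset = default_factors()
    return (
        systems,
        cset,
        int(cfg.get("n_runs", 1000)),
        cfg.get("mode", "dependent"),
        int(cfg.get("seed", 0)),
    )
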