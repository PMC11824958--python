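"""Assembly of the national nitrogen flow network and its balance checks.

The budget is a directed graph of pools (atmosphere, hydrosphere, land
pools, livestock, fisheries, people, industry, rest-of-world) connected by
yearly N flows in Gg.  Because nitrogen cannot be converted into another
element, the bookkeeping must conserve mass: the residual (inflow minus
outflow) of every pool is reported, and the global identity

    sum of internal residuals + sum of boundary residuals = 0

holds exactly (it is computed with rational arithmetic over the flow
list).  Residuals of real-data pools are surfaced, never forced to zero —
an unbalanced pool marks a data or model gap, which is the point of
keeping the budget.
"""

from __future__ import annotations

import io as _io
import json
import os
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple

import networkx as nx
import pandas as pd

from .sectors import SectorAccount

#: Pool name -> kind.  Boundary pools absorb the bookkeeping's net
#: exchange; internal pools are expected to balance on closed scenarios.
POOLS: Dict[str, str] = {
    "atmosphere": "boundary",
    "hydrosphere": "internal",
    "non-managed land": "internal",
    "forest": "internal",
    "agricultural land": "internal",
    "livestock": "internal",
    "fisheries & coastal waters": "internal",
    "people & settlements": "internal",
    "industry": "internal",
    "rest-of-world": "boundary",
}


@dataclass(frozen=True)
class FlowRecord:
    source: str
    sink: str
    n_gg: float
    label: str
    year: int
    note: str = ""

    def __post_init__(self):
        if self.source == self.sink:
            raise ValueError(f"{self.label}: source and sink must differ")
        if not (self.n_gg >= 0 and self.n_gg == self.n_gg):
            raise ValueError(f"{self.label}: flow must be finite and >= 0")


class FlowNetwork:
    """Pool graph with labeled N flows (Gg N yr-1) and balance residuals."""

    def __init__(self, year: Optional[int] = None,
                 pools: Optional[Mapping[str, str]] = None):
        self.year = year
        self.pools: Dict[str, str] = dict(pools if pools is not None else POOLS)
        self.graph = nx.MultiDiGraph()
        for name, kind in self.pools.items():
            self.graph.add_node(name, kind=kind)

    # -- construction -------------------------------------------------

    def add_pool(self, name: str, kind: str = "internal") -> None:
        self.pools[name] = kind
        self.graph.add_node(name, kind=kind)

    def add_flow(self, source: str, sink: str, n_gg: float, label: str,
                 year: Optional[int] = None, note: str = "") -> FlowRecord:
        for pool in (source, sink):
            if pool not in self.pools:
                raise KeyError(f"unknown pool {pool!r}; known: {sorted(self.pools)}")
        rec = FlowRecord(source, sink, float(n_gg), label,
                         year if year is not None else (self.year or 0), note)
        self.graph.add_edge(source, sink, n_gg=rec.n_gg, label=rec.label,
                            year=rec.year, note=rec.note)
        return rec

    @property
    def flows(self) -> list[FlowRecord]:
        return [FlowRecord(u, v, d["n_gg"], d["label"], d["year"], d.get("note", ""))
                for u, v, d in sorted(self.graph.edges(data=True),
                                      key=lambda e: (e[2]["label"], e[0], e[1]))]

    # -- balance ------------------------------------------------------

    def residuals_exact(self) -> Dict[str, Fraction]:
        """Pool residuals (inflow - outflow) as exact rationals.

        ``Fraction(float)`` is exact, so the residuals sum to zero as a
        mathematical identity of the flow list.
        """
        res = {pool: Fraction(0) for pool in self.pools}
        for u, v, d in self.graph.edges(data=True):
            f = Fraction(d["n_gg"])
            res[u] -= f
            res[v] += f
        return res

    def residuals(self) -> Dict[str, float]:
        return {p: float(r) for p, r in self.residuals_exact().items()}

    def pool_balance(self, pool: str) -> float:
        """Residual (inflow - outflow, Gg N yr-1) of one pool."""
        if pool not in self.pools:
            raise KeyError(f"unknown pool {pool!r}")
        return self.residuals()[pool]

    def total_trade(self, boundary: str = "rest-of-world") -> Tuple[float, float]:
        """(import_total, export_total) over flows crossing *boundary*."""
        imports = sum(d["n_gg"] for u, _, d in self.graph.edges(data=True) if u == boundary)
        exports = sum(d["n_gg"] for _, v, d in self.graph.edges(data=True) if v == boundary)
        return imports, exports

    def balance_report(self, warn_gg: float = 1.0) -> str:
        """Human-readable residual table; pools beyond *warn_gg* are flagged."""
        lines = [f"Pool balance residuals (Gg N, year {self.year}):"]
        for pool, res in sorted(self.residuals().items()):
            kind = self.pools[pool]
            flag = "  <-- unbalanced" if kind == "internal" and abs(res) > warn_gg else ""
            lines.append(f"  {pool:28s} {kind:8s} {res:+10.3f}{flag}")
        total = sum(self.residuals_exact().values())
        lines.append(f"  global identity (sum of residuals): {float(total):+g}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": f.source, "sink": f.sink, "n_gg": f.n_gg,
              "label": f.label, "year": f.year, "note": f.note}
             for f in self.flows]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, year: Optional[int] = None) -> "FlowNetwork":
        net = cls(year=year)
        for row in frame.itertuples(index=False):
            for pool in (row.source, row.sink):
                if pool not in net.pools:
                    net.add_pool(pool)
            net.add_flow(row.source, row.sink, float(row.n_gg), row.label,
                         int(row.year), getattr(row, "note", "") or "")
        if year is None and len(frame):
            net.year = int(frame["year"].iloc[0])
        return net

    def to_sankey(self) -> dict:
        """Sankey-ready {nodes, links} JSON structure."""
        names = sorted(self.pools)
        index = {n: i for i, n in enumerate(names)}
        return {
            "nodes": [{"name": n} for n in names],
            "links": [{"source": index[f.source], "target": index[f.sink],
                       "value": f.n_gg, "label": f.label} for f in self.flows],
        }

    def to_dot(self) -> str:
        buf = _io.StringIO()
        buf.write("digraph nitrogen {\n  rankdir=LR;\n")
        for pool, kind in sorted(self.pools.items()):
            shape = "box" if kind == "boundary" else "ellipse"
            buf.write(f'  "{pool}" [shape={shape}];\n')
        for f in self.flows:
            buf.write(f'  "{f.source}" -> "{f.sink}" '
                      f'[label="{f.label}\\n{f.n_gg:g} Gg"];\n')
        buf.write("}\n")
        return buf.getvalue()


def export_flows(net: FlowNetwork, path: str | Path, fmt: str = "csv") -> Path:
    """Write the network to *path* as csv, json (Sankey) or dot.

    Writes are atomic (temp file + rename); re-exporting the same network
    yields byte-identical files.
    """
    path = Path(path)
    if fmt == "csv":
        payload = net.to_frame().to_csv(index=False)
    elif fmt == "json":
        payload = json.dumps(net.to_sankey(), indent=2, sort_keys=True) + "\n"
    elif fmt == "dot":
        payload = net.to_dot()
    else:
        raise ValueError(f"unknown format {fmt!r}; expected csv, json or dot")
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(payload, encoding="utf-8")
    os.replace(tmp, path)
    return path


def import_flows(path: str | Path) -> FlowNetwork:
    """Read a flow CSV back into a network (inverse of csv export)."""
    return FlowNetwork.from_frame(pd.read_csv(str(path), keep_default_na=False))


# -- assembly ---------------------------------------------------------

#: Default mapping of (sector, direction) -> (source pool, sink pool).
#: A value of None skips the direction (e.g. domestic supply that would
#: double-count production and trade already routed into the same pool).
DEFAULT_TOPOLOGY: Dict[Tuple[str, str], Optional[Tuple[str, str]]] = {
    ("fertilizer", "production"): ("atmosphere", "industry"),
    ("fertilizer", "import"): ("rest-of-world", "industry"),
    ("fertilizer", "export"): ("industry", "rest-of-world"),
    ("fertilizer", "domestic_supply"): ("industry", "agricultural land"),
    ("fossil", "production"): ("rest-of-world", "industry"),
    ("fossil", "import"): ("rest-of-world", "industry"),
    ("fossil", "export"): ("industry", "rest-of-world"),
    ("fossil", "domestic_supply"): ("industry", "people & settlements"),
    ("forestry", "production"): ("forest", "people & settlements"),
    ("forestry", "import"): ("rest-of-world", "people & settlements"),
    ("forestry", "export"): ("forest", "rest-of-world"),
    ("forestry", "domestic_supply"): None,
    ("fisheries", "production"): ("hydrosphere", "fisheries & coastal waters"),
    ("fisheries", "import"): ("rest-of-world", "fisheries & coastal waters"),
    ("fisheries", "export"): ("fisheries & coastal waters", "rest-of-world"),
    ("fisheries", "domestic_supply"): ("fisheries & coastal waters", "people & settlements"),
    ("food", "production"): ("agricultural land", "people & settlements"),
    ("food", "import"): ("rest-of-world", "people & settlements"),
    ("food", "export"): ("people & settlements", "rest-of-world"),
    ("food", "domestic_supply"): None,
    ("feed", "production"): ("agricultural land", "livestock"),
    ("feed", "import"): ("rest-of-world", "livestock"),
    ("feed", "export"): ("agricultural land", "rest-of-world"),
    ("feed", "domestic_supply"): None,
    ("livestock", "retained"): ("livestock", "people & settlements"),
    ("livestock", "applied_to_soil"): ("livestock", "agricultural land"),
    ("livestock", "loss_to_water"): ("agricultural land", "hydrosphere"),
    ("livestock", "loss_to_air"): ("agricultural land", "atmosphere"),
    ("livestock", "import"): ("rest-of-world", "livestock"),
    ("livestock", "export"): ("livestock", "rest-of-world"),
    ("people", "loss_to_air"): ("people & settlements", "atmosphere"),
    ("people", "loss_to_water"): ("people & settlements", "hydrosphere"),
    ("people", "applied_to_soil"): ("people & settlements", "agricultural land"),
    ("people", "import"): ("rest-of-world", "people & settlements"),
    ("people", "export"): ("people & settlements", "rest-of-world"),
    ("emissions", "loss_to_air"): ("people & settlements", "atmosphere"),
    ("waste", "applied_to_soil"): ("people & settlements", "agricultural land"),
}


def assemble_budget(year: int,
                    accounts: Iterable[SectorAccount] = (),
                    natural_allocation_gg: Optional[Mapping[str, float]] = None,
                    topology: Optional[Mapping[Tuple[str, str],
                                               Optional[Tuple[str, str]]]] = None,
                    ) -> FlowNetwork:
    """Compose sector accounts and natural inputs into a flow network.

    Natural inputs (deposition + fixation + weathering, already partitioned
    per land pool) enter from the atmosphere.  Sector flows are routed to
    pools via the (sector, direction) topology table; an account whose
    sector/direction pair has no entry is an error, so silent drops cannot
    occur.  Assembly is deterministic and independent of input order.
    """
    topo = dict(DEFAULT_TOPOLOGY)
    if topology:
        topo.update(topology)
    net = FlowNetwork(year=year)
    if natural_allocation_gg:
        for pool, gg in sorted(natural_allocation_gg.items()):
            net.add_flow("atmosphere", pool, gg, f"natural inputs to {pool}", year,
                         note="deposition + biological fixation + rock weathering")
    for acc in sorted(accounts, key=lambda a: (a.sector, a.year)):
        if acc.year != year:
            continue
        for flow in sorted(acc.flows, key=lambda f: f.label):
            key = (acc.sector, flow.direction)
            if key not in topo:
                raise KeyError(f"no topology entry for sector={acc.sector!r} "
                               f"direction={flow.direction!r}")
            route = topo[key]
            if route is None:
                continue
            src, snk = route
            net.add_flow(src, snk, flow.n_grams / 1e9,
                         f"{acc.sector}: {flow.label}", year)
    return net


def load_reference_flows(year: int = 2018) -> FlowNetwork:
    """Load the packaged reference flow table for the given budget year."""
    if year != 2018:
        raise ValueError("only the 2018 reference flow table is shipped")
    source = resources.files("nbudget.data").joinpath("flows_2018.csv")
    with resources.as_file(source) as path:
        frame = pd.read_csv(path, keep_default_na=False)
    return FlowNetwork.from_frame(frame, year=year)
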