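"""Consensus-network extraction: frequency curves, cutoff detection,
thresholding, neighborhood queries and network file IO.

Scanning the edge-frequency cutoff from near zero to one traces out curves
of retained edge count E(f) and node count N(f).  False-positive edges pile
up at low f, high-confidence edges sit near one, and between the two the
edge curve flattens; the consensus cutoff f* is read off at the point where
the magnitude of the (smoothed) slope of E(f) is minimal.  Edges with
f >= f* form the consensus network, annotated with the correlation sign r
and any modulator/conditional class.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ensemble import EDGE_COLUMNS, EnsembleSummary

log = logging.getLogger(__name__)

#: lowest cutoff on the grid; any observed edge has f >= 1/M >= this
GRID_FLOOR = 0.001


@dataclass
class FrequencyCurve:
    grid: np.ndarray
    n_edges: np.ndarray
    n_nodes: np.ndarray
    slope: np.ndarray  # smoothed central-difference slope of E(f)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_edges) > 0) or np.any(np.diff(self.n_nodes) > 0):
            raise ValueError("E(f) and N(f) must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.grid, "n_edges": self.n_edges,
            "n_nodes": self.n_nodes, "slope": self.slope,
        })


def _edge_table(summary: EnsembleSummary | pd.DataFrame) -> pd.DataFrame:
    # curves and consensus count a relationship once per node pair; the
    # per-variant breakdown stays available on the summary for conditional
    # edge reporting
    if isinstance(summary, EnsembleSummary):
        return summary.pair_table()
    return summary


def frequency_curves(
    summary: EnsembleSummary | pd.DataFrame,
    step: float = 0.01,
    smooth_window: int = 5,
) -> FrequencyCurve:
    """Exact E(f) and N(f) on a cutoff grid, plus a smoothed slope of E(f).

    Distinct (edge, modulator, class) relationships count separately, the
    convention under which conditional edges are reported.  The slope is a
    central difference of the moving-average-smoothed edge curve.
    """
    edges = _edge_table(summary)
    if edges.empty:
        raise ValueError("empty ensemble summary")
    grid = np.round(np.arange(step, 1.0 + step / 2, step), 10)
    grid = np.concatenate(([GRID_FLOOR], grid[grid > GRID_FLOOR]))
    f = edges["f"].to_numpy()
    pairs = edges[["node1", "node2"]].to_numpy()
    n_edges = np.empty(len(grid), dtype=int)
    n_nodes = np.empty(len(grid), dtype=int)
    for i, c in enumerate(grid):
        keep = f >= c
        n_edges[i] = int(keep.sum())
        n_nodes[i] = len(np.unique(pairs[keep])) if keep.any() else 0

    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    padded = np.concatenate((np.full(w // 2, n_edges[0]), n_edges.astype(float),
                             np.full(w - 1 - w // 2, n_edges[-1])))
    smoothed = np.convolve(padded, kernel, mode="valid")
    slope = np.gradient(smoothed, grid)
    return FrequencyCurve(grid, n_edges, n_nodes, slope)


def detect_cutoff(
    curve: FrequencyCurve, window: tuple[float, float] = (0.2, 0.9)
) -> float:
    """Grid point minimizing |slope of E(f)| inside the search window.

    E(f) is nonincreasing, so its most negative slope sits in the
    false-positive mass near f = 0; the informative feature is the plateau
    where the slope magnitude is smallest.  Ties go to the smallest cutoff,
    which is conservative toward larger networks.
    """
    lo, hi = window
    if not (0 < lo < hi <= 1):
        raise ValueError(f"invalid search window {window}")
    mask = (curve.grid >= lo) & (curve.grid <= hi)
    if not mask.any():
        raise ValueError("search window contains no grid points")
    idx = np.flatnonzero(mask)
    mag = np.abs(curve.slope[idx])
    floor = mag.min()
    # ties (within float noise) resolve to the smallest cutoff
    tol = 1e-9 * max(1.0, floor)
    best = idx[np.flatnonzero(mag <= floor + tol)[0]]
    return float(curve.grid[best])


@dataclass
class ConsensusNetwork:
    """Edges surviving the frequency cutoff, with sign and conditional class."""

    cutoff: float
    edges: pd.DataFrame  # EDGE_COLUMNS
    metadata: dict = field(default_factory=dict)
    #: nodes kept without an incident edge (used by radius-0 neighborhoods;
    #: empty for a consensus network proper, whose nodes are edge endpoints)
    isolated_nodes: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        endpoints = (
            set(self.edges["node1"]) | set(self.edges["node2"])
            if not self.edges.empty else set()
        )
        return sorted(endpoints | set(self.isolated_nodes))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges_per_node(self) -> float:
        return self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def graph(self) -> nx.Graph:
        """Relationships carry a sign, not a direction: an undirected graph."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.node1, row.node2, f=float(row.f), r=float(row.r),
                modulator=row.modulator, mod_class=row.mod_class,
                active_level=int(row.active_level),
            )
        return g


def extract_consensus(
    summary: EnsembleSummary | pd.DataFrame, cutoff: float
) -> ConsensusNetwork:
    """Retain relationships with f >= cutoff (inclusive threshold)."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    edges = _edge_table(summary)
    kept = edges[edges["f"] >= cutoff].reset_index(drop=True)
    meta = {"M": summary.M} if isinstance(summary, EnsembleSummary) else {}
    return ConsensusNetwork(cutoff, kept, meta)


def neighborhood(
    net: ConsensusNetwork, seeds, radius: int = 2
) -> ConsensusNetwork:
    """Induced subgraph on nodes within ``radius`` undirected hops of a seed.

    Unknown seeds are reported via the run log and ignored.  Radius 0 keeps
    the seed nodes only, with no edges.
    """
    seeds = list(seeds)
    known = set(net.nodes)
    missing = [s for s in seeds if s not in known]
    if missing:
        log.warning("neighborhood: %d unknown seed node(s): %s", len(missing), missing)
    seeds = [s for s in seeds if s in known]
    g = net.graph()
    reach: set[str] = set(seeds)
    frontier = set(seeds)
    for _ in range(radius):
        frontier = {nb for v in frontier for nb in g.neighbors(v)} - reach
        if not frontier:
            break
        reach |= frontier
    if radius == 0:
        kept = net.edges.iloc[0:0]
    else:
        e = net.edges
        kept = e[e["node1"].isin(reach) & e["node2"].isin(reach)]
    endpoints = set(kept["node1"]) | set(kept["node2"])
    return ConsensusNetwork(
        net.cutoff, kept.reset_index(drop=True),
        dict(net.metadata, seeds=sorted(seeds), radius=radius),
        isolated_nodes=sorted(reach - endpoints),
    )


# -- IO -------------------------------------------------------------------

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def write_network(net: ConsensusNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as XGMML, GraphML or a TSV edge list (round-trippable)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "xgmml":
        _write_xgmml(net, path)
    elif fmt == "graphml":
        nx.write_graphml(net.graph(), path)
    elif fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str | None = None,
                 cutoff: float = GRID_FLOOR) -> ConsensusNetwork:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "xgmml":
        return _read_xgmml(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        rows = [
            {"node1": u, "node2": v,
             "modulator": d.get("modulator", ""), "mod_class": d.get("mod_class", "plain"),
             "active_level": int(d.get("active_level", -1)),
             "count": -1, "f": float(d["f"]), "r": float(d["r"])}
            for u, v, d in g.edges(data=True)
        ]
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return ConsensusNetwork(cutoff, edges)
    if fmt == "tsv":
        edges = pd.read_csv(path, sep="\t", keep_default_na=False,
                            dtype={"modulator": str})
        return ConsensusNetwork(cutoff, edges[EDGE_COLUMNS])
    raise ValueError(f"unknown network format {fmt!r}")


def _write_xgmml(net: ConsensusNetwork, path: Path) -> None:
    root = ET.Element("graph", {
        "xmlns": _XGMML_NS, "label": "consensus", "directed": "0",
    })
    att = ET.SubElement(root, "att", {"name": "cutoff", "type": "real",
                                      "value": repr(net.cutoff)})
    del att
    for v in net.nodes:
        ET.SubElement(root, "node", {"id": v, "label": v})
    for row in net.edges.itertuples(index=False):
        e = ET.SubElement(root, "edge", {"source": row.node1, "target": row.node2})
        ET.SubElement(e, "att", {"name": "f", "type": "real", "value": repr(float(row.f))})
        ET.SubElement(e, "att", {"name": "r", "type": "real", "value": repr(float(row.r))})
        ET.SubElement(e, "att", {"name": "modulator", "type": "string",
                                 "value": str(row.modulator)})
        ET.SubElement(e, "att", {"name": "mod_class", "type": "string",
                                 "value": str(row.mod_class)})
        ET.SubElement(e, "att", {"name": "active_level", "type": "integer",
                                 "value": str(int(row.active_level))})
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _read_xgmml(path: Path) -> ConsensusNetwork:
    root = ET.parse(path).getroot()
    ns = {"x": _XGMML_NS}
    cutoff = GRID_FLOOR
    for att in root.findall("x:att", ns):
        if att.get("name") == "cutoff":
            cutoff = float(att.get("value"))
    rows = []
    for e in root.findall("x:edge", ns):
        atts = {a.get("name"): a.get("value") for a in e.findall("x:att", ns)}
        rows.append({
            "node1": e.get("source"), "node2": e.get("target"),
            "modulator": atts.get("modulator", ""),
            "mod_class": atts.get("mod_class", "plain"),
            "active_level": int(atts.get("active_level", -1)),
            "count": -1, "f": float(atts["f"]), "r": float(atts["r"]),
        })
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return ConsensusNetwork(cutoff, edges)
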