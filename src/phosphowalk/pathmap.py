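"""Comparative pathway maps.

The up- and down-direction chain sets are merged into one styled map: node
set = proteins incident to any selected chain edge; edge set = union of
chain edges keyed by (kinase, substrate, site), tagged with their direction,
signed CFC and log2 fold change. When the same edge is delivered by chains
of both directions, the version with the greater |log2fc| wins (the same
magnitude-precedence principle used for parallel phosphorylation).

Styling maps |log2fc| linearly onto an arrow-width range and sign onto a
color class (up vs down); rendering is left to external layout tools — the
package exports GraphML, DOT and JSON (node-link) documents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import ParameterError
from .walks import PhosphoChain

__all__ = ["PathwayMap", "assemble_map", "style_edges", "export_map", "import_map"]


def _log2fc_from_cfc(cfc: float | None) -> float:
    """log2(1 + cfc/100) — the exact log2 fold change behind a percent change."""
    if cfc is None or cfc <= -100.0:
        return 0.0
    return math.log2(1.0 + cfc / 100.0)


@dataclass
class PathwayMap:
    """A styled multigraph of selected chain edges, keyed by site."""

    graph: nx.MultiDiGraph

    def edge_keys(self) -> list[tuple[str, str, str]]:
        return sorted(self.graph.edges(keys=True))

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_data(self, kinase: str, substrate: str, site: str) -> dict:
        return self.graph[kinase][substrate][site]

    def plot(self, ax=None):
        """Quick matplotlib rendering (spring layout); optional dependency."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        g = self.graph
        pos = nx.spring_layout(g, seed=0)
        colors = ["#c0392b" if d.get("direction") == "up" else "#2980b9"
                  for _, _, d in g.edges(data=True)]
        widths = [d.get("width", 1.0) for _, _, d in g.edges(data=True)]
        nx.draw_networkx(g, pos=pos, ax=ax, node_color="#ecf0f1",
                         edge_color=colors, width=widths, font_size=8)
        ax.set_axis_off()
        return ax


def assemble_map(
    up_chains: Iterable[PhosphoChain], down_chains: Iterable[PhosphoChain]
) -> PathwayMap:
    """Merge both directions' selected chains into one comparative map."""
    records: dict[tuple[str, str, str], dict] = {}
    for chains, direction in ((up_chains, "up"), (down_chains, "down")):
        for chain in chains:
            for (kin, sub, site, effect), (value, source) in zip(
                chain.edges, chain.per_edge_cfc
            ):
                candidate = {
                    "site": site,
                    "effect": effect,
                    "direction": direction,
                    "cfc": 0.0 if value is None else float(value),
                    "log2fc": float(_log2fc_from_cfc(value)),
                    "source": source,
                    "n_chains": 1,
                }
                key = (kin, sub, site)
                prev = records.get(key)
                if prev is None:
                    records[key] = candidate
                else:
                    prev["n_chains"] += 1
                    # direction conflict: the greater |log2fc| wins
                    if prev["direction"] != direction and abs(candidate["log2fc"]) > abs(
                        prev["log2fc"]
                    ):
                        candidate["n_chains"] = prev["n_chains"]
                        records[key] = candidate
    g = nx.MultiDiGraph()
    for (kin, sub, site), data in sorted(records.items()):
        g.add_edge(kin, sub, key=site, **data)
    return PathwayMap(g)


def style_edges(
    pathway_map: PathwayMap, width_range: tuple[float, float] = (0.5, 4.0)
) -> PathwayMap:
    """Attach deterministic style: width linear in |log2fc|, color class by direction."""
    lo, hi = width_range
    if hi < lo:
        raise ParameterError("width_range must be (min, max) with max >= min")
    g = pathway_map.graph
    mags = [abs(d["log2fc"]) for _, _, d in g.edges(data=True)]
    top = max(mags) if mags else 0.0
    for _, _, d in g.edges(data=True):
        frac = abs(d["log2fc"]) / top if top > 0 else 0.0
        d["width"] = lo + frac * (hi - lo)
        d["color_class"] = d["direction"]
    return pathway_map


def export_map(pathway_map: PathwayMap, path: str | Path, format: str) -> None:
    """Write the map as 'graphml', 'dot' or 'json' with stable element order."""
    path = Path(path)
    g = pathway_map.graph
    if format == "graphml":
        out = nx.MultiDiGraph()
        for node in sorted(g.nodes):
            out.add_node(node, **g.nodes[node])
        for u, v, k in sorted(g.edges(keys=True)):
            out.add_edge(u, v, key=k, **g[u][v][k])
        nx.write_graphml(out, path)
    elif format == "json":
        doc = {
            "nodes": [{"id": n, **g.nodes[n]} for n in sorted(g.nodes)],
            "edges": [
                {"kinase": u, "substrate": v, **g[u][v][k]}
                for u, v, k in sorted(g.edges(keys=True))
            ],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif format == "dot":
        path.write_text(_to_dot(g))
    else:
        raise ParameterError(f"unknown export format {format!r}")


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _to_dot(g: nx.MultiDiGraph) -> str:
    """Minimal DOT serialisation carrying the style attributes."""
    lines = ["digraph pathway_map {"]
    for node in sorted(g.nodes):
        lines.append(f"    {_dot_quote(node)};")
    for u, v, k in sorted(g.edges(keys=True)):
        d = g[u][v][k]
        attrs = {
            "label": f"{k} ({d.get('cfc', 0):+.1f}%)",
            "penwidth": f"{d.get('width', 1.0):.3f}",
            "color": "red" if d.get("direction") == "up" else "blue",
            "arrowhead": "tee" if d.get("effect") == "inhibition" else "normal",
        }
        attr_text = ", ".join(f"{a}={_dot_quote(b)}" for a, b in attrs.items())
        lines.append(f"    {_dot_quote(u)} -> {_dot_quote(v)} [{attr_text}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def import_map(path: str | Path, format: str) -> PathwayMap:
    """Read back a 'graphml' or 'json' export (lossless for both)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        out = nx.MultiDiGraph()
        for node, data in g.nodes(data=True):
            out.add_node(node, **data)
        for u, v, k, d in g.edges(keys=True, data=True):
            out.add_edge(u, v, key=d.get("site", k), **d)
        return PathwayMap(out)
    if format == "json":
        doc = json.loads(path.read_text())
        g = nx.MultiDiGraph()
        for node in doc["nodes"]:
            node = dict(node)
            g.add_node(node.pop("id"), **node)
        for edge in doc["edges"]:
            edge = dict(edge)
            u = edge.pop("kinase")
            v = edge.pop("substrate")
            g.add_edge(u, v, key=edge["site"], **edge)
        return PathwayMap(g)
    raise ParameterError(f"unknown import format {format!r}")
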