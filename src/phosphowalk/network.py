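"""Signed kinase-substrate networks.

The prior-knowledge input is a set of directed relations *kinase
phosphorylates substrate at site, with activating/inhibitory/unknown effect*.
The network built from them is a :class:`networkx.MultiDiGraph` keyed by
site, so the same protein pair may carry several per-site edges (e.g. AKT
activated via S473 and via Y326 are distinct edges).

Construction coerces every ``unknown`` effect to ``activation``: where no
curated biological data exist the phosphorylation is assumed activating for
the purposes of chain inference. Root kinases — nodes with no incoming
phosphorylation edge — are the only permitted start points of a walk, since
array data alone cannot say which upstream kinase produced a measured event.

Measurements attach per edge target: a retained phosphosite probe for
(substrate, site) sets ``cfc`` (signed percent) and ``weight`` (its absolute
value) on *every* edge delivering that site; pan (expression) probes only
annotate nodes with ``expression_log2fc`` and never influence walks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .arrays import KSRelation, ProbeMeasurement
from .errors import AmbiguousProbeError, TableValidationError

__all__ = [
    "SignedNetwork",
    "build_network",
    "find_roots",
    "attach_measurements",
    "split_signed",
]

UP = "up"
DOWN = "down"


class SignedNetwork:
    """A signed, site-resolved kinase-substrate graph with attached measurements.

    Thin wrapper over a :class:`networkx.MultiDiGraph` whose edge keys are the
    phosphosite labels. Edge attributes: ``effect`` ('activation' |
    'inhibition'), ``cfc`` (signed percent or None when unmeasured),
    ``weight`` (abs(cfc) or None). Node attribute ``expression_log2fc`` comes
    from pan probes.
    """

    def __init__(self, graph: nx.MultiDiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiDiGraph()
        self.unmapped_probes: list[str] = []

    # -- inspection ---------------------------------------------------------

    @property
    def nodes(self):
        return self.graph.nodes

    def edge_keys(self) -> list[tuple[str, str, str]]:
        """Deterministically ordered (kinase, substrate, site) triples."""
        return sorted(self.graph.edges(keys=True))

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_data(self, kinase: str, substrate: str, site: str) -> dict:
        return self.graph[kinase][substrate][site]

    def measured_edges(self) -> list[tuple[str, str, str]]:
        return [
            (u, v, k)
            for u, v, k, d in sorted(self.graph.edges(keys=True, data=True))
            if d.get("cfc") is not None
        ]

    def copy(self) -> "SignedNetwork":
        out = SignedNetwork(self.graph.copy())
        out.unmapped_probes = list(self.unmapped_probes)
        return out

    # -- serialisation ------------------------------------------------------

    def to_edgelist(self, path: str | Path, sep: str = "\t") -> None:
        lines = ["kinase\tsubstrate\tsite\teffect\tcfc\tweight".replace("\t", sep)]
        for u, v, k in self.edge_keys():
            d = self.graph[u][v][k]
            cfc = "" if d.get("cfc") is None else repr(d["cfc"])
            w = "" if d.get("weight") is None else repr(d["weight"])
            lines.append(sep.join([u, v, k, d["effect"], cfc, w]))
        Path(path).write_text("\n".join(lines) + "\n")

    def to_graphml(self, path: str | Path) -> None:
        g = nx.MultiDiGraph()
        for node, data in sorted(self.graph.nodes(data=True)):
            g.add_node(node, **{k: v for k, v in data.items() if v is not None})
        for u, v, k in self.edge_keys():
            d = self.graph[u][v][k]
            g.add_edge(u, v, key=k, site=k, **{a: b for a, b in d.items() if b is not None})
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path: str | Path) -> "SignedNetwork":
        g = nx.read_graphml(path, force_multigraph=True)
        out = nx.MultiDiGraph()
        for node, data in g.nodes(data=True):
            out.add_node(node, **data)
        for u, v, k, d in g.edges(keys=True, data=True):
            key = d.get("site", k)
            d = dict(d)
            d.pop("site", None)
            out.add_edge(u, v, key=key, **d)
        return cls(out)


def build_network(relations: Iterable[KSRelation]) -> SignedNetwork:
    """Build the signed network; ``unknown`` effects become ``activation``."""
    graph = nx.MultiDiGraph()
    for rel in relations:
        effect = "activation" if rel.effect == "unknown" else rel.effect
        if graph.has_edge(rel.kinase, rel.substrate, key=rel.site):
            raise TableValidationError(
                f"duplicate relation {rel.kinase}->{rel.substrate}@{rel.site}"
            )
        graph.add_edge(
            rel.kinase, rel.substrate, key=rel.site, effect=effect, cfc=None, weight=None
        )
    return SignedNetwork(graph)


def find_roots(network: SignedNetwork) -> set[str]:
    """Nodes with in-degree 0 — the most probable upstream kinases, and the
    only permitted walk start points. May be empty (e.g. a pure cycle); the
    walk, not this function, raises for rootless networks."""
    return {v for v in network.graph.nodes if network.graph.in_degree(v) == 0}


def attach_measurements(
    network: SignedNetwork, measurements: Sequence[ProbeMeasurement]
) -> SignedNetwork:
    """Map preprocessed probes onto a copy of the network.

    Phosphosite probes set ``cfc``/``weight`` on every edge delivering their
    (substrate, site); pan probes set the node's ``expression_log2fc`` only.
    Probes matching nothing are recorded in ``unmapped_probes``. Two retained
    probes for the same (substrate, site) raise :class:`AmbiguousProbeError`.
    """
    out = network.copy()
    g = out.graph
    out.unmapped_probes = []
    claimed: dict[tuple[str, str], str] = {}
    for m in measurements:
        target = m.probe.target_symbol
        if m.probe.is_pan:
            if target in g.nodes:
                g.nodes[target]["expression_log2fc"] = m.log2fc
            else:
                out.unmapped_probes.append(m.probe.probe_id)
            continue
        site_key = (target, m.probe.site)
        hit = False
        for u, v, k in g.in_edges(target, keys=True) if target in g.nodes else []:
            if k == m.probe.site:
                hit = True
        if not hit:
            out.unmapped_probes.append(m.probe.probe_id)
            continue
        if site_key in claimed:
            raise AmbiguousProbeError(
                f"probes {claimed[site_key]!r} and {m.probe.probe_id!r} both map to "
                f"{target}@{m.probe.site}"
            )
        claimed[site_key] = m.probe.probe_id
        if m.cfc_percent is None:
            raise TableValidationError(
                f"probe {m.probe.probe_id!r} has no cfc_percent; run preprocessing first"
            )
        for u, v, k in g.in_edges(target, keys=True):
            if k == m.probe.site:
                g[u][v][k]["cfc"] = m.cfc_percent
                g[u][v][k]["weight"] = abs(m.cfc_percent)
    return out


def split_signed(network: SignedNetwork) -> tuple[SignedNetwork, SignedNetwork]:
    """Split into (up, down) subnetworks for the two independent analyses.

    The up network keeps edges with cfc > 0 or unmeasured; the down network
    keeps cfc < 0 or unmeasured; a measured cfc of exactly 0 is neither an up-
    nor a down-regulated event and is excluded from both. Each subnetwork
    keeps exactly the nodes incident to its kept edges.
    """
    def subset(keep) -> SignedNetwork:
        g = nx.MultiDiGraph()
        for u, v, k, d in network.graph.edges(keys=True, data=True):
            cfc = d.get("cfc")
            if keep(cfc):
                g.add_edge(u, v, key=k, **dict(d))
        for node in g.nodes:
            src = network.graph.nodes[node]
            if "expression_log2fc" in src:
                g.nodes[node]["expression_log2fc"] = src["expression_log2fc"]
        return SignedNetwork(g)

    up = subset(lambda c: c is None or c > 0)
    down = subset(lambda c: c is None or c < 0)
    return up, down
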