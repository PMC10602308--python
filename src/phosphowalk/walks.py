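"""Random-walk inference of phosphorylation chains.

A *chain* is a root-anchored, edge-self-avoiding walk over the signed
kinase-substrate network. Walks start at a uniformly chosen root kinase and
step along an untraversed outgoing edge with probability proportional to
``weight + epsilon``, where the weight is the measured |CFC| of the edge's
phosphosite (or an imputed value, below) and epsilon keeps unmeasured edges
reachable. A walk terminates when

1. the current node has no untraversed outgoing edge (``sink``),
2. the last traversed phosphorylation is inhibitory (``inhibition``), or
3. the length cap is reached (``max_length``; only relevant on cyclic input).

Where a node has exactly one downstream option and that edge carries no
measurement, a percent fold change is imputed for the single path: drawn
uniformly in [0, 20] for an experimental dataset, exactly 20 for a control
dataset. Imputed values are flagged in the chain record. Because imputation
only ever applies to single options, it never alters transition
probabilities — only the recorded per-edge CFC.

"Occurring more or less frequently than expected" is made precise by a
permutation null: the multiset of measured signed CFC values is reassigned
to a uniformly random subset of the full network's edges, the up/down split
is recomputed, and the walks rerun; the expected frequency of a chain is its
mean frequency over these reruns. This preserves the network topology and
the measured value distribution while breaking the association between
values and edges.

:func:`enumerate_chains` is an exact brute-force enumeration of the same
walk process, used as an independent oracle for the sampler on small
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .config import RunConfig
from .errors import NotApplicableError, ParameterError, RootlessNetworkError
from .network import SignedNetwork
from .seeds import derive_seed

__all__ = [
    "PhosphoChain",
    "WalkEstimate",
    "InferenceRun",
    "check_termination",
    "impute_single_path",
    "enumerate_chains",
    "random_walk",
    "null_expectation",
    "resolve_parallel",
    "select_chains",
    "infer_direction_run",
]

MEASURED = "measured"
IMPUTED = "imputed"
UNMEASURED = "none"

ChainKey = tuple[tuple[str, str, str], ...]


@dataclass(frozen=True)
class PhosphoChain:
    """One inferred chain of phosphorylation events.

    ``edges`` are (kinase, substrate, site, effect) in walk order;
    ``per_edge_cfc`` pairs each edge with (signed percent or None, source),
    source in {"measured", "imputed", "none"}.
    """

    edges: tuple[tuple[str, str, str, str], ...]
    direction: str
    per_edge_cfc: tuple[tuple[float | None, str], ...]
    termination_reason: str

    @property
    def key(self) -> ChainKey:
        return tuple((k, s, site) for k, s, site, _ in self.edges)

    @property
    def root(self) -> str:
        return self.edges[0][0]

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.edges[0][0],) + tuple(e[1] for e in self.edges)

    @property
    def n_intermediates(self) -> int:
        """Internal nodes strictly between the root and the terminal node."""
        return len(self.edges) - 1

    @property
    def score(self) -> float:
        """min over edges of |CFC|; an edge without a value scores 0."""
        return min((abs(v) if v is not None else 0.0) for v, _ in self.per_edge_cfc)

    def path_label(self) -> str:
        parts = [self.edges[0][0]]
        for k, s, site, effect in self.edges:
            arrow = "-|" if effect == "inhibition" else "->"
            parts.append(f"{arrow}{s}@{site}")
        return "".join(parts)


@dataclass
class WalkEstimate:
    """Observed vs null-expected chain frequencies.

    ``observed`` maps a chain key to its fraction of walks (sums to 1 over
    complete chains); ``expected``/``enrichment`` are filled by
    :func:`null_expectation`.
    """

    observed: dict[ChainKey, float]
    chains: dict[ChainKey, PhosphoChain]
    n_walks: int
    seed: int
    expected: dict[ChainKey, float] | None = None
    enrichment: dict[ChainKey, float] | None = None
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# compiled representation


class _Compiled:
    """Array view of a SignedNetwork with a deterministic edge order."""

    def __init__(self, network: SignedNetwork):
        g = network.graph
        self.nodes: list[str] = sorted(g.nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        triples = []
        for u, v, k in sorted(g.edges(keys=True)):
            d = g[u][v][k]
            triples.append((u, v, k, d["effect"], d.get("cfc")))
        self.triples = [(u, v, k, e) for u, v, k, e, _ in triples]
        self.tail = np.array([self.index[t[0]] for t in triples], dtype=np.int64)
        self.head = np.array([self.index[t[1]] for t in triples], dtype=np.int64)
        self.inhib = np.array([t[3] == "inhibition" for t in triples], dtype=bool)
        self.cfc = np.array(
            [np.nan if t[4] is None else float(t[4]) for t in triples], dtype=float
        )
        self.acyclic = nx.is_directed_acyclic_graph(g)

    @property
    def n_edges(self) -> int:
        return len(self.triples)


class _WalkGraph:
    """A walkable (sub)graph: one CFC assignment plus a direction mask."""

    def __init__(
        self,
        comp: _Compiled,
        cfc: np.ndarray,
        direction: str | None,
        epsilon: float,
        impute_rng: np.random.Generator,
        condition: str,
        impute_mode: str,
    ):
        self.comp = comp
        measured = ~np.isnan(cfc)
        if direction == "up":
            allowed = ~measured | (cfc > 0)
        elif direction == "down":
            allowed = ~measured | (cfc < 0)
        else:
            allowed = np.ones(comp.n_edges, dtype=bool)
        eids = np.flatnonzero(allowed)
        self.cfc = cfc
        self.measured = measured
        self.empty = eids.size == 0
        self.direction = direction
        if self.empty:
            self.roots = np.empty(0, dtype=np.int64)
            self.imputed: dict[int, float] = {}
            return
        tails = comp.tail[eids]
        heads = comp.head[eids]
        incident = np.zeros(comp.n, dtype=bool)
        incident[tails] = True
        incident[heads] = True
        indeg = np.bincount(heads, minlength=comp.n)
        self.roots = np.flatnonzero(incident & (indeg == 0))
        order = np.argsort(tails, kind="stable")
        self.out_eids = eids[order]
        sorted_tails = tails[order]
        self.indptr = np.searchsorted(sorted_tails, np.arange(comp.n + 1))
        self.outdeg = np.diff(self.indptr)

        weights = np.where(measured, np.abs(cfc), 0.0)
        # rule 3: single downstream option with no measurement gets an imputed
        # percent fold change (node index order keeps the draws deterministic)
        self.imputed = {}
        for v in np.flatnonzero(self.outdeg == 1):
            e = int(self.out_eids[self.indptr[v]])
            if not measured[e]:
                if condition == "control":
                    value = 20.0
                elif impute_mode == "fixed":
                    value = 10.0
                else:
                    value = float(impute_rng.uniform(0.0, 20.0))
                self.imputed[e] = value
                weights[e] = value
        self.weights = weights
        self.walk_w = weights + epsilon
        # per-node cumulative weight over its outgoing allowed edges
        self.cumw = [
            np.cumsum(self.walk_w[self.out_eids[self.indptr[v]: self.indptr[v + 1]]])
            if self.outdeg[v]
            else None
            for v in range(comp.n)
        ]

    def out_edges(self, v: int) -> np.ndarray:
        return self.out_eids[self.indptr[v]: self.indptr[v + 1]]


def _walk_paths(
    wg: _WalkGraph, n_walks: int, rng: np.random.Generator, max_length: int
) -> np.ndarray:
    """Simulate n_walks walks; rows are edge-id paths padded with -1."""
    if wg.roots.size == 0:
        raise RootlessNetworkError(
            "network has no in-degree-0 node to start a walk from"
        )
    if wg.comp.acyclic:
        return _walk_vectorized(wg, n_walks, rng, max_length)
    return _walk_generic(wg, n_walks, rng, max_length)


def _walk_vectorized(
    wg: _WalkGraph, n_walks: int, rng: np.random.Generator, max_length: int
) -> np.ndarray:
    # on an acyclic network a walk can never revisit a node, so edge
    # self-avoidance is vacuous and all walks can step in lock-step
    paths = np.full((n_walks, max_length), -1, dtype=np.int32)
    pos = wg.roots[rng.integers(0, wg.roots.size, size=n_walks)]
    active = np.ones(n_walks, dtype=bool)
    for t in range(max_length):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        nodes_at = pos[idx]
        deg = wg.outdeg[nodes_at]
        stuck = deg == 0
        if stuck.any():
            active[idx[stuck]] = False
            idx = idx[~stuck]
            nodes_at = nodes_at[~stuck]
        if idx.size == 0:
            continue
        r = rng.random(idx.size)
        chosen = np.empty(idx.size, dtype=np.int64)
        order = np.argsort(nodes_at, kind="stable")
        uniq, starts = np.unique(nodes_at[order], return_index=True)
        bounds = np.append(starts, idx.size)
        for gi, v in enumerate(uniq):
            sel = order[bounds[gi]: bounds[gi + 1]]
            cw = wg.cumw[v]
            picks = np.searchsorted(cw, r[sel] * cw[-1], side="right")
            picks = np.minimum(picks, cw.size - 1)  # guard float edge case
            chosen[sel] = wg.out_eids[wg.indptr[v] + picks]
        paths[idx, t] = chosen
        pos[idx] = wg.comp.head[chosen]
        hit_inhib = wg.comp.inhib[chosen]
        if hit_inhib.any():
            active[idx[hit_inhib]] = False
    return paths


def _walk_generic(
    wg: _WalkGraph, n_walks: int, rng: np.random.Generator, max_length: int
) -> np.ndarray:
    paths = np.full((n_walks, max_length), -1, dtype=np.int32)
    head = wg.comp.head
    inhib = wg.comp.inhib
    for w in range(n_walks):
        node = int(wg.roots[rng.integers(0, wg.roots.size)])
        traversed: set[int] = set()
        for t in range(max_length):
            cands = [int(e) for e in wg.out_edges(node) if int(e) not in traversed]
            if not cands:
                break
            weights = wg.walk_w[cands]
            cum = np.cumsum(weights)
            pick = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            pick = min(pick, len(cands) - 1)
            e = cands[pick]
            paths[w, t] = e
            traversed.add(e)
            node = int(head[e])
            if inhib[e]:
                break
    return paths


def _termination_reason(wg: _WalkGraph, eids: Sequence[int], max_length: int) -> str:
    last = eids[-1]
    if wg.comp.inhib[last]:
        return "inhibition"
    if len(eids) < max_length:
        return "sink"
    node = int(wg.comp.head[last])
    remaining = [e for e in wg.out_edges(node) if int(e) not in set(eids)]
    return "sink" if not remaining else "max_length"


def _chain_record(
    wg: _WalkGraph, eids: Sequence[int], direction: str | None, max_length: int
) -> PhosphoChain:
    sign = -1.0 if direction == "down" else 1.0
    per_edge = []
    for e in eids:
        if wg.measured[e]:
            per_edge.append((float(wg.cfc[e]), MEASURED))
        elif int(e) in wg.imputed:
            per_edge.append((sign * wg.imputed[int(e)], IMPUTED))
        else:
            per_edge.append((None, UNMEASURED))
    return PhosphoChain(
        edges=tuple(wg.comp.triples[int(e)] for e in eids),
        direction=direction or "",
        per_edge_cfc=tuple(per_edge),
        termination_reason=_termination_reason(wg, list(map(int, eids)), max_length),
    )


def _count_paths(paths: np.ndarray) -> dict[tuple[int, ...], int]:
    used = np.flatnonzero((paths >= 0).any(axis=0))
    if used.size == 0:
        return {}
    trimmed = paths[:, : used[-1] + 1]
    order = np.lexsort(trimmed.T[::-1])
    rows = trimmed[order]
    change = np.any(rows[1:] != rows[:-1], axis=1)
    starts = np.concatenate([[0], np.flatnonzero(change) + 1])
    counts = np.diff(np.concatenate([starts, [rows.shape[0]]]))
    out: dict[tuple[int, ...], int] = {}
    for start, count in zip(starts, counts):
        eids = tuple(int(e) for e in rows[start] if e >= 0)
        if eids:
            out[eids] = out.get(eids, 0) + int(count)
    return out


# ---------------------------------------------------------------------------
# public operations


def check_termination(chain: PhosphoChain, network: SignedNetwork) -> str:
    """Apply the termination rules to a partial chain: 'inhibition' if the last
    phosphorylation is inhibitory, 'sink' if the terminal node has no
    untraversed outgoing edge, else 'continue'."""
    if not chain.edges:
        raise ParameterError("chain must be nonempty")
    if chain.edges[-1][3] == "inhibition":
        return "inhibition"
    terminal = chain.edges[-1][1]
    used = {(k, s, site) for k, s, site, _ in chain.edges}
    g = network.graph
    if terminal in g.nodes:
        for u, v, k in g.out_edges(terminal, keys=True):
            if (u, v, k) not in used:
                return "continue"
    return "sink"


def impute_single_path(
    node: str,
    network: SignedNetwork,
    condition: str = "experimental",
    rng_seed: int = 0,
    impute_mode: str = "uniform",
) -> float:
    """Imputed percent fold change for a node's single unmeasured downstream path.

    Control datasets get exactly 20; experimental datasets a seeded uniform
    draw in [0, 20] (or the fixed midpoint 10 with ``impute_mode='fixed'``).
    Raises :class:`NotApplicableError` unless the node has exactly one
    outgoing edge and that edge is unmeasured.
    """
    out = list(network.graph.out_edges(node, keys=True, data=True))
    if len(out) != 1:
        raise NotApplicableError(
            f"single-path imputation needs exactly one downstream option, "
            f"{node!r} has {len(out)}"
        )
    if out[0][3].get("cfc") is not None:
        raise NotApplicableError(f"the single downstream edge of {node!r} is measured")
    if condition == "control":
        return 20.0
    if impute_mode == "fixed":
        return 10.0
    return float(np.random.default_rng(rng_seed).uniform(0.0, 20.0))


def enumerate_chains(
    network: SignedNetwork, max_length: int = 25, *, epsilon: float = 1.0
) -> dict[ChainKey, float]:
    """Exact chain distribution of the walk process by exhaustive enumeration.

    Independent oracle for :func:`random_walk`: every root-to-termination
    chain with its exact probability under the transition rule; probabilities
    sum to 1. Exponential in the worst case — intended for small networks.
    """
    comp = _Compiled(network)
    wg = _WalkGraph(
        comp,
        comp.cfc,
        None,
        epsilon,
        np.random.default_rng(0),
        "experimental",
        "fixed",
    )
    if wg.empty or wg.roots.size == 0:
        raise RootlessNetworkError("cannot enumerate chains of a rootless network")
    dist: dict[tuple[int, ...], float] = {}

    def rec(node: int, traversed: frozenset[int], prob: float, path: tuple[int, ...]):
        cands = [int(e) for e in wg.out_edges(node) if int(e) not in traversed]
        if not cands or len(path) >= max_length:
            dist[path] = dist.get(path, 0.0) + prob
            return
        total = float(np.sum(wg.walk_w[cands]))
        for e in cands:
            p = prob * float(wg.walk_w[e]) / total
            if wg.comp.inhib[e]:
                key = path + (e,)
                dist[key] = dist.get(key, 0.0) + p
            else:
                rec(int(wg.comp.head[e]), traversed | {e}, p, path + (e,))

    root_p = 1.0 / wg.roots.size
    for r in wg.roots:
        rec(int(r), frozenset(), root_p, ())
    return {
        tuple((comp.triples[e][0], comp.triples[e][1], comp.triples[e][2]) for e in eids): p
        for eids, p in dist.items()
        if eids
    }


def random_walk(
    network: SignedNetwork,
    n_walks: int,
    seed: int,
    *,
    epsilon: float = 1.0,
    max_length: int = 25,
    condition: str = "experimental",
    impute_mode: str = "uniform",
    direction: str | None = None,
) -> WalkEstimate:
    """Monte Carlo estimate of the chain distribution (observed only)."""
    if n_walks < 1:
        raise ParameterError("n_walks must be >= 1")
    comp = _Compiled(network)
    rng = np.random.default_rng(seed)
    wg = _WalkGraph(comp, comp.cfc, None, epsilon, rng, condition, impute_mode)
    if wg.empty:
        return WalkEstimate(observed={}, chains={}, n_walks=n_walks, seed=seed)
    paths = _walk_paths(wg, n_walks, rng, max_length)
    counts = _count_paths(paths)
    observed: dict[ChainKey, float] = {}
    chains: dict[ChainKey, PhosphoChain] = {}
    for eids, c in counts.items():
        chain = _chain_record(wg, eids, direction, max_length)
        observed[chain.key] = c / n_walks
        chains[chain.key] = chain
    return WalkEstimate(observed=observed, chains=chains, n_walks=n_walks, seed=seed)


def null_expectation(
    network: SignedNetwork,
    n_walks: int,
    n_permutations: int,
    seed: int,
    *,
    direction: str | None = None,
    epsilon: float = 1.0,
    max_length: int = 25,
    condition: str = "experimental",
    impute_mode: str = "uniform",
) -> WalkEstimate:
    """Observed chain frequencies plus their permutation-null expectation.

    ``network`` is the full measurement-attached network; ``direction``
    restricts the walks to the up or down subnetwork (None walks everything).
    Each permutation reassigns the measured signed CFC values to a random
    subset of all edges, recomputes the direction split and reruns the walks.
    Chains never seen under the null get the pseudo-floor
    ``1 / (n_walks * n_permutations)`` as their expectation.
    """
    if n_walks < 1 or n_permutations < 1:
        raise ParameterError("n_walks and n_permutations must be >= 1")
    comp = _Compiled(network)
    rng = np.random.default_rng(seed)

    wg = _WalkGraph(comp, comp.cfc, direction, epsilon, rng, condition, impute_mode)
    estimate = WalkEstimate(
        observed={}, chains={}, n_walks=n_walks, seed=seed, n_permutations=n_permutations
    )
    if wg.empty:
        estimate.expected = {}
        estimate.enrichment = {}
        return estimate
    paths = _walk_paths(wg, n_walks, rng, max_length)
    counts = _count_paths(paths)
    for eids, c in counts.items():
        chain = _chain_record(wg, eids, direction, max_length)
        estimate.observed[chain.key] = c / n_walks
        estimate.chains[chain.key] = chain

    measured_ids = np.flatnonzero(~np.isnan(comp.cfc))
    values = comp.cfc[measured_ids]
    null_counts: dict[ChainKey, int] = {key: 0 for key in estimate.observed}
    # map edge-id tuples to observed chain keys for fast null lookups
    key_by_eids = {eids: _chain_record(wg, eids, direction, max_length).key for eids in counts}

    for _ in range(n_permutations):
        null_cfc = np.full(comp.n_edges, np.nan)
        if values.size:
            targets = rng.permutation(comp.n_edges)[: values.size]
            null_cfc[targets] = rng.permutation(values)
        nwg = _WalkGraph(comp, null_cfc, direction, epsilon, rng, condition, impute_mode)
        if nwg.empty or nwg.roots.size == 0:
            continue  # this null draw admits no walks; contributes zero counts
        npaths = _walk_paths(nwg, n_walks, rng, max_length)
        ncounts = _count_paths(npaths)
        for eids, c in ncounts.items():
            key = key_by_eids.get(eids)
            if key is None:
                # not an observed chain; only observed chains need expectations
                continue
            null_counts[key] += c

    floor = 1.0 / (n_walks * n_permutations)
    total = n_walks * n_permutations
    estimate.expected = {
        key: (null_counts[key] / total if null_counts[key] else floor)
        for key in estimate.observed
    }
    estimate.enrichment = {
        key: estimate.observed[key] / estimate.expected[key] for key in estimate.observed
    }
    return estimate


# ---------------------------------------------------------------------------
# chain post-processing


def _effective_abs(value: float | None) -> float:
    return abs(value) if value is not None else 0.0


def _trim_trailing(chain: PhosphoChain, min_cfc: float) -> PhosphoChain | None:
    """Drop trailing edges whose |CFC| does not exceed ``min_cfc``.

    Complete walks routinely overshoot the measured part of a cascade into
    unmeasured (~0% change) territory; the selection rules apply to the
    measured pathway, so trailing sub-threshold edges are trimmed before
    filtering. Interior failures still reject the chain later. Returns None
    when nothing survives.
    """
    n = len(chain.edges)
    while n > 0 and _effective_abs(chain.per_edge_cfc[n - 1][0]) <= min_cfc:
        n -= 1
    if n == 0:
        return None
    if n == len(chain.edges):
        return chain
    reason = "inhibition" if chain.edges[n - 1][3] == "inhibition" else "sink"
    return replace(
        chain,
        edges=chain.edges[:n],
        per_edge_cfc=chain.per_edge_cfc[:n],
        termination_reason=reason,
    )


def _chain_sort_key(chain: PhosphoChain):
    return (-chain.score, chain.key)


def resolve_parallel(chains: Iterable[PhosphoChain]) -> list[PhosphoChain]:
    """Resolve parallel phosphorylation: when several chains deliver the same
    (substrate, site) via *different* immediate kinases, keep only those whose
    delivering edge has the greatest |CFC|; ties keep all. Different sites on
    the same substrate are untouched."""
    chains = list(chains)
    best: dict[tuple[str, str], float] = {}
    kinases: dict[tuple[str, str], set[str]] = {}
    for chain in chains:
        for (kin, sub, site, _), (value, _src) in zip(chain.edges, chain.per_edge_cfc):
            target = (sub, site)
            mag = _effective_abs(value)
            kinases.setdefault(target, set()).add(kin)
            if mag > best.get(target, -1.0):
                best[target] = mag

    def keeps(chain: PhosphoChain) -> bool:
        for (kin, sub, site, _), (value, _src) in zip(chain.edges, chain.per_edge_cfc):
            target = (sub, site)
            if len(kinases[target]) < 2:
                continue  # no competing kinase for this site
            if _effective_abs(value) < best[target]:
                return False
        return True

    return sorted((c for c in chains if keeps(c)), key=_chain_sort_key)


def select_chains(
    chains: Iterable[PhosphoChain],
    min_intermediates: int = 2,
    min_cfc: float = 5.0,
    *,
    cfc_mode: str = "all_edges",
) -> list[PhosphoChain]:
    """Apply the pathway selection rules.

    After trimming trailing sub-threshold edges, a chain is kept iff it has
    strictly more than ``min_intermediates`` internal nodes and (all-edges
    mode) every per-edge |CFC| strictly exceeds ``min_cfc`` — an edge without
    a measured or imputed value counts as 0. ``cfc_mode='mean'`` tests the
    mean |CFC| instead. Output is deduplicated and sorted by score descending.
    """
    selected: dict[ChainKey, PhosphoChain] = {}
    for chain in chains:
        trimmed = _trim_trailing(chain, min_cfc)
        if trimmed is None or trimmed.n_intermediates <= min_intermediates:
            continue
        mags = [_effective_abs(v) for v, _ in trimmed.per_edge_cfc]
        if cfc_mode == "mean":
            ok = sum(mags) / len(mags) > min_cfc
        else:
            ok = all(m > min_cfc for m in mags)
        if not ok:
            continue
        prev = selected.get(trimmed.key)
        if prev is None or trimmed.score > prev.score:
            selected[trimmed.key] = trimmed
    return sorted(selected.values(), key=_chain_sort_key)


@dataclass
class InferenceRun:
    """Full two-direction inference output."""

    up_chains: list[PhosphoChain]
    down_chains: list[PhosphoChain]
    hits: list[tuple[str, str, str, float]]  # (target, site, direction, cfc)
    up_estimate: WalkEstimate
    down_estimate: WalkEstimate

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    def all_chains(self) -> list[PhosphoChain]:
        return list(self.up_chains) + list(self.down_chains)


def infer_direction_run(
    network: SignedNetwork, config: RunConfig | None = None, seed: int | None = None
) -> InferenceRun:
    """Run the complete inference for both directions on an attached network.

    Per direction: walk -> permutation null -> enrichment gate (keep chains
    with enrichment >= hi or <= lo) -> trailing trim -> parallel resolution ->
    selection. A *hit* is a measured phosphosite appearing in at least one
    selected chain of a direction.
    """
    config = (config or RunConfig()).validate()
    seed = config.seed if seed is None else seed

    per_direction: dict[str, tuple[list[PhosphoChain], WalkEstimate]] = {}
    for direction in ("up", "down"):
        est = null_expectation(
            network,
            config.n_walks,
            config.n_permutations,
            derive_seed(seed, "walk", direction),
            direction=direction,
            epsilon=config.epsilon,
            max_length=config.max_length,
            condition=config.condition,
            impute_mode=config.impute_mode,
        )
        if config.enrichment_gate and est.enrichment:
            kept = [
                est.chains[k]
                for k in sorted(est.chains)
                if est.enrichment[k] >= config.enrichment_hi
                or est.enrichment[k] <= config.enrichment_lo
            ]
        else:
            kept = [est.chains[k] for k in sorted(est.chains)]
        # trim before parallel resolution so trailing ~0% edges cannot make a
        # chain "deliver" a site it has no real evidence for
        trimmed: dict[ChainKey, PhosphoChain] = {}
        for chain in kept:
            t = _trim_trailing(chain, config.min_cfc)
            if t is None:
                continue
            prev = trimmed.get(t.key)
            if prev is None or t.score > prev.score:
                trimmed[t.key] = t
        kept = resolve_parallel(trimmed.values())
        chains = select_chains(
            kept,
            min_intermediates=config.min_intermediates,
            min_cfc=config.min_cfc,
            cfc_mode=config.cfc_mode,
        )
        per_direction[direction] = (chains, est)

    hits: dict[tuple[str, str, str], float] = {}
    for direction in ("up", "down"):
        for chain in per_direction[direction][0]:
            for (kin, sub, site, _), (value, src) in zip(chain.edges, chain.per_edge_cfc):
                if src == MEASURED:
                    hits.setdefault((sub, site, direction), float(value))
    hit_list = sorted((t, s, d, v) for (t, s, d), v in hits.items())

    return InferenceRun(
        up_chains=per_direction["up"][0],
        down_chains=per_direction["down"][0],
        hits=hit_list,
        up_estimate=per_direction["up"][1],
        down_estimate=per_direction["down"][1],
    )
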