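"""Functional network construction and overlapping module detection.

Modules are detected with a clique-seeded agglomerative procedure (EAGLE):
maximal cliques at least ``min_clique`` large seed the initial communities,
uncovered genes start as singletons, and communities are merged greedily by
the modularity-flavoured similarity

    S(C1, C2) = (1/2m) * sum_{v in C1\\C2} sum_{w in C2\\C1} [A_vw - k_v k_w / 2m]

until one community remains per connected component. The cover reported is
the dendrogram level maximizing the extended modularity

    EQ = (1/2m) * sum_M sum_{v,w in M} [A_vw - k_v k_w / 2m] / (O_v O_w)

where O_v counts the communities containing gene v, so overlapping genes are
down-weighted rather than double-counted. Edge weights, when present, are
accepted but ignored: adjacency is binary throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ComorbnetError, FormatError
from .stats import EnrichmentResult, bh_adjust, fisher_one_sided
from .types import CHANNELS, EvidenceChannel

__all__ = [
    "EDGE_TYPES",
    "Network",
    "Cover",
    "ModuleAnnotation",
    "build_network",
    "maximal_cliques",
    "extended_modularity",
    "eagle",
    "module_overlap_genes",
    "annotate_modules",
    "write_cover",
]

#: Functional edge classes admitted into the shared-gene network.
EDGE_TYPES = frozenset({"coexpression", "physical", "pathway"})


@dataclass
class Network:
    """A simple undirected gene network with typed edges.

    Parallel typed edges collapse into one edge carrying a type set (edge
    attribute ``types``); isolated genes stay in the node set.
    """

    graph: nx.Graph
    connectivity: float  # fraction of nodes with degree >= 1

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class Cover:
    """A possibly-overlapping module assignment with its extended modularity."""

    modules: list[tuple[str, ...]]
    eq: float
    dendrogram: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(
        default_factory=list
    )


@dataclass
class ModuleAnnotation:
    module_id: int
    size: int
    channel_counts: dict[EvidenceChannel, int]
    enrichment: list[EnrichmentResult]


def build_network(
    tbl,  # SharedGeneTable
    edge_file,
    allowed_types: frozenset[str] = EDGE_TYPES,
) -> Network:
    """Restrict an edge list to the shared genes and the allowed edge types.

    The edge file is a TSV with columns gene1, gene2, type and an optional
    weight column; '#' lines are ignored. Edges whose type is outside the
    declared vocabulary raise; edges touching genes outside the shared set
    are dropped; self-loops are discarded.
    """
    shared = {row.gene for row in tbl.rows}
    df = pd.read_csv(edge_file, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("gene1", "gene2", "type"):
        if col not in df.columns:
            raise FormatError(f"edge file missing mandatory column {col!r}")
    g = nx.Graph()
    g.add_nodes_from(sorted(shared))
    vocabulary = EDGE_TYPES | frozenset(allowed_types)
    for row in df.itertuples(index=False):
        etype = row.type
        if etype not in vocabulary:
            raise FormatError(f"unknown edge type {etype!r}")
        if etype not in allowed_types:
            continue
        u, v = row.gene1, row.gene2
        if u == v or u not in shared or v not in shared:
            continue
        if g.has_edge(u, v):
            g[u][v]["types"] = g[u][v]["types"] | {etype}
        else:
            weight = float(row.weight) if hasattr(row, "weight") and row.weight else None
            g.add_edge(u, v, types={etype}, weight=weight)
    n = g.number_of_nodes()
    connected = sum(1 for v in g if g.degree(v) > 0)
    return Network(graph=g, connectivity=connected / n if n else 0.0)


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, Network) else net


def maximal_cliques(net) -> list[tuple[str, ...]]:
    """All maximal cliques, members sorted, ordered by (size desc, members)."""
    g = _as_graph(net)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def extended_modularity(net, modules: Sequence[Iterable[str]]) -> float:
    """Extended modularity EQ of a (possibly overlapping) cover.

    Genes outside every module contribute membership count 1 (implicit
    singletons); a module referencing a gene absent from the network raises.
    """
    g = _as_graph(net)
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mods = [frozenset(m) for m in modules]
    for m in mods:
        unknown = [v for v in m if v not in idx]
        if unknown:
            raise ComorbnetError(f"module contains unknown gene(s): {sorted(unknown)}")
    m_edges = g.number_of_edges()
    if m_edges == 0:
        return 0.0
    two_m = 2.0 * m_edges
    deg = np.array([g.degree(v) for v in nodes], dtype=float)
    o = np.ones(len(nodes))
    counts = np.zeros(len(nodes))
    for mod in mods:
        for v in mod:
            counts[idx[v]] += 1
    o = np.maximum(counts, 1.0)
    eq = 0.0
    for mod in mods:
        members = sorted(mod)
        # adjacency part: ordered pairs of adjacent members
        a_part = 0.0
        mset = set(members)
        for v in members:
            ov = o[idx[v]]
            for w in g[v]:
                if w in mset:
                    a_part += 1.0 / (ov * o[idx[w]])
        # null part over all ordered pairs including the diagonal
        s = sum(deg[idx[v]] / o[idx[v]] for v in members)
        eq += a_part - s * s / two_m
    return eq / two_m


def _similarity_matrix(memberships: list[np.ndarray], bmat: np.ndarray):
    m_arr = np.array(memberships, dtype=float)
    v_arr = m_arr @ bmat
    return m_arr, v_arr @ m_arr.T


def eagle(
    net,
    min_clique: int = 10,
    min_complex: int = 10,
    seed: int = 0,
) -> Cover:
    """Clique-seeded agglomerative overlapping-module detection.

    ``min_clique`` filters the maximal-clique seeds; ``min_complex`` filters
    the modules of the reported cover (smaller communities remain visible in
    the dendrogram). The procedure is fully deterministic: similarity ties
    break by lexicographic comparison of the sorted member lists, so ``seed``
    only labels the run. Connected components are agglomerated independently.
    """
    if min_clique < 2:
        raise ComorbnetError("min_clique must be >= 2")
    if min_complex < 1:
        raise ComorbnetError("min_complex must be >= 1")
    g = _as_graph(net)
    nodes = sorted(g.nodes)
    if not nodes:
        return Cover(modules=[], eq=0.0, dendrogram=[])
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m_edges = g.number_of_edges()

    seeds = [frozenset(idx[v] for v in c) for c in maximal_cliques(g) if len(c) >= min_clique]
    covered: set[int] = set().union(*seeds) if seeds else set()
    comms: list[frozenset[int]] = seeds + [
        frozenset({idx[v]}) for v in nodes if idx[v] not in covered
    ]
    comms.sort(key=lambda c: tuple(sorted(nodes[i] for i in c)))

    comp_of: dict[int, int] = {}
    for ci, cc in enumerate(sorted(nx.connected_components(g), key=min)):
        for v in cc:
            comp_of[idx[v]] = ci

    def labels(c: frozenset[int]) -> tuple[str, ...]:
        return tuple(sorted(nodes[i] for i in c))

    if m_edges == 0:
        mods = [labels(c) for c in comms if len(c) >= min_complex]
        mods.sort(key=lambda t: (-len(t), t))
        return Cover(modules=mods, eq=0.0, dendrogram=[])

    two_m = 2.0 * m_edges
    adj = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = adj.sum(axis=1)
    bmat = adj - np.outer(deg, deg) / two_m

    active: dict[int, frozenset[int]] = {i: c for i, c in enumerate(comms)}
    lab: dict[int, tuple[str, ...]] = {i: labels(c) for i, c in enumerate(comms)}
    comp: dict[int, int] = {i: comp_of[next(iter(c))] for i, c in enumerate(comms)}
    member_vec: dict[int, np.ndarray] = {}
    bvec: dict[int, np.ndarray] = {}
    for i, c in active.items():
        mv = np.zeros(n)
        mv[list(c)] = 1.0
        member_vec[i] = mv
        bvec[i] = bmat @ mv

    def similarity(i: int, j: int) -> float:
        ci, cj = active[i], active[j]
        overlap = ci & cj
        s2m = float(member_vec[i] @ bvec[j])
        if overlap:
            ov = np.zeros(n)
            ov[list(overlap)] = 1.0
            bo = bmat @ ov
            s2m = s2m - float((member_vec[i] + member_vec[j]) @ bo) + float(ov @ bo)
        return s2m / two_m

    sim: dict[tuple[int, int], float] = {}
    ids = sorted(active)
    for ai in range(len(ids)):
        for aj in range(ai + 1, len(ids)):
            i, j = ids[ai], ids[aj]
            if comp[i] == comp[j]:
                sim[(i, j)] = similarity(i, j)

    # membership counts and per-community EQ terms
    o_counts = np.zeros(n)
    for c in active.values():
        for v in c:
            o_counts[v] += 1

    def eq_term(i: int) -> float:
        w = member_vec[i] / o_counts
        return float(w @ (bmat @ w))

    terms: dict[int, float] = {i: eq_term(i) for i in active}
    current_eq = sum(terms.values()) / two_m
    best_eq = current_eq
    best_cover = [active[i] for i in sorted(active)]
    dendrogram: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    next_id = len(comms)

    while sim:
        s_best = max(sim.values())
        # among pairs with maximal S, the lexicographically smallest (sorted)
        # pair of member lists wins
        candidates = [k for k, v in sim.items() if v == s_best]
        i, j = min(candidates, key=lambda k: tuple(sorted((lab[k[0]], lab[k[1]]))))
        left, right = sorted((lab[i], lab[j]))
        dendrogram.append((left, right, s_best))

        merged = active[i] | active[j]
        overlap = active[i] & active[j]
        for v in overlap:
            o_counts[v] -= 1  # two memberships collapse into one
        for k in (i, j):
            del active[k], lab[k], member_vec[k], bvec[k], terms[k]
        sim = {k: v for k, v in sim.items() if i not in k and j not in k}
        new_id = next_id
        next_id += 1
        active[new_id] = merged
        lab[new_id] = labels(merged)
        mv = np.zeros(n)
        mv[list(merged)] = 1.0
        member_vec[new_id] = mv
        bvec[new_id] = bmat @ mv
        comp[new_id] = comp_of[next(iter(merged))]
        for k in list(active):
            if k != new_id and comp[k] == comp[new_id]:
                sim[(min(k, new_id), max(k, new_id))] = similarity(
                    min(k, new_id), max(k, new_id)
                )
        # recompute EQ terms affected by membership-count changes
        if overlap:
            for k, c in active.items():
                if k != new_id and c & overlap:
                    terms[k] = eq_term(k)
        terms[new_id] = eq_term(new_id)
        current_eq = sum(terms.values()) / two_m
        if current_eq > best_eq + 1e-12:
            best_eq = current_eq
            best_cover = [active[k] for k in sorted(active)]

    mods = [labels(c) for c in best_cover if len(c) >= min_complex]
    mods.sort(key=lambda t: (-len(t), t))
    return Cover(modules=mods, eq=best_eq, dendrogram=dendrogram)


def module_overlap_genes(cover: Cover) -> dict[str, set[int]]:
    """Genes belonging to two or more modules, mapped to 1-based module ids."""
    membership: dict[str, set[int]] = {}
    for mid, mod in enumerate(cover.modules, start=1):
        for gene in mod:
            membership.setdefault(gene, set()).add(mid)
    return {g: ids for g, ids in membership.items() if len(ids) >= 2}


def annotate_modules(
    cover: Cover,
    tbl,  # SharedGeneTable
    collections: Mapping[str, Iterable[str]],
    background: Optional[set[str]] = None,
    alpha: float = 0.05,
) -> list[ModuleAnnotation]:
    """Evidence-channel counts and gene-set enrichment per module.

    The enrichment background defaults to the network node set implied by the
    shared-gene table; BH correction runs jointly across all (module, term)
    tests so module annotations are comparable.
    """
    channels_by_gene = {
        row.gene: row.channels_a | row.channels_b for row in tbl.rows
    }
    if background is None:
        background = set(channels_by_gene)
    term_members = {t: set(members) & background for t, members in collections.items()}
    tests = []  # (module index, term, k, K, p)
    for mi, mod in enumerate(cover.modules):
        query = set(mod) & background
        n = len(query)
        for term in sorted(term_members):
            members = term_members[term]
            K = len(members)
            k = len(query & members)
            res = fisher_one_sided(k, n - k, K - k, len(background) - K - (n - k))
            tests.append((mi, term, k, K, n, res.p))
    qvals = bh_adjust([t[5] for t in tests]) if tests else []
    per_module: dict[int, list[EnrichmentResult]] = {i: [] for i in range(len(cover.modules))}
    for (mi, term, k, K, n, p), q in zip(tests, qvals):
        per_module[mi].append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=len(background), p=p, q=q,
                significant=q <= alpha,
            )
        )
    annotations = []
    for mi, mod in enumerate(cover.modules):
        counts = {
            ch: sum(1 for g in mod if ch in channels_by_gene.get(g, set()))
            for ch in CHANNELS
        }
        enr = sorted(per_module[mi], key=lambda r: (r.q, r.p, r.term))
        annotations.append(
            ModuleAnnotation(
                module_id=mi + 1, size=len(mod), channel_counts=counts, enrichment=enr
            )
        )
    return annotations


def write_cover(cover: Cover, tsv_path, json_path) -> None:
    """Export a cover as (module_id, gene) rows plus a JSON summary."""
    with open(tsv_path, "w") as fh:
        fh.write("module_id\tgene\n")
        for mid, mod in enumerate(cover.modules, start=1):
            for gene in mod:
                fh.write(f"{mid}\t{gene}\n")
    summary = {
        "n_modules": len(cover.modules),
        "sizes": [len(m) for m in cover.modules],
        "eq": cover.eq,
        "overlap_genes": {
            g: sorted(ids) for g, ids in sorted(module_overlap_genes(cover).items())
        },
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
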