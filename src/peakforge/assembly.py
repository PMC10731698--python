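"""Partial assembly: iterative longest-path peeling through abundance bottlenecks.

Each weakly connected component is first turned into a DAG by cutting the
back edges met during a deterministic depth-first search.  Assembly then
repeats four steps until the graph is consumed:

1. find a longest path (in bases) by dynamic programming over a topological
   order;
2. locate the bottleneck — the vertex whose minimum per-k-mer abundance is
   lowest on that path; its abundance A upper-bounds the total abundance of
   all paths through it;
3. enumerate the maximum-length paths constrained to pass the bottleneck
   (longest prefix into it x longest suffix out of it);
4. split A as evenly as possible over at most A of those paths in positive
   integers, emit the reconstructed sequences with their path abundances,
   subtract each path's abundance from every k-mer it used, delete exhausted
   k-mers (re-splitting unitigs around the holes) and drop the bottleneck.

A path's share is additionally capped by the smallest abundance currently
available along it, so no k-mer's emitted mass can ever exceed its initial
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .graph import Component, DeBruijnGraph


@dataclass
class AssemblyDag:
    """Acyclic view of a component, with the edges cut to make it so."""

    graph: DeBruijnGraph
    removed_edges: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class AssembledSequence:
    """A reconstructed sequence carrying one integer path abundance."""

    sequence: str
    abundance: int
    component_id: int


def to_dag(component: Component) -> AssemblyDag:
    """Break cycles by removing the back edges of a deterministic DFS.

    Self-loops are always cut.  DFS roots are the zero-in-degree vertices in
    sequence order; if none exist (pure cycle), the vertex of maximum total
    abundance (tie: smallest sequence) is used.  Neighbours are visited in
    sequence order, so the set of cut edges is reproducible.
    """
    graph = component.graph.copy()
    g = graph.g
    removed = [(u, v) for u, v in g.edges if u == v]
    g.remove_edges_from(removed)

    seq = graph.seq
    visited: set[int] = set()

    def dfs(root: int) -> None:
        # iterative DFS; stack holds (vertex, successor iterator)
        on_stack = {root}
        stack = [(root, iter(sorted(g.successors(root), key=seq)))]
        visited.add(root)
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if w in on_stack:
                    removed.append((v, w))
                elif w not in visited:
                    visited.add(w)
                    on_stack.add(w)
                    stack.append((w, iter(sorted(g.successors(w), key=seq))))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                on_stack.discard(v)

    roots = sorted((v for v in g.nodes if g.in_degree(v) == 0), key=seq)
    for r in roots:
        if r not in visited:
            dfs(r)
    while len(visited) < g.number_of_nodes():
        rest = [v for v in g.nodes if v not in visited]
        rest.sort(key=lambda v: (-graph.vertex_total_abundance(v), seq(v)))
        dfs(rest[0])
    g.remove_edges_from([e for e in removed if e[0] != e[1]])
    return AssemblyDag(graph=graph, removed_edges=removed)


def _gain(graph: DeBruijnGraph, v: int) -> int:
    """Bases contributed by v when appended after a k-1 overlap."""
    return len(graph.seq(v)) - (graph.k - 1)


def reconstruct_sequence(path: list[int], graph: DeBruijnGraph) -> str:
    """Contract a vertex path into its sequence via k-1 overlaps."""
    k = graph.k
    parts = [graph.seq(path[0])]
    for u, v in zip(path, path[1:]):
        su, sv = graph.seq(u), graph.seq(v)
        if su[-(k - 1) :] != sv[: k - 1]:
            raise ValueError("consecutive path vertices do not overlap by k-1")
        parts.append(sv[k - 1 :])
    return "".join(parts)


def _topo_order(graph: DeBruijnGraph) -> list[int]:
    return list(nx.lexicographical_topological_sort(graph.g, key=graph.seq))


def longest_path(dag: AssemblyDag) -> list[int]:
    """Longest path in bases; ties by total abundance, then smallest sequence."""
    graph = dag.graph
    g = graph.g
    if g.number_of_nodes() == 0:
        raise ValueError("longest_path on empty DAG")
    # best[v] = (length, abundance, sequence, path ending at v)
    best: dict[int, tuple[int, int, str, list[int]]] = {}
    for v in _topo_order(graph):
        sv = graph.seq(v)
        cand = (len(sv), graph.vertex_total_abundance(v), sv, [v])
        for u in g.predecessors(v):
            lu, au, qu, pu = best[u]
            c = (lu + _gain(graph, v), au + graph.vertex_total_abundance(v),
                 qu + sv[graph.k - 1 :], pu + [v])
            if _better(c, cand):
                cand = c
        best[v] = cand
    overall = None
    for v in best:
        if overall is None or _better(best[v], overall):
            overall = best[v]
    return overall[3]


def _better(a: tuple, b: tuple) -> bool:
    """True if candidate a beats b: longer, then more abundant, then smaller seq."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] > b[1]
    return a[2] < b[2]


def find_bottleneck(path: list[int], graph: DeBruijnGraph) -> tuple[int, int]:
    """Vertex of minimum per-k-mer abundance on the path (earliest on ties)."""
    if not path:
        raise ValueError("empty path")
    best_v = path[0]
    best_a = graph.vertex_min_abundance(best_v)
    for v in path[1:]:
        a = graph.vertex_min_abundance(v)
        if a < best_a:
            best_v, best_a = v, a
    return best_v, best_a


def _optimal_half_paths(graph: DeBruijnGraph, target: int, forward: bool,
                        limit: int) -> list[list[int]]:
    """All optimal-length paths ending at (forward) / starting from target.

    Returned paths exclude the target itself; at most ``limit`` are produced.
    """
    g = graph.g if forward else graph.g.reverse(copy=False)
    order = _topo_order(graph)
    if not forward:
        order = order[::-1]
    length: dict[int, int] = {}
    for v in order:
        base = len(graph.seq(v))
        best = base
        for u in g.predecessors(v):
            best = max(best, length[u] + _gain(graph, v))
        length[v] = best

    out: list[list[int]] = []

    def backtrack(v: int, acc: list[int]) -> None:
        if len(out) >= limit:
            return
        preds = sorted(g.predecessors(v), key=graph.seq)
        opts = [u for u in preds if length[u] + _gain(graph, v) == length[v]]
        if length[v] == len(graph.seq(v)):
            out.append(list(acc))  # the path may start here
        for u in opts:
            backtrack(u, acc + [u])

    backtrack(target, [])
    if forward:
        # collected target-outwards; orient source -> target
        return [p[::-1] for p in out]
    # reverse-graph predecessors are original successors: already in path order
    return out


def enumerate_paths_through(dag: AssemblyDag, bottleneck: int,
                            m_max: int) -> list[list[int]]:
    """Up to m_max maximum-length paths through the bottleneck vertex.

    Ordered by total path abundance (descending), then by sequence.
    """
    graph = dag.graph
    # enumerate generously, rank, then truncate: a small m_max must still
    # return the globally top-ranked paths
    half_limit = max(m_max, 64)
    prefixes = _optimal_half_paths(graph, bottleneck, forward=True, limit=half_limit)
    suffixes = _optimal_half_paths(graph, bottleneck, forward=False, limit=half_limit)
    paths = []
    cap = max(m_max * 4, 256)
    for pre in prefixes:
        for suf in suffixes:
            paths.append(pre + [bottleneck] + suf)
            if len(paths) >= cap:
                break
        if len(paths) >= cap:
            break
    keyed = [
        (-sum(graph.vertex_total_abundance(v) for v in p),
         reconstruct_sequence(p, graph), p)
        for p in paths
    ]
    keyed.sort(key=lambda t: (t[0], t[1]))
    return [p for _, _, p in keyed[:m_max]]


def _resplit_vertex(graph: DeBruijnGraph, v: int) -> None:
    """Delete zero-abundance k-mers of v, splitting the unitig around them."""
    g = graph.g
    abund = graph.abund(v)
    if all(a > 0 for a in abund):
        return
    seq = graph.seq(v)
    k = graph.k
    runs: list[tuple[int, int]] = []
    start = None
    for i, a in enumerate(abund):
        if a > 0 and start is None:
            start = i
        elif a <= 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(abund)))
    in_edges = [u for u in g.predecessors(v) if u != v]
    out_edges = [w for w in g.successors(v) if w != v]
    g.remove_node(v)
    for a, b in runs:
        nid = graph.add_vertex(seq[a : b - 1 + k], abund[a:b])
        if a == 0:
            for u in in_edges:
                g.add_edge(u, nid)
        if b == len(abund):
            for w in out_edges:
                g.add_edge(nid, w)


def distribute_and_consume(dag: AssemblyDag, bottleneck: int, A: int,
                           paths: list[list[int]],
                           component_id: int = 0) -> list[AssembledSequence]:
    """Assign bottleneck abundance to paths, emit sequences, consume k-mers.

    ``min(A, len(paths))`` paths receive positive integer shares summing to
    at most A, as even as possible with larger shares to earlier-ranked
    paths.  A share never exceeds the smallest abundance currently left on
    the path, so consumption cannot overdraw any k-mer.  Used abundance is
    subtracted along each path, exhausted k-mers are deleted (splitting
    unitigs), and the bottleneck vertex is removed.
    """
    if A < 1 or not paths:
        raise ValueError("need A >= 1 and at least one path")
    graph = dag.graph
    g = graph.g
    n_used = min(A, len(paths))
    base, rem = divmod(A, n_used)
    emitted = []
    touched: set[int] = set()
    for i, path in enumerate(paths[:n_used]):
        share = base + 1 if i < rem else base
        avail = min(min(graph.abund(v)) for v in path)
        share = min(share, avail)
        if share <= 0:
            continue
        emitted.append(AssembledSequence(
            sequence=reconstruct_sequence(path, graph),
            abundance=share,
            component_id=component_id,
        ))
        for v in path:
            ab = g.nodes[v]["abund"]
            for j in range(len(ab)):
                ab[j] = max(0, ab[j] - share)
            touched.add(v)
    if bottleneck in g:
        g.remove_node(bottleneck)
        touched.discard(bottleneck)
    for v in touched:
        _resplit_vertex(graph, v)
    return emitted


def assemble_component(component: Component,
                       m_max_floor: int = 64) -> list[AssembledSequence]:
    """Peel a component into assembled sequences until it is empty."""
    dag = to_dag(component)
    graph = dag.graph
    n0 = max(1, len(graph))
    max_a0 = max((max(graph.abund(v)) for v in graph.g.nodes), default=1)
    budget = n0 * max_a0 + 10
    out: list[AssembledSequence] = []
    iterations = 0
    while len(graph) > 0:
        iterations += 1
        if iterations > budget:
            raise RuntimeError(
                f"partial assembly of component {component.component_id} "
                f"made no progress after {iterations} iterations"
            )
        path = longest_path(dag)
        bottleneck, A = find_bottleneck(path, graph)
        paths = enumerate_paths_through(dag, bottleneck, m_max=max(A, m_max_floor))
        out.extend(distribute_and_consume(dag, bottleneck, A, paths,
                                          component_id=component.component_id))
    return out
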