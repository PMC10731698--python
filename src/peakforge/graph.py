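"""Node-centric de Bruijn graph: construction, compaction, components, bubbles.

Vertices are unitigs: sequences of length >= k carrying one abundance value
per constituent k-mer.  A directed edge connects two vertices whose flanking
k-mers overlap by k-1 bases *and* whose contraction (k+1)-mer was observed in
the reads — overlap alone is not evidence that the junction exists.

The graph is held in a networkx DiGraph with integer node ids; node
attributes are ``seq`` (string) and ``abund`` (list of per-k-mer counts).
All iteration orders are made deterministic by sorting on vertex sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import edlib
import networkx as nx


class DeBruijnGraph:
    """Compacted de Bruijn graph with per-k-mer abundances."""

    def __init__(self, k: int, g: nx.DiGraph | None = None):
        self.k = k
        self.g = g if g is not None else nx.DiGraph()
        self._next_id = max(self.g.nodes, default=-1) + 1

    # -- node helpers -------------------------------------------------
    def add_vertex(self, seq: str, abund: list[int]) -> int:
        if len(abund) != len(seq) - self.k + 1:
            raise ValueError("abundance list length must be len(seq) - k + 1")
        nid = self._next_id
        self._next_id += 1
        self.g.add_node(nid, seq=seq, abund=list(abund))
        return nid

    def seq(self, v: int) -> str:
        return self.g.nodes[v]["seq"]

    def abund(self, v: int) -> list[int]:
        return self.g.nodes[v]["abund"]

    def vertex_min_abundance(self, v: int) -> int:
        return min(self.g.nodes[v]["abund"])

    def vertex_total_abundance(self, v: int) -> int:
        return sum(self.g.nodes[v]["abund"])

    def total_abundance(self) -> int:
        return sum(self.vertex_total_abundance(v) for v in self.g.nodes)

    def kmers(self, v: int):
        """Constituent k-mers of vertex v, in sequence order."""
        s = self.seq(v)
        return (s[i : i + self.k] for i in range(len(s) - self.k + 1))

    def kmer_abundances(self) -> dict[str, int]:
        """Aggregate abundance per k-mer over all vertices (repeats summed)."""
        out: dict[str, int] = {}
        for v in self.g.nodes:
            for m, a in zip(self.kmers(v), self.abund(v)):
                out[m] = out.get(m, 0) + a
        return out

    def copy(self) -> "DeBruijnGraph":
        return DeBruijnGraph(self.k, self.g.copy())

    def __len__(self) -> int:
        return self.g.number_of_nodes()


@dataclass
class Component:
    """One weakly connected component of the de Bruijn graph."""

    component_id: int
    graph: DeBruijnGraph


def build_graph(retained: dict[str, int], observed_k1mers: set[str], k: int) -> DeBruijnGraph:
    """Build the k-mer-level graph (one vertex per retained k-mer).

    Edge u -> v iff suffix(u, k-1) == prefix(v, k-1) and the contraction
    u + v[-1] is an observed (k+1)-mer.  Self-loops (e.g. poly-A) arise
    naturally from this rule.
    """
    dbg = DeBruijnGraph(k)
    if not retained:
        return dbg
    ids: dict[str, int] = {}
    by_prefix: dict[str, list[str]] = {}
    for m in sorted(retained):
        ids[m] = dbg.add_vertex(m, [retained[m]])
        by_prefix.setdefault(m[: k - 1], []).append(m)
    for u in sorted(retained):
        for v in by_prefix.get(u[1:], ()):
            if u + v[-1] in observed_k1mers:
                dbg.g.add_edge(ids[u], ids[v])
    return dbg


def _contract(seqs: list[str], k: int) -> str:
    out = [seqs[0]]
    for s in seqs[1:]:
        out.append(s[k - 1 :])
    return "".join(out)


def compact_unitigs(graph: DeBruijnGraph) -> DeBruijnGraph:
    """Merge maximal non-branching paths into single unitig vertices.

    A vertex is merged into its predecessor when it is the unique successor
    of a vertex with out-degree 1 and itself has in-degree 1.  Isolated
    cycles (every vertex with in/out degree 1) are collapsed into a single
    vertex with a self-loop, starting from the lexicographically smallest
    sequence.  Idempotent.
    """
    g = graph.g
    k = graph.k
    order = sorted(g.nodes, key=lambda v: g.nodes[v]["seq"])

    def chain_internal(w: int) -> bool:
        if g.in_degree(w) != 1:
            return False
        (pred,) = g.predecessors(w)
        return pred != w and g.out_degree(pred) == 1

    visited: set[int] = set()
    chains: list[list[int]] = []
    for s in order:
        if s in visited or chain_internal(s):
            continue
        chain = [s]
        visited.add(s)
        cur = s
        while g.out_degree(cur) == 1:
            (nxt,) = g.successors(cur)
            if nxt == s or nxt in visited or not chain_internal(nxt):
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        chains.append(chain)
    # isolated cycles: all remaining vertices are chain-internal
    for s in order:
        if s in visited:
            continue
        chain = [s]
        visited.add(s)
        cur = s
        while True:
            (nxt,) = g.successors(cur)
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        chains.append(chain)

    out = DeBruijnGraph(k)
    head: dict[int, int] = {}  # old first vertex -> new id
    tail: dict[int, int] = {}  # old last vertex -> new id
    for chain in chains:
        seq = _contract([g.nodes[v]["seq"] for v in chain], k)
        abund = list(itertools.chain.from_iterable(g.nodes[v]["abund"] for v in chain))
        nid = out.add_vertex(seq, abund)
        head[chain[0]] = nid
        tail[chain[-1]] = nid
    for u, v in g.edges:
        if u in tail and v in head:
            out.g.add_edge(tail[u], head[v])
    return out


def weakly_connected_components(graph: DeBruijnGraph) -> list[Component]:
    """Split into weakly connected components, deterministically ordered.

    Components are sorted by descending total abundance, then by the
    lexicographically smallest vertex sequence they contain.
    """
    comps = []
    for nodes in nx.weakly_connected_components(graph.g):
        sub = DeBruijnGraph(graph.k, graph.g.subgraph(nodes).copy())
        total = sub.total_abundance()
        smallest = min(sub.seq(v) for v in sub.g.nodes)
        comps.append((total, smallest, sub))
    comps.sort(key=lambda t: (-t[0], t[1]))
    return [Component(component_id=i, graph=sub) for i, (_, _, sub) in enumerate(comps)]


def _path_sequence(graph: DeBruijnGraph, path: list[int]) -> str:
    return _contract([graph.seq(v) for v in path], graph.k)


def _interior_slots(graph: DeBruijnGraph, path: list[int]) -> list[tuple[int, int]]:
    """(vertex, index) abundance slots of a bubble arm's interior vertices."""
    slots = []
    for v in path[1:-1]:
        slots.extend((v, i) for i in range(len(graph.abund(v))))
    return slots


def _find_bubble(graph: DeBruijnGraph, max_bubble_len: int, similarity: float,
                 max_paths: int = 50):
    """Locate one mergeable bubble, or None.

    A bubble is a pair of directed s->t paths with non-empty, vertex-disjoint
    interiors whose interior arms both reconstruct to <= max_bubble_len bases
    and are at least ``similarity`` identical (edit-distance identity).  The
    default span 2k covers the interior created by a single substitution,
    which is 2k-1 bases long.
    """
    g = graph.g
    order = sorted(g.nodes, key=graph.seq)
    for s in order:
        if g.out_degree(s) < 2:
            continue
        for t in order:
            if g.in_degree(t) < 2 or t == s:
                continue
            paths = []
            gen = nx.all_simple_paths(g, s, t, cutoff=max(2, max_bubble_len))
            for p in itertools.islice(gen, max_paths):
                if len(p) < 3:
                    continue  # direct edge: no interior arm to merge
                arm = _path_sequence(graph, p[1:-1])
                if len(arm) <= max_bubble_len:
                    paths.append((p, arm))
            for (p1, q1), (p2, q2) in itertools.combinations(paths, 2):
                if set(p1[1:-1]) & set(p2[1:-1]):
                    continue
                dist = edlib.align(q1, q2, mode="NW", task="distance")["editDistance"]
                ident = 1.0 - dist / max(len(q1), len(q2))
                if ident >= similarity:
                    return p1, p2
    return None


def remove_bubbles(component: Component, max_bubble_len: int | None = None,
                   similarity: float = 0.9) -> Component:
    """Merge short, highly similar parallel paths (Tour Bus style).

    The arm with the lower interior abundance is merged into the other: its
    interior abundance mass is added position-wise onto the survivor's
    interior (remainder onto the survivor's last slot, so no mass is lost)
    and its interior vertices are deleted.  Repeats until no bubble
    qualifies.  The result may have lost weak connectivity; callers re-run
    :func:`weakly_connected_components` afterwards.
    """
    graph = component.graph.copy()
    if max_bubble_len is None:
        max_bubble_len = 2 * graph.k
    while True:
        found = _find_bubble(graph, max_bubble_len, similarity)
        if found is None:
            break
        p1, p2 = found
        a1 = sum(graph.abund(v)[i] for v, i in _interior_slots(graph, p1))
        a2 = sum(graph.abund(v)[i] for v, i in _interior_slots(graph, p2))
        s1, s2 = _path_sequence(graph, p1), _path_sequence(graph, p2)
        if (a1, s2) >= (a2, s1):  # keep higher abundance; tie: smaller seq
            winner, loser = p1, p2
        else:
            winner, loser = p2, p1
        lose_slots = _interior_slots(graph, loser)
        if not lose_slots:
            # loser is a direct s->t shortcut edge: no mass to move, drop it
            graph.g.remove_edge(loser[0], loser[1])
            continue
        win_slots = _interior_slots(graph, winner)
        if not win_slots:
            # direct s->t edge survives: fold the arm's mass onto s's last slot
            v = winner[0]
            win_slots = [(v, len(graph.abund(v)) - 1)]
        for j, (v, i) in enumerate(lose_slots):
            wv, wi = win_slots[min(j, len(win_slots) - 1)]
            graph.g.nodes[wv]["abund"][wi] += graph.abund(v)[i]
        graph.g.remove_nodes_from(loser[1:-1])
    return Component(component_id=component.component_id, graph=graph)
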