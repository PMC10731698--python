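"""Shared builders for graph- and read-level tests."""

from __future__ import annotations

import random

import pytest

from peakforge.graph import DeBruijnGraph, build_graph, compact_unitigs
from peakforge.io import ReadSet
from peakforge.kmers import count_kmers, extract_kmers


def graph_from_strings(strings: list[tuple[str, int]], k: int) -> DeBruijnGraph:
    """k-mer graph from (sequence, copy-count) pairs; counts summed, compacted.

    Every k-mer of each string is retained with abundance = sum of copy
    counts of the strings containing it; (k+1)-mers of all strings validate
    the edges.  Mirrors graph preparation with an abundance threshold of 1.
    """
    retained: dict[str, int] = {}
    observed: set[str] = set()
    for s, copies in strings:
        for m in extract_kmers(s, k):
            retained[m] = retained.get(m, 0) + copies
        observed.update(extract_kmers(s, k + 1))
    return compact_unitigs(build_graph(retained, observed, k))


def chain_graph(seqs: list[str], abunds: list[list[int]], k: int) -> tuple[DeBruijnGraph, list[int]]:
    """Hand-built unitig graph: vertices chained in order with given abundances."""
    g = DeBruijnGraph(k)
    ids = [g.add_vertex(s, a) for s, a in zip(seqs, abunds)]
    for u, v in zip(ids, ids[1:]):
        g.g.add_edge(u, v)
    return g, ids


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def readset(reads: list[str], condition: str = "treatment", rep: str = "r1") -> ReadSet:
    return ReadSet(reads=reads, replicate_id=rep, condition=condition)


@pytest.fixture
def count_table():
    def make(reads, k, condition="treatment", rep="r1"):
        return count_kmers(readset(reads, condition, rep), k)

    return make
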