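"""Merge assembled sequences into chiptigs; map pruned k-mers back onto them.

Shorter assembled sequences that occur verbatim inside a longer one from the
same component are absorbed: their abundance is added to the profile of the
leftmost occurrence.  The survivors are "chiptigs" — reconstructed sequences
carrying a per-position abundance profile.  Low-abundance k-mers that were
set aside before graph construction are then aligned back by seed-and-extend
(exact words of ``word_size`` bases, ungapped extension, Karlin-Altschul
E-value m*n*2^-bits with +1/-2 scoring) and, when sufficiently identical,
added to the best-matching profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .assembly import AssembledSequence

# Karlin-Altschul parameters for ungapped +1/-2 nucleotide scoring on a
# uniform background; bit score = (lambda * S - ln K) / ln 2
_KA_LAMBDA = 1.33
_KA_K = 0.62


@dataclass
class Chiptig:
    """A reconstructed sequence with per-position integer abundance."""

    chiptig_id: str
    sequence: str
    profile: list[int]
    component_id: int

    def __post_init__(self) -> None:
        if len(self.profile) != len(self.sequence):
            raise ValueError("profile length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


def merge_subsequences(sequences: list[AssembledSequence],
                       component_id: int) -> list[Chiptig]:
    """Absorb exact-substring sequences into longer ones, building profiles.

    Sequences are processed longest first.  A sequence contained in an
    already-kept survivor adds its abundance over the leftmost occurrence in
    the first such survivor; otherwise it becomes a new chiptig with a flat
    profile equal to its path abundance.  Total abundance mass
    (sum of abundance x length) is conserved.
    """
    ordered = sorted(sequences, key=lambda s: (-len(s.sequence), s.sequence))
    survivors: list[tuple[str, list[int]]] = []
    for s in ordered:
        for seq, profile in survivors:
            off = seq.find(s.sequence)
            if off >= 0:
                for j in range(len(s.sequence)):
                    profile[off + j] += s.abundance
                break
        else:
            survivors.append((s.sequence, [s.abundance] * len(s.sequence)))
    return [
        Chiptig(
            chiptig_id=f"c{component_id}.{i + 1}",
            sequence=seq,
            profile=profile,
            component_id=component_id,
        )
        for i, (seq, profile) in enumerate(survivors)
    ]


def _best_hit(kmer: str, chiptigs: list[Chiptig],
              index: dict[str, list[tuple[int, int]]], word_size: int,
              db_len: int) -> tuple[int, int, int, float] | None:
    """Best ungapped placement of a k-mer: (chiptig idx, start, end, identity).

    Candidate placements come from exact word seeds; each is scored over the
    overlap of the k-mer span with the chiptig.  Best = highest identity,
    then longest alignment, then first chiptig, then leftmost offset.
    """
    k = len(kmer)
    w = min(word_size, k)
    seen: set[tuple[int, int]] = set()
    best = None
    best_key = None
    for i in range(k - w + 1):
        for ci, pos in index.get(kmer[i : i + w], ()):
            offset = pos - i
            if (ci, offset) in seen:
                continue
            seen.add((ci, offset))
            target = chiptigs[ci].sequence
            a = max(0, offset)
            b = min(len(target), offset + k)
            aln_len = b - a
            if aln_len < w:
                continue
            matches = sum(
                1 for j in range(a, b) if target[j] == kmer[j - offset]
            )
            identity = matches / aln_len
            score = matches - 2 * (aln_len - matches)
            bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
            evalue = k * db_len * 2.0 ** (-bits)
            key = (-identity, -aln_len, ci, offset)
            if best_key is None or key < best_key:
                best_key = key
                best = (ci, a, b, identity, evalue)
    if best is None:
        return None
    ci, a, b, identity, evalue = best
    if evalue > 1e-3:
        return None
    return ci, a, b, identity


def map_low_abundance_kmers(chiptigs: list[Chiptig], low_kmers: dict[str, int],
                            identity_threshold: float = 0.95,
                            min_abs: int = 0,
                            word_size: int = 10) -> list[Chiptig]:
    """Add the counts of mappable low-abundance k-mers to chiptig profiles.

    Only k-mers with count >= ``min_abs`` are considered.  A k-mer is added
    to its single best hit when that hit reaches ``identity_threshold`` and
    an E-value of at most 1e-3; unmappable k-mers are discarded.  Profiles
    are modified in place (never lowered) and the same list is returned.
    """
    if not chiptigs or not low_kmers:
        return chiptigs
    # seeds cannot be longer than the k-mers being mapped
    word_size = min(word_size, min(len(m) for m in low_kmers))
    index: dict[str, list[tuple[int, int]]] = {}
    db_len = 0
    for ci, ct in enumerate(chiptigs):
        seq = ct.sequence
        db_len += len(seq)
        for pos in range(len(seq) - word_size + 1):
            index.setdefault(seq[pos : pos + word_size], []).append((ci, pos))
    for kmer in sorted(low_kmers):
        count = low_kmers[kmer]
        if count < min_abs:
            continue
        hit = _best_hit(kmer, chiptigs, index, word_size, db_len)
        if hit is None:
            continue
        ci, a, b, identity = hit
        if identity < identity_threshold:
            continue
        profile = chiptigs[ci].profile
        for j in range(a, b):
            profile[j] += count
    return chiptigs
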