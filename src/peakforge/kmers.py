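"""k-mer counting, control correction and abundance thresholding.

Reads are traversed with a sliding window of size ``k``; counts are kept per
replicate so that replicate-level abundance matrices can be rebuilt later for
peak calling.  Treatment replicate counts are summed, corrected against the
pooled control by depth-scaled subtraction, and split into a sufficiently
abundant set (which seeds the de Bruijn graph) and a low-abundance set (which
is mapped back onto the reconstructed sequences afterwards).

Strands are never collapsed: a k-mer and its reverse complement are distinct
sequences throughout.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import ReadSet

_ACGT = frozenset("ACGT")


@dataclass
class KmerTable:
    """Per-replicate k-mer counts for one condition.

    Besides the k-mer counts, the table records the set of (k+1)-mers observed
    in the reads; an edge of the de Bruijn graph is only drawn if the
    contraction of its two endpoint k-mers was actually seen in the data, and
    the (k+1)-mer set is exactly that evidence.
    """

    k: int
    counts: dict[str, int]
    condition: str
    replicate_id: str
    k1mers: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if self.condition not in ("treatment", "control"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ThresholdSplit:
    """Partition of corrected k-mer counts at an abundance threshold."""

    retained: dict[str, int]
    low_abundance: dict[str, int]
    threshold: int


def extract_kmers(read: str, k: int) -> list[str]:
    """Return the sliding windows of size ``k``, skipping ambiguous ones.

    Windows containing a character outside A/C/G/T are omitted; reads shorter
    than ``k`` yield an empty list.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    n = len(read)
    if n < k:
        return []
    if _ACGT.issuperset(read):
        return [read[i : i + k] for i in range(n - k + 1)]
    out = []
    # track index of the last non-ACGT character seen so far
    last_bad = -1
    for i, c in enumerate(read):
        if c not in _ACGT:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            out.append(read[i - k + 1 : i + 1])
    return out


def count_kmers(reads: ReadSet, k: int) -> KmerTable:
    """Count k-mer occurrences across all reads of one replicate.

    Also collects the (k+1)-mer presence set used to validate graph edges.
    """
    counts: Counter[str] = Counter()
    k1mers: set[str] = set()
    for read in reads.reads:
        counts.update(extract_kmers(read, k))
        k1mers.update(extract_kmers(read, k + 1))
    if not counts:
        warnings.warn(
            f"no k-mers of size {k} extracted from replicate "
            f"{reads.replicate_id!r} (all reads shorter than k?)"
        )
    return KmerTable(
        k=k,
        counts=dict(counts),
        condition=reads.condition,
        replicate_id=reads.replicate_id,
        k1mers=k1mers,
    )


def sum_treatment(tables: list[KmerTable]) -> dict[str, int]:
    """Pointwise sum of treatment replicate counts."""
    if not tables:
        return {}
    k = tables[0].k
    for t in tables:
        if t.k != k:
            raise ValueError("all tables must share the same k")
        if t.condition != "treatment":
            raise ValueError("sum_treatment expects treatment tables")
    total: Counter[str] = Counter()
    for t in tables:
        total.update(t.counts)
    return dict(total)


def correct_with_control(
    treatment: dict[str, int], control_tables: list[KmerTable]
) -> dict[str, int]:
    """Subtract depth-scaled control counts from the summed treatment counts.

    For each k-mer m, ``corrected(m) = max(0, t(m) - round(s * c(m)))`` where
    c(m) is the summed control count and ``s`` is the ratio of total treatment
    k-mer instances to total control k-mer instances.  k-mers whose corrected
    count reaches zero are dropped.  With no control reads the treatment
    counts are returned unchanged.
    """
    control: Counter[str] = Counter()
    for t in control_tables:
        control.update(t.counts)
    control_mass = sum(control.values())
    if control_mass == 0:
        return dict(treatment)
    s = sum(treatment.values()) / control_mass
    corrected = {}
    for m, t_count in treatment.items():
        c = control.get(m, 0)
        # round half up, not banker's rounding, for determinism across values
        v = t_count - math.floor(s * c + 0.5)
        if v > 0:
            corrected[m] = v
    return corrected


def split_by_threshold(
    corrected: dict[str, int], mode: str, value: float
) -> ThresholdSplit:
    """Split corrected counts into retained and low-abundance sets.

    In percentile mode the threshold is the ceiling of the p-th percentile
    (linear interpolation) of the count multiset restricted to counts >= 2;
    singletons are treated as sequencing errors and never enter the
    distribution.  k-mers with count >= threshold are retained.
    """
    if not corrected:
        warnings.warn("empty k-mer table: nothing to threshold")
        return ThresholdSplit(retained={}, low_abundance={}, threshold=0)
    if mode == "absolute":
        threshold = int(value)
        if threshold < 1:
            raise ValueError("absolute threshold must be >= 1")
    elif mode == "percentile":
        if not 0 <= value <= 100:
            raise ValueError("percentile must be in [0, 100]")
        dist = [c for c in corrected.values() if c >= 2]
        if dist:
            threshold = math.ceil(np.percentile(dist, value))
        else:
            # only singletons: retain nothing below count 2
            threshold = 2
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    retained = {}
    low = {}
    for m, c in corrected.items():
        if c >= threshold:
            retained[m] = c
        else:
            low[m] = c
    return ThresholdSplit(retained=retained, low_abundance=low, threshold=threshold)
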