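"""Peak calling on chiptigs: GHMM segmentation + Mann-Whitney enrichment.

For every chiptig and every replicate (treatment and control) an integer
abundance row of length l is built from the replicate's own k-mer counts;
counts of k-mers occurring in several chiptig positions are divided between
the occurrences proportionally to the reconstructed profile, with
largest-remainder rounding so the replicate count is conserved exactly.

The per-position treatment mean is segmented with a Gaussian hidden Markov
model; short state runs between long runs of one state are smoothed away.
Each segment is then tested per treatment replicate against the pooled
control rows with a one-sided Mann-Whitney U test (treatment greater),
Bonferroni-corrected over segments x replicates.  With several replicates,
only peaks recovered in every replicate (within an edit-distance tolerance)
are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import edlib
import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import stats

from .io import RunConfig
from .kmers import KmerTable
from .merging import Chiptig


@dataclass
class AbundanceMatrix:
    """r x l integer abundance matrix of one chiptig in one condition."""

    chiptig_id: str
    condition: str
    matrix: np.ndarray  # shape (r, l)
    replicate_ids: list[str]


@dataclass
class Segment:
    chiptig_id: str
    start: int
    end: int
    state: int


@dataclass
class Peak:
    """A significantly enriched chiptig interval."""

    chiptig_id: str
    start: int
    end: int
    p_raw: dict[str, float]
    p_bonferroni: dict[str, float]
    n_supporting_replicates: int


def occurrence_index(chiptigs: list[Chiptig], k: int) -> dict[str, list[tuple[int, int]]]:
    """k-mer -> [(chiptig index, position)] over all chiptig positions."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, ct in enumerate(chiptigs):
        seq = ct.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((ci, pos))
    return index


def _largest_remainder(total: int, weights: list[float]) -> list[int]:
    """Integer shares of ``total`` proportional to weights, summing exactly."""
    if total == 0:
        return [0] * len(weights)
    wsum = sum(weights)
    if wsum == 0:
        weights = [1.0] * len(weights)
        wsum = float(len(weights))
    exact = [total * w / wsum for w in weights]
    shares = [math.floor(e) for e in exact]
    rem = total - sum(shares)
    order = sorted(range(len(weights)), key=lambda i: (-(exact[i] - shares[i]), i))
    for i in order[:rem]:
        shares[i] += 1
    return shares


def replicate_matrix(chiptig: Chiptig, replicate_table: KmerTable,
                     all_chiptigs: list[Chiptig],
                     index: dict[str, list[tuple[int, int]]] | None = None) -> np.ndarray:
    """One replicate's abundance row for one chiptig.

    Position j carries the replicate count of the k-mer starting at j (the
    trailing k-1 positions inherit the last k-mer's value).  Counts of
    k-mers shared between chiptig positions are split proportionally to the
    reconstructed profile values of the occurrences.
    """
    k = replicate_table.k
    if index is None:
        index = occurrence_index(all_chiptigs, k)
    ci_self = next(
        i for i, ct in enumerate(all_chiptigs) if ct.chiptig_id == chiptig.chiptig_id
    )
    l = len(chiptig.sequence)
    row = np.zeros(l, dtype=np.int64)
    cache: dict[str, dict[tuple[int, int], int]] = {}
    for j in range(l - k + 1):
        m = chiptig.sequence[j : j + k]
        count = replicate_table.counts.get(m, 0)
        if count == 0:
            continue
        occs = index[m]
        if len(occs) == 1:
            row[j] = count
            continue
        if m not in cache:
            weights = [all_chiptigs[ci].profile[pos] for ci, pos in occs]
            shares = _largest_remainder(count, weights)
            cache[m] = dict(zip(occs, shares))
        row[j] = cache[m][(ci_self, j)]
    if l >= k:
        row[l - k + 1 :] = row[l - k]
    return row


def build_matrices(chiptigs: list[Chiptig], tables: list[KmerTable],
                   condition: str) -> dict[str, AbundanceMatrix]:
    """Abundance matrices for all chiptigs from one condition's replicates."""
    tables = [t for t in tables if t.condition == condition]
    if not tables:
        return {}
    index = occurrence_index(chiptigs, tables[0].k)
    out = {}
    for ct in chiptigs:
        rows = [replicate_matrix(ct, t, chiptigs, index) for t in tables]
        out[ct.chiptig_id] = AbundanceMatrix(
            chiptig_id=ct.chiptig_id,
            condition=condition,
            matrix=np.vstack(rows),
            replicate_ids=[t.replicate_id for t in tables],
        )
    return out


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, end, state)."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((start, i, int(states[start])))
            start = i
    return runs


def smooth_states(states, short_len: int = 5, long_factor: float = 2.0):
    """Rewrite short runs sandwiched between long runs of one state.

    A run of length <= short_len flanked on both sides by runs of the same
    state with length >= long_factor * short_len takes the flanking state.
    Applied until a fixpoint is reached.
    """
    states = np.asarray(states).copy()
    long_len = long_factor * short_len
    changed = True
    while changed:
        changed = False
        runs = _runs(states)
        for i in range(1, len(runs) - 1):
            s, e, st = runs[i]
            ls, le, lst = runs[i - 1]
            rs, re, rst = runs[i + 1]
            if (e - s <= short_len and lst == rst and st != lst
                    and le - ls >= long_len and re - rs >= long_len):
                states[s:e] = lst
                changed = True
                break
    return states


def segment_ghmm(treatment_matrix: AbundanceMatrix, n_states: int = 3,
                 seed: int = 42, smoothing_short_len: int = 5) -> list[Segment]:
    """Segment a chiptig by a Gaussian HMM on the mean treatment signal.

    The model is fit by EM with up to 10 random restarts (best
    log-likelihood kept); the Viterbi state path, after short-run smoothing,
    is cut into maximal constant-state segments that tile [0, l).
    """
    signal = treatment_matrix.matrix.mean(axis=0)
    l = len(signal)
    cid = treatment_matrix.chiptig_id
    if l < n_states:
        warnings.warn(f"chiptig {cid} shorter than the number of GHMM states")
        return [Segment(cid, 0, l, 0)]
    n_levels = len(np.unique(signal))
    if n_levels == 1:
        return [Segment(cid, 0, l, 0)]
    n = min(n_states, n_levels)
    X = signal.reshape(-1, 1)
    best_model = None
    best_score = -np.inf
    for r in range(10):
        model = GaussianHMM(
            n_components=n, covariance_type="diag", n_iter=100,
            random_state=(seed + 7919 * r) % (2**31),
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X)
                score = model.score(X)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if np.isfinite(score) and score > best_score:
            best_score = score
            best_model = model
    if best_model is None:
        return [Segment(cid, 0, l, 0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        states = best_model.predict(X)
    states = smooth_states(states, short_len=smoothing_short_len)
    return [Segment(cid, s, e, st) for s, e, st in _runs(states)]


def test_segment(seg: Segment, treatment_row: np.ndarray,
                 control_matrix: AbundanceMatrix) -> float:
    """One-sided Mann-Whitney p (treatment > pooled control) on a segment."""
    t = np.asarray(treatment_row[seg.start : seg.end], dtype=float)
    c = control_matrix.matrix[:, seg.start : seg.end].ravel().astype(float)
    if t.size == 0 or c.size == 0:
        return 1.0
    both = np.concatenate([t, c])
    if both.max() == both.min():
        return 1.0  # every value tied: no evidence either way
    res = stats.mannwhitneyu(t, c, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def call_peaks(chiptigs: list[Chiptig],
               treatment_matrices: dict[str, AbundanceMatrix],
               control_matrices: dict[str, AbundanceMatrix],
               config: RunConfig) -> dict[str, list[Peak]]:
    """Per-replicate peak sets over all sufficiently long chiptigs.

    Only chiptigs longer than ``min_chiptig_factor * k`` are segmented.
    The Bonferroni family is (segments tested) x (treatment replicates);
    a segment is a peak for a replicate when its corrected p <= alpha.
    """
    min_len = config.min_chiptig_factor * config.k
    eligible = [ct for ct in chiptigs if len(ct.sequence) > min_len]
    all_segments: list[Segment] = []
    for ct in eligible:
        tm = treatment_matrices[ct.chiptig_id]
        segs = segment_ghmm(tm, n_states=config.ghmm_states, seed=config.seed,
                            smoothing_short_len=config.smoothing_short_len)
        all_segments.extend(s for s in segs if s.end - s.start >= 2)
    if not all_segments:
        return {}
    rep_ids = next(iter(treatment_matrices.values())).replicate_ids
    family = len(all_segments) * len(rep_ids)
    peak_sets: dict[str, list[Peak]] = {rid: [] for rid in rep_ids}
    for seg in all_segments:
        tm = treatment_matrices[seg.chiptig_id]
        cm = control_matrices[seg.chiptig_id]
        for ri, rid in enumerate(rep_ids):
            p_raw = test_segment(seg, tm.matrix[ri], cm)
            p_bon = min(1.0, p_raw * family)
            if p_bon <= config.alpha:
                peak_sets[rid].append(Peak(
                    chiptig_id=seg.chiptig_id, start=seg.start, end=seg.end,
                    p_raw={rid: p_raw}, p_bonferroni={rid: p_bon},
                    n_supporting_replicates=1,
                ))
    return {rid: pk for rid, pk in peak_sets.items()}


def intersect_replicates(peak_sets: dict[str, list[Peak]],
                         chiptig_seqs: dict[str, str],
                         tolerance: int = 4) -> list[Peak]:
    """Peaks recovered in every replicate, within an edit-distance slack.

    A peak of the first replicate is reported iff every other replicate has
    a peak whose sequence is within edit distance
    ``max(tolerance, ceil(0.05 * length))``.  Reported intervals are the
    first replicate's.
    """
    if not peak_sets:
        return []
    rep_ids = list(peak_sets)
    first = rep_ids[0]
    if len(rep_ids) == 1:
        return list(peak_sets[first])
    out = []
    for pk in peak_sets[first]:
        seq = chiptig_seqs[pk.chiptig_id][pk.start : pk.end]
        slack = max(tolerance, math.ceil(0.05 * len(seq)))
        p_raw = dict(pk.p_raw)
        p_bon = dict(pk.p_bonferroni)
        supported = 1
        for rid in rep_ids[1:]:
            match = None
            for other in peak_sets[rid]:
                oseq = chiptig_seqs[other.chiptig_id][other.start : other.end]
                d = edlib.align(seq, oseq, mode="NW", task="distance")["editDistance"]
                if d <= slack:
                    match = other
                    break
            if match is None:
                break
            supported += 1
            p_raw.update(match.p_raw)
            p_bon.update(match.p_bonferroni)
        if supported == len(rep_ids):
            out.append(Peak(
                chiptig_id=pk.chiptig_id, start=pk.start, end=pk.end,
                p_raw=p_raw, p_bonferroni=p_bon,
                n_supporting_replicates=supported,
            ))
    return out
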