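"""End-to-end run: reads in, chiptigs and peaks out."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import assembly, graph, kmers, merging, peaks
from .io import ReadSet, RunConfig, write_chiptigs, write_peaks


@dataclass
class PipelineResult:
    chiptigs: list[merging.Chiptig]
    peaks: list[peaks.Peak]
    per_replicate_peaks: dict[str, list[peaks.Peak]]
    threshold: int
    n_components: int
    config: RunConfig = field(repr=False, default=None)


def assemble_chiptigs(treatment: list[ReadSet], control: list[ReadSet],
                      config: RunConfig):
    """Graph preparation, partial assembly and merging; no peak calling.

    Returns (chiptigs, treatment tables, control tables, threshold,
    component count).
    """
    k = config.k
    t_tables = [kmers.count_kmers(rs, k) for rs in treatment]
    c_tables = [kmers.count_kmers(rs, k) for rs in control]
    summed = kmers.sum_treatment(t_tables)
    corrected = kmers.correct_with_control(summed, c_tables)
    split = kmers.split_by_threshold(
        corrected, config.threshold_mode, config.threshold_value
    )
    observed_k1: set[str] = set()
    for t in t_tables:
        observed_k1 |= t.k1mers

    g = graph.build_graph(split.retained, observed_k1, k)
    g = graph.compact_unitigs(g)
    components = graph.weakly_connected_components(g)
    cleaned: list[graph.Component] = []
    for comp in components:
        comp = graph.remove_bubbles(
            comp, config.bubble_span, config.bubble_similarity
        )
        # bubble removal can cut connectivity: deconstruct again
        cleaned.extend(graph.weakly_connected_components(comp.graph))
    for i, comp in enumerate(cleaned):
        comp.component_id = i

    chiptigs: list[merging.Chiptig] = []
    for comp in cleaned:
        seqs = assembly.assemble_component(comp)
        chiptigs.extend(merging.merge_subsequences(seqs, comp.component_id))
    for n, ct in enumerate(chiptigs, start=1):
        ct.chiptig_id = f"chiptig_{n}"
    merging.map_low_abundance_kmers(
        chiptigs, split.low_abundance,
        identity_threshold=config.identity_threshold,
        min_abs=config.low_kmer_min_abundance,
        word_size=config.word_size,
    )
    return chiptigs, t_tables, c_tables, split.threshold, len(cleaned)


def run_pipeline(treatment: list[ReadSet], control: list[ReadSet],
                 config: RunConfig, out_dir: str | Path | None = None,
                 skip_peaks: bool = False) -> PipelineResult:
    """Run the full reference-free peak-calling workflow."""
    chiptigs, t_tables, c_tables, threshold, n_comp = assemble_chiptigs(
        treatment, control, config
    )
    per_rep: dict[str, list[peaks.Peak]] = {}
    final: list[peaks.Peak] = []
    if skip_peaks or not control:
        if not control and not skip_peaks:
            warnings.warn("no control provided: skipping peak calling")
    elif chiptigs:
        eligible = [
            ct for ct in chiptigs
            if len(ct.sequence) > config.min_chiptig_factor * config.k
        ]
        if eligible:
            tmat = peaks.build_matrices(eligible, t_tables, "treatment")
            cmat = peaks.build_matrices(eligible, c_tables, "control")
            per_rep = peaks.call_peaks(eligible, tmat, cmat, config)
            seqs = {ct.chiptig_id: ct.sequence for ct in eligible}
            final = peaks.intersect_replicates(
                per_rep, seqs, tolerance=config.intersection_tolerance
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_chiptigs(chiptigs, out_dir)
        all_seqs = {ct.chiptig_id: ct.sequence for ct in chiptigs}
        if not skip_peaks and control:
            write_peaks(final, all_seqs, out_dir)
    return PipelineResult(
        chiptigs=chiptigs, peaks=final, per_replicate_peaks=per_rep,
        threshold=threshold, n_components=n_comp, config=config,
    )
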