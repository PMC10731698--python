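"""Deterministic synthetic ChIP-seq experiments with known binding loci.

The generator emulates the essentials of a pulldown sequencing experiment:
an i.i.d. uniform background genome, non-overlapping implanted binding-site
loci, uniform control read coverage, treatment coverage elevated by
``enrichment_fold`` over the sites, and per-base substitution errors.  The
immunoprecipitation signal is modelled by extra treatment reads drawn
uniformly from within each site, on top of a background read layer identical
in law to the control; fragment-size effects, PCR duplicates and mappability
are deliberately not modelled.  Everything is a deterministic function of
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ReadSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic experiment."""

    genome_length: int = 20_000
    n_sites: int = 1
    site_length: int = 200
    motif: str = "random"  # explicit site sequence, or "random"
    enrichment_fold: float = 20.0
    read_length: int = 50
    background_depth: float = 15.0
    error_rate: float = 0.005
    n_replicates: int = 2
    seed: int = 0
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.site_length < self.read_length:
            raise ValueError("site_length must be >= read_length")
        if self.motif != "random" and len(self.motif) != self.site_length:
            raise ValueError("explicit motif must have length site_length")
        if self.n_sites * self.site_length > self.genome_length // 2:
            raise ValueError("sites occupy too much of the genome to place")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _place_sites(rng: np.random.Generator, spec: SimulationSpec) -> list[tuple[int, int]]:
    """Non-overlapping site intervals, retried placement."""
    sites: list[tuple[int, int]] = []
    for _ in range(1000):
        if len(sites) == spec.n_sites:
            break
        start = int(rng.integers(0, spec.genome_length - spec.site_length + 1))
        end = start + spec.site_length
        if all(end <= s or start >= e for s, e in sites):
            sites.append((start, end))
    if len(sites) < spec.n_sites:
        raise ValueError("could not place non-overlapping sites; lower n_sites")
    return sorted(sites)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _sample_reads(rng: np.random.Generator, genome: str, starts: np.ndarray,
                  read_length: int, error_rate: float,
                  both_strands: bool) -> list[str]:
    reads = []
    for s in starts:
        read = genome[s : s + read_length]
        if error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(read_length) < error_rate)[0]
            for h in hits:
                choices = _BASES[_BASES != arr[h]]
                arr[h] = rng.choice(choices)
            read = arr.tobytes().decode()
        if both_strands and rng.random() < 0.5:
            read = _revcomp(read)
        reads.append(read)
    return reads


def simulate(spec: SimulationSpec) -> tuple[list[ReadSet], list[ReadSet], list[tuple[int, int]], str]:
    """Generate treatment and control replicates plus the ground truth.

    Returns (treatment read sets, control read sets, site intervals as
    0-based half-open tuples, genome sequence).  Control replicates carry
    ``round(depth * genome_length / read_length)`` uniformly placed reads;
    treatment replicates carry the same background layer plus
    ``round((fold - 1) * depth * site_length / read_length)`` extra reads per
    site, placed uniformly inside the site so that mean site coverage is
    ``fold`` times the background.
    """
    rng = np.random.default_rng(spec.seed)
    genome = _random_seq(rng, spec.genome_length)
    sites = _place_sites(rng, spec)
    if spec.motif != "random":
        for s, e in sites:
            genome = genome[:s] + spec.motif + genome[e:]
    truth = list(sites)

    g, rl = spec.genome_length, spec.read_length
    n_bg = round(spec.background_depth * g / rl)
    n_extra = round((spec.enrichment_fold - 1) * spec.background_depth
                    * spec.site_length / rl)

    treatment, control = [], []
    for cond, holder in (("control", control), ("treatment", treatment)):
        for rep in range(spec.n_replicates):
            rep_rng = np.random.default_rng(
                [spec.seed, 1 if cond == "treatment" else 0, rep]
            )
            starts = rep_rng.integers(0, g - rl + 1, size=n_bg)
            if cond == "treatment":
                extra = [
                    rep_rng.integers(s, e - rl + 1, size=n_extra)
                    for s, e in sites
                ]
                starts = np.concatenate([starts] + extra)
            reads = _sample_reads(rep_rng, genome, starts, rl,
                                  spec.error_rate, spec.both_strands)
            holder.append(ReadSet(reads=reads, replicate_id=f"{cond}_{rep + 1}",
                                  condition=cond))
    return treatment, control, truth, genome


def write_simulation(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated experiment as FASTQ files plus a truth BED."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    treatment, control, truth, genome = simulate(spec)
    paths: dict[str, Path] = {}
    for rs in treatment + control:
        p = out_dir / f"{rs.replicate_id}.fastq"
        with open(p, "w") as fh:
            for i, read in enumerate(rs.reads):
                fh.write(f"@{rs.replicate_id}.{i}\n{read}\n+\n{'I' * len(read)}\n")
        paths[rs.replicate_id] = p
    bed = out_dir / "truth.bed"
    with open(bed, "w") as fh:
        for i, (s, e) in enumerate(truth):
            fh.write(f"sim\t{s}\t{e}\tsite_{i + 1}\n")
    paths["truth"] = bed
    fa = out_dir / "genome.fasta"
    with open(fa, "w") as fh:
        fh.write(f">sim\n{genome}\n")
    paths["genome"] = fa
    return paths
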