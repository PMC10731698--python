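"""Sequence input, result serialization and run configuration.

FASTA/FASTQ input goes through Bio.SeqIO; the format is auto-detected from
the first character of the file ('>' vs '@'), and gzip compression is
detected from the ``.gz`` suffix.  Outputs are plain FASTA plus TSV sidecars;
all intervals are 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .merging import Chiptig
    from .peaks import Peak


@dataclass
class ReadSet:
    """Reads of one replicate of one condition."""

    reads: list[str]
    replicate_id: str
    condition: str  # "treatment" | "control"

    def __post_init__(self) -> None:
        if self.condition not in ("treatment", "control"):
            raise ValueError(f"condition must be treatment/control, got {self.condition!r}")
        if any(not r for r in self.reads):
            raise ValueError("empty read in ReadSet")


@dataclass
class RunConfig:
    """Tunable parameters of a full run.

    ``k`` is the k-mer size; the abundance threshold is either an absolute
    count or a percentile of the corrected count distribution.  Only chiptigs
    longer than ``min_chiptig_factor * k`` enter peak calling.
    """

    k: int
    threshold_mode: str = "percentile"  # "absolute" | "percentile"
    threshold_value: float = 90.0
    min_chiptig_factor: float = 1.25
    identity_threshold: float = 0.95
    low_kmer_min_abundance: int = 0
    alpha: float = 0.05
    smoothing_short_len: int = 5
    ghmm_states: int = 3
    seed: int = 42
    intersection_tolerance: int = 4
    word_size: int = 10
    max_bubble_len: int | None = None  # defaults to 2k
    bubble_similarity: float = 0.9

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.threshold_mode not in ("absolute", "percentile"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_mode == "percentile" and not 0 <= self.threshold_value <= 100:
            raise ValueError("percentile threshold must be in [0, 100]")
        if self.min_chiptig_factor < 1:
            raise ValueError("min_chiptig_factor must be >= 1")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")

    @property
    def bubble_span(self) -> int:
        return self.max_bubble_len if self.max_bubble_len is not None else 2 * self.k


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path, condition: str, replicate_id: str) -> ReadSet:
    """Load a FASTA or FASTQ file (optionally gzipped) into a ReadSet.

    Raises ValueError for missing/empty files and for malformed records.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"input file does not exist: {path}")
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            raise ValueError(f"input file is empty: {path}")
        else:
            raise ValueError(
                f"cannot detect format of {path}: first character {first!r} "
                "is neither '>' (FASTA) nor '@' (FASTQ)"
            )
    reads = []
    with _open_text(path) as fh:
        try:
            for i, record in enumerate(SeqIO.parse(fh, fmt)):
                seq = str(record.seq).upper()
                if not seq:
                    raise ValueError(f"record {i} in {path} has an empty sequence")
                reads.append(seq)
        except ValueError as e:
            raise ValueError(f"malformed {fmt.upper()} in {path}: {e}") from e
    if not reads:
        raise ValueError(f"no sequence records found in {path}")
    return ReadSet(reads=reads, replicate_id=replicate_id, condition=condition)


def write_chiptigs(chiptigs: "list[Chiptig]", out_dir: str | Path) -> dict[str, Path]:
    """Write chiptig sequences (FASTA) and per-position abundances (TSV).

    FASTA ids are ``chiptig_<n>`` in input order, n starting at 1.  The TSV
    has columns chiptig_id, position (0-based), abundance and round-trips the
    profiles exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "chiptigs.fasta"
    tsv = out_dir / "chiptig_profiles.tsv"
    with open(fasta, "w") as fa, open(tsv, "w") as tf:
        tf.write("chiptig_id\tposition\tabundance\n")
        for n, ct in enumerate(chiptigs, start=1):
            name = f"chiptig_{n}"
            fa.write(f">{name}\n{ct.sequence}\n")
            for pos, a in enumerate(ct.profile):
                tf.write(f"{name}\t{pos}\t{a}\n")
    return {"fasta": fasta, "profiles": tsv}


def read_chiptigs(out_dir: str | Path) -> "list[Chiptig]":
    """Re-load chiptigs written by :func:`write_chiptigs`."""
    from .merging import Chiptig

    out_dir = Path(out_dir)
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(out_dir / "chiptigs.fasta"), "fasta"):
        seqs[rec.id] = str(rec.seq)
        order.append(rec.id)
    profiles: dict[str, list[int]] = {name: [] for name in order}
    with open(out_dir / "chiptig_profiles.tsv") as fh:
        next(fh)  # header
        for line in fh:
            name, pos, a = line.rstrip("\n").split("\t")
            profiles[name].append(int(a))
    return [
        Chiptig(chiptig_id=name, sequence=seqs[name], profile=profiles[name], component_id=-1)
        for name in order
    ]


def write_peaks(peaks: "list[Peak]", chiptig_seqs: dict[str, str], out_dir: str | Path) -> dict[str, Path]:
    """Write peak subsequences (FASTA) and their statistics (TSV).

    TSV columns: chiptig_id, start, end (0-based half-open), p_raw,
    p_bonferroni (minimum over supporting replicates), n_replicates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "peaks.fasta"
    tsv = out_dir / "peaks.tsv"
    with open(fasta, "w") as fa, open(tsv, "w") as tf:
        tf.write("chiptig_id\tstart\tend\tp_raw\tp_bonferroni\tn_replicates\n")
        for n, pk in enumerate(peaks, start=1):
            seq = chiptig_seqs[pk.chiptig_id][pk.start : pk.end]
            fa.write(f">peak_{n} {pk.chiptig_id}:{pk.start}-{pk.end}\n{seq}\n")
            p_raw = min(pk.p_raw.values())
            p_bon = min(pk.p_bonferroni.values())
            tf.write(
                f"{pk.chiptig_id}\t{pk.start}\t{pk.end}\t{p_raw:.6g}\t{p_bon:.6g}\t"
                f"{pk.n_supporting_replicates}\n"
            )
    return {"fasta": fasta, "peaks": tsv}
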