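"""Readers and writers for the formats the pipeline touches.

All coordinates inside the package are 1-based inclusive, the convention of
archaeal genome annotation and of the published circRNA junction tables this
pipeline reproduces.  BED output converts to 0-based half-open on the way out,
so ``bed_end - bed_start`` always equals the predicted circle length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("circfind")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a normalized DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Upper-case, U→T; reject characters outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"{context}: invalid characters {sorted(bad)!r}; expected A/C/G/T/U/N"
        )
    return seq


@dataclass(frozen=True)
class GenomeRecord:
    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """A reference genome: named sequences over {A,C,G,T,N}, unique names."""

    records: tuple[GenomeRecord, ...]

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate record names in genome")
        for r in self.records:
            if not r.sequence:
                raise ValueError(f"record {r.name!r}: empty sequence")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def sequence(self, name: str) -> str:
        for r in self.records:
            if r.name == name:
                return r.sequence
        raise KeyError(name)

    def fetch(self, name: str, start: int, end: int) -> str:
        """Sub-sequence at 1-based inclusive [start, end]."""
        seq = self.sequence(name)
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval {start}-{end} out of bounds for {name!r} (len {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass(frozen=True)
class SequenceRead:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> Genome:
    """Parse a FASTA file into a :class:`Genome` with a normalized alphabet."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
            records.append(GenomeRecord(rec.id, seq))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no records")
    return Genome(tuple(records))


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in genome.records:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> Iterator[SequenceRead]:
    """Stream reads from FASTQ in file order.

    Qualities are parsed (so truncated/mismatched records raise, with the
    failing record index) but are not used: inputs are assumed quality- and
    adapter-trimmed upstream.
    """
    path = Path(path)
    index = 0
    parser = SeqIO.parse(str(path), "fastq")
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"{path}: bad FASTQ record #{index + 1}: {exc}") from exc
        index += 1
        yield SequenceRead(rec.id, normalize_sequence(str(rec.seq), context=rec.id))


def write_fastq(reads: Iterable[SequenceRead], path) -> None:
    """Write reads with a flat placeholder quality (qualities are unused here)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * r.length}\n")


# ---------------------------------------------------------------------------
# candidate reports

CANDIDATE_COLUMNS = [
    "locus_name",
    "chrom",
    "junction_start",
    "junction_end",
    "predicted_length",
    "strand",
    "circ_read_count",
    "passed_filters",
    "cdbox_call",
    "stem_pairs",
]


def candidates_to_frame(candidates, annotations=None) -> pd.DataFrame:
    """Tabulate candidates; ``annotations`` maps locus_name -> (cdbox, stem_pairs)."""
    annotations = annotations or {}
    rows = []
    for c in candidates:
        cdbox, stem = annotations.get(c.locus_name, ("", ""))
        rows.append(
            {
                "locus_name": c.locus_name,
                "chrom": c.chrom,
                "junction_start": c.circ_start,
                "junction_end": c.circ_end,
                "predicted_length": c.predicted_length,
                "strand": c.strand,
                "circ_read_count": c.total_count,
                "passed_filters": bool(c.passed_filters),
                "cdbox_call": cdbox,
                "stem_pairs": stem,
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates_tsv(candidates, path, annotations=None) -> None:
    candidates_to_frame(candidates, annotations).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_bed(candidates, path) -> None:
    """BED6 output: internal 1-based inclusive → 0-based half-open."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.chrom}\t{c.circ_start - 1}\t{c.circ_end}\t{c.locus_name}"
                f"\t{c.total_count}\t{c.strand}\n"
            )


def bed_interval(circ_start: int, circ_end: int) -> tuple[int, int]:
    """1-based inclusive → BED 0-based half-open (an exact bijection)."""
    return circ_start - 1, circ_end


def write_bedgraph(track, path) -> None:
    """Run-length-encoded bedGraph of a coverage track (see compare module)."""
    with open(path, "w") as fh:
        for chrom, depth in track.depth.items():
            start = 0
            for pos in range(1, len(depth) + 1):
                if pos == len(depth) or depth[pos] != depth[start]:
                    if depth[start] != 0:
                        fh.write(f"{chrom}\t{start}\t{pos}\t{depth[start]:g}\n")
                    start = pos


# ---------------------------------------------------------------------------
# packaged reference data

FIXTURE_NAME = "tk_circrna_survey.tsv"


def load_published_circrna_table() -> pd.DataFrame:
    """Published circRNA survey of T. kodakarensis WT vs Rnl-knockout.

    31 loci with circular-junction coordinates (1-based inclusive on
    NC_006624.1), printed predicted lengths, small-RNA-seq aligned and
    circular read counts per strain, total-RNA-seq circular counts, and the
    published depleted/retained classification.
    """
    with resources.files("circfind.data").joinpath(FIXTURE_NAME).open() as fh:
        return pd.read_csv(fh, sep="\t")
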