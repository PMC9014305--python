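"""Circular-junction detection by exact split-read matching.

A read supports a circular junction when it splits into two parts, each at
least ``min_segment_len`` nt, that both match the genome exactly on the same
strand but in inverse genomic order: the read's first part lies strictly
downstream of its second part.  Such a read can only arise by reading through
the closure point of a circle, so the junction is (start of second part's
placement, end of first part's placement).  Reads that also place contiguously
anywhere in the genome are vetoed as linear.

Matching is exact (no mismatches): inputs are assumed quality-trimmed, and
exactness keeps the detector equivalent to a brute-force enumeration oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .config import AnalysisConfig
from .io import Genome, SequenceRead, reverse_complement

logger = logging.getLogger("circfind")


class SequenceIndex:
    """Exact-match index over a genome.

    A dictionary of fixed-length seed k-mers (default 20 nt, the minimum
    segment length) maps to genome positions; a query is located by looking up
    its leading seed and verifying the full match, so ``locate`` is equivalent
    to a naive scan of both strands.  Queries shorter than the seed fall back
    to an explicit scan.  Queries containing N never match.
    """

    def __init__(self, genome: Genome, seed_len: int = 20):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.genome = genome
        self.seed_len = seed_len
        self._seqs = [(rec.name, rec.sequence) for rec in genome.records]
        seeds: dict[str, list[tuple[int, int]]] = {}
        for ci, (_, s) in enumerate(self._seqs):
            for i in range(len(s) - seed_len + 1):
                seeds.setdefault(s[i : i + seed_len], []).append((ci, i))
        self._seeds = seeds

    def chrom_name(self, chrom_index: int) -> str:
        return self._seqs[chrom_index][0]

    def locate_forward(self, query: str) -> list[tuple[int, int]]:
        """All forward-strand placements as (chrom_index, 0-based start)."""
        if not query or "N" in query:
            return []
        out: list[tuple[int, int]] = []
        if len(query) >= self.seed_len:
            for ci, i in self._seeds.get(query[: self.seed_len], ()):
                if self._seqs[ci][1].startswith(query, i):
                    out.append((ci, i))
        else:
            for ci, (_, s) in enumerate(self._seqs):
                i = s.find(query)
                while i != -1:
                    out.append((ci, i))
                    i = s.find(query, i + 1)
        return out

    def locate(self, query: str) -> list[tuple[str, int, int, str]]:
        """Every exact placement on either strand.

        Returns (chrom, start, end, strand) with 1-based inclusive
        coordinates on the forward frame; a minus-strand placement means the
        reverse complement of the query matches the forward genome there.
        """
        query = query.upper().replace("U", "T")
        res = []
        for strand, q in (("+", query), ("-", reverse_complement(query))):
            for ci, i in self.locate_forward(q):
                res.append((self.chrom_name(ci), i + 1, i + len(q), strand))
        return res


def build_index(genome: Genome, seed_len: int = 20) -> SequenceIndex:
    return SequenceIndex(genome, seed_len=seed_len)


@dataclass(frozen=True)
class JunctionHit:
    """One read's evidence of a circular junction.

    ``upstream_segment`` is the placement of the read's *first* part (which
    lies genomically downstream — that inversion is the junction signature);
    ``downstream_segment`` places the read's second part.  ``split_pos`` is
    the length of the first part in the oriented (+-frame) read sequence.
    """

    read_id: str
    chrom: str
    strand: str
    split_pos: int
    upstream_segment: tuple[int, int]
    downstream_segment: tuple[int, int]
    junction: tuple[int, int]

    def __post_init__(self):
        a1, b1 = self.upstream_segment
        a2, b2 = self.downstream_segment
        cs, ce = self.junction
        if not (a1 <= b1 and a2 <= b2):
            raise ValueError("malformed segment placements")
        if a1 <= b2:
            raise ValueError("segments must be in inverse order, non-overlapping")
        if (cs, ce) != (a2, b1) or ce < cs:
            raise ValueError("junction inconsistent with segment placements")


def find_circular_junctions(
    read: SequenceRead, index: SequenceIndex, cfg: AnalysisConfig
) -> list[JunctionHit]:
    """All circular junctions supported by one read.

    Both strands are searched by running the forward-frame computation on the
    read and on its reverse complement; minus-strand junctions are reported in
    forward-frame coordinates with strand "-".  Per split, if both parts place
    more than once the split is discarded as ambiguous (repeat-derived); if
    one part is unique, one hit per placement pair is emitted.  Identical
    junctions reachable from several splits of one read (junction
    micro-homology) are emitted once, keeping the leftmost split.
    """
    seq = read.sequence
    n = len(seq)
    k = cfg.min_segment_len
    if n < 2 * k:
        logger.debug("read %s: length %d < 2 x %d, skipped", read.id, n, k)
        return []
    rc = reverse_complement(seq)
    # Linear veto: a contiguous full-length placement trumps any split.
    if index.locate_forward(seq) or index.locate_forward(rc):
        return []
    hits: list[JunctionHit] = []
    seen: set[tuple[str, str, int, int]] = set()
    for strand, oriented in (("+", seq), ("-", rc)):
        for split in range(k, n - k + 1):
            p1 = index.locate_forward(oriented[:split])
            if not p1:
                continue
            p2 = index.locate_forward(oriented[split:])
            if not p2:
                continue
            if len(p1) > 1 and len(p2) > 1:
                logger.debug(
                    "read %s: split %d ambiguous (%dx%d placements), discarded",
                    read.id,
                    split,
                    len(p1),
                    len(p2),
                )
                continue
            for c1, i1 in p1:
                a1, b1 = i1 + 1, i1 + split
                for c2, i2 in p2:
                    if c1 != c2:
                        continue
                    a2, b2 = i2 + 1, i2 + (n - split)
                    if a1 <= b2:  # need part 1 strictly downstream of part 2
                        continue
                    chrom = index.chrom_name(c1)
                    key = (chrom, strand, a2, b1)
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(
                        JunctionHit(
                            read_id=read.id,
                            chrom=chrom,
                            strand=strand,
                            split_pos=split,
                            upstream_segment=(a1, b1),
                            downstream_segment=(a2, b2),
                            junction=(a2, b1),
                        )
                    )
    return hits


def detect_sample(
    reads: Iterable[SequenceRead], index: SequenceIndex, cfg: AnalysisConfig
) -> tuple[list[JunctionHit], dict]:
    """Run junction detection over a read stream.

    Returns the concatenated per-read hits plus a summary with the total read
    count and the number of reads contributing at least one hit.
    """
    hits: list[JunctionHit] = []
    total = 0
    with_hits = 0
    for read in reads:
        total += 1
        found = find_circular_junctions(read, index, cfg)
        if found:
            with_hits += 1
            hits.extend(found)
    summary = {"total_reads": total, "reads_with_hits": with_hits}
    logger.info(
        "junction detection: %d/%d reads carry circular junctions",
        with_hits,
        total,
    )
    return hits, summary


def hits_to_frame(hits: Iterable[JunctionHit]) -> pd.DataFrame:
    """Dump intermediate hits as a table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "chrom": h.chrom,
                "strand": h.strand,
                "circ_start": h.junction[0],
                "circ_end": h.junction[1],
                "split_pos": h.split_pos,
            }
            for h in hits
        ],
        columns=["read_id", "chrom", "strand", "circ_start", "circ_end", "split_pos"],
    )
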