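"""Grouping junction hits into circRNA candidates.

Raw junctions are clustered within a coordinate tolerance (both endpoints
within +/- tol of a representative), then count and length filters are applied
per library type: total-RNA libraries keep clusters with >=100 reads; small-RNA
libraries keep clusters with >=20 reads and a predicted length <=10 kb.  The
predicted circle length is the genomic span of the junction, end - start + 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import AnalysisConfig
from .detect import JunctionHit

LIBRARY_TYPES = ("total", "small")


def predicted_length(circ_start: int, circ_end: int) -> int:
    """Circle length implied by a junction: ``circ_end - circ_start + 1``."""
    if circ_end < circ_start:
        raise ValueError(f"malformed junction: end {circ_end} < start {circ_start}")
    return circ_end - circ_start + 1


@dataclass
class JunctionCluster:
    chrom: str
    strand: str
    members: list[tuple[int, int, int]]  # (circ_start, circ_end, count)
    representative: tuple[int, int]

    @property
    def total_count(self) -> int:
        return sum(m[2] for m in self.members)


@dataclass
class CircCandidate:
    cluster: JunctionCluster
    predicted_length: int
    passed_filters: bool
    filter_reason: str = ""
    locus_name: str = ""

    @property
    def chrom(self) -> str:
        return self.cluster.chrom

    @property
    def strand(self) -> str:
        return self.cluster.strand

    @property
    def circ_start(self) -> int:
        return self.cluster.representative[0]

    @property
    def circ_end(self) -> int:
        return self.cluster.representative[1]

    @property
    def total_count(self) -> int:
        return self.cluster.total_count


def cluster_junctions(hits: Iterable[JunctionHit], tol: int) -> list[JunctionCluster]:
    """Greedy count-weighted grouping of raw junctions.

    The highest-count unassigned junction (ties: smaller start, then smaller
    end) seeds a cluster and absorbs every unassigned junction on the same
    chrom and strand with both |delta start| <= tol and |delta end| <= tol.
    Each raw junction joins exactly one cluster; the representative is the
    seed (the modal junction), matching how single junction coordinates are
    reported for a group.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    counts = Counter(
        (h.chrom, h.strand, h.junction[0], h.junction[1]) for h in hits
    )
    order = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], kv[0][2], kv[0][3], kv[0][0], kv[0][1]),
    )
    assigned: set[tuple] = set()
    clusters: list[JunctionCluster] = []
    for key, _ in order:
        if key in assigned:
            continue
        chrom, strand, s0, e0 = key
        members = []
        for key2, cnt2 in order:
            if key2 in assigned:
                continue
            c2, st2, s2, e2 = key2
            if c2 == chrom and st2 == strand and abs(s2 - s0) <= tol and abs(e2 - e0) <= tol:
                members.append((s2, e2, cnt2))
                assigned.add(key2)
        clusters.append(
            JunctionCluster(chrom=chrom, strand=strand, members=members, representative=(s0, e0))
        )
    return clusters


def filter_clusters(
    clusters: Iterable[JunctionCluster], cfg: AnalysisConfig, library_type: str
) -> list[CircCandidate]:
    """Apply per-library count/length filters, keeping failures annotated.

    ``total`` libraries: count >= min_count_total_rna, no length filter.
    ``small`` libraries: count >= min_count_small_rna and predicted length
    <= max_predicted_len.
    """
    if library_type not in LIBRARY_TYPES:
        raise ValueError(f"unknown library_type {library_type!r}; expected {LIBRARY_TYPES}")
    min_count = (
        cfg.min_count_total_rna if library_type == "total" else cfg.min_count_small_rna
    )
    out = []
    for cl in clusters:
        plen = predicted_length(*cl.representative)
        reasons = []
        if cl.total_count < min_count:
            reasons.append(f"count<{min_count}")
        if library_type == "small" and plen > cfg.max_predicted_len:
            reasons.append(f"length>{cfg.max_predicted_len}")
        out.append(
            CircCandidate(
                cluster=cl,
                predicted_length=plen,
                passed_filters=not reasons,
                filter_reason=";".join(reasons),
            )
        )
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _match_annotation(cand: CircCandidate, annotation: Sequence[tuple]) -> str | None:
    """Name a candidate from an interval table (name, chrom, start, end).

    A candidate takes an annotated name when its junction interval is
    contained in the annotated interval, or when they reciprocally overlap by
    at least 50% of each length.  Best (largest-overlap) match wins.
    """
    iv = (cand.circ_start, cand.circ_end)
    best, best_ov = None, 0
    for name, chrom, start, end in annotation:
        if chrom != cand.chrom:
            continue
        ov = _overlap(iv, (start, end))
        if ov == 0:
            continue
        contained = start <= iv[0] and iv[1] <= end
        reciprocal = ov >= 0.5 * (iv[1] - iv[0] + 1) and ov >= 0.5 * (end - start + 1)
        if (contained or reciprocal) and ov > best_ov:
            best, best_ov = name, ov
    return best


def aggregate_sample(
    hits: Iterable[JunctionHit],
    cfg: AnalysisConfig,
    library_type: str,
    annotation: Sequence[tuple] | None = None,
) -> list[CircCandidate]:
    """Cluster, filter, sort and name one sample's junction hits.

    ``annotation`` is an optional table of named loci (name, chrom, start,
    end) in 1-based inclusive coordinates; unmatched candidates get
    deterministic auto-names in genomic order.
    """
    clusters = cluster_junctions(hits, cfg.junction_group_tolerance)
    cands = filter_clusters(clusters, cfg, library_type)
    cands.sort(key=lambda c: (c.chrom, c.circ_start, c.circ_end, c.strand))
    for idx, cand in enumerate(cands, start=1):
        name = _match_annotation(cand, annotation) if annotation else None
        cand.locus_name = name or f"circ{idx:04d}"
    return cands
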