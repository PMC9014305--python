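"""Wild-type vs knockout comparison.

Three layers: RPKM expression with flooring/omission filters and strict
>2-fold classification; per-locus circular-read depletion calls (a circRNA is
"depleted" when its knockout circular-read count falls below a configurable
fraction, default 5%, of the wild-type count); and per-base coverage tracks
from contiguous exact placements, with cross-sample normalization.

No statistical testing is attempted: the study design has a single biological
replicate per strain, so calls are deterministic threshold rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregate import CircCandidate, JunctionCluster, predicted_length
from .config import AnalysisConfig
from .detect import SequenceIndex

logger = logging.getLogger("circfind")


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionRecord:
    gene_id: str
    length: int
    count_wt: float
    count_ko: float
    rpkm_wt: float = 0.0
    rpkm_ko: float = 0.0
    status: str = "unchanged"  # up | down | unchanged | omitted


def compute_rpkm(count: float, gene_length: int, total_mapped: float) -> float:
    """Reads per kilobase per million mapped reads: count*1e9/(total*length)."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (total_mapped * gene_length)


def apply_expression_filters(
    records: Iterable[ExpressionRecord], cfg: AnalysisConfig
) -> list[ExpressionRecord]:
    """Floor RPKM below ``rpkm_floor`` to 0, then omit genes below
    ``rpkm_min_either`` in both strains (kept in the table, status="omitted")."""
    out = []
    for rec in records:
        if rec.rpkm_wt < cfg.rpkm_floor:
            rec.rpkm_wt = 0.0
        if rec.rpkm_ko < cfg.rpkm_floor:
            rec.rpkm_ko = 0.0
        if rec.rpkm_wt < cfg.rpkm_min_either and rec.rpkm_ko < cfg.rpkm_min_either:
            rec.status = "omitted"
        out.append(rec)
    return out


def classify_fold_change(record: ExpressionRecord, cfg: AnalysisConfig) -> str:
    """Strictly-greater-than fold-change call on floored RPKM values.

    up: ko > cutoff*wt; down: ko < wt/cutoff; else unchanged.  A floored 0 on
    one side yields a direction call driven by the other side (which, for a
    non-omitted record, is at least ``rpkm_min_either``).
    """
    if record.status == "omitted":
        return "omitted"
    fc = cfg.fold_change_cutoff
    if record.rpkm_ko > fc * record.rpkm_wt:
        record.status = "up"
    elif fc * record.rpkm_ko < record.rpkm_wt:
        record.status = "down"
    else:
        record.status = "unchanged"
    return record.status


def expression_table(
    genes: Sequence[tuple[str, int]],
    counts_wt: dict[str, float],
    counts_ko: dict[str, float],
    total_wt: float,
    total_ko: float,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """RPKM + filter + fold-change table for genes given as (id, length)."""
    records = []
    for gene_id, length in genes:
        rec = ExpressionRecord(
            gene_id=gene_id,
            length=length,
            count_wt=counts_wt.get(gene_id, 0.0),
            count_ko=counts_ko.get(gene_id, 0.0),
        )
        rec.rpkm_wt = compute_rpkm(rec.count_wt, length, total_wt)
        rec.rpkm_ko = compute_rpkm(rec.count_ko, length, total_ko)
        records.append(rec)
    for rec in apply_expression_filters(records, cfg):
        classify_fold_change(rec, cfg)
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "length": r.length,
                "count_wt": r.count_wt,
                "count_ko": r.count_ko,
                "rpkm_wt": r.rpkm_wt,
                "rpkm_ko": r.rpkm_ko,
                "status": r.status,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# depletion

@dataclass(frozen=True)
class DepletionCall:
    locus_name: str
    circ_wt: int
    circ_ko: int
    ratio: float | None
    call: str  # depleted | retained | not_detected_in_wt


def classify_depletion(
    circ_wt: int, circ_ko: int, cfg: AnalysisConfig, locus_name: str = ""
) -> DepletionCall:
    """KO/WT circular-read ratio rule for "absent or significantly reduced"."""
    if circ_wt < 0 or circ_ko < 0:
        raise ValueError("counts must be >= 0")
    if circ_wt == 0:
        return DepletionCall(locus_name, circ_wt, circ_ko, None, "not_detected_in_wt")
    ratio = circ_ko / circ_wt
    call = "depleted" if ratio < cfg.depletion_ratio else "retained"
    return DepletionCall(locus_name, circ_wt, circ_ko, ratio, call)


def compare_samples(
    candidates_wt: Sequence[CircCandidate],
    candidates_ko: Sequence[CircCandidate],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Per-locus WT vs KO circular-read report.

    WT candidates that passed filters define the loci; each is matched to a
    KO cluster whose representative lies within the grouping tolerance on
    both endpoints (same chrom and strand).  KO candidates are matched
    regardless of their own filter status: residual knockout counts below the
    count floor are exactly the signal of interest.  Loci absent from KO get
    circ_ko = 0.
    """
    wt_chroms = {c.chrom for c in candidates_wt}
    ko_chroms = {c.chrom for c in candidates_ko}
    if wt_chroms and ko_chroms and not (wt_chroms & ko_chroms):
        raise ValueError("genome mismatch: samples share no reference sequences")
    tol = cfg.junction_group_tolerance
    rows = []
    for cand in candidates_wt:
        if not cand.passed_filters:
            continue
        best, best_dist = None, None
        for ko in candidates_ko:
            if ko.chrom != cand.chrom or ko.strand != cand.strand:
                continue
            ds = abs(ko.circ_start - cand.circ_start)
            de = abs(ko.circ_end - cand.circ_end)
            if ds <= tol and de <= tol and (best is None or ds + de < best_dist):
                best, best_dist = ko, ds + de
        circ_ko = best.total_count if best is not None else 0
        call = classify_depletion(cand.total_count, circ_ko, cfg, cand.locus_name)
        rows.append(
            {
                "locus_name": cand.locus_name,
                "chrom": cand.chrom,
                "strand": cand.strand,
                "circ_start": cand.circ_start,
                "circ_end": cand.circ_end,
                "predicted_length": cand.predicted_length,
                "circ_wt": call.circ_wt,
                "circ_ko": call.circ_ko,
                "ratio": call.ratio,
                "call": call.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_name",
            "chrom",
            "strand",
            "circ_start",
            "circ_end",
            "predicted_length",
            "circ_wt",
            "circ_ko",
            "ratio",
            "call",
        ],
    )


def depletion_calls_from_table(
    table: pd.DataFrame,
    cfg: AnalysisConfig,
    wt_col: str = "wt_circ",
    ko_col: str = "ko_circ",
    name_col: str = "locus_name",
) -> list[DepletionCall]:
    """Apply the depletion rule to a published-style count table."""
    return [
        classify_depletion(int(row[wt_col]), int(row[ko_col]), cfg, str(row[name_col]))
        for _, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# coverage

@dataclass
class CoverageTrack:
    depth: dict[str, np.ndarray]
    total_placed: float  # reads placed (fractions of multi-mapped reads sum to 1)


def compute_coverage(
    reads, index: SequenceIndex, normalize_to: CoverageTrack | None = None
) -> CoverageTrack:
    """Per-base depth from contiguous full-length exact placements.

    Multi-placed reads contribute fractionally (1/n per placement).  When
    ``normalize_to`` is given (the wild-type track), depths are scaled by
    (its total placed reads / this sample's total placed reads), putting both
    tracks on the wild-type scale.
    """
    depth = {
        rec.name: np.zeros(rec.length, dtype=float) for rec in index.genome.records
    }
    total_placed = 0.0
    for read in reads:
        placements = index.locate(read.sequence)
        if not placements:
            continue
        w = 1.0 / len(placements)
        total_placed += 1.0
        for chrom, start, end, _ in placements:
            depth[chrom][start - 1 : end] += w
    track = CoverageTrack(depth=depth, total_placed=total_placed)
    if normalize_to is not None:
        if track.total_placed == 0:
            logger.warning("coverage normalization skipped: no placed reads")
        else:
            scale = normalize_to.total_placed / track.total_placed
            for arr in track.depth.values():
                arr *= scale
    return track
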