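"""Synthetic genomes and reads with a machine-readable truth table.

The generator emulates the study design the pipeline targets: a
prokaryote-scale genome carrying circularized C/D-box-like sRNA loci (61-71
nt, GC-rich terminal stems of >=3 designed pairings, C box near the 5' end, D
box near the 3' end), non-circular C/D loci (identical layout but stems broken
to <=2 pairings), plain linear genes, and optionally one rRNA-like locus with
a 40-nt internal segment excluded from read generation (mimicking an excised
helix's coverage hole).  Two 51-nt single-end read samples are drawn: a
wild-type-like sample and a knockout-like sample in which the junction-read
abundance of circular loci is multiplied by ``ko_circ_ratio`` while all other
abundances are unchanged.

Every random draw flows from ``SimConfig.seed``; identical configs produce
bit-identical genomes, truth tables and reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cdbox import terminal_stem_pairs
from .io import Genome, GenomeRecord, SequenceRead, reverse_complement

_LETTERS = np.array(list("ACGT"))
_PLACEMENT_PAD = 30  # nt kept free around each locus


@dataclass
class SimConfig:
    genome_len: int = 100_000
    n_circ_loci: int = 20
    n_noncirc_cd_loci: int = 10
    n_linear_genes: int = 50
    circ_locus_len_range: tuple[int, int] = (61, 71)
    linear_gene_len_range: tuple[int, int] = (200, 1000)
    read_len: int = 51
    n_reads_per_sample: int = 200_000
    junction_read_fraction: float = 0.5
    ko_circ_ratio: float = 0.01
    error_rate: float = 0.0
    include_rrna_like: bool = True
    rrna_like_len: int = 1200
    rrna_gap_len: int = 40
    min_segment_len: int = 20  # generated junction reads keep both arms >= this
    seed: int = 0

    def validate(self) -> None:
        if self.read_len < 2 * self.min_segment_len:
            raise ValueError(
                "read_len < 2 x min_segment_len: junction reads would be undetectable"
            )
        if not 0.0 <= self.junction_read_fraction <= 1.0:
            raise ValueError("junction_read_fraction must lie in [0, 1]")
        if not 0.0 <= self.ko_circ_ratio <= 1.0:
            raise ValueError("ko_circ_ratio must lie in [0, 1]")
        lo, hi = self.circ_locus_len_range
        if lo < self.read_len + 1:
            raise ValueError("circular loci must be longer than a read")


@dataclass
class TruthRecord:
    locus_name: str
    kind: str  # circular_cd | noncirc_cd | linear_gene | rrna_like
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    stem_pairs_designed: int
    expected_junction: Optional[tuple[int, int]] = None
    excluded_gap: Optional[tuple[int, int]] = None  # genomic coords, rrna_like only

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _gc_rich(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_LETTERS, size=n, p=[0.1, 0.4, 0.4, 0.1]))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_LETTERS[rng.integers(0, 4, size=n)])


def build_cd_locus(rng: np.random.Generator, length: int, designed_pairs: int) -> str:
    """A C/D-box-like locus with an exactly ``designed_pairs``-long terminal stem.

    Layout: k GC-rich 5' bases Watson-Crick paired to the k 3'-terminal bases,
    immediately followed by a C box (RUGAUGA) whose first base cannot pair
    with the last base of the D box (CUGA) ending just inside the 3' stem —
    so the outermost-in pairing run stops at exactly k, wobble or not.
    """
    k = designed_pairs
    if length < 2 * k + 12:
        raise ValueError("locus too short for the requested stem and boxes")
    stem5 = _gc_rich(rng, k)
    seq = list(stem5 + _random_seq(rng, length - 2 * k) + reverse_complement(stem5))
    c_box = ("A" if rng.integers(0, 2) else "G") + "TGATGA"
    seq[k : k + 7] = list(c_box)
    seq[length - k - 4 : length - k] = list("CTGA")
    out = "".join(seq)
    assert terminal_stem_pairs(out, window=8, count_gu=True) == k
    return out


def _place_loci(
    rng: np.random.Generator, lengths: list[int], genome_len: int
) -> list[int]:
    """Non-overlapping 0-based start positions, padded; error when too dense."""
    if sum(L + 2 * _PLACEMENT_PAD for L in lengths) > 0.8 * genome_len:
        raise ValueError(
            "cannot place loci without overlap: increase genome_len or reduce loci"
        )
    occupied: list[tuple[int, int]] = []
    starts = []
    for L in lengths:
        for _ in range(2000):
            s = int(rng.integers(_PLACEMENT_PAD, genome_len - L - _PLACEMENT_PAD))
            if all(s + L + _PLACEMENT_PAD <= a or s >= b + _PLACEMENT_PAD for a, b in occupied):
                occupied.append((s, s + L))
                starts.append(s)
                break
        else:
            raise ValueError(
                "cannot place loci without overlap: increase genome_len or reduce loci"
            )
    return starts


def _locus_rna(genome: Genome, rec: TruthRecord) -> str:
    seq = genome.fetch(rec.chrom, rec.start, rec.end)
    return reverse_complement(seq) if rec.strand == "-" else seq


def _kmers_unique(genome_seq: str, rna: str, k: int) -> bool:
    rc_genome = reverse_complement(genome_seq)
    for i in range(len(rna) - k + 1):
        kmer = rna[i : i + k]
        if genome_seq.count(kmer) + rc_genome.count(kmer) != 1:
            return False
    return True


def simulate_genome(cfg: SimConfig) -> tuple[Genome, list[TruthRecord]]:
    """Random genome with planted loci and their truth records.

    Circular loci are built with unique flanks: every k-mer (k =
    min_segment_len) of the locus RNA occurs exactly once genome-wide, so
    planted junctions are recoverable without ambiguity; loci violating this
    are regenerated in place.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom = "sim_chr"

    plans: list[tuple[str, str, int, int]] = []  # (name, kind, length, designed_pairs)
    lo, hi = cfg.circ_locus_len_range
    for i in range(cfg.n_circ_loci):
        plans.append(
            (f"circ{i:02d}", "circular_cd", int(rng.integers(lo, hi + 1)), int(rng.integers(3, 7)))
        )
    for i in range(cfg.n_noncirc_cd_loci):
        plans.append(
            (f"cdnc{i:02d}", "noncirc_cd", int(rng.integers(lo, hi + 1)), int(rng.integers(0, 3)))
        )
    glo, ghi = cfg.linear_gene_len_range
    for i in range(cfg.n_linear_genes):
        plans.append((f"gene{i:02d}", "linear_gene", int(rng.integers(glo, ghi + 1)), 0))
    if cfg.include_rrna_like:
        plans.append(("rrna_like", "rrna_like", cfg.rrna_like_len, 0))

    starts = _place_loci(rng, [p[2] for p in plans], cfg.genome_len)
    g = _LETTERS[rng.integers(0, 4, size=cfg.genome_len)]

    truth: list[TruthRecord] = []
    for (name, kind, length, pairs), s0 in zip(plans, starts):
        strand = "+" if rng.integers(0, 2) else "-"
        if kind in ("circular_cd", "noncirc_cd"):
            rna = build_cd_locus(rng, length, pairs)
        else:
            rna = _random_seq(rng, length)
        g[s0 : s0 + length] = list(rna if strand == "+" else reverse_complement(rna))
        start, end = s0 + 1, s0 + length
        rec = TruthRecord(
            locus_name=name,
            kind=kind,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            stem_pairs_designed=pairs,
            expected_junction=(start, end) if kind == "circular_cd" else None,
        )
        if kind == "rrna_like":
            gap0 = s0 + (length - cfg.rrna_gap_len) // 2
            rec.excluded_gap = (gap0 + 1, gap0 + cfg.rrna_gap_len)
        truth.append(rec)

    genome_seq = "".join(g)
    # enforce unique flanks for the junction-bearing loci
    for rec in truth:
        if rec.kind != "circular_cd":
            continue
        for attempt in range(20):
            rna = _locus_rna(Genome((GenomeRecord(chrom, genome_seq),)), rec)
            if _kmers_unique(genome_seq, rna, cfg.min_segment_len):
                break
            new_rna = build_cd_locus(rng, rec.length, rec.stem_pairs_designed)
            ins = new_rna if rec.strand == "+" else reverse_complement(new_rna)
            genome_seq = genome_seq[: rec.start - 1] + ins + genome_seq[rec.end :]
        else:
            raise ValueError("could not make locus flanks unique; increase genome_len")

    return Genome((GenomeRecord(chrom, genome_seq),)), truth


def _rotation_read(rna: str, first_arm: int, read_len: int) -> str:
    """A junction-spanning read: the circle's 3' end fused to its 5' start."""
    return rna[len(rna) - first_arm :] + rna[: read_len - first_arm]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    genome: Genome, truth: list[TruthRecord], cfg: SimConfig, sample: str
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Draw one sample's reads plus a per-read provenance table.

    Each locus gets unit abundance weight; a circular locus splits its weight
    into junction-spanning reads (fraction ``junction_read_fraction``, with
    both arms >= min_segment_len) and contiguous reads.  In the KO sample the
    junction-read weight of circular loci is multiplied by ``ko_circ_ratio``;
    everything else is untouched.
    """
    cfg.validate()
    sample = sample.upper()
    if sample not in ("WT", "KO"):
        raise ValueError("sample must be 'WT' or 'KO'")
    sample_idx = 0 if sample == "WT" else 1
    rng = np.random.default_rng([cfg.seed, sample_idx])
    # separate stream: turning errors on does not move the sampled positions
    err_rng = np.random.default_rng([cfg.seed, sample_idx, 7])
    jf = cfg.junction_read_fraction
    circ_scale = cfg.ko_circ_ratio if sample == "KO" else 1.0

    categories: list[tuple[TruthRecord, bool, float]] = []  # (locus, junction?, weight)
    for rec in truth:
        if rec.kind == "circular_cd":
            categories.append((rec, False, 1.0 - jf))
            categories.append((rec, True, jf * circ_scale))
        else:
            categories.append((rec, False, 1.0))

    weights = np.array([w for _, _, w in categories], dtype=float)
    reads: list[SequenceRead] = []
    prov_rows = []
    if cfg.n_reads_per_sample > 0 and weights.sum() > 0:
        counts = rng.multinomial(cfg.n_reads_per_sample, weights / weights.sum())
    else:
        counts = np.zeros(len(categories), dtype=int)

    idx = 0
    L_read = cfg.read_len
    for (rec, is_junction, _), cnt in zip(categories, counts):
        if cnt == 0:
            continue
        rna = _locus_rna(genome, rec)
        if is_junction:
            arms = rng.integers(
                cfg.min_segment_len, L_read - cfg.min_segment_len + 1, size=cnt
            )
            seqs = (_rotation_read(rna, int(a), L_read) for a in arms)
        else:
            n_pos = len(rna) - L_read + 1
            if rec.kind == "rrna_like" and rec.excluded_gap is not None:
                if rec.strand == "+":
                    rel = (rec.excluded_gap[0] - rec.start, rec.excluded_gap[1] - rec.start)
                else:
                    rel = (rec.end - rec.excluded_gap[1], rec.end - rec.excluded_gap[0])
                allowed = np.array(
                    [s for s in range(n_pos) if s + L_read - 1 < rel[0] or s > rel[1]]
                )
                starts = rng.choice(allowed, size=cnt)
            else:
                starts = rng.integers(0, n_pos, size=cnt)
            seqs = (rna[int(s) : int(s) + L_read] for s in starts)
        for seq in seqs:
            read_id = f"{sample}_{idx:07d}"
            idx += 1
            reads.append(SequenceRead(read_id, _apply_errors(err_rng, seq, cfg.error_rate)))
            prov_rows.append(
                {"read_id": read_id, "locus_name": rec.locus_name, "spans_junction": is_junction}
            )
    provenance = pd.DataFrame(
        prov_rows, columns=["read_id", "locus_name", "spans_junction"]
    )
    return reads, provenance


TRUTH_COLUMNS = [
    "locus_name",
    "kind",
    "chrom",
    "start",
    "end",
    "strand",
    "stem_pairs_designed",
    "junction_start",
    "junction_end",
    "gap_start",
    "gap_end",
]


def truth_to_frame(truth: Iterable[TruthRecord]) -> pd.DataFrame:
    rows = []
    for r in truth:
        js, je = r.expected_junction or ("", "")
        gs, ge = r.excluded_gap or ("", "")
        rows.append(
            {
                "locus_name": r.locus_name,
                "kind": r.kind,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "stem_pairs_designed": r.stem_pairs_designed,
                "junction_start": js,
                "junction_end": je,
                "gap_start": gs,
                "gap_end": ge,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def emit_truth(truth: Iterable[TruthRecord], path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        junction = (
            (int(row["junction_start"]), int(row["junction_end"]))
            if str(row["junction_start"]) != ""
            else None
        )
        gap = (
            (int(row["gap_start"]), int(row["gap_end"]))
            if str(row["gap_start"]) != ""
            else None
        )
        out.append(
            TruthRecord(
                locus_name=str(row["locus_name"]),
                kind=str(row["kind"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                stem_pairs_designed=int(row["stem_pairs_designed"]),
                expected_junction=junction,
                excluded_gap=gap,
            )
        )
    return out
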