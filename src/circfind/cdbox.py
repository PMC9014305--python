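"""C/D box sRNA annotation and terminal-stem circularizability.

Archaeal C/D box sRNAs carry a C box (consensus RUGAUGA, R = A/G) near the 5'
end and a D box (consensus CUGA) near the 3' end, with internal C'/D' copies,
and their termini can hybridize into a short stem that brings the two ends
into proximity for intramolecular ligation.  This module scans for the box
consensus motifs, assigns boxes positionally (5' third / 3' third / internal),
and scores the terminal stem as the gapless run of complementary pairs from
the outermost positions inward.  Three or more pairings call a locus
circularizable; two or fewer call it unlikely to circularize.

The stem score is deliberately not a thermodynamic fold: it is an integer
pairing count over a fixed terminal window, which is what the dichotomy it
feeds (>=3 vs <=2 pairings) is defined on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .config import AnalysisConfig
from .io import Genome, normalize_sequence

C_BOX_RE = re.compile(r"(?=([AG]TGATGA))")
D_BOX_RE = re.compile(r"(?=(CTGA))")

C_BOX_LEN = 7
D_BOX_LEN = 4

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class MotifHit:
    motif_class: str  # C_box | D_box
    position: int  # 1-based offset in the scanned sequence
    matched: str


@dataclass(frozen=True)
class CDBoxAnnotation:
    locus_name: str
    is_cdbox: bool
    c_box: Optional[MotifHit] = None
    d_box: Optional[MotifHit] = None
    c_prime: Optional[MotifHit] = None
    d_prime: Optional[MotifHit] = None


@dataclass(frozen=True)
class StemReport:
    locus_name: str
    stem_pairs: int
    window: int
    circularizable: bool


def scan_cdbox_motifs(sequence: str) -> list[MotifHit]:
    """All C box (RUGAUGA) and D box (CUGA) matches, overlaps allowed.

    Input may be RNA or DNA in either case; positions are 1-based.
    """
    seq = normalize_sequence(sequence)
    hits = [
        MotifHit("C_box", m.start() + 1, m.group(1)) for m in C_BOX_RE.finditer(seq)
    ] + [
        MotifHit("D_box", m.start() + 1, m.group(1)) for m in D_BOX_RE.finditer(seq)
    ]
    hits.sort(key=lambda h: (h.position, h.motif_class))
    return hits


def _pairs(count_gu: bool) -> set:
    return _WC_PAIRS | _WOBBLE_PAIRS if count_gu else set(_WC_PAIRS)


def terminal_stem_pairs(sequence: str, window: int = 8, count_gu: bool = True) -> int:
    """Gapless outermost-in pairing count between the two termini.

    The 5'-terminal ``window`` is aligned against the reversed 3'-terminal
    window (base 1 vs last base, base 2 vs second-to-last, ...) and
    consecutive complementary pairs are counted from the outside in, stopping
    at the first non-pair.  Watson-Crick pairs always count; G:U wobble pairs
    count when ``count_gu`` is true.
    """
    seq = normalize_sequence(sequence)
    if len(seq) < 2 * window:
        raise ValueError(f"sequence length {len(seq)} < 2 x window ({window})")
    pairs = _pairs(count_gu)
    n = len(seq)
    count = 0
    for i in range(window):
        if (seq[i], seq[n - 1 - i]) in pairs:
            count += 1
        else:
            break
    return count


def classify_circularizable(stem_pairs: int, cfg: AnalysisConfig) -> bool:
    """Three or more terminal pairings (by default) predict circularizability."""
    return stem_pairs >= cfg.min_stem_pairs_circular


def annotate_sequence(locus_name: str, sequence: str) -> CDBoxAnnotation:
    """Positional C/D box annotation of one locus sequence.

    A locus is called a C/D box sRNA when a C box starts within the 5' third
    of the sequence and a D box starts within the 3' third.  The first
    internal C-consensus match becomes C', the first internal D-consensus
    match becomes D'.
    """
    seq = normalize_sequence(sequence)
    n = len(seq)
    hits = scan_cdbox_motifs(seq)
    c_box = d_box = c_prime = d_prime = None
    for h in hits:
        start0 = h.position - 1
        if h.motif_class == "C_box":
            if start0 < n / 3:
                if c_box is None:
                    c_box = h
            elif c_prime is None:
                c_prime = h
        else:
            if start0 >= 2 * n / 3:
                if d_box is None:
                    d_box = h
            elif d_prime is None:
                d_prime = h
    return CDBoxAnnotation(
        locus_name=locus_name,
        is_cdbox=c_box is not None and d_box is not None,
        c_box=c_box,
        d_box=d_box,
        c_prime=c_prime,
        d_prime=d_prime,
    )


def locus_sequence(candidate, genome: Genome) -> str:
    """Strand-aware sequence of a candidate's junction interval."""
    from .io import reverse_complement

    seq = genome.fetch(candidate.chrom, candidate.circ_start, candidate.circ_end)
    return reverse_complement(seq) if candidate.strand == "-" else seq


def annotate_locus(candidate, genome: Genome) -> CDBoxAnnotation:
    """C/D box annotation of a circRNA candidate against its genome."""
    return annotate_sequence(candidate.locus_name, locus_sequence(candidate, genome))


def stem_report(candidate, genome: Genome, cfg: AnalysisConfig) -> StemReport:
    seq = locus_sequence(candidate, genome)
    pairs = terminal_stem_pairs(seq, window=cfg.stem_window, count_gu=cfg.count_gu_wobble)
    return StemReport(
        locus_name=candidate.locus_name,
        stem_pairs=pairs,
        window=cfg.stem_window,
        circularizable=classify_circularizable(pairs, cfg),
    )


def annotate_candidates(
    candidates: Iterable, genome: Genome, cfg: AnalysisConfig
) -> dict[str, tuple[str, int]]:
    """Per-locus (cdbox_call, stem_pairs) map for candidate report columns."""
    out = {}
    for cand in candidates:
        ann = annotate_locus(cand, genome)
        rep = stem_report(cand, genome, cfg)
        out[cand.locus_name] = ("CD_box" if ann.is_cdbox else "none", rep.stem_pairs)
    return out
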