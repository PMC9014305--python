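"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's k-mer index: all matching is done with
plain ``str.find`` scans, and motif scanning with a character-by-character
loop, so they share no code path with what they verify.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_locate_forward(seqs, query):
    """All forward occurrences of query in (name, seq) records via str.find."""
    if not query or "N" in query:
        return []
    out = []
    for ci, (_, s) in enumerate(seqs):
        i = s.find(query)
        while i != -1:
            out.append((ci, i))
            i = s.find(query, i + 1)
    return out


def oracle_find_junctions(seqs, read_seq, min_seg):
    """Brute-force split x scan enumeration of circular junctions.

    Returns a list of (chrom_name, strand, circ_start, circ_end) tuples under
    the same contract as the detector: per-split both-parts-ambiguous
    discard, strictly-downstream inverse order, contiguous-placement veto,
    per-read dedup of identical junctions.
    """
    n = len(read_seq)
    if n < 2 * min_seg:
        return []
    rcr = rc(read_seq)
    if naive_locate_forward(seqs, read_seq) or naive_locate_forward(seqs, rcr):
        return []
    out = []
    seen = set()
    for strand, oriented in (("+", read_seq), ("-", rcr)):
        for split in range(min_seg, n - min_seg + 1):
            p1 = naive_locate_forward(seqs, oriented[:split])
            p2 = naive_locate_forward(seqs, oriented[split:])
            if not p1 or not p2:
                continue
            if len(p1) > 1 and len(p2) > 1:
                continue
            for c1, i1 in p1:
                a1, b1 = i1 + 1, i1 + split
                for c2, i2 in p2:
                    if c1 != c2:
                        continue
                    a2, b2 = i2 + 1, i2 + (n - split)
                    if a1 <= b2:
                        continue
                    key = (seqs[c1][0], strand, a2, b1)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(key)
    return out


def oracle_scan_motifs(seq):
    """Character-loop motif scan: C box RUGAUGA (R=A/G), D box CUGA."""
    s = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(s)):
        if s[i : i + 7] in ("ATGATGA", "GTGATGA"):
            hits.append(("C_box", i + 1, s[i : i + 7]))
        if s[i : i + 4] == "CTGA":
            hits.append(("D_box", i + 1, s[i : i + 4]))
    return sorted(hits, key=lambda h: (h[1], h[0]))
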