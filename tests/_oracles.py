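"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own machinery: the local-alignment
oracle runs Biopython's PairwiseAligner (the implementation uses its own DP),
and the TSD/tandem/context oracles are plain exhaustive loops.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def _aligner() -> Align.PairwiseAligner:
    mat = substitution_matrices.Array("ACGTN#", dims=2)
    for a in "ACGTN#":
        for b in "ACGTN#":
            if a in "ACGT" and b in "ACGT":
                mat[a, b] = 1 if a == b else -2
            elif a == "#" or b == "#":
                mat[a, b] = -100000
            else:
                mat[a, b] = -2
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = mat
    al.open_gap_score = -7   # gap of length L costs -5 - 2L
    al.extend_gap_score = -2
    return al


def exhaustive_local_hits(query, records, min_id, min_len):
    """All qualifying local alignments on both strands, by iterated optimal
    Smith-Waterman with masking.  Returns (contig, start, end, strand,
    identity, aln_len) tuples sorted by locus."""
    import math

    al = _aligner()
    min_score = max(1, math.ceil(min_len * (min_id * 1 + (1 - min_id) * -2)))
    hits = []
    for rec in records:
        for strand in "+-":
            q = query if strand == "+" else rc(query)
            subject = list(rec.seq)
            for _ in range(100):
                alns = al.align("".join(subject), q)
                if alns.score < min_score:
                    break
                a = alns[0]
                t0, t1 = int(a.coordinates[0][0]), int(a.coordinates[0][-1])
                rows = (str(a[0]), str(a[1]))
                cols = len(rows[0])
                matches = sum(
                    1 for x, y in zip(*rows) if x == y and x in "ACGT"
                )
                if cols >= min_len and matches / cols >= min_id:
                    hits.append(
                        (rec.id, t0, t1, strand, matches / cols, cols)
                    )
                for j in range(t0, t1):
                    subject[j] = "#"
    hits.sort(key=lambda h: (h[0], h[1], h[2], h[3]))
    return hits


def brute_tsd(up: str, down: str, max_len: int = 20, min_len: int = 5):
    """All (length, mismatches) candidates; longest first, then fewest
    mismatches.  Returns (length, mismatches) or None."""
    cands = []
    for length in range(min_len, max_len + 1):
        mm = sum(
            1
            for a, b in zip(up[-length:], down[:length])
            if a != b or a not in "ACGT"
        )
        if mm <= 1:
            cands.append((length, mm))
    if not cands:
        return None
    return max(cands, key=lambda c: (c[0], -c[1]))


def brute_tandem(seq: str, window: int = 60, min_units: int = 3,
                 min_purity: float = 0.8, end_slack: int = 5, max_unit: int = 6,
                 min_run_bp: int = 10):
    """Exhaustive (unit, phase, extent) tandem search; returns the canonical
    primitive unit of the best run or None.  Key: (full-unit run length,
    purity, primitive-unit length); a run must open with two exact unit
    copies and span at least ``min_run_bp``."""
    tail = seq[-window:]
    L = len(tail)
    cands = []
    for ulen in range(1, max_unit + 1):
        for start in range(L):
            unit = tail[start : start + ulen]
            if len(unit) < ulen or "N" in unit:
                continue
            if tail[start + ulen : start + 2 * ulen] != unit:
                continue
            for n in range(min_units, (L - start) // ulen + 1):
                run = n * ulen
                if run < min_run_bp:
                    continue
                if L - (start + run) > end_slack:
                    continue
                m = sum(1 for i in range(run) if tail[start + i] == unit[i % ulen])
                purity = m / run
                if purity < min_purity:
                    continue
                prim = unit
                for d in range(1, ulen):
                    if ulen % d == 0 and unit == unit[:d] * (ulen // d):
                        prim = unit[:d]
                        break
                canon = min(prim[i:] + prim[:i] for i in range(len(prim)))
                cands.append(((run, purity, len(prim)), canon))
    if not cands:
        return None
    return max(cands, key=lambda c: c[0])[1]


_PREC = {
    "CDS": 0, "UTR5": 1, "UTR3": 1, "exon_nc": 2, "intron": 3,
    "downstream_5k": 4, "upstream_5k": 5,
}


def brute_context(midpoint: int, contig: str, genes, downstream_bp: int = 5000):
    """Enumerate every feature of every gene overlapping the midpoint and
    apply the precedence list; returns (category, gene_id)."""
    cands = []
    for g in genes:
        if g.contig != contig:
            continue
        feats = [("CDS", iv) for iv in g.cds]
        feats += [("UTR5", iv) for iv in g.utr5]
        feats += [("UTR3", iv) for iv in g.utr3]
        feats += [("intron", iv) for iv in g.introns]
        # exonic-minus-classified
        classified = sorted(list(g.cds) + list(g.utr5) + list(g.utr3))
        for es, ee in g.exons:
            cur = es
            for cs, ce in classified:
                if ce <= es or cs >= ee:
                    continue
                if cur < cs:
                    feats.append(("exon_nc", (cur, cs)))
                cur = max(cur, ce)
            if cur < ee:
                feats.append(("exon_nc", (cur, ee)))
        s, e = g.span
        if g.strand == "+":
            feats.append(("downstream_5k", (e, e + downstream_bp)))
            feats.append(("upstream_5k", (max(0, s - downstream_bp), s)))
        else:
            feats.append(("downstream_5k", (max(0, s - downstream_bp), s)))
            feats.append(("upstream_5k", (e, e + downstream_bp)))
        for cat, (fs, fe) in feats:
            if fs <= midpoint < fe:
                cands.append((_PREC[cat], g.gene_id, cat))
    if not cands:
        return ("intergenic", None)
    p, gid, cat = min(cands)
    return (cat, gid)
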