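"""Seeded local-alignment search for genomic copies of a query element.

The search is k-mer seeding (two hits on the same diagonal band) followed by
full affine-gap local alignment inside a small candidate window, iterated with
masking so that tandem copies sharing a window are all recovered.  Three
threshold regimes are applied downstream of the same machinery:

* discovery: >=70% identity over >=50 aligned columns;
* copy counting: >=80% identity over >=100 columns, with head-only copies
  falling entirely inside an ambiguous query region excluded;
* divergence set: >=80% identity over >=80% of the consensus length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import encode, local_align, revcomp
from .core_io import GenomeRecord, RunConfig


@dataclass
class SearchParams:
    """Scoring and seeding knobs of the aligner (the paper's external search
    tool is replaced by this self-contained implementation)."""

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: int = 20
    band: int = 25          # max diagonal spread for the two-hit rule
    window_pad: int = 60    # genomic padding around a seed cluster
    max_hits_per_window: int = 50

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")


@dataclass
class AlignmentHit:
    """One local alignment of the query on a genomic contig.

    ``start``/``end`` are plus-strand 0-based half-open genomic coordinates
    whatever the strand; ``qstart``/``qend`` are on the query as given.  The
    gapped rows (query orientation) are kept so that downstream identity and
    divergence reuse this alignment without realigning.
    """

    contig: str
    start: int
    end: int
    strand: str
    identity: float
    aln_len: int
    qcov: float
    qstart: int
    qend: int
    matches: int = 0
    q_aln: str = ""
    s_aln: str = ""
    family_id: str | None = None

    @property
    def seq(self) -> str:
        """Ungapped genomic sequence oriented to match the query."""
        return self.s_aln.replace("-", "")


def _kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, hashes) of all N-free k-mers of ``seq``."""
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        window = codes[t : t + n]
        h = h * 4 + np.where(window < 4, window, 0)
        bad |= window >= 4
    pos = np.nonzero(~bad)[0]
    return pos, h[pos]


def _candidate_windows(
    query: str, contig_seq: str, params: SearchParams
) -> list[tuple[int, int]]:
    """Merged genomic windows holding >=2 query seeds on one diagonal band."""
    k = params.word_size
    qpos, qhash = _kmer_hashes(query, k)
    if len(qpos) == 0:
        return []
    index: dict[int, list[int]] = {}
    for p, h in zip(qpos.tolist(), qhash.tolist()):
        index.setdefault(h, []).append(p)
    gpos, ghash = _kmer_hashes(contig_seq, k)
    mask = np.isin(ghash, qhash)
    seeds: list[tuple[int, int]] = []  # (genome pos, diagonal)
    for g, h in zip(gpos[mask].tolist(), ghash[mask].tolist()):
        for qp in index[h]:
            seeds.append((g, g - qp))
    if not seeds:
        return []
    seeds.sort()
    qlen = len(query)
    clusters: list[list[tuple[int, int]]] = []
    for seed in seeds:
        if clusters and seed[0] - clusters[-1][-1][0] <= qlen:
            clusters[-1].append(seed)
        else:
            clusters.append([seed])
    windows = []
    for cluster in clusters:
        diags = sorted(d for _, d in cluster)
        two_hit = any(
            d2 - d1 <= params.band for d1, d2 in zip(diags, diags[1:])
        ) and len(cluster) >= 2
        if not two_hit:
            continue
        lo = min(d for _, d in cluster) - params.window_pad
        hi = max(d for _, d in cluster) + qlen + params.window_pad
        windows.append((max(0, lo), min(len(contig_seq), hi)))
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def seed_and_extend_search(
    query: str,
    genome: list[GenomeRecord],
    params: SearchParams | None = None,
    min_id: float = 0.70,
    min_len: int = 50,
) -> list[AlignmentHit]:
    """All local alignments of ``query`` on either strand passing the
    identity/length thresholds, sorted by (contig, start)."""
    params = params or SearchParams()
    query = query.upper()
    if len(query) < params.word_size:
        raise ValueError(
            f"query ({len(query)} bp) shorter than word size {params.word_size}"
        )
    qlen = len(query)
    min_score = int(np.ceil(min_len * (min_id * params.match + (1 - min_id) * params.mismatch)))
    min_score = max(min_score, 1)
    hits: list[AlignmentHit] = []
    for record in genome:
        for strand in "+-":
            oriented = query if strand == "+" else revcomp(query)
            for wlo, whi in _candidate_windows(oriented, record.seq, params):
                window = list(record.seq[wlo:whi])
                for _ in range(params.max_hits_per_window):
                    aln = local_align(
                        oriented, "".join(window),
                        match=params.match, mismatch=params.mismatch,
                        gap_open=params.gap_open, gap_extend=params.gap_extend,
                    )
                    if aln is None or aln.score < min_score:
                        break
                    cols = len(aln.q_aln)
                    ident = _aln_identity(aln.q_aln, aln.s_aln)
                    if cols >= min_len and ident >= min_id:
                        hits.append(
                            _to_hit(aln, record.id, wlo, strand, qlen)
                        )
                    for j in range(aln.sstart, aln.send):
                        window[j] = "#"
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.strand))
    # drop exact duplicates that merged windows may produce
    out: list[AlignmentHit] = []
    seen = set()
    for h in hits:
        key = (h.contig, h.start, h.end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def _aln_identity(q_aln: str, s_aln: str) -> float:
    matches = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a in "ACGT")
    return matches / len(q_aln) if q_aln else 0.0


def _to_hit(aln, contig: str, wlo: int, strand: str, qlen: int) -> AlignmentHit:
    start = wlo + aln.sstart
    end = wlo + aln.send
    if strand == "+":
        qstart, qend = aln.qstart, aln.qend
        q_aln, s_aln = aln.q_aln, aln.s_aln
    else:
        # alignment used revcomp(query); store rows in original query
        # orientation so downstream consensus/divergence can mix strands
        qstart, qend = qlen - aln.qend, qlen - aln.qstart
        q_aln, s_aln = revcomp(aln.q_aln), revcomp(aln.s_aln)
    cols = len(q_aln)
    matches = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a in "ACGT")
    return AlignmentHit(
        contig=contig, start=start, end=end, strand=strand,
        identity=matches / cols, aln_len=cols, qcov=(qend - qstart) / qlen,
        qstart=qstart, qend=qend, matches=matches, q_aln=q_aln, s_aln=s_aln,
    )


def merge_overlapping_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Greedy non-redundancy: same-strand hits overlapping by more than half
    of the shorter one keep only the higher-identity hit (ties: longer
    alignment, then lower start)."""
    ordered = sorted(
        hits, key=lambda h: (-h.identity, -h.aln_len, h.contig, h.start)
    )
    kept: list[AlignmentHit] = []
    for h in ordered:
        redundant = False
        for k in kept:
            if k.contig != h.contig or k.strand != h.strand:
                continue
            ov = min(h.end, k.end) - max(h.start, k.start)
            shorter = min(h.end - h.start, k.end - k.start)
            if shorter > 0 and ov > 0.5 * shorter:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start))
    return kept


def count_copies(
    consensus: str,
    genome: list[GenomeRecord],
    params: SearchParams | None = None,
    ambiguous_region: tuple[int, int] | None = None,
    config: RunConfig | None = None,
) -> tuple[list[AlignmentHit], int]:
    """Copy-number estimate: hits at >=80% identity over >=100 bp, merged to
    one per locus; hits aligning only within ``ambiguous_region`` of the
    consensus (a head shared between families) are excluded."""
    cfg = config or RunConfig()
    if len(consensus) < cfg.copy_len:
        raise ValueError("consensus shorter than the copy-length threshold")
    raw = seed_and_extend_search(
        consensus, genome, params, min_id=cfg.copy_id, min_len=cfg.copy_len
    )
    merged = merge_overlapping_hits(raw)
    if ambiguous_region is not None:
        alo, ahi = ambiguous_region
        merged = [
            h for h in merged if not (h.qstart >= alo and h.qend <= ahi)
        ]
    return merged, len(merged)


def select_divergence_set(
    consensus: str,
    copies: list[AlignmentHit],
    config: RunConfig | None = None,
) -> list[AlignmentHit]:
    """Copies at >=80% identity covering >=80% of the consensus length."""
    cfg = config or RunConfig()
    return [
        h for h in copies if h.identity >= cfg.div_id and h.qcov >= cfg.div_lenfrac
    ]
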