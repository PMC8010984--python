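"""Family consensus reconstruction and boundary/TSD inference.

Copies of a family are aligned with a center-star multiple alignment (the
center is the copy maximizing summed pairwise identity) and collapsed to a
majority-rule consensus.  Element boundaries are refined by aligning a filled
locus (element plus flanks) against its empty insertion site; the segment of
the empty site covered by both flank alignments is the target-site duplication
(TSD) created at integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import global_align, identity, local_align


@dataclass
class CopyAlignment:
    """Center-star MSA of a family's copies (rows over ``ACGT-``)."""

    family_id: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least two members")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class ConsensusModel:
    family_id: str
    seq: str
    support: list[float]
    n_members: int


@dataclass
class TSDReport:
    left: str
    right: str
    length: int
    mismatches: int


@dataclass
class EmptySiteRefinement:
    """Outcome of aligning a filled locus to its empty site."""

    status: str                      # "refined" | "no_insertion" | "no_orthologous_site"
    element: tuple[int, int] | None  # on the filled locus, 0-based half-open
    tsd: TSDReport | None


def build_msa_center_star(
    seqs: list[str],
    ids: list[str] | None = None,
    family_id: str = "family",
) -> CopyAlignment:
    """Center-star MSA: align every copy to the center pairwise and merge the
    gap patterns into one coordinate frame.

    The center maximizes summed pairwise identity; ties resolve to the
    lexicographically smallest id so the result is independent of input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if ids is None:
        ids = [f"copy{i + 1}" for i in range(len(seqs))]
    seqs = [s.upper() for s in seqs]
    n = len(seqs)
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = global_align(seqs[i], seqs[j])
            ident = identity(a, b)
            sums[i] += ident
            sums[j] += ident
    order = sorted(range(n), key=lambda i: (-sums[i], ids[i]))
    c = order[0]
    center = seqs[c]
    pairs = []  # (index, center_gapped, seq_gapped)
    for i in range(n):
        if i == c:
            continue
        ca, sa = global_align(center, seqs[i])
        pairs.append((i, ca, sa))

    # insertion length needed before each center position (and at the end)
    ins = np.zeros(len(center) + 1, dtype=int)
    for _, ca, _ in pairs:
        p = 0
        run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                ins[p] = max(ins[p], run)
                run = 0
                p += 1
        ins[len(center)] = max(ins[len(center)], run)

    def pad_center() -> str:
        out = []
        for p, base in enumerate(center):
            out.append("-" * ins[p])
            out.append(base)
        out.append("-" * ins[len(center)])
        return "".join(out)

    def pad_pair(ca: str, sa: str) -> str:
        out = []
        p = 0
        buffer = []  # sequence chars aligned to center gaps before position p
        for cch, sch in zip(ca, sa):
            if cch == "-":
                buffer.append(sch)
            else:
                pad = ins[p] - len(buffer)
                out.append("-" * pad)
                out.extend(buffer)
                out.append(sch)
                buffer = []
                p += 1
        pad = ins[len(center)] - len(buffer)
        out.extend(buffer)
        out.append("-" * pad)
        return "".join(out)

    rows: dict[int, str] = {c: pad_center()}
    for i, ca, sa in pairs:
        rows[i] = pad_pair(ca, sa)
    ordered_ids = [ids[i] for i in range(n)]
    return CopyAlignment(family_id, ordered_ids, [rows[i] for i in range(n)])


def majority_consensus(aln: CopyAlignment) -> ConsensusModel:
    """Majority-rule collapse: columns with >50% gaps are dropped; base ties
    break in the fixed order A<C<G<T; N does not vote."""
    mat = np.array([list(r) for r in aln.rows])
    n = mat.shape[0]
    seq: list[str] = []
    support: list[float] = []
    for col in mat.T:
        gaps = np.count_nonzero((col == "-") | (col == "N"))
        if gaps * 2 > n:
            continue
        counts = [(np.count_nonzero(col == b), b) for b in "ACGT"]
        best = max(counts, key=lambda t: (t[0], -ord(t[1])))
        seq.append(best[1])
        support.append(best[0] / n)
    return ConsensusModel(aln.family_id, "".join(seq), support, n)


def detect_tsd(
    upstream_flank: str,
    downstream_flank: str,
    max_len: int = 20,
    min_len: int = 5,
) -> TSDReport | None:
    """Longest suffix of the upstream flank matching a prefix of the
    downstream flank with at most one mismatch, length within [min_len,
    max_len]; among equal lengths fewer mismatches wins."""
    up = upstream_flank.upper()
    down = downstream_flank.upper()
    if len(up) < max_len or len(down) < max_len:
        raise ValueError("flanks must be at least max_len long")
    best: TSDReport | None = None
    for length in range(max_len, min_len - 1, -1):
        left = up[-length:]
        right = down[:length]
        mism = sum(
            1 for a, b in zip(left, right) if a != b or a not in "ACGT"
        )
        if mism <= 1:
            cand = TSDReport(left, right, length, mism)
            if best is None or (cand.length, -cand.mismatches) > (best.length, -best.mismatches):
                best = cand
            break  # lengths iterate downward: first admissible is the longest
    return best


def _trim_to_match_run(aln, min_run: int = 4):
    """Trim alignment ends until both terminate in ``min_run`` consecutive
    exact matches.  Chance extensions past an insertion junction end ragged
    (a mismatch propped up by a few downstream matches) and are cut back to
    the last solid anchor; genuine junction-flush alignments are untouched."""
    from ._align import LocalAlignment

    cols = [
        (q, s, q == s and q in "ACGT")
        for q, s in zip(aln.q_aln, aln.s_aln)
    ]

    def ok_tail(cs):
        return len(cs) >= min_run and all(m for _, _, m in cs[-min_run:])

    def ok_head(cs):
        return len(cs) >= min_run and all(m for _, _, m in cs[:min_run])

    qend, send = aln.qend, aln.send
    while cols and not ok_tail(cols):
        q, s, _ = cols.pop()
        if q != "-":
            qend -= 1
        if s != "-":
            send -= 1
    qstart, sstart = aln.qstart, aln.sstart
    while cols and not ok_head(cols):
        q, s, _ = cols.pop(0)
        if q != "-":
            qstart += 1
        if s != "-":
            sstart += 1
    if not cols:
        return None
    return LocalAlignment(
        score=aln.score, qstart=qstart, qend=qend, sstart=sstart, send=send,
        q_aln="".join(c[0] for c in cols), s_aln="".join(c[1] for c in cols),
    )


def refine_boundaries_empty_site(
    filled_locus: str,
    empty_site: str,
    min_flank_identity: float = 0.70,
    min_flank_len: int = 50,
    min_tsd: int = 5,
) -> EmptySiteRefinement:
    """Align both flanks of a filled locus to the orthologous empty site.

    The two best local alignments of filled-vs-empty correspond to the left
    and right flanks.  Element boundaries are the innermost filled positions
    where the flank alignments end; if the two alignments overlap on the
    empty site by >= ``min_tsd`` bp, the duplicated segment is reported as the
    TSD.
    """
    filled = filled_locus.upper()
    empty = empty_site.upper()
    def _bad(aln) -> bool:
        return (
            aln is None
            or aln.send - aln.sstart < min_flank_len
            or identity(aln.q_aln, aln.s_aln) < min_flank_identity
        )

    first = local_align(empty, filled)
    if first is not None:
        first = _trim_to_match_run(first)
    if _bad(first):
        return EmptySiteRefinement("no_orthologous_site", None, None)
    # no insertion: a single alignment explains (almost) the whole locus
    if first.send - first.sstart >= len(filled) - 10:
        return EmptySiteRefinement("no_insertion", (first.send, first.send), None)
    masked = filled[: first.sstart] + "#" * (first.send - first.sstart) + filled[first.send:]
    second = local_align(empty, masked)
    if second is not None:
        second = _trim_to_match_run(second)
    if _bad(second):
        return EmptySiteRefinement("no_orthologous_site", None, None)
    left, right = sorted([first, second], key=lambda a: a.sstart)
    element = (left.send, right.sstart)
    tsd = None
    ov_lo = max(left.qstart, right.qstart)
    ov_hi = min(left.qend, right.qend)
    if ov_hi - ov_lo >= min_tsd:
        dup = empty[ov_lo:ov_hi]
        # the two copies on the filled locus
        left_copy = filled[left.send - len(dup): left.send]
        right_copy = filled[right.sstart: right.sstart + len(dup)]
        mism = sum(1 for a, b in zip(left_copy, right_copy) if a != b)
        tsd = TSDReport(left_copy, right_copy, len(dup), mism)
    return EmptySiteRefinement("refined", element, tsd)


def reconstruction_set(copies, min_qcov: float = 0.9):
    """Near-full-length copies used to rebuild the consensus."""
    return [c for c in copies if c.qcov >= min_qcov]
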