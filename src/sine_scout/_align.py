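"""Low-level pairwise alignment machinery shared across the pipeline.

Two routes live here:

* :func:`local_align` — an affine-gap (Gotoh) Smith–Waterman written against
  numpy, vectorized along the query axis.  This is the workhorse of the
  seed-and-extend genome search, where it is only ever run on small candidate
  windows.  A gap of length ``L`` costs ``gap_open + L * gap_extend``.
* :func:`global_align` — Needleman–Wunsch through ``Bio.Align.PairwiseAligner``
  with the same residue scoring, used for the ordinary pairwise-alignment
  plumbing (consensus building, distance computation, head classification).

``N`` never scores as a match anywhere; masked positions (``#``) are scored so
harshly that no optimal local alignment crosses them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

DNA_ALPHABET = "ACGTN#"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> code lookup: A,C,G,T -> 0..3, N -> 4, mask '#' -> 5
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("#")] = 5

MASK_PENALTY = -10_000


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGTN symbols pass through the N rule upstream."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class LocalAlignment:
    """One local alignment of query against subject (0-based half-open)."""

    score: int
    qstart: int
    qend: int
    sstart: int
    send: int
    q_aln: str
    s_aln: str


def _substitution_row(q_codes: np.ndarray, s_code: int, match: int, mismatch: int) -> np.ndarray:
    if s_code >= 5:
        return np.full(q_codes.shape, MASK_PENALTY, dtype=np.int32)
    sub = np.where((q_codes == s_code) & (q_codes < 4), match, mismatch).astype(np.int32)
    sub[q_codes == 5] = MASK_PENALTY
    return sub


def local_align(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> LocalAlignment | None:
    """Best-scoring Smith–Waterman alignment with affine gaps (Gotoh).

    The DP is row-wise over the subject with numpy vectorization over the
    query.  The within-row gap state E (gaps consuming query) is closed-form:
    ``E[i] = gap_open + gap_extend*i + max_{k<i}(H[k] - gap_extend*k)``,
    resolved with a prefix maximum; a second pass is never needed because
    re-opening a gap out of a gap state is always dominated by extending.

    Returns None when no positive-scoring alignment exists.
    """
    n, m = len(query), len(subject)
    if n == 0 or m == 0:
        return None
    q = encode(query)
    s = encode(subject)
    go, ge = gap_open, gap_extend
    NEG = np.int32(-(1 << 30))

    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)

    for j in range(1, m + 1):
        sub = _substitution_row(q, s[j - 1], match, mismatch)
        # F: gap consuming subject (vertical), depends on previous row only
        F[j, 1:] = np.maximum(H[j - 1, 1:] + go, F[j - 1, 1:]) + ge
        h1 = np.maximum(H[j - 1, :-1] + sub, F[j, 1:])
        h1 = np.maximum(h1, 0)
        row = np.empty(n + 1, dtype=np.int32)
        row[0] = 0
        row[1:] = h1
        # E via prefix max over the row computed so far
        prefix = np.maximum.accumulate(row - ge * idx)
        E[j, 1:] = go + ge * idx[1:] + prefix[:-1]
        H[j] = np.maximum(row, E[j])
        H[j, 0] = 0

    best = int(H.max())
    if best <= 0:
        return None
    j, i = np.unravel_index(int(H.argmax()), H.shape)
    return _traceback(query, subject, q, s, H, E, F, int(i), int(j), match, mismatch, go, ge)


def _traceback(query, subject, q, s, H, E, F, i, j, match, mismatch, go, ge) -> LocalAlignment:
    qa: list[str] = []
    sa: list[str] = []
    qend, send = i, j
    score = int(H[j, i])
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[j, i]
            if h == 0:
                break
            sc = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            if q[i - 1] == 5 or s[j - 1] >= 5:
                sc = MASK_PENALTY
            if h == H[j - 1, i - 1] + sc:
                qa.append(query[i - 1])
                sa.append(subject[j - 1])
                i -= 1
                j -= 1
            elif h == E[j, i]:
                state = "E"
            elif h == F[j, i]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "E":
            # gap consuming query: walk left until the opening H is found
            qa.append(query[i - 1])
            sa.append("-")
            if E[j, i] == H[j, i - 1] + go + ge:
                state = "H"
            i -= 1
        else:  # F: gap consuming subject
            qa.append("-")
            sa.append(subject[j - 1])
            if F[j, i] == H[j - 1, i] + go + ge:
                state = "H"
            j -= 1
    return LocalAlignment(
        score=score,
        qstart=i,
        qend=qend,
        sstart=j,
        send=send,
        q_aln="".join(reversed(qa)),
        s_aln="".join(reversed(sa)),
    )


@lru_cache(maxsize=16)
def _matrix(match: int, mismatch: int) -> substitution_matrices.Array:
    mat = substitution_matrices.Array(DNA_ALPHABET, dims=2)
    for a in DNA_ALPHABET:
        for b in DNA_ALPHABET:
            if a in "ACGT" and b in "ACGT":
                mat[a, b] = match if a == b else mismatch
            elif a == "#" or b == "#":
                mat[a, b] = MASK_PENALTY
            else:  # anything involving N is never a match
                mat[a, b] = mismatch
    return mat


@lru_cache(maxsize=32)
def _global_aligner(
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    free_target_ends: bool,
    free_query_ends: bool,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(match, mismatch)
    # our convention: gap of length L costs gap_open + L*gap_extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    if free_target_ends:
        aligner.open_left_insertion_score = 0
        aligner.extend_left_insertion_score = 0
        aligner.open_right_insertion_score = 0
        aligner.extend_right_insertion_score = 0
    if free_query_ends:
        aligner.open_left_deletion_score = 0
        aligner.extend_left_deletion_score = 0
        aligner.open_right_deletion_score = 0
        aligner.extend_right_deletion_score = 0
    return aligner


def global_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
    free_end_gaps: bool | str = True,
) -> tuple[str, str]:
    """Global alignment of ``a`` (target) vs ``b`` (query) as gapped strings.

    ``free_end_gaps`` may be True (semiglobal on both sequences — right for
    truncated element copies), False (strict global), or ``"target"`` to
    leave only the target's ends unpenalized (the query must align in full,
    e.g. a reference head against a consensus 5' region).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    # "insertion" end gaps sit in the target row, "deletion" end gaps in the
    # query row; a free target *overhang* therefore needs free query-row ends
    free_t = free_end_gaps is True
    free_q = free_end_gaps in (True, "target")
    aligner = _global_aligner(match, mismatch, gap_open, gap_extend, free_t, free_q)
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def alignment_stats(a_aln: str, b_aln: str, exclude_terminal: bool = True) -> tuple[int, int]:
    """(matches, columns) of a gapped pair.

    Internal gap columns count as mismatch columns; terminal gap columns are
    excluded when ``exclude_terminal``; N never matches.
    """
    if len(a_aln) != len(b_aln):
        raise ValueError("gapped rows differ in length")
    lo, hi = 0, len(a_aln)
    if exclude_terminal:
        while lo < hi and (a_aln[lo] == "-" or b_aln[lo] == "-"):
            lo += 1
        while hi > lo and (a_aln[hi - 1] == "-" or b_aln[hi - 1] == "-"):
            hi -= 1
    matches = 0
    cols = hi - lo
    for x, y in zip(a_aln[lo:hi], b_aln[lo:hi]):
        if x == y and x in "ACGT":
            matches += 1
    return matches, cols


def identity(a_aln: str, b_aln: str, exclude_terminal: bool = True) -> float:
    matches, cols = alignment_stats(a_aln, b_aln, exclude_terminal)
    if cols == 0:
        return 0.0
    return matches / cols
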