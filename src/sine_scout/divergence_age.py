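"""Copy-to-consensus divergence and relative-age profiling.

Divergence uses the Kimura two-parameter (K2P) model, which separates the
transition proportion P from the transversion proportion Q over the gap-free
compared sites (pairwise deletion):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Relative age profiles are histograms of integer copy-to-consensus percent
identities over the 80..100 range: a mode near 100 marks a recent
transpositional burst, a flat or low-identity profile an old family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._align import alignment_stats, global_align

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDivergenceError(ValueError):
    """The K2P log arguments left their domain: distance is saturated."""


class NoComparableSitesError(ValueError):
    """No gap-free, unambiguous columns to compare."""


@dataclass
class PairwiseDistance:
    P: float
    Q: float
    d: float
    sites: int


@dataclass
class AgeProfile:
    family_id: str
    bins: dict[int, int]
    n_total: int


def kimura2p_distance(a: str, b: str, aligned: bool = False) -> PairwiseDistance:
    """K2P distance between two sequences.

    Unaligned inputs are globally aligned first (free end gaps).  Columns
    containing a gap or N are dropped.  Raises
    :class:`SaturatedDivergenceError` when ``1-2P-Q <= 0`` or ``1-2Q <= 0``
    and :class:`NoComparableSitesError` when nothing is comparable.
    """
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        a_aln, b_aln = a.upper(), b.upper()
    else:
        a_aln, b_aln = global_align(a, b)
    ts = tv = sites = 0
    for x, y in zip(a_aln, b_aln):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise NoComparableSitesError("no comparable sites")
    P = ts / sites
    Q = tv / sites
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergenceError(
            f"K2P distance saturated (P={P:.3f}, Q={Q:.3f})"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return PairwiseDistance(P=P, Q=Q, d=d, sites=sites)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def copy_identity(copy, consensus: str | None = None) -> int:
    """Integer percent identity of one copy to the consensus (half-up).

    Accepts an AlignmentHit carrying its stored search alignment (reused, no
    realignment) or a raw sequence plus the consensus.
    """
    q_aln = getattr(copy, "q_aln", "")
    s_aln = getattr(copy, "s_aln", "")
    if q_aln and s_aln:
        matches, cols = alignment_stats(q_aln, s_aln)
    else:
        seq = copy if isinstance(copy, str) else copy.seq
        if consensus is None:
            raise ValueError("consensus required when the copy has no stored alignment")
        # strict global: with free end gaps the aligner converts terminal
        # mismatches into unpenalized overhangs and inflates identity
        a, b = global_align(consensus, seq, free_end_gaps=False)
        matches, cols = alignment_stats(a, b)
    if cols == 0:
        raise NoComparableSitesError("empty alignment")
    return _round_half_up(100.0 * matches / cols)


def family_divergence_summary(
    copies, consensus: str
) -> tuple[float, int, int]:
    """Mean per-copy K2P distance to the consensus.

    Copies whose distance is saturated or incomparable are excluded from the
    mean and counted separately (third return value) rather than clamped.
    """
    if not copies:
        raise ValueError("empty copy set")
    dists = []
    n_excluded = 0
    for c in copies:
        q_aln = getattr(c, "q_aln", "")
        s_aln = getattr(c, "s_aln", "")
        try:
            if q_aln and s_aln:
                dists.append(kimura2p_distance(q_aln, s_aln, aligned=True).d)
            else:
                seq = c if isinstance(c, str) else c.seq
                dists.append(kimura2p_distance(consensus, seq).d)
        except (SaturatedDivergenceError, NoComparableSitesError):
            n_excluded += 1
    if not dists:
        raise ValueError("all copies saturated or incomparable")
    return sum(dists) / len(dists), len(dists), n_excluded


def age_distribution(copies, consensus: str | None = None, family_id: str = "family") -> AgeProfile:
    """Histogram of integer copy identities over bins 80..100 (zero bins
    retained); copies land in the nearest admissible bin."""
    bins = {i: 0 for i in range(80, 101)}
    for c in copies:
        ident = copy_identity(c, consensus)
        ident = min(100, max(80, ident))
        bins[ident] += 1
    return AgeProfile(family_id, bins, len(list(copies)))
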