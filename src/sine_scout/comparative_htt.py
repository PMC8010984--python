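"""Cross-species comparison of family consensi: distance matrix, NJ tree with
bootstrap, partner-LINE discovery via shared 3' tails, and horizontal-transfer
(HTT) screening.

A SINE copy in a distantly related host (here: a baculovirus genome) that is
nearly identical to an insect family consensus, together with an orthologous
*empty* site in related viral genomes, is the classic HTT signature.  The
published maximum-likelihood tree is replaced by neighbor joining on K2P
distances with a site-resampling bootstrap — a documented substitution that
reproduces topology, not support values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import global_align, identity, local_align, revcomp
from .consensus_builder import TSDReport, build_msa_center_star, detect_tsd
from .core_io import GenomeRecord
from .homology_search import SearchParams, seed_and_extend_search

RANKS = ("same_genus", "same_family", "cross_family", "cross_kingdom")
_RANK_ORDER = {r: i for i, r in enumerate(RANKS)}


@dataclass
class ConsensusDistanceMatrix:
    labels: list[str]
    D: np.ndarray  # p-distances, NaN where no comparable sites

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class PartnerLineCandidate:
    contig: str
    start: int
    end: int
    strand: str
    length: int
    tail_identity: float
    tsd: TSDReport | None
    orf_codons: int
    orf_ok: bool


@dataclass
class HTTCandidate:
    family_a: str
    species_a: str
    family_b: str
    species_b: str
    consensus_identity: float
    host_relatedness: str
    empty_site_evidence: str = "not_tested"
    flagged: bool = False


# ---------------------------------------------------------------------------
# distances and trees


def consensus_p_distance_matrix(
    consensi: list[tuple[str, str]]
) -> ConsensusDistanceMatrix:
    """Pairwise p-distances (base differences per site) between consensi;
    gap/N columns are dropped per pair (pairwise deletion)."""
    if len(consensi) < 2:
        raise ValueError("need at least two consensi")
    labels = [c[0] for c in consensi]
    n = len(consensi)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = global_align(consensi[i][1], consensi[j][1])
        sites = diffs = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                sites += 1
                if x != y:
                    diffs += 1
        D[i, j] = D[j, i] = diffs / sites if sites else np.nan
    return ConsensusDistanceMatrix(labels, D)


class _Node:
    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=0.0, support=None):
        self.label = label
        self.children = children or []
        self.length = length
        self.support = support

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.label])
        out = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out

    def newick(self, with_support: bool = False) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c.newick(with_support) for c in self.children)
        lab = ""
        if with_support and self.support is not None:
            lab = f"{self.support:.2f}"
        return f"({inner}){lab}:{self.length:.6f}"


def neighbor_joining(D: np.ndarray, labels: list[str]) -> _Node:
    """Classic NJ; deterministic tie-breaks by (Q value, smaller indices)."""
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least three taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries")
    nodes = [_Node(label=l) for l in labels]
    D = D.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                q = (m - 2) * sub[ai, bi] - r[ai] - r[bi]
                key = (q, ai, bi)
                if best is None or key < best:
                    best = key
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = _Node(children=[nodes[i], nodes[j]])
        new_row = np.zeros(D.shape[0] + 1)
        for ci in range(m):
            k = active[ci]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # final star of three
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    nodes[i].length = 0.5 * (dij + dik - djk)
    nodes[j].length = 0.5 * (dij + djk - dik)
    nodes[k].length = 0.5 * (dik + djk - dij)
    return _Node(children=[nodes[i], nodes[j], nodes[k]])


def _normalize_side(side: frozenset, taxa: frozenset) -> frozenset:
    """Canonical side of a bipartition: the one without the smallest taxon."""
    ref = min(taxa)
    return frozenset(taxa - side) if ref in side else frozenset(side)


def bipartitions(tree: _Node) -> set[frozenset]:
    """Non-trivial bipartitions of the (unrooted) tree, normalized to the
    side not containing the lexicographically smallest taxon."""
    taxa = tree.leaves()
    out = set()

    def walk(node: _Node):
        for child in node.children:
            side = child.leaves()
            if 1 < len(side) < len(taxa) - 1:
                out.add(_normalize_side(side, taxa))
            walk(child)

    walk(tree)
    return out


def _k2p_matrix_from_codes(codes: np.ndarray, cols: np.ndarray, cap: float = 5.0) -> np.ndarray:
    """K2P distances between all rows of an encoded alignment restricted to
    ``cols``; saturated pairs are capped at ``cap`` (documented fallback so
    bootstrap replicates always yield a usable matrix)."""
    sub = codes[:, cols]
    n = sub.shape[0]
    D = np.zeros((n, n))
    purine = (sub == 0) | (sub == 2)  # A or G
    valid = sub < 4
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        sites = int(ok.sum())
        if sites == 0:
            D[i, j] = D[j, i] = np.nan
            continue
        diff = ok & (sub[i] != sub[j])
        ts = int((diff & (purine[i] == purine[j])).sum())
        tv = int(diff.sum()) - ts
        P, Q = ts / sites, tv / sites
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            d = cap
        else:
            d = min(cap, -0.5 * np.log(w1 * np.sqrt(w2)))
        D[i, j] = D[j, i] = d
    return D


def nj_tree_with_bootstrap(
    consensi: list[tuple[str, str]],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[_Node, str]:
    """NJ tree on K2P distances from a center-star alignment of the consensi,
    with site-resampling bootstrap supports on internal nodes.

    Returns (tree, newick-with-supports).
    """
    from ._align import encode

    if len(consensi) < 3:
        raise ValueError("need at least three consensi")
    labels = [c[0] for c in consensi]
    aln = build_msa_center_star([c[1] for c in consensi], ids=labels)
    order = {cid: k for k, cid in enumerate(aln.ids)}
    rows = [aln.rows[order[l]] for l in labels]
    codes = np.vstack([encode(r.replace("-", "N")) for r in rows])
    ncols = codes.shape[1]
    all_cols = np.arange(ncols)
    D = _k2p_matrix_from_codes(codes, all_cols)
    if np.isnan(D).any():
        raise ValueError("pairs without comparable sites")
    tree = neighbor_joining(D, labels)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        cols = rng.integers(0, ncols, size=ncols)
        Db = _k2p_matrix_from_codes(codes, cols)
        if np.isnan(Db).any():
            continue
        for bp in bipartitions(neighbor_joining(Db, labels)):
            counts[bp] = counts.get(bp, 0) + 1

    taxa = tree.leaves()

    def annotate(node: _Node):
        for child in node.children:
            side = child.leaves()
            if 1 < len(side) < len(taxa) - 1:
                child.support = counts.get(_normalize_side(side, taxa), 0) / n_boot
            annotate(child)

    annotate(tree)
    return tree, tree.newick(with_support=True)


# ---------------------------------------------------------------------------
# partner LINEs


def _longest_orf_codons(seq: str) -> int:
    """Longest ATG..stop open reading frame, in codons, over both strands."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            start = None
            for p in range(frame, len(s) - 2, 3):
                codon = s[p : p + 3]
                if start is None:
                    if codon == "ATG":
                        start = p
                elif codon in stops:
                    best = max(best, (p - start) // 3)
                    start = None
            if start is not None:
                best = max(best, (len(s) - start) // 3)
    return best


def find_partner_line_candidates(
    sine_tail: str,
    genome: list[GenomeRecord],
    params: SearchParams | None = None,
    min_tail_identity: float = 0.80,
    min_tail_len: int = 30,
    min_upstream: int = 2000,
    element_span: int = 3000,
    min_orf_codons: int = 200,
    flank_bp: int = 50,
) -> list[PartnerLineCandidate]:
    """Search the 50-bp 3'-tail of a SINE family against a genome and extend
    matches into candidate partner-LINE spans.

    A partner LINE shares the SINE's 3' tail (its reverse transcriptase
    recognizes it); candidates need >= ``min_upstream`` bp of sequence
    upstream of the matched tail (element orientation) and are annotated with
    their longest ORF and any TSD on the span flanks.
    """
    if len(sine_tail) < min_tail_len:
        raise ValueError("tail query shorter than the minimum matched segment")
    params = params or SearchParams(word_size=7, band=15, window_pad=30)
    hits = seed_and_extend_search(
        sine_tail, genome, params, min_id=min_tail_identity, min_len=min_tail_len
    )
    by_contig = {g.id: g for g in genome}
    out: list[PartnerLineCandidate] = []
    for h in hits:
        rec = by_contig[h.contig]
        if h.strand == "+":
            upstream = h.start
            span = (max(0, h.end - element_span), h.end)
        else:
            upstream = rec.length - h.end
            span = (h.start, min(rec.length, h.start + element_span))
        if upstream < min_upstream:
            continue
        seg = rec.seq[span[0] : span[1]]
        orf = _longest_orf_codons(seg)
        left = rec.seq[max(0, span[0] - flank_bp) : span[0]]
        right = rec.seq[span[1] : span[1] + flank_bp]
        tsd = None
        if len(left) >= 20 and len(right) >= 20:
            tsd = detect_tsd(left, right)
        out.append(
            PartnerLineCandidate(
                contig=h.contig, start=span[0], end=span[1], strand=h.strand,
                length=span[1] - span[0], tail_identity=h.identity, tsd=tsd,
                orf_codons=orf, orf_ok=orf >= min_orf_codons,
            )
        )
    out.sort(key=lambda c: (-c.tail_identity, c.contig, c.start))
    return out


# ---------------------------------------------------------------------------
# HTT screening


def host_relatedness(taxonomy: pd.DataFrame, a: str, b: str) -> str:
    """Rank of separation between two hosts from a lineage table with columns
    species, genus, family, order, kingdom."""
    tax = taxonomy.set_index("species")
    for sp in (a, b):
        if sp not in tax.index:
            raise ValueError(f"unknown species label {sp!r}")
    ra, rb = tax.loc[a], tax.loc[b]
    if ra["genus"] == rb["genus"]:
        return "same_genus"
    if ra["family"] == rb["family"]:
        return "same_family"
    if ra["kingdom"] == rb["kingdom"]:
        return "cross_family"
    return "cross_kingdom"


def flag_htt_candidates(
    consensi: list[tuple[str, str, str]],   # (family_id, species, sequence)
    taxonomy: pd.DataFrame,
    id_threshold: float = 0.90,
    min_rank: str = "cross_family",
) -> list[HTTCandidate]:
    """Score all cross-species family pairs; a pair is flagged when consensus
    identity reaches ``id_threshold`` and the hosts are at least ``min_rank``
    apart.  Verdicts stay provisional until empty-site evidence is attached."""
    out: list[HTTCandidate] = []
    for (fa, sa, qa), (fb, sb, qb) in itertools.combinations(consensi, 2):
        if sa == sb:
            continue
        rank = host_relatedness(taxonomy, sa, sb)
        a, b = global_align(qa, qb)
        ident = identity(a, b)
        flagged = (
            ident >= id_threshold
            and _RANK_ORDER[rank] >= _RANK_ORDER[min_rank]
        )
        out.append(
            HTTCandidate(
                family_a=fa, species_a=sa, family_b=fb, species_b=sb,
                consensus_identity=ident, host_relatedness=rank, flagged=flagged,
            )
        )
    out.sort(key=lambda c: (-c.consensus_identity, c.family_a, c.family_b))
    return out


def orthologous_empty_site_check(
    left_flank: str,
    right_flank: str,
    related_genomes: list[GenomeRecord],
    min_identity: float = 0.70,
    max_gap: int = 50,
) -> dict[str, str]:
    """Search each related genome for both flanks of a filled locus.

    Evidence is "found" when both flanks align at >= ``min_identity`` on the
    same strand, adjacent (inner gap <= ``max_gap`` bp) and in order — i.e.
    the element is absent from the orthologous locus.
    """
    if len(left_flank) < 100 or len(right_flank) < 100:
        raise ValueError("flanks must be at least 100 bp")
    evidence: dict[str, str] = {}
    for rec in related_genomes:
        found = False
        for strand in "+-":
            target = rec.seq if strand == "+" else revcomp(rec.seq)
            la = local_align(left_flank, target)
            ra = local_align(right_flank, target)
            if la is None or ra is None:
                continue
            if (
                identity(la.q_aln, la.s_aln) < min_identity
                or identity(ra.q_aln, ra.s_aln) < min_identity
            ):
                continue
            # require most of each flank to be involved
            if (la.qend - la.qstart) < 0.5 * len(left_flank):
                continue
            if (ra.qend - ra.qstart) < 0.5 * len(right_flank):
                continue
            gap = ra.sstart - la.send
            if -max_gap <= gap <= max_gap:
                found = True
                break
        evidence[rec.id] = "found" if found else "not_found"
    return evidence
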