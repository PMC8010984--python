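"""Insertion-context classification of element copies against gene models.

Each copy is assigned exactly one category by the midpoint rule with the
precedence CDS > UTR5/UTR3 > exon_nc > intron > downstream_5k > upstream_5k >
intergenic.  Flank categories are measured from the gene span respecting
strand; nested or overlapping genes are resolved over the union of all
features, the winning feature's gene providing the gene id (ties: smaller id).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .core_io import GeneModel

CATEGORIES = (
    "CDS", "UTR5", "UTR3", "exon_nc", "intron",
    "downstream_5k", "upstream_5k", "intergenic",
)
# UTR5 and UTR3 share one precedence level; same-level conflicts between
# genes resolve to the smaller gene id
_PRECEDENCE = {
    "CDS": 0, "UTR5": 1, "UTR3": 1, "exon_nc": 2, "intron": 3,
    "downstream_5k": 4, "upstream_5k": 5, "intergenic": 6,
}


@dataclass
class InsertionContext:
    copy_id: str
    contig: str
    midpoint: int
    category: str
    gene_id: str | None
    distance_to_gene: int | None
    family_id: str | None = None


class GeneIndex:
    """Interval trees of gene features per contig, built once per annotation."""

    def __init__(self, genes: list[GeneModel], downstream_bp: int = 5000):
        self.downstream_bp = downstream_bp
        self.trees: dict[str, IntervalTree] = {}
        self.spans: dict[str, list[tuple[int, int, str]]] = {}
        for g in sorted(genes, key=lambda g: g.gene_id):
            tree = self.trees.setdefault(g.contig, IntervalTree())
            for cat, ivs in (
                ("CDS", g.cds), ("UTR5", g.utr5), ("UTR3", g.utr3),
                ("intron", g.introns),
            ):
                for s, e in ivs:
                    if e > s:
                        tree.addi(s, e, (cat, g.gene_id))
            for s, e in self._exon_nc(g):
                tree.addi(s, e, ("exon_nc", g.gene_id))
            s, e = g.span
            down = (e, e + downstream_bp) if g.strand == "+" else (s - downstream_bp, s)
            up = (s - downstream_bp, s) if g.strand == "+" else (e, e + downstream_bp)
            if down[1] > down[0]:
                tree.addi(max(0, down[0]), down[1], ("downstream_5k", g.gene_id))
            if up[1] > up[0]:
                tree.addi(max(0, up[0]), up[1], ("upstream_5k", g.gene_id))
            self.spans.setdefault(g.contig, []).append((s, e, g.gene_id))
        for contig in self.spans:
            self.spans[contig].sort()

    @staticmethod
    def _exon_nc(g: GeneModel) -> list[tuple[int, int]]:
        from .core_io import _subtract

        classified = list(g.cds) + list(g.utr5) + list(g.utr3)
        return _subtract(list(g.exons), classified)

    def nearest_gene(self, contig: str, pos: int) -> tuple[str, int] | None:
        spans = self.spans.get(contig)
        if not spans:
            return None
        best: tuple[int, str] | None = None
        for s, e, gid in spans:
            if s <= pos < e:
                d = 0
            else:
                d = s - pos if pos < s else pos - e + 1
            if best is None or (d, gid) < best:
                best = (d, gid)
        return best[1], best[0]


def classify_insertion_context(
    copy,
    index: GeneIndex,
    copy_id: str = "copy",
) -> InsertionContext:
    """Classify one copy (an AlignmentHit or a (contig, start, end) triple)."""
    if isinstance(copy, tuple):
        contig, start, end = copy
        family = None
    else:
        contig, start, end = copy.contig, copy.start, copy.end
        family = getattr(copy, "family_id", None)
    if contig not in index.trees and contig not in index.spans:
        raise ValueError(f"unknown contig {contig!r}")
    mid = (start + end) // 2
    overlaps = index.trees.get(contig, IntervalTree())[mid]
    winner: tuple[int, str, str] | None = None  # (precedence, gene_id, category)
    for iv in overlaps:
        cat, gid = iv.data
        key = (_PRECEDENCE[cat], gid, cat)
        if winner is None or key < winner:
            winner = key
    if winner is None:
        near = index.nearest_gene(contig, mid)
        gid, dist = near if near else (None, None)
        return InsertionContext(copy_id, contig, mid, "intergenic", gid, dist, family)
    _, gid, cat = winner
    if cat in ("downstream_5k", "upstream_5k"):
        near = index.nearest_gene(contig, mid)
        dist = near[1] if near else None
    else:
        dist = 0
    return InsertionContext(copy_id, contig, mid, cat, gid, dist, family)


def classify_all(copies, genes: list[GeneModel], downstream_bp: int = 5000):
    index = GeneIndex(genes, downstream_bp)
    return [
        classify_insertion_context(c, index, copy_id=f"copy{i + 1}")
        for i, c in enumerate(copies)
    ]


@dataclass
class GeneAssociationReport:
    category_counts: pd.DataFrame    # families x categories
    category_fractions: pd.DataFrame
    per_gene: pd.DataFrame           # gene x family counts + total
    hot_genes: list[str]             # genes with >= threshold copies


def per_gene_insertion_counts(
    contexts: list[InsertionContext], threshold: int = 10
) -> GeneAssociationReport:
    """Per-family category breakdown and per-gene accumulation.

    ``hot_genes`` lists genes carrying at least ``threshold`` genic copies
    (mirrors reporting genes accumulating ten or more elements).
    """
    rows = [
        {
            "family": c.family_id or "all",
            "category": c.category,
            "gene": c.gene_id,
            "genic": c.category in ("CDS", "UTR5", "UTR3", "exon_nc", "intron"),
        }
        for c in contexts
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        empty = pd.DataFrame()
        return GeneAssociationReport(empty, empty, empty, [])
    counts = (
        df.groupby(["family", "category"]).size().unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    genic = df[df["genic"] & df["gene"].notna()]
    if genic.empty:
        per_gene = pd.DataFrame()
        hot = []
    else:
        per_gene = (
            genic.groupby(["gene", "family"]).size().unstack(fill_value=0)
        )
        per_gene["total"] = per_gene.sum(axis=1)
        per_gene = per_gene.sort_values("total", ascending=False)
        hot = per_gene.index[per_gene["total"] >= threshold].tolist()
    return GeneAssociationReport(counts, fractions, per_gene, hot)
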