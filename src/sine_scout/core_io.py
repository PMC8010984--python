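"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions, fixed here and used everywhere else:

* internal coordinates are 0-based half-open;
* GFF3 is read and written 1-based inclusive;
* BED6 is written 0-based half-open.

Sequences are uppercased on ingest and any symbol outside ``ACGTN`` is mapped
to ``N``.  ``N`` never counts as a match in any identity computation.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import revcomp

logger = logging.getLogger("sine_scout")

_NON_ACGTN = re.compile(r"[^ACGTN]")

Interval = tuple[int, int]


def _clean_seq(seq: str) -> str:
    return _NON_ACGTN.sub("N", str(seq).upper())


@dataclass
class GenomeRecord:
    """A contig/scaffold: identifier plus an uppercase ACGTN sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = _clean_seq(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One gene collapsed to a single (longest) mRNA isoform.

    All intervals are 0-based half-open, sorted and non-overlapping; ``cds``
    lies within ``exons``; introns are the gaps between consecutive exons.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        self.cds = sorted(tuple(c) for c in self.cds)
        self.utr5 = sorted(tuple(u) for u in self.utr5)
        self.utr3 = sorted(tuple(u) for u in self.utr3)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (e1_end, e2_start)
            for (_, e1_end), (e2_start, _) in zip(self.exons, self.exons[1:])
            if e2_start > e1_end
        ]


@dataclass
class RunConfig:
    """All thresholds of the search / counting / divergence regimes.

    ``discovery_*`` gates the initial homology search (70% identity over
    50 bp); ``copy_*`` the copy-number estimate (80% over 100 bp);
    ``div_*`` the divergence set (80% identity over 80% of the consensus).
    """

    discovery_id: float = 0.70
    discovery_len: int = 50
    copy_id: float = 0.80
    copy_len: int = 100
    div_id: float = 0.80
    div_lenfrac: float = 0.80
    flank_bp: int = 500
    downstream_bp: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("discovery_id", "copy_id", "div_id", "div_lenfrac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("discovery_len", "copy_len", "flank_bp", "downstream_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords, order preserved."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.seq if isinstance(r, GenomeRecord) else r[1]),
                  id=r.id if isinstance(r, GenomeRecord) else r[0],
                  description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, genome: dict[str, int] | None = None) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels.

    Multi-isoform genes are collapsed to the mRNA with the longest spliced
    length.  UTRs are taken from ``five_prime_UTR``/``three_prime_UTR``
    features when present, otherwise inferred as exonic-minus-CDS, split by
    strand around the CDS extent.  Orphan children are skipped with a warning;
    coordinates outside the (optional) contig lengths raise.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    known_ids = {f.id for f in db.all_features()}
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, dict] | None = None
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            parents = mrna.attributes.get("Parent", [])
            if parents and any(p not in known_ids for p in parents):
                warnings.warn(f"skipping {mrna.id}: unknown parent {parents}")
                continue
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(mrna, order_by="start"):
                iv = (child.start - 1, child.end)  # 1-based incl -> 0-based half-open
                if child.start < 1 or child.end < child.start:
                    raise ValueError(f"bad coordinates on {child.id}")
                if genome is not None:
                    limit = genome.get(child.seqid)
                    if limit is not None and child.end > limit:
                        raise ValueError(
                            f"{child.featuretype} {child.id} ends at {child.end} "
                            f"beyond contig {child.seqid} ({limit} bp)"
                        )
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            if not exons:
                continue
            spliced = sum(e - s for s, e in exons)
            key = (spliced, mrna.id)
            if best is None or key > (best[0], best[1]):
                best = (spliced, mrna.id, dict(exons=exons, cds=cds, utr5=utr5, utr3=utr3))
        if best is None:
            continue
        parts = best[2]
        if not parts["utr5"] and not parts["utr3"] and parts["cds"]:
            parts["utr5"], parts["utr3"] = _infer_utrs(
                parts["exons"], parts["cds"], gene.strand
            )
        genes.append(
            GeneModel(
                gene_id=gene.id, contig=gene.seqid, strand=gene.strand,
                exons=sorted(parts["exons"]), cds=sorted(parts["cds"]),
                utr5=parts["utr5"], utr3=parts["utr3"],
            )
        )
    return genes


def _subtract(intervals: list[Interval], others: list[Interval]) -> list[Interval]:
    out = []
    for s, e in intervals:
        pieces = [(s, e)]
        for os, oe in others:
            nxt = []
            for ps, pe in pieces:
                if oe <= ps or os >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < os:
                        nxt.append((ps, os))
                    if oe < pe:
                        nxt.append((oe, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def _infer_utrs(exons, cds, strand) -> tuple[list[Interval], list[Interval]]:
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    noncoding = _subtract(exons, cds)
    low = [iv for iv in noncoding if iv[1] <= cds_lo]
    high = [iv for iv in noncoding if iv[0] >= cds_hi]
    if strand == "+":
        return low, high
    return high, low


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS rows, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.contig}\tsine_scout\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tsine_scout\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for fs, fe in g.exons:
                fh.write(
                    f"{g.contig}\tsine_scout\texon\t{fs + 1}\t{fe}\t.\t{g.strand}\t.\t"
                    f"Parent={mid}\n"
                )
            for fs, fe in g.cds:
                fh.write(
                    f"{g.contig}\tsine_scout\tCDS\t{fs + 1}\t{fe}\t.\t{g.strand}\t0\t"
                    f"Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# BED


def write_copies_bed(copies, path: str | Path) -> None:
    """BED6 of copy loci; name = family:index, score = round(identity*1000)."""
    counters: dict[str, int] = {}
    with open(path, "w") as fh:
        for hit in copies:
            fam = getattr(hit, "family_id", None) or "copy"
            counters[fam] = counters.get(fam, 0) + 1
            score = min(1000, round(hit.identity * 1000))
            fh.write(
                f"{hit.contig}\t{hit.start}\t{hit.end}\t{fam}:{counters[fam]}\t"
                f"{score}\t{hit.strand}\n"
            )


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        c, s, e, name, score, strand = line.split("\t")
        rows.append((c, int(s), int(e), name, int(score), strand))
    return rows


def extract_sequence(record: GenomeRecord, start: int, end: int, strand: str = "+") -> str:
    """Sequence of [start, end) on the plus strand; '-' returns the revcomp."""
    seg = record.seq[start:end]
    return revcomp(seg) if strand == "-" else seg
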