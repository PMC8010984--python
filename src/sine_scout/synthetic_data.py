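"""Synthetic genomes with implanted SINE/LINE elements and full ground truth.

The generator emulates the statistical structure of a lepidopteran
SINE landscape so that every pipeline stage is testable without downloads:

* multi-family SINE masters built as head + body + simple-repeat tail, the
  head derived from a (synthetic) tRNA or 5S rRNA reference carrying exact
  Pol III promoter boxes;
* per-copy divergence drawn from a burst or mixture age model under the K2P
  substitution process with transition bias ``kappa`` (expected
  transition:transversion *count* ratio);
* insertions biased toward introns and 5-kb-downstream regions of generated
  gene models, each creating a fresh target-site duplication (TSD);
* optionally one partner LINE sharing a family's 3' tail, and one
  near-identical family copy implanted into a small "virus" record as a
  horizontal-transfer event, with two related virus records carrying the
  joined empty site.

Mutation is substitution-only by default (an indel knob exists but defaults
to 0) so identity arithmetic in oracles stays exact.  All randomness flows
from one seed; outputs are byte-identical across runs with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import revcomp
from .core_io import GeneModel, GenomeRecord, write_fasta, write_gff3

# concrete realizations of the degenerate promoter-box consensi
A_BOX_SEQ = "TAGCGGAATCAG"    # matches TRGCNNARYNNG
B_BOX_SEQ = "GTTCGAATC"       # matches GWTCRANNC
IE_BOX_SEQ = "GATGGA"         # matches GATGGR
C_BOX_SEQ = "AGGTCGGGC"       # matches RGGTCGGGC

TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

DEFAULT_CONTEXT_WEIGHTS = {
    "intron": 0.45,
    "downstream_5k": 0.25,
    "upstream_5k": 0.05,
    "intergenic": 0.22,
    "CDS": 0.01,
    "UTR3": 0.02,
}


@dataclass
class FamilySpec:
    """One SINE family to implant.

    ``age_model`` is ``("burst", d)`` — every copy at divergence ~d — or
    ``("mixture", [(d1, w1), (d2, w2), ...])`` for multi-burst landscapes.
    """

    name: str
    head_class: str = "tRNA"            # "tRNA" | "5S_rRNA"
    body_bp: int = 173                  # 72-bp tRNA head + body + 18-bp tail = 263
    tail_unit: str = "GT"
    tail_n_units: int = 9
    n_copies: int = 100
    age_model: tuple = ("burst", 0.05)
    truncation_prob: float = 0.0
    tsd_len_range: tuple[int, int] = (5, 15)
    context_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_WEIGHTS)
    )
    head_divergence: float = 0.25       # head vs its reference (boxes replanted)

    def __post_init__(self) -> None:
        total = sum(self.context_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"context weights of {self.name} sum to {total}")
        for d in self._divergences():
            if not 0 <= d <= 0.3:
                raise ValueError("divergence must lie in [0, 0.3]")

    def _divergences(self):
        if self.age_model[0] == "burst":
            return [self.age_model[1]]
        return [d for d, _ in self.age_model[1]]


@dataclass
class SimulationConfig:
    genome_bp: int = 1_000_000
    gc: float = 0.40
    n_genes: int = 50
    families: list[FamilySpec] = field(default_factory=list)
    kappa: float = 2.0
    indel_rate: float = 0.0
    partner_line: bool = False
    partner_line_family: str | None = None
    htt_event: bool = False
    htt_family: str | None = None
    virus_bp: int = 15_000
    min_implant_spacing: int = 60
    flank_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be a fraction")


@dataclass
class TruthTable:
    implants: pd.DataFrame          # one row per implanted copy
    masters: dict[str, str]         # family -> master sequence
    head_refs: list[tuple[str, str, str]]
    partner_line: dict | None = None
    htt: dict | None = None


@dataclass
class SimulatedDataset:
    genome: list[GenomeRecord]
    genes: list[GeneModel]
    truth: TruthTable
    base_seq: dict[str, str]        # contig -> pre-insertion sequence
    virus_records: list[GenomeRecord] = field(default_factory=list)
    related_virus_records: list[GenomeRecord] = field(default_factory=list)
    taxonomy: pd.DataFrame | None = None
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# mutation model


def k2p_event_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition/transversion proportions (P, Q) for K2P distance
    ``d`` with count ratio ``kappa`` = E[ts]/E[tv]."""
    at = d * kappa / (kappa + 1)          # alpha * t
    bt = d / (2 * (kappa + 1))            # beta * t
    P = 0.25 - 0.5 * np.exp(-2 * (at + bt)) + 0.25 * np.exp(-4 * bt)
    Q = 0.5 - 0.5 * np.exp(-4 * bt)
    return float(P), float(Q)


def divergence_for_identity(identity_pct: float, kappa: float = 2.0) -> float:
    """K2P distance whose expected observed identity is ``identity_pct``
    (inverts the expected mismatch proportion P(d)+Q(d) numerically)."""
    from scipy.optimize import brentq

    q = 1 - identity_pct / 100.0
    if q <= 0:
        return 0.0
    if q >= 0.75:
        raise ValueError("identity below the K2P saturation limit of 25%")

    def f(d):
        P, Q = k2p_event_probabilities(d, kappa)
        return P + Q - q

    return float(brentq(f, 0.0, 20.0))


def mutate_copy_k2p(
    master: str,
    d: float,
    kappa: float = 2.0,
    rng: np.random.Generator | None = None,
    truncate_5p: int = 0,
    indel_rate: float = 0.0,
) -> str:
    """Apply K2P substitutions at expected distance ``d`` (transition bias
    ``kappa``), optionally a 5' truncation and rare 1-3 bp indels."""
    if not 0 <= d <= 0.3:
        raise ValueError(f"divergence {d} outside [0, 0.3]")
    rng = rng or np.random.default_rng()
    P, Q = k2p_event_probabilities(d, kappa)
    out = []
    u = rng.random(len(master))
    for ch, x in zip(master, u):
        if ch not in "ACGT":
            out.append(ch)
        elif x < P:
            out.append(TS_PARTNER[ch])
        elif x < P + Q:
            out.append(TV_PARTNERS[ch][rng.integers(0, 2)])
        else:
            out.append(ch)
    seq = "".join(out)
    if indel_rate > 0:
        seq = _apply_indels(seq, indel_rate, rng)
    if truncate_5p:
        seq = seq[truncate_5p:]
    return seq


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(ch)
            out.append(_random_seq(rng, rng.integers(1, 4), 0.5))
        else:
            out.append(ch)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=int(n), p=p)])


# ---------------------------------------------------------------------------
# masters and references


def make_head_refs(rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Synthetic stand-ins for the tRNA and 5S rRNA head references (labelled
    synthetic; they carry exact promoter boxes at fixed offsets)."""
    trna = list(_random_seq(rng, 72, 0.5))
    trna[8 : 8 + len(A_BOX_SEQ)] = A_BOX_SEQ
    trna[52 : 52 + len(B_BOX_SEQ)] = B_BOX_SEQ
    r5s = list(_random_seq(rng, 118, 0.5))
    r5s[10 : 10 + len(A_BOX_SEQ)] = A_BOX_SEQ
    r5s[35 : 35 + len(IE_BOX_SEQ)] = IE_BOX_SEQ
    r5s[50 : 50 + len(C_BOX_SEQ)] = C_BOX_SEQ
    return [
        ("synthetic_tRNA_Arg", "tRNA", "".join(trna)),
        ("synthetic_5S_rRNA", "5S_rRNA", "".join(r5s)),
    ]


def make_master(
    spec: FamilySpec,
    head_refs: list[tuple[str, str, str]],
    rng: np.random.Generator,
    kappa: float = 2.0,
    shared_body: str | None = None,
) -> str:
    """Head (diverged copy of its reference with boxes replanted) + body +
    simple-repeat tail.  ``shared_body`` plants a conserved central segment
    shared with another family."""
    ref = next(r for r in head_refs if r[1] == spec.head_class)
    head = list(mutate_copy_k2p(ref[2], spec.head_divergence, kappa, rng))
    if spec.head_class == "tRNA":
        head[8 : 8 + len(A_BOX_SEQ)] = A_BOX_SEQ
        head[52 : 52 + len(B_BOX_SEQ)] = B_BOX_SEQ
    else:
        head[10 : 10 + len(A_BOX_SEQ)] = A_BOX_SEQ
        head[35 : 35 + len(IE_BOX_SEQ)] = IE_BOX_SEQ
        head[50 : 50 + len(C_BOX_SEQ)] = C_BOX_SEQ
    body = _random_seq(rng, spec.body_bp, 0.45)
    if shared_body:
        body = shared_body + body[len(shared_body):]
    tail = spec.tail_unit * spec.tail_n_units
    return "".join(head) + body + tail


# ---------------------------------------------------------------------------
# gene models


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator, contig: str) -> list[GeneModel]:
    """Non-overlapping gene models with >=2 exons, CDS and UTRs, spaced so
    that 5-kb flank regions never overlap a neighboring gene."""
    genes: list[GeneModel] = []
    pos = 12_000
    for i in range(cfg.n_genes):
        n_exons = int(rng.integers(2, 6))
        exons = []
        cursor = pos
        for _ in range(n_exons):
            elen = int(rng.integers(150, 401))
            exons.append((cursor, cursor + elen))
            cursor += elen + int(rng.integers(400, 1501))
        gene_end = exons[-1][1]
        if gene_end + 12_000 > cfg.genome_bp:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        # CDS from mid first exon to mid last exon -> both UTRs exist
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        cds_lo = first_s + (first_e - first_s) // 2
        cds_hi = last_s + (last_e - last_s) // 2
        cds = [
            (max(s, cds_lo), min(e, cds_hi))
            for s, e in exons
            if min(e, cds_hi) > max(s, cds_lo)
        ]
        low_utr = [(s, min(e, cds_lo)) for s, e in exons if s < cds_lo]
        high_utr = [(max(s, cds_hi), e) for s, e in exons if e > cds_hi]
        utr5, utr3 = (low_utr, high_utr) if strand == "+" else (high_utr, low_utr)
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:03d}", contig=contig, strand=strand,
                exons=exons, cds=cds, utr5=utr5, utr3=utr3,
            )
        )
        pos = gene_end + int(rng.integers(12_000, 18_000))
        if pos > cfg.genome_bp - 15_000:
            break
    return genes


# ---------------------------------------------------------------------------
# placement


def _sample_position(
    category: str,
    genes: list[GeneModel],
    genome_len: int,
    rng: np.random.Generator,
) -> int | None:
    """One candidate base-coordinate insertion point for a context category."""
    if category == "intron":
        candidates = [iv for g in genes for iv in g.introns if iv[1] - iv[0] > 80]
        if not candidates:
            return None
        s, e = candidates[rng.integers(0, len(candidates))]
        return int(rng.integers(s + 30, e - 30))
    if category == "CDS":
        candidates = [iv for g in genes for iv in g.cds if iv[1] - iv[0] > 40]
        if not candidates:
            return None
        s, e = candidates[rng.integers(0, len(candidates))]
        return int(rng.integers(s + 15, e - 15))
    if category == "UTR3":
        candidates = [iv for g in genes for iv in g.utr3 if iv[1] - iv[0] > 40]
        if not candidates:
            return None
        s, e = candidates[rng.integers(0, len(candidates))]
        return int(rng.integers(s + 15, e - 15))
    if category == "UTR5":
        candidates = [iv for g in genes for iv in g.utr5 if iv[1] - iv[0] > 40]
        if not candidates:
            return None
        s, e = candidates[rng.integers(0, len(candidates))]
        return int(rng.integers(s + 15, e - 15))
    if category in ("downstream_5k", "upstream_5k"):
        if not genes:
            return None
        g = genes[rng.integers(0, len(genes))]
        s, e = g.span
        # sampled well inside the 5-kb window: insertions stacking between
        # the gene and a later implant shift its realized distance outward,
        # and the margin keeps nearly all implants within the window
        after = (g.strand == "+") == (category == "downstream_5k")
        if after:
            return int(rng.integers(e + 200, e + 2800))
        return int(rng.integers(max(0, s - 2800), s - 200))
    if category == "intergenic":
        for _ in range(200):
            p = int(rng.integers(1000, genome_len - 1000))
            if all(
                p < g.span[0] - 5600 or p > g.span[1] + 5600 for g in genes
            ):
                return p
        return None
    raise ValueError(f"unknown category {category!r}")


@dataclass
class _Insertion:
    pos: int            # base coordinate
    seq: str            # inserted element (already oriented)
    tsd_len: int
    meta: dict


def _assemble(base: str, insertions: list[_Insertion]):
    """Insert elements left-to-right; at base position p the target site
    base[p:p+L] is duplicated so it flanks the element.  Returns the final
    sequence and per-insertion final coordinates."""
    insertions = sorted(insertions, key=lambda i: i.pos)
    pieces = []
    cursor = 0
    shift = 0
    finals = []
    for ins in insertions:
        p, L = ins.pos, ins.tsd_len
        pieces.append(base[cursor:p])
        dup = base[p : p + L]
        pieces.append(dup)
        pieces.append(ins.seq)
        start = p + shift + L
        finals.append((start, start + len(ins.seq)))
        shift += L + len(ins.seq)
        cursor = p
    pieces.append(base[cursor:])
    return "".join(pieces), finals, insertions


def _shift_genes(genes: list[GeneModel], insertions: list[_Insertion]) -> list[GeneModel]:
    """Map gene features to post-insertion coordinates.  Interval starts move
    for insertions at p <= start, ends for p < end, so intervals containing
    an insertion stretch around it."""
    pos = np.array([i.pos for i in insertions])
    add = np.array([i.tsd_len + len(i.seq) for i in insertions])
    cum = np.concatenate([[0], np.cumsum(add)])

    def map_start(x: int) -> int:
        return x + int(cum[np.searchsorted(pos, x, side="right")])

    def map_end(x: int) -> int:
        return x + int(cum[np.searchsorted(pos, x, side="left")])

    out = []
    for g in genes:
        out.append(
            GeneModel(
                gene_id=g.gene_id, contig=g.contig, strand=g.strand,
                exons=[(map_start(s), map_end(e)) for s, e in g.exons],
                cds=[(map_start(s), map_end(e)) for s, e in g.cds],
                utr5=[(map_start(s), map_end(e)) for s, e in g.utr5],
                utr3=[(map_start(s), map_end(e)) for s, e in g.utr3],
            )
        )
    return out


def _draw_divergence(spec: FamilySpec, rng: np.random.Generator) -> float:
    if spec.age_model[0] == "burst":
        d0 = spec.age_model[1]
    else:
        comps = spec.age_model[1]
        weights = np.array([w for _, w in comps], dtype=float)
        weights /= weights.sum()
        d0 = comps[rng.choice(len(comps), p=weights)][0]
    return float(min(0.3, max(0.0, d0)))


def generate_genome_with_families(cfg: SimulationConfig) -> SimulatedDataset:
    """Build the genome, gene models, implants and ground truth for a config."""
    rng = np.random.default_rng(cfg.seed)
    contig = "chr1"
    base = _random_seq(rng, cfg.genome_bp, cfg.gc)
    genes = _make_genes(cfg, rng, contig)
    head_refs = make_head_refs(rng)

    masters: dict[str, str] = {}
    shared = None
    for i, spec in enumerate(cfg.families):
        master = make_master(spec, head_refs, rng, cfg.kappa, shared_body=None if i == 0 else shared)
        if i == 0:
            # later families share a conserved central segment with the first
            body_start = len(master) - spec.body_bp - len(spec.tail_unit) * spec.tail_n_units
            shared = master[body_start : body_start + 44]
        masters[spec.name] = master

    insertions: list[_Insertion] = []
    used: list[int] = []

    def place(seq: str, meta: dict, category: str, tsd_len: int) -> bool:
        for _ in range(400):
            p = _sample_position(category, genes, cfg.genome_bp, rng)
            if p is None:
                return False
            if any(abs(p - q) < cfg.min_implant_spacing + tsd_len for q in used):
                continue
            # keep implant boundaries unambiguous: if the element's terminal
            # base matched the adjacent host base, the target-site
            # duplication would be genuinely one longer than drawn
            if seq[0] == base[p + tsd_len] or seq[-1] == base[p - 1]:
                continue
            used.append(p)
            insertions.append(_Insertion(p, seq, tsd_len, meta))
            return True
        return False

    for spec in cfg.families:
        master = masters[spec.name]
        cats = list(spec.context_weights)
        weights = np.array([spec.context_weights[c] for c in cats])
        for ci in range(spec.n_copies):
            d = _draw_divergence(spec, rng)
            trunc = 0
            if rng.random() < spec.truncation_prob:
                trunc = int(rng.integers(1, len(master) // 2))
            copy = mutate_copy_k2p(master, d, cfg.kappa, rng, truncate_5p=trunc,
                                   indel_rate=cfg.indel_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = copy if strand == "+" else revcomp(copy)
            category = cats[rng.choice(len(cats), p=weights)]
            tsd_len = int(rng.integers(spec.tsd_len_range[0], spec.tsd_len_range[1] + 1))
            meta = {
                "family": spec.name, "copy": ci + 1, "strand": strand,
                "d_true": d, "truncated_bp": trunc, "category": category,
            }
            if not place(oriented, meta, category, tsd_len):
                raise ValueError(
                    f"genome too small to place copy {ci + 1} of {spec.name}"
                )

    partner_truth = None
    if cfg.partner_line:
        fam = cfg.partner_line_family or (cfg.families[0].name if cfg.families else None)
        if fam is None:
            raise ValueError("partner_line requires at least one family")
        line_seq, tail_ident = _make_partner_line(masters[fam], rng)
        tsd_len = int(rng.integers(8, 16))
        meta = {"family": f"{fam}_LINE", "copy": 1, "strand": "+",
                "d_true": 0.0, "truncated_bp": 0, "category": "intergenic"}
        if not place(line_seq, meta, "intergenic", tsd_len):
            raise ValueError("genome too small for the partner LINE")
        partner_truth = {
            "family": fam, "length": len(line_seq), "tail_identity": tail_ident,
        }

    final_seq, finals, ordered = _assemble(base, insertions)
    shifted_genes = _shift_genes(genes, ordered)
    rows = []
    for (start, end), ins in zip(finals, ordered):
        gene_id = None
        for g in genes:
            if g.span[0] <= ins.pos < g.span[1]:
                gene_id = g.gene_id
                break
        rows.append(
            {
                **ins.meta, "contig": contig, "start": start, "end": end,
                "base_pos": ins.pos, "tsd_len": ins.tsd_len,
                "tsd_seq": base[ins.pos : ins.pos + ins.tsd_len],
                "length": end - start, "gene_id": gene_id,
            }
        )
    implants = pd.DataFrame(rows)
    if partner_truth is not None:
        mask = implants["family"] == f"{partner_truth['family']}_LINE"
        row = implants[mask].iloc[0]
        partner_truth.update(contig=contig, start=int(row["start"]), end=int(row["end"]))
        implants = implants[~mask].reset_index(drop=True)

    genome = [GenomeRecord(contig, final_seq)]
    truth = TruthTable(
        implants=implants, masters=masters, head_refs=head_refs,
        partner_line=partner_truth,
    )
    ds = SimulatedDataset(
        genome=genome, genes=shifted_genes, truth=truth,
        base_seq={contig: base}, config=cfg,
    )
    _attach_taxonomy(ds)
    if cfg.htt_event:
        fam = cfg.htt_family or (cfg.families[0].name if cfg.families else None)
        if fam is None:
            raise ValueError("htt_event requires at least one family")
        implant_htt_event(ds, fam, cfg.virus_bp, rng)
    return ds


def _make_partner_line(sine_master: str, rng: np.random.Generator,
                       total_bp: int = 3000, orf_codons: int = 700) -> tuple[str, float]:
    """A LINE-like element: 5' leader + long ORF + 3' region whose final 43 bp
    are ~84% identical to the SINE master's 3' end."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < orf_codons - 2:
        c = _random_seq(rng, 3, 0.5)
        if c not in stops:
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    tail43 = list(sine_master[-43:])
    # ~16% mismatches -> 84% identity over the shared tail
    for p in rng.choice(len(tail43), size=7, replace=False):
        tail43[p] = TV_PARTNERS[tail43[p]][rng.integers(0, 2)] if tail43[p] in "ACGT" else "A"
    tail = "".join(tail43)
    remaining = total_bp - len(orf) - len(tail)
    leader_len = max(50, remaining // 2)
    utr3_len = max(20, remaining - leader_len)
    seq = _random_seq(rng, leader_len, 0.45) + orf + _random_seq(rng, utr3_len, 0.45) + tail
    ident = sum(1 for a, b in zip(sine_master[-43:], tail) if a == b) / 43
    return seq, ident


def _attach_taxonomy(ds: SimulatedDataset) -> None:
    ds.taxonomy = pd.DataFrame(
        [
            {"species": "host_species", "genus": "Hostgenus", "family": "Hostfamily",
             "order": "Lepidoptera", "kingdom": "Animalia"},
            {"species": "virus_isolate", "genus": "Alphabaculovirus",
             "family": "Baculoviridae", "order": "Lefavirales", "kingdom": "Viruses"},
            {"species": "related_virus_1", "genus": "Alphabaculovirus",
             "family": "Baculoviridae", "order": "Lefavirales", "kingdom": "Viruses"},
            {"species": "related_virus_2", "genus": "Alphabaculovirus",
             "family": "Baculoviridae", "order": "Lefavirales", "kingdom": "Viruses"},
        ]
    )


def implant_htt_event(
    ds: SimulatedDataset,
    family: str,
    virus_bp: int = 15_000,
    rng: np.random.Generator | None = None,
) -> None:
    """Copy one family master (~98% identity) into a small virus record.

    The viral copy carries a shared host-derived 5' flank, no TSD and no
    upstream duplication (the non-homologous end-joining configuration); two
    related virus records carry the joined empty site of the insertion locus.
    """
    if family not in ds.truth.masters:
        raise ValueError(f"unknown family {family!r}")
    rng = rng or np.random.default_rng(0)
    master = ds.truth.masters[family]
    copy = mutate_copy_k2p(master, 0.01, 2.0, rng)
    host = ds.base_seq[next(iter(ds.base_seq))]
    share_start = int(rng.integers(1000, len(host) - 2000))
    shared_flank = host[share_start : share_start + 800]
    virus_base = _random_seq(rng, virus_bp, 0.42)
    p = virus_bp // 2
    insert = shared_flank + copy
    virus_seq = virus_base[:p] + insert + virus_base[p:]
    ds.virus_records = [GenomeRecord("virus_isolate", virus_seq)]
    # related isolates: the same locus without the insertion (joined empty site)
    for k in (1, 2):
        related = mutate_copy_k2p(virus_base, 0.02, 2.0, rng)
        ds.related_virus_records.append(GenomeRecord(f"related_virus_{k}", related))
    ds.truth.htt = {
        "family": family, "virus_id": "virus_isolate",
        "element_start": p + len(shared_flank),
        "element_end": p + len(insert),
        "insert_start": p,
        "shared_flank_host_start": share_start,
        "copy_identity": sum(a == b for a, b in zip(master, copy)) / len(master),
    }


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, out / "genome.fa")
    write_gff3(ds.genes, out / "genes.gff3")
    ds.truth.implants.to_csv(out / "truth.tsv", sep="\t", index=False)
    write_fasta(
        [(f"{name}", seq) for name, seq in ds.truth.masters.items()],
        out / "masters.fa",
    )
    write_fasta([(r[0], r[2]) for r in ds.truth.head_refs], out / "head_refs.fa")
    if ds.virus_records:
        write_fasta(ds.virus_records + ds.related_virus_records, out / "virus.fa")
    if ds.taxonomy is not None:
        ds.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# cross-species consensus panels for the HTT screen


def generate_species_panel(
    seed: int,
    include_htt: bool = False,
    kappa: float = 2.0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Family consensi across a small host panel with purely vertical descent,
    identity decaying with host distance; optionally one virus-borne copy
    nearly identical to a donor host family (the HTT event).

    Returns (consensi as (family, species, seq), taxonomy table).
    """
    rng = np.random.default_rng(seed)
    refs = make_head_refs(rng)
    root = make_master(
        FamilySpec(name="SE1", body_bp=179, tail_unit="GT", tail_n_units=6),
        refs, rng, kappa,
    )
    taxonomy = pd.DataFrame(
        [
            {"species": "moth_a1", "genus": "GenusA", "family": "FamilyA",
             "order": "Lepidoptera", "kingdom": "Animalia"},
            {"species": "moth_a2", "genus": "GenusA", "family": "FamilyA",
             "order": "Lepidoptera", "kingdom": "Animalia"},
            {"species": "moth_b", "genus": "GenusB", "family": "FamilyA",
             "order": "Lepidoptera", "kingdom": "Animalia"},
            {"species": "moth_c", "genus": "GenusC", "family": "FamilyC",
             "order": "Lepidoptera", "kingdom": "Animalia"},
            {"species": "npv_virus", "genus": "Alphabaculovirus",
             "family": "Baculoviridae", "order": "Lefavirales", "kingdom": "Viruses"},
        ]
    )
    # vertical descent: shared branch then per-species divergence
    genus_a_anc = mutate_copy_k2p(root, 0.02, kappa, rng)
    consensi = [
        ("A1SE1", "moth_a1", mutate_copy_k2p(genus_a_anc, 0.015, kappa, rng)),
        ("A2SE1", "moth_a2", mutate_copy_k2p(genus_a_anc, 0.015, kappa, rng)),
        ("BSE1", "moth_b", mutate_copy_k2p(root, 0.06, kappa, rng)),
        ("CSE1", "moth_c", mutate_copy_k2p(root, 0.20, kappa, rng)),
    ]
    if include_htt:
        donor = consensi[0][2]
        consensi.append(("NPVSE1", "npv_virus", mutate_copy_k2p(donor, 0.01, kappa, rng)))
    return consensi, taxonomy
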