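"""Seed-and-extend search against an exhaustive Smith-Waterman oracle."""

import numpy as np
import pytest

from sine_scout.core_io import GenomeRecord, RunConfig
from sine_scout.homology_search import (
    AlignmentHit,
    SearchParams,
    count_copies,
    merge_overlapping_hits,
    seed_and_extend_search,
    select_divergence_set,
)
from sine_scout.synthetic_data import mutate_copy_k2p
from _oracles import exhaustive_local_hits, rc


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, int(n))])


def _implant(genome: str, pos: int, seq: str) -> str:
    return genome[:pos] + seq + genome[pos + len(seq):]


class TestSeedAndExtend:
    def test_exact_implant_found_once(self, rng):
        query = _random_seq(rng, 200)
        g = _implant(_random_seq(rng, 50_000), 10_000, query)
        hits = seed_and_extend_search(query, [GenomeRecord("c", g)], min_id=0.8, min_len=100)
        assert len(hits) == 1
        (h,) = hits
        assert h.identity == 1.0
        assert abs(h.start - 10_000) <= 2 and abs(h.end - 10_200) <= 2
        assert h.strand == "+"

    def test_reverse_complement_implant(self, rng):
        query = _random_seq(rng, 200)
        g = _implant(_random_seq(rng, 50_000), 10_000, rc(query))
        hits = seed_and_extend_search(query, [GenomeRecord("c", g)], min_id=0.8, min_len=100)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert abs(hits[0].start - 10_000) <= 2

    def test_no_implant_no_hits(self, rng):
        query = _random_seq(rng, 263)
        genome = [GenomeRecord("c", _random_seq(rng, 50_000))]
        assert seed_and_extend_search(query, genome, min_id=0.80, min_len=100) == []
        assert exhaustive_local_hits(query, genome, 0.80, 100) == []

    def test_query_shorter_than_word_size_errors(self):
        with pytest.raises(ValueError):
            seed_and_extend_search("ACGT", [GenomeRecord("c", "ACGT" * 100)])

    def test_matches_oracle_on_divergent_implants(self, rng):
        """Hit set equals the exhaustive SW oracle (loci within 2 bp,
        identity within 0.01) on genomes carrying 0.05-0.15-divergence
        copies."""
        query = _random_seq(rng, 263)
        g = _random_seq(rng, 60_000)
        positions = [5_000, 20_000, 35_000, 50_000]
        for p, d in zip(positions, (0.05, 0.10, 0.15, 0.0)):
            copy = mutate_copy_k2p(query, d, 2.0, rng)
            g = _implant(g, p, copy if p % 2 == 0 else rc(copy))
        genome = [GenomeRecord("c", g)]
        mine = seed_and_extend_search(query, genome, min_id=0.80, min_len=100)
        oracle = exhaustive_local_hits(query, genome, 0.80, 100)
        assert len(mine) == len(oracle) == len(positions)
        for h, o in zip(mine, oracle):
            assert h.strand == o[3]
            assert abs(h.start - o[1]) <= 2 and abs(h.end - o[2]) <= 2
            assert abs(h.identity - o[4]) <= 0.01

    def test_invariant_under_contig_permutation_and_revcomp(self, rng):
        query = _random_seq(rng, 150)
        recs = []
        for i in range(3):
            g = _implant(_random_seq(rng, 10_000), 4_000, query)
            recs.append(GenomeRecord(f"c{i}", g))
        base = seed_and_extend_search(query, recs, min_id=0.9, min_len=100)
        permuted = seed_and_extend_search(query, recs[::-1], min_id=0.9, min_len=100)
        assert {(h.contig, h.start, h.end, h.strand) for h in base} == {
            (h.contig, h.start, h.end, h.strand) for h in permuted
        }
        flipped = [GenomeRecord(r.id, rc(r.seq)) for r in recs]
        mirror = seed_and_extend_search(query, flipped, min_id=0.9, min_len=100)
        n = 10_000
        assert {(h.contig, n - h.end, n - h.start) for h in base} == {
            (h.contig, h.start, h.end) for h in mirror
        }
        assert all(h.strand == "-" for h in mirror)


def _hit(start, end, identity, strand="+", aln_len=None):
    return AlignmentHit(
        contig="c", start=start, end=end, strand=strand, identity=identity,
        aln_len=aln_len or (end - start), qcov=1.0, qstart=0, qend=end - start,
    )


class TestMergeOverlapping:
    def test_identical_hits_collapse(self):
        assert len(merge_overlapping_hits([_hit(0, 100, 0.9), _hit(0, 100, 0.9)])) == 1

    def test_higher_identity_wins(self):
        kept = merge_overlapping_hits([_hit(100, 300, 0.9), _hit(150, 350, 0.85)])
        assert [(h.start, h.end) for h in kept] == [(100, 300)]

    def test_small_overlap_not_merged(self):
        kept = merge_overlapping_hits([_hit(0, 200, 0.9), _hit(150, 350, 0.85)])
        assert len(kept) == 2

    def test_opposite_strands_not_merged(self):
        kept = merge_overlapping_hits([_hit(0, 200, 0.9), _hit(0, 200, 0.85, strand="-")])
        assert len(kept) == 2

    def test_matches_bruteforce_greedy(self, rng):
        """Random overlapping sets resolve exactly as greedy-by-identity."""
        for _ in range(20):
            hits = [
                _hit(int(s), int(s + l), float(i), str(st))
                for s, l, i, st in zip(
                    rng.integers(0, 2_000, 30), rng.integers(60, 400, 30),
                    rng.uniform(0.7, 1.0, 30), rng.choice(["+", "-"], 30),
                )
            ]
            kept = merge_overlapping_hits(hits)
            expected = []
            for h in sorted(hits, key=lambda h: (-h.identity, -h.aln_len, h.contig, h.start)):
                if not any(
                    k.strand == h.strand
                    and min(h.end, k.end) - max(h.start, k.start)
                    > 0.5 * min(h.end - h.start, k.end - k.start)
                    for k in expected
                ):
                    expected.append(h)
            assert {(h.start, h.end, h.strand) for h in kept} == {
                (h.start, h.end, h.strand) for h in expected
            }


class TestCountCopies:
    def test_counts_implants(self, rng):
        consensus = _random_seq(rng, 263)
        g = _random_seq(rng, 80_000)
        for i in range(10):
            g = _implant(g, 5_000 + 7_000 * i, mutate_copy_k2p(consensus, 0.05, 2.0, rng))
        _, n = count_copies(consensus, [GenomeRecord("c", g)])
        assert n == 10

    def test_short_hit_excluded(self, rng):
        consensus = _random_seq(rng, 263)
        g = _implant(_random_seq(rng, 30_000), 10_000, consensus[:90])
        _, n = count_copies(consensus, [GenomeRecord("c", g)])
        assert n == 0

    def test_ambiguous_head_only_copies_excluded(self, rng):
        """Copies aligning only within the shared 120-bp head region do not
        count; a copy extending beyond it does."""
        consensus = _random_seq(rng, 263)
        g = _random_seq(rng, 40_000)
        g = _implant(g, 10_000, consensus[:120])   # head-only
        g = _implant(g, 25_000, consensus[:180])   # extends past the head
        genome = [GenomeRecord("c", g)]
        _, n_all = count_copies(consensus, genome)
        copies, n = count_copies(consensus, genome, ambiguous_region=(0, 120))
        assert n_all == 2
        assert n == 1
        assert copies[0].qend > 120

    def test_consensus_too_short_errors(self):
        with pytest.raises(ValueError):
            count_copies("ACGT" * 20, [GenomeRecord("c", "ACGT" * 1000)])


class TestDivergenceSet:
    def test_coverage_boundary(self):
        keep = _hit(0, 263, 0.9)
        keep.qcov = 0.80
        drop = _hit(300, 500, 0.9)
        drop.qcov = 0.79
        out = select_divergence_set("A" * 263, [keep, drop])
        assert out == [keep]

    def test_full_length_exact_copy_retained(self):
        h = _hit(0, 263, 1.0)
        assert select_divergence_set("A" * 263, [h]) == [h]

    def test_equals_bruteforce_filter(self, rng):
        cfg = RunConfig()
        hits = []
        for s, i, c in zip(
            rng.integers(0, 100_000, 200), rng.uniform(0.7, 1.0, 200),
            rng.uniform(0.5, 1.0, 200),
        ):
            h = _hit(int(s), int(s) + 263, float(i))
            h.qcov = float(c)
            hits.append(h)
        out = select_divergence_set("A" * 263, hits, cfg)
        brute = [h for h in hits if h.identity >= 0.80 and h.qcov >= 0.80]
        assert out == brute
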