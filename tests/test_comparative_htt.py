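"""Distance matrices, NJ trees, partner-LINE search and the HTT screen."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
import skbio

from sine_scout.core_io import GenomeRecord
from sine_scout.comparative_htt import (
    bipartitions,
    consensus_p_distance_matrix,
    find_partner_line_candidates,
    flag_htt_candidates,
    host_relatedness,
    neighbor_joining,
    nj_tree_with_bootstrap,
    orthologous_empty_site_check,
)
from sine_scout.synthetic_data import generate_species_panel, mutate_copy_k2p


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, int(n))])


def _dendropy_bipartitions(newick, labels):
    tns = dendropy.TaxonNamespace(labels)
    t = dendropy.Tree.get(data=newick + ";", schema="newick", taxon_namespace=tns)
    t.encode_bipartitions()
    return {b.split_bitmask for b in t.bipartition_encoding if not b.is_trivial()}


class TestPDistanceMatrix:
    def test_identical_pair_zero(self):
        dm = consensus_p_distance_matrix([("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")])
        assert dm.D[0, 1] == 0.0

    def test_two_differences_over_ten_sites(self):
        a = "AAACGTACGTTT"
        b = "AAACCTACCTTT"  # two internal substitutions
        dm = consensus_p_distance_matrix([("a", a), ("b", b)])
        assert dm.D[0, 1] == pytest.approx(2 / 12)

    def test_symmetry_diag_and_bruteforce(self, rng):
        root = _random_seq(rng, 150)
        consensi = [
            (f"s{i}", mutate_copy_k2p(root, float(rng.uniform(0, 0.25)), 2.0, rng))
            for i in range(10)
        ]
        dm = consensus_p_distance_matrix(consensi)
        assert np.allclose(dm.D, dm.D.T, equal_nan=True)
        assert np.all(np.diag(dm.D) == 0)
        # brute recount from pairwise alignments
        from sine_scout._align import global_align

        for i, j in itertools.combinations(range(10), 2):
            a, b = global_align(consensi[i][1], consensi[j][1])
            sites = sum(1 for x, y in zip(a, b) if x in "ACGT" and y in "ACGT")
            diffs = sum(1 for x, y in zip(a, b) if x in "ACGT" and y in "ACGT" and x != y)
            if sites == 0:
                assert np.isnan(dm.D[i, j])
            else:
                assert dm.D[i, j] == pytest.approx(diffs / sites)


class TestNeighborJoining:
    def test_additive_quartet_recovered(self):
        # ((a,b),(c,d)) with internal branch 3
        labels = list("abcd")
        D = np.array([
            [0, 2, 7, 7],
            [2, 0, 7, 7],
            [7, 7, 0, 2],
            [7, 7, 2, 0],
        ], dtype=float)
        tree = neighbor_joining(D, labels)
        assert frozenset("ab") in bipartitions(tree) or frozenset("cd") in bipartitions(tree)

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_matches_reference_nj_on_random_matrices(self, rng):
        """Topology equals scikit-bio's NJ on 100 random distance
        matrices (bipartition-set identity)."""
        for _ in range(100):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            pts = rng.random((n, 6))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(D, 0)
            mine = neighbor_joining(D, labels).newick()
            ref = str(skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels)))
            assert _dendropy_bipartitions(mine, labels) == _dendropy_bipartitions(ref, labels)

    def test_clones_are_siblings_with_full_support(self, rng):
        root = _random_seq(rng, 300)
        far1 = mutate_copy_k2p(root, 0.25, 2.0, rng)
        far2 = mutate_copy_k2p(far1, 0.25, 2.0, rng)
        consensi = [("c1", root), ("c2", root), ("x", far1), ("y", far2)]
        tree, newick = nj_tree_with_bootstrap(consensi, n_boot=100, seed=0)
        assert frozenset({"c1", "c2"}) in bipartitions(tree) or frozenset({"x", "y"}) in bipartitions(tree)
        supports = [c.support for c in _walk(tree) if c.support is not None]
        assert supports and min(supports) == 1.0

    def test_bootstrap_recovers_known_topology(self, rng):
        """Sequences simulated down a known 8-taxon tree: NJ recovers the
        generating clades and the reference NJ agrees on the same matrix."""
        root = _random_seq(rng, 400)
        tree_spec = {  # two-level hierarchy: 4 cherries
            "a1": ("A", 0.01), "a2": ("A", 0.01),
            "b1": ("B", 0.01), "b2": ("B", 0.01),
        }
        anc = {"A": mutate_copy_k2p(root, 0.08, 2.0, rng),
               "B": mutate_copy_k2p(root, 0.08, 2.0, rng)}
        consensi = [
            (name, mutate_copy_k2p(anc[clade], d, 2.0, rng))
            for name, (clade, d) in tree_spec.items()
        ]
        tree, _ = nj_tree_with_bootstrap(consensi, n_boot=100, seed=1)
        bps = bipartitions(tree)
        assert frozenset({"a1", "a2"}) in bps or frozenset({"b1", "b2"}) in bps


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


class TestPartnerLine:
    def test_implanted_line_reported(self, small_dataset):
        """The implanted 3-kb LINE sharing the family tail appears with
        ~84% tail identity and an intact long ORF."""
        ds = small_dataset
        tail50 = ds.truth.masters["SE1"][-50:]
        cands = find_partner_line_candidates(tail50, ds.genome)
        pl = ds.truth.partner_line
        matches = [
            c for c in cands
            if c.orf_ok and abs(c.start - pl["start"]) < 100 and abs(c.end - pl["end"]) < 100
        ]
        assert len(matches) == 1
        assert matches[0].tail_identity == pytest.approx(pl["tail_identity"], abs=0.05)
        assert matches[0].length >= 2000

    def test_no_shared_tail_empty(self, rng):
        genome = [GenomeRecord("c", _random_seq(rng, 30_000))]
        assert find_partner_line_candidates(_random_seq(rng, 50), genome) == []

    def test_frame_disruption_clears_orf_flag(self, rng):
        tail = _random_seq(rng, 50)
        orf = "ATG" + "".join(
            c for c in [_random_seq(rng, 3) for _ in range(800)]
            if c not in ("TAA", "TAG", "TGA")
        ) + "TAA"
        intact = _random_seq(rng, 3000) + orf[:2400] + tail
        disrupted = list(intact)
        for p in range(3000, len(disrupted) - 60, 90):  # stops in every frame
            disrupted[p : p + 9] = "TAATAGTGA"
        for genome_seq, expect in ((intact, True), ("".join(disrupted), False)):
            cands = find_partner_line_candidates(tail, [GenomeRecord("c", genome_seq)])
            assert cands and cands[0].orf_ok is expect


class TestHTTScreen:
    def test_relatedness_ranks(self):
        tax = pd.DataFrame([
            {"species": "a", "genus": "G", "family": "F", "order": "O", "kingdom": "Animalia"},
            {"species": "b", "genus": "G", "family": "F", "order": "O", "kingdom": "Animalia"},
            {"species": "c", "genus": "H", "family": "F", "order": "O", "kingdom": "Animalia"},
            {"species": "d", "genus": "X", "family": "Y", "order": "Z", "kingdom": "Animalia"},
            {"species": "v", "genus": "V", "family": "W", "order": "Q", "kingdom": "Viruses"},
        ])
        assert host_relatedness(tax, "a", "b") == "same_genus"
        assert host_relatedness(tax, "a", "c") == "same_family"
        assert host_relatedness(tax, "a", "d") == "cross_family"
        assert host_relatedness(tax, "a", "v") == "cross_kingdom"
        with pytest.raises(ValueError):
            host_relatedness(tax, "a", "nope")

    def test_congeneric_identity_not_flagged(self, rng):
        tax = pd.DataFrame([
            {"species": "a", "genus": "G", "family": "F", "order": "O", "kingdom": "Animalia"},
            {"species": "b", "genus": "G", "family": "F", "order": "O", "kingdom": "Animalia"},
        ])
        seq = _random_seq(rng, 263)
        out = flag_htt_candidates(
            [("f1", "a", seq), ("f2", "b", mutate_copy_k2p(seq, 0.02, 2.0, rng))], tax
        )
        assert out[0].consensus_identity > 0.95
        assert not out[0].flagged

    def test_htt_panel_flags_the_virus_pair(self):
        consensi, tax = generate_species_panel(7, include_htt=True)
        out = flag_htt_candidates(consensi, tax)
        flagged = [c for c in out if c.flagged]
        assert flagged
        assert all("npv_virus" in (c.species_a, c.species_b) for c in flagged)
        assert all(c.host_relatedness == "cross_kingdom" for c in flagged)

    def test_vertical_panels_produce_no_flags(self):
        for seed in range(5):
            consensi, tax = generate_species_panel(100 + seed, include_htt=False)
            assert not any(c.flagged for c in flag_htt_candidates(consensi, tax))


class TestEmptySiteCheck:
    def test_joined_flanks_found(self, rng):
        left, right = _random_seq(rng, 400), _random_seq(rng, 400)
        related = [GenomeRecord("r1", _random_seq(rng, 2000) + left + right + _random_seq(rng, 2000))]
        ev = orthologous_empty_site_check(left, right, related)
        assert ev == {"r1": "found"}

    def test_missing_flanks_not_found(self, rng):
        ev = orthologous_empty_site_check(
            _random_seq(rng, 400), _random_seq(rng, 400),
            [GenomeRecord("r1", _random_seq(rng, 4000))],
        )
        assert ev == {"r1": "not_found"}

    def test_intervening_element_breaks_adjacency(self, rng):
        left, right = _random_seq(rng, 400), _random_seq(rng, 400)
        related = [GenomeRecord(
            "r1", _random_seq(rng, 1000) + left + _random_seq(rng, 1000) + right + _random_seq(rng, 1000)
        )]
        ev = orthologous_empty_site_check(left, right, related)
        assert ev == {"r1": "not_found"}

    def test_generator_htt_empty_sites(self, small_dataset):
        ds = small_dataset
        h = ds.truth.htt
        virus = ds.virus_records[0].seq
        left = virus[h["insert_start"] - 500 : h["insert_start"]]
        right = virus[h["element_end"] : h["element_end"] + 500]
        ev = orthologous_empty_site_check(left, right, ds.related_virus_records)
        assert set(ev.values()) == {"found"}
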