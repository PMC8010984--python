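"""Promoter-box scanning, head classification and tail-repeat detection."""

import numpy as np
import pytest

from sine_scout.structure_annotator import (
    BoxMotifs,
    classify_head,
    detect_tail_repeat,
    scan_pol3_boxes,
)
from sine_scout.synthetic_data import (
    A_BOX_SEQ,
    B_BOX_SEQ,
    C_BOX_SEQ,
    IE_BOX_SEQ,
    divergence_for_identity,
    make_head_refs,
    mutate_copy_k2p,
)
from _oracles import brute_tandem


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, int(n))])


class TestPol3Boxes:
    def test_planted_type2_exact_coords(self, rng):
        seq = list(_random_seq(rng, 300))
        seq[8 : 8 + len(A_BOX_SEQ)] = A_BOX_SEQ
        seq[55 : 55 + len(B_BOX_SEQ)] = B_BOX_SEQ
        res = scan_pol3_boxes("".join(seq))
        assert res.type == "pol3_type2"
        assert res.boxes["A"] == (8, 8 + len(A_BOX_SEQ))
        assert res.boxes["B"] == (55, 55 + len(B_BOX_SEQ))

    def test_planted_type1_in_order(self, rng):
        seq = list(_random_seq(rng, 300))
        seq[10 : 10 + len(A_BOX_SEQ)] = A_BOX_SEQ
        seq[35 : 35 + len(IE_BOX_SEQ)] = IE_BOX_SEQ
        seq[50 : 50 + len(C_BOX_SEQ)] = C_BOX_SEQ
        res = scan_pol3_boxes("".join(seq))
        assert res.type == "pol3_type1"
        a, i, c = res.boxes["A"], res.boxes["IE"], res.boxes["C"]
        assert a[0] < i[0] < c[0]

    def test_degenerate_position_changes_still_recovered(self, rng):
        """Swaps within the IUPAC class at degenerate motif positions never
        cost the architecture (A box = TRGCNNARYNNG: R at +1/+7, Y at +8)."""
        seq = list(_random_seq(rng, 300))
        seq[8 : 8 + len(A_BOX_SEQ)] = A_BOX_SEQ
        seq[55 : 55 + len(B_BOX_SEQ)] = B_BOX_SEQ
        seq[9] = "G" if seq[9] == "A" else "A"      # R position
        seq[16] = "C" if seq[16] == "T" else "T"    # Y position
        res = scan_pol3_boxes("".join(seq))
        assert res.type == "pol3_type2"
        assert res.boxes["A"] == (8, 20)
        assert res.mismatches == {"A": 0, "B": 0}

    def test_single_mismatch_recovered(self, rng):
        seq = list(_random_seq(rng, 300))
        seq[8 : 8 + len(A_BOX_SEQ)] = A_BOX_SEQ
        seq[55 : 55 + len(B_BOX_SEQ)] = B_BOX_SEQ
        seq[55] = "A"  # B box starts with G
        res = scan_pol3_boxes("".join(seq))
        assert res.type == "pol3_type2"
        assert res.boxes["B"] == (55, 64)

    def test_false_positive_rate_on_random_sequence(self):
        """At default stringency random 300-bp sequence yields an
        architecture in under 5% of trials."""
        rng = np.random.default_rng(202)
        fp = sum(
            scan_pol3_boxes(_random_seq(rng, 300)).type != "none"
            for _ in range(300)
        )
        assert fp / 300 < 0.05

    def test_spacing_constraint_enforced(self, rng):
        seq = list(_random_seq(rng, 300))
        seq[8 : 8 + len(A_BOX_SEQ)] = A_BOX_SEQ
        seq[25 : 25 + len(B_BOX_SEQ)] = B_BOX_SEQ  # only 5 bp after A end
        res = scan_pol3_boxes("".join(seq), BoxMotifs(max_total_mismatch=0))
        assert res.type == "none"


class TestClassifyHead:
    def test_exact_trna_head(self, rng):
        refs = make_head_refs(rng)
        trna = refs[0][2]
        consensus = trna + _random_seq(rng, 190)
        call = classify_head(consensus, refs)
        assert call.origin == "tRNA"
        assert call.head_identity == 1.0

    def test_unknown_below_floor_without_boxes(self, rng):
        refs = make_head_refs(rng)
        consensus = _random_seq(rng, 300)
        call = classify_head(consensus, refs)
        assert call.origin == "unknown"

    def test_5s_head_at_63_percent_identity(self):
        """A head derived from a 5S reference at ~63% identity classifies
        as 5S even though the identity is far below 100%."""
        rng = np.random.default_rng(5)
        refs = make_head_refs(rng)
        r5s = next(r for r in refs if r[1] == "5S_rRNA")[2]
        # 37% of sites substituted -> ~63% identity (beyond the simulator's
        # divergence range, so mutate directly)
        head = list(r5s)
        sites = rng.choice(len(head), size=round(0.37 * len(head)), replace=False)
        for p in sites:
            head[p] = rng.choice([b for b in "ACGT" if b != head[p]])
        consensus = "".join(head) + _random_seq(rng, 250)
        call = classify_head(consensus, refs)
        assert call.origin == "5S_rRNA"
        assert 0.5 < call.head_identity < 0.8

    def test_reference_order_invariance_and_label_swap(self, rng):
        refs = make_head_refs(rng)
        consensus = refs[0][2] + _random_seq(rng, 200)
        a = classify_head(consensus, refs)
        b = classify_head(consensus, refs[::-1])
        assert (a.origin, a.best_ref) == (b.origin, b.best_ref)
        swapped = [(rid, {"tRNA": "5S_rRNA", "5S_rRNA": "tRNA"}[rc], seq) for rid, rc, seq in refs]
        c = classify_head(consensus, swapped)
        assert c.origin == "5S_rRNA"  # same best ref, swapped class label

    def test_empty_refs_error(self):
        with pytest.raises(ValueError):
            classify_head("A" * 200, [])


class TestTailRepeat:
    def test_gt_dinucleotide_tail(self, rng):
        cons = _random_seq(rng, 245) + "AC" + "GT" * 8
        t = detect_tail_repeat(cons)
        assert t is not None
        assert t.unit == "GT"
        assert t.n_units >= 5

    def test_random_tail_none(self):
        rng = np.random.default_rng(77)
        # random sequence only rarely ends in a qualifying tandem run
        hits = sum(
            detect_tail_repeat(_random_seq(rng, 300)) is not None for _ in range(100)
        )
        assert hits <= 5

    def test_tetramer_beats_contained_dimer(self, rng):
        cons = _random_seq(rng, 244) + "ATGT" * 4
        t = detect_tail_repeat(cons)
        assert t.unit == "ATGT"
        assert t.n_units == 4

    def test_primitive_unit_enforced(self, rng):
        cons = _random_seq(rng, 244) + "AT" * 8
        t = detect_tail_repeat(cons)
        assert t.unit == "AT"

    def test_matches_bruteforce_on_random_windows(self):
        rng = np.random.default_rng(13)
        agree = 0
        for i in range(300):
            seq = _random_seq(rng, 70)
            if i % 3 == 0:  # plant a tandem tail in a third of the cases
                unit = ["GT", "TAT", "ATGT", "TGTTA", "A"][i % 5]
                n = int(rng.integers(3, 9))
                seq = seq[: 70 - len(unit) * n] + unit * n
            got = detect_tail_repeat(seq, window=60)
            want = brute_tandem(seq, window=60)
            assert (got.unit if got else None) == want
            agree += 1
        assert agree == 300
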