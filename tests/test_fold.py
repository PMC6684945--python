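"""Folding engine: DP optimality, segmentation and hairpin metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from follimir.fold import (
    MIN_HAIRPIN_LOOP,
    NotHairpinError,
    SecondaryStructure,
    _pair_code,
    annotate_stemloop,
    dotbracket_from_pair_table,
    fold_mfe,
    measure,
    pair_table_from_dotbracket,
    structure_energy,
)


def enumerate_structures(seq):
    """All nested structures over canonical pairs with min loop 3 (oracle)."""

    def rec(positions):
        if not positions:
            yield []
            return
        i, rest = positions[0], positions[1:]
        yield from rec(rest)
        for j in rest:
            if j - i > MIN_HAIRPIN_LOOP and _pair_code(seq[i], seq[j]) >= 0:
                inside = tuple(k for k in rest if i < k < j)
                outside = tuple(k for k in rest if k > j)
                for a in rec(inside):
                    for b in rec(outside):
                        yield [(i, j)] + a + b

    for pairs in rec(tuple(range(len(seq)))):
        pt = np.full(len(seq), -1, int)
        for i, j in pairs:
            pt[i], pt[j] = j, i
        yield pt


def max_pairs_brute(seq, i=0, j=None):
    """Exhaustive-recursion maximum matching (no DP memoization), an
    independent oracle for the pair_count folding mode."""
    if j is None:
        j = len(seq) - 1
    if j - i < MIN_HAIRPIN_LOOP + 1:
        return 0
    best = max_pairs_brute(seq, i + 1, j)
    for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
        if _pair_code(seq[i], seq[k]) >= 0:
            best = max(best, 1 + max_pairs_brute(seq, i + 1, k - 1) + max_pairs_brute(seq, k + 1, j))
    return best


def make_structure(seq, db):
    pt = pair_table_from_dotbracket(db)
    return SecondaryStructure(seq, pt, db, structure_energy(seq, pt))


class TestFoldMfe:
    def test_perfect_gc_hairpin_meets_energy_gate(self):
        st_ = fold_mfe("G" * 25 + "TTCG" + "C" * 25)
        assert st_.n_pairs == 25
        assert st_.free_energy <= -15.0

    def test_no_complementarity_folds_open(self):
        st_ = fold_mfe("A" * 10)
        assert st_.n_pairs == 0 and st_.free_energy == 0.0

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGTNACGTT")

    def test_mfe_equals_enumeration_minimum(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(10, 16))
            seq = "".join(rng.choice(list("ACGT"), n))
            st_ = fold_mfe(seq)
            best = min(structure_energy(seq, pt) for pt in enumerate_structures(seq))
            assert st_.free_energy == pytest.approx(best, abs=1e-6)

    def test_pair_count_mode_equals_nussinov_maximum(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(10, 16))
            seq = "".join(rng.choice(list("ACGT"), n))
            st_ = fold_mfe(seq, model="pair_count")
            maxp = max(int((pt >= 0).sum()) // 2 for pt in enumerate_structures(seq))
            assert st_.n_pairs == maxp

    def test_added_gc_stack_never_raises_energy(self):
        energies = [fold_mfe("G" * k + "TTCG" + "C" * k).free_energy for k in range(4, 12)]
        assert all(b <= a for a, b in zip(energies, energies[1:]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=10, max_size=18))
    def test_structure_is_well_formed(self, seq):
        st_ = fold_mfe(seq)
        pt = st_.pair_table
        for i, j in enumerate(pt):
            if j >= 0:
                assert pt[j] == i and j != i
                if j > i:
                    assert j - i > MIN_HAIRPIN_LOOP
                    assert _pair_code(st_.sequence[i], st_.sequence[j]) >= 0
        assert dotbracket_from_pair_table(pt) == st_.dot_bracket
        assert pair_table_from_dotbracket(st_.dot_bracket).tolist() == pt.tolist()

    def test_determinism(self):
        seq = "GGCAGCUGUAACGGUUAGCUGCC"
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert a.dot_bracket == b.dot_bracket and a.free_energy == b.free_energy


class TestSegmentation:
    def test_perfect_stem_and_loop(self):
        s = make_structure("G" * 25 + "TTCG" + "C" * 25, "(" * 25 + "." * 4 + ")" * 25)
        seg = annotate_stemloop(s)
        assert seg.loop_len == 4
        assert len(seg.stem_pairs) == 25
        assert seg.loops == []

    def test_single_five_prime_bulge(self):
        # 6 pairs, a 3-nt bulge on the 5' arm, then 4 more pairs and loop
        db = "((((((...((((....))))))))))"
        seq = "GGGGGG" + "AAA" + "GGGG" + "TTTT" + "CCCC" + "CCCCCC"
        s = make_structure(seq, db)
        seg = annotate_stemloop(s)
        assert len(seg.loops) == 1
        lp = seg.loops[0]
        assert (lp.run5[1], lp.run3[1]) == (3, 0)
        assert lp.biased

    def test_multibranch_rejected(self):
        db = "((..((((....))))..((((....))))..))"
        seq = "GC" + "AT" + "GGGG" + "TTTT" + "CCCC" + "AT" + "GGGG" + "TTTT" + "CCCC" + "AT" + "GC"
        s = make_structure(seq, db)
        with pytest.raises(NotHairpinError):
            annotate_stemloop(s)

    def test_no_pairs_rejected(self):
        s = make_structure("A" * 12, "." * 12)
        with pytest.raises(NotHairpinError):
            annotate_stemloop(s)

    def test_flanking_helix_ignored(self):
        # a small 4-pair helix next to a 10-pair stem-loop: the larger wins
        db = "((((....))))" + ".." + "((((((((((....))))))))))"
        seq = "GGGG" + "AAAA" + "CCCC" + "TT" + "G" * 10 + "AAAA" + "C" * 10
        seg = annotate_stemloop(make_structure(seq, db))
        assert len(seg.stem_pairs) == 10


class TestMeasure:
    def _perfect(self, stem=25, loop=4):
        seq = "G" * stem + "T" * loop + "C" * stem
        db = "(" * stem + "." * loop + ")" * stem
        s = make_structure(seq, db)
        return s, annotate_stemloop(s)

    def test_fully_paired_mature(self):
        s, seg = self._perfect()
        m = measure(s, seg, (0, 22))
        assert m.mature_errors == 0
        assert m.mature_bp == 22
        assert m.mature_pct_in_stem == 100.0
        assert m.stem_bp == 25
        assert m.hairpin_len == 54
        assert m.loop_len == 4

    def test_mature_extending_into_terminal_loop(self):
        # 22-nt mature whose last 5 nt fall in the terminal loop
        s, seg = self._perfect(stem=17, loop=6)
        m = measure(s, seg, (0, 22))
        assert m.mature_pct_in_stem == pytest.approx(100 * 17 / 22)
        assert m.mature_errors == 5
        assert m.mature_bp == 17

    def test_symmetric_internal_loop_in_mature(self):
        # 8 pairs, symmetric 2+2 internal loop, 6 pairs, loop 4
        db = "((((((((.." + "((((((" + "...." + "))))))" + "..))))))))"
        seq = "GGGGGGGG" + "AA" + "GGGGGG" + "TTTT" + "CCCCCC" + "AA" + "CCCCCCCC"
        s = make_structure(seq, db)
        seg = annotate_stemloop(s)
        m = measure(s, seg, (0, 14))  # mature spans the internal loop's 5' side
        assert m.mature_bulge_max_nt == 4
        assert m.mature_biased_bulges == 0
        assert m.mature_biased_errors_max == 2

    def test_representation_invariance(self):
        s, seg = self._perfect()
        via_db = make_structure(s.sequence, s.dot_bracket)
        m1 = measure(s, seg, (0, 22))
        m2 = measure(via_db, annotate_stemloop(via_db), (0, 22))
        assert m1 == m2
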