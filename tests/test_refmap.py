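"""Tag-to-precursor alignment and the tiered classification cascade."""

import numpy as np
import pytest

from follimir.preprocess import UniqueTag, revcomp
from follimir.refmap import (
    MatureInterval,
    PrecursorRecord,
    align_tag,
    classify_cascade,
    extract_candidate_precursor,
    genome_search,
)


def make_precursor(rng, mature_len=22, arm="5p", pre_id="mir-x"):
    stem = "".join(rng.choice(list("ACGT"), mature_len + 3, p=[0.15, 0.35, 0.35, 0.15]))
    loop = "".join(rng.choice(list("ACGT"), 8))
    pre = stem + loop + revcomp(stem)
    iv = (0, mature_len) if arm == "5p" else (len(pre) - mature_len, len(pre))
    return PrecursorRecord(pre_id, "dre", pre, [MatureInterval(*iv, arm)]), pre[iv[0] : iv[1]]


def brute_force_align(tag, pre_seq, max_mismatch):
    """Oracle: every offset x substitution count, fewest mismatches then leftmost."""
    best = None
    for off in range(len(pre_seq) - len(tag) + 1):
        mm = sum(1 for a, b in zip(tag, pre_seq[off : off + len(tag)]) if a != b)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, off)
    return best


class TestAlignTag:
    def test_identity_on_annotated_mature(self):
        rng = np.random.default_rng(0)
        pre, mature = make_precursor(rng)
        aln = align_tag(mature, pre)
        assert aln.mismatches == 0
        assert aln.end_shifts == (0, 0)
        assert aln.arm == "5p" and aln.on_annotated_mature

    def test_two_substitutions_rejected(self):
        rng = np.random.default_rng(1)
        pre, mature = make_precursor(rng)
        bad = "TT" + mature[2:] if mature[:2] not in ("TT",) else "AA" + mature[2:]
        mutated = "".join(
            ("A" if c != "A" else "C") if k < 2 else c for k, c in enumerate(mature)
        )
        assert align_tag(mutated, pre) is None

    def test_shifted_isomir_with_one_substitution(self):
        rng = np.random.default_rng(2)
        pre, mature = make_precursor(rng)
        tag = pre.sequence[2:24]  # +2 shift at the 5' end
        tag = tag[:10] + ("A" if tag[10] != "A" else "C") + tag[11:]
        aln = align_tag(tag, pre)
        assert aln is not None
        assert aln.mismatches == 1
        assert aln.end_shifts[0] == 2

    def test_shift_beyond_end_window_rejected(self):
        rng = np.random.default_rng(3)
        pre, mature = make_precursor(rng)
        tag = pre.sequence[5:27]  # +5 shift exceeds the default +/-4 window
        assert align_tag(tag, pre, end_window=4) is None
        assert align_tag(tag, pre, end_window=5) is not None

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pre, mature = make_precursor(rng)
            n = len(pre.sequence)
            start = int(rng.integers(0, n - 20))
            tag = list(pre.sequence[start : start + 20])
            if rng.random() < 0.7:
                p = int(rng.integers(0, 20))
                tag[p] = "ACGT"[(("ACGT".index(tag[p])) + 1) % 4]
            tag = "".join(tag)
            oracle = brute_force_align(tag, pre.sequence, 1)
            aln = align_tag(tag, pre, end_window=60)  # wide window isolates the scan
            if oracle is None:
                assert aln is None
            else:
                assert (aln.mismatches, aln.offset) == oracle


class TestCascade:
    def build_world(self, seed=5):
        rng = np.random.default_rng(seed)
        known, known_mat = make_precursor(rng, pre_id="dre-mir-1")
        other, other_mat = make_precursor(rng, pre_id="mir-99")
        other.species = "xsp"
        novel_stem = "".join(rng.choice(list("ACGT"), 25, p=[0.15, 0.35, 0.35, 0.15]))
        novel_hp = novel_stem + "ACGTACGT" + revcomp(novel_stem)
        genome = {
            "chr1": "".join(rng.choice(list("ACGT"), 400))
            + novel_hp
            + "".join(rng.choice(list("ACGT"), 400))
            + other_mat
            + "".join(rng.choice(list("ACGT"), 100))
        }
        return known, known_mat, other, other_mat, novel_stem, genome

    def test_tier_assignment(self):
        known, known_mat, other, other_mat, novel_stem, genome = self.build_world()
        tags = [
            UniqueTag(known_mat, {"s1": 10}),
            UniqueTag(other_mat, {"s1": 7}),
            UniqueTag(novel_stem[:22], {"s1": 5}),
            UniqueTag("AT" * 11, {"s1": 1}),
        ]
        out = classify_cascade(tags, [known], [other], genome)
        tiers = {r.mature_seq: r.tier for r in out}
        assert tiers[known_mat] == "known"
        assert tiers[other_mat] == "conserved_novel"
        assert tiers[novel_stem[:22]] == "novel_candidate"
        assert any(r.tier == "unmapped" for r in out)
        # exclusivity: each mature sequence in exactly one tier
        assert len(out) == len({r.mature_seq for r in out})

    def test_opposite_arm_variant_labelled_p3(self):
        known, known_mat, *_ = self.build_world()
        # the annotated arm is 5p; a read from the 3' arm is an arm variant
        opp = known.sequence[-23:-1]
        out = classify_cascade([UniqueTag(opp, {"s1": 4})], [known], [], {"chr1": "A" * 100})
        (rec,) = [r for r in out if r.tier == "known_arm_variant"]
        assert rec.mirna_id.endswith("-p3")
        assert rec.arm == "3p"

    def test_isomir_counts_merge_into_known(self):
        known, known_mat, *_ = self.build_world()
        shifted = known.sequence[1:23]
        out = classify_cascade(
            [UniqueTag(known_mat, {"s1": 10}), UniqueTag(shifted, {"s1": 3})],
            [known],
            [],
            {"chr1": "A" * 100},
        )
        (rec,) = [r for r in out if r.tier == "known"]
        assert rec.counts["s1"] == 13
        assert rec.mature_seq == known_mat

    def test_genome_required_for_novel_tier(self):
        with pytest.raises(ValueError):
            classify_cascade([UniqueTag("ACGT" * 6, {"s1": 1})], [], [], None)


class TestGenomeSearch:
    def test_both_strands(self):
        genome = {"chr1": "AAAA" + "GGCATCGATCGTTAGCCATGCA" + "TTTT"}
        seq = "GGCATCGATCGTTAGCCATGCA"
        assert genome_search(genome, seq) == ("chr1", 4, 26, "+")
        assert genome_search(genome, revcomp(seq)) == ("chr1", 4, 26, "-")
        assert genome_search(genome, "C" * 22) is None


class TestCandidateWindows:
    def test_plus_strand_windows(self):
        genome = {"chr1": "".join(np.random.default_rng(8).choice(list("ACGT"), 500))}
        locus = ("chr1", 200, 222, "+")
        (wa, ma), (wb, mb) = extract_candidate_precursor(genome, locus, flank=100)
        assert wa == genome["chr1"][100:222] and ma == (100, 122)
        assert wb == genome["chr1"][200:322] and mb == (0, 22)
        assert wa[ma[0] : ma[1]] == genome["chr1"][200:222]

    def test_contig_start_clipped(self):
        genome = {"chr1": "".join(np.random.default_rng(9).choice(list("ACGT"), 300))}
        (wa, ma), _ = extract_candidate_precursor(genome, ("chr1", 10, 32, "+"), flank=100)
        assert wa == genome["chr1"][0:32] and ma == (10, 32)

    def test_minus_strand_is_reverse_complement(self):
        genome = {"chr1": "".join(np.random.default_rng(10).choice(list("ACGT"), 500))}
        locus = ("chr1", 200, 222, "-")
        (wa, ma), (wb, mb) = extract_candidate_precursor(genome, locus, flank=50)
        assert wa == revcomp(genome["chr1"][200:272])
        assert wa[ma[0] : ma[1]] == revcomp(genome["chr1"][200:222])
        assert wb == revcomp(genome["chr1"][150:222])
        assert wb[mb[0] : mb[1]] == revcomp(genome["chr1"][200:222])

    def test_locus_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            extract_candidate_precursor({"chr1": "ACGT" * 50}, ("chr1", 190, 230, "+"))
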