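"""Tiered classification of unique tags against precursor references and genome.

The cascade mirrors small RNA annotation practice: a tag is first aligned
(ungapped, at most one mismatch, up to +/-4 nt end variation) to same-species
precursors; hits on an annotated mature arm are *known* miRNAs, hits on the
unannotated opposite arm are known arm variants (labelled p5/p3 by the arm
they map to).  Remaining tags are aligned to other-species precursors
(*conserved novel*), and tags still unplaced are searched exactly against the
genome on both strands (*novel candidates* to be folded and screened).

Internal coordinates are 0-based half-open; emitted GFF3 is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .preprocess import UniqueTag, revcomp, normalize

DEFAULT_END_WINDOW = 4
DEFAULT_FLANK = 100


@dataclass
class MatureInterval:
    start: int
    end: int  # half-open
    arm: str  # "5p" | "3p"


@dataclass
class PrecursorRecord:
    """A hairpin reference sequence with annotated mature arm interval(s)."""

    id: str
    species: str
    sequence: str
    matures: list[MatureInterval] = field(default_factory=list)
    locus: tuple[str, int, int, str] | None = None  # (chrom, start, end, strand)

    def __post_init__(self):
        self.sequence = normalize(self.sequence)
        for m in self.matures:
            if not (0 <= m.start < m.end <= len(self.sequence)):
                raise ValueError(f"mature interval outside precursor {self.id}")
        armed = sorted(self.matures, key=lambda m: m.start)
        if len(armed) == 2 and not (armed[0].arm == "5p" and armed[1].arm == "3p"):
            raise ValueError(f"5p interval must precede 3p in {self.id}")

    def mature_seq(self, arm: str) -> str | None:
        for m in self.matures:
            if m.arm == arm:
                return self.sequence[m.start : m.end]
        return None


@dataclass
class TagAlignment:
    """An ungapped placement of a tag on a precursor."""

    tag_seq: str
    precursor_id: str
    offset: int
    mismatches: int
    arm: str  # "5p" | "3p" | "loop"
    end_shifts: tuple[int, int]  # (5' shift, 3' shift) vs the annotated mature
    on_annotated_mature: bool


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def align_tag(
    tag: UniqueTag | str,
    precursor: PrecursorRecord,
    max_mismatch: int = 1,
    end_window: int = DEFAULT_END_WINDOW,
) -> TagAlignment | None:
    """Best ungapped alignment of a tag to a precursor, or None.

    Every offset is scanned; an alignment is valid when substitutions are at
    most ``max_mismatch`` and, if the tag overlaps an annotated mature arm (by
    at least half the tag length), both end shifts relative to that arm stay
    within ``end_window``.  The best alignment has the fewest mismatches, ties
    broken by the smallest offset.
    """
    seq = tag.sequence if isinstance(tag, UniqueTag) else normalize(tag)
    pre = precursor.sequence
    L, n = len(seq), len(pre)
    best: TagAlignment | None = None
    for off in range(0, n - L + 1):
        mm = _mismatches(seq, pre[off : off + L])
        if mm > max_mismatch:
            continue
        arm, shifts, on_mature = "loop", (0, 0), False
        overlapped = None
        for m in precursor.matures:
            ov = min(off + L, m.end) - max(off, m.start)
            if ov >= 0.5 * L:
                overlapped = m
                break
        if overlapped is not None:
            shifts = (off - overlapped.start, (off + L) - overlapped.end)
            if abs(shifts[0]) > end_window or abs(shifts[1]) > end_window:
                continue
            arm, on_mature = overlapped.arm, True
        else:
            # opposite/unannotated arm: side of the precursor midpoint by tag
            # center; tags straddling the midpoint are loop-spanning
            center = off + L / 2
            if off + L <= n / 2 + 2:
                arm = "5p"
            elif off >= n / 2 - 2:
                arm = "3p"
            else:
                arm = "5p" if center < n / 2 else "3p" if center > n / 2 else "loop"
        cand = TagAlignment(seq, precursor.id, off, mm, arm, shifts, on_mature)
        if best is None or (mm, off) < (best.mismatches, best.offset):
            best = cand
    return best


@dataclass
class ClassifiedMiRNA:
    """One mature miRNA (or candidate) with its tier and merged counts."""

    mirna_id: str
    mature_seq: str
    tier: str  # known | known_arm_variant | conserved_novel | novel_candidate | unmapped
    source: str  # precursor id or locus string
    counts: dict[str, int]
    arm: str | None = None
    locus: tuple[str, int, int, str] | None = None  # mature locus on the genome
    member_tags: list[str] = field(default_factory=list)


def genome_search(genome: dict[str, str], seq: str) -> tuple[str, int, int, str] | None:
    """First exact occurrence of seq in the genome, either strand.

    Plus strand is searched first, contigs in dict order; coordinates are
    always on the plus strand, half-open.
    """
    rc = revcomp(seq)
    for chrom, contig in genome.items():
        pos = contig.find(seq)
        if pos >= 0:
            return (chrom, pos, pos + len(seq), "+")
        pos = contig.find(rc)
        if pos >= 0:
            return (chrom, pos, pos + len(seq), "-")
    return None


def classify_cascade(
    tags: list[UniqueTag],
    same_species: list[PrecursorRecord],
    other_species: list[PrecursorRecord],
    genome: dict[str, str] | None,
    max_mismatch: int = 1,
    end_window: int = DEFAULT_END_WINDOW,
) -> list[ClassifiedMiRNA]:
    """Run the strict classification cascade over family-unannotated tags.

    Tags that align to the same annotated mature arm merge their counts into
    one known miRNA whose representative sequence is the annotated mature.
    Arm-variant and conserved-novel calls group by (precursor, arm) with the
    highest-count member tag as representative; novel candidates group by tag
    sequence.
    """
    samples: list[str] = []
    for t in tags:
        for s in t.counts:
            if s not in samples:
                samples.append(s)

    def empty_counts() -> dict[str, int]:
        return dict.fromkeys(samples, 0)

    def add_counts(dst: dict[str, int], src: dict[str, int]) -> None:
        for s, c in src.items():
            dst[s] = dst.get(s, 0) + c

    known: dict[tuple[str, str], ClassifiedMiRNA] = {}
    variants: dict[tuple[str, str], ClassifiedMiRNA] = {}
    conserved: dict[tuple[str, str], ClassifiedMiRNA] = {}
    novel: dict[str, ClassifiedMiRNA] = {}
    unmapped: list[ClassifiedMiRNA] = []

    for tag in tags:
        if tag.family is not None:
            continue  # contaminant families never enter the cascade
        placed = False

        # (a)/(b) same-species precursors
        hits = []
        for pre in same_species:
            aln = align_tag(tag, pre, max_mismatch, end_window)
            if aln is not None:
                hits.append((aln.mismatches, not aln.on_annotated_mature, pre, aln))
        if hits:
            hits.sort(key=lambda h: (h[0], h[1]))
            _, _, pre, aln = hits[0]
            if aln.on_annotated_mature:
                key = (pre.id, aln.arm)
                rec = known.get(key)
                if rec is None:
                    rec = ClassifiedMiRNA(
                        mirna_id=f"{pre.id}-{aln.arm}",
                        mature_seq=pre.mature_seq(aln.arm),
                        tier="known",
                        source=pre.id,
                        counts=empty_counts(),
                        arm=aln.arm,
                        locus=pre.locus,
                    )
                    known[key] = rec
            elif aln.arm in ("5p", "3p"):
                key = (pre.id, aln.arm)
                rec = variants.get(key)
                if rec is None:
                    label = "p5" if aln.arm == "5p" else "p3"
                    rec = ClassifiedMiRNA(
                        mirna_id=f"{pre.id}-{label}",
                        mature_seq=tag.sequence,
                        tier="known_arm_variant",
                        source=pre.id,
                        counts=empty_counts(),
                        arm=aln.arm,
                        locus=pre.locus,
                    )
                    variants[key] = rec
            else:
                rec = None  # loop-spanning tag: fall through the cascade
            if rec is not None:
                add_counts(rec.counts, tag.counts)
                rec.member_tags.append(tag.sequence)
                placed = True
        if placed:
            continue

        # (c) other-species precursors -> conserved novel
        hits = []
        for pre in other_species:
            aln = align_tag(tag, pre, max_mismatch, end_window)
            if aln is not None:
                hits.append((aln.mismatches, pre, aln))
        if hits:
            hits.sort(key=lambda h: h[0])
            _, pre, aln = hits[0]
            key = (pre.id, aln.arm)
            rec = conserved.get(key)
            if rec is None:
                locus = genome_search(genome, tag.sequence) if genome else None
                rec = ClassifiedMiRNA(
                    mirna_id=f"{pre.species}-{pre.id}",
                    mature_seq=tag.sequence,
                    tier="conserved_novel",
                    source=pre.id,
                    counts=empty_counts(),
                    arm=aln.arm,
                    locus=locus,
                )
                conserved[key] = rec
            add_counts(rec.counts, tag.counts)
            rec.member_tags.append(tag.sequence)
            continue

        # (d) exact genome search -> novel candidate
        if genome is None:
            raise ValueError("genome required for the novel tier but not provided")
        locus = genome_search(genome, tag.sequence)
        if locus is not None:
            rec = novel.get(tag.sequence)
            if rec is None:
                rec = ClassifiedMiRNA(
                    mirna_id="",  # assigned below in count order (PC-<n>)
                    mature_seq=tag.sequence,
                    tier="novel_candidate",
                    source=f"{locus[0]}:{locus[1]}-{locus[2]}({locus[3]})",
                    counts=empty_counts(),
                    locus=locus,
                )
                novel[tag.sequence] = rec
            add_counts(rec.counts, tag.counts)
            rec.member_tags.append(tag.sequence)
            continue

        # (e) unmapped
        rec = ClassifiedMiRNA(
            mirna_id=f"unmapped-{tag.sequence[:8]}",
            mature_seq=tag.sequence,
            tier="unmapped",
            source="",
            counts=dict(tag.counts),
        )
        unmapped.append(rec)

    novel_list = sorted(novel.values(), key=lambda r: (-sum(r.counts.values()), r.mature_seq))
    for idx, rec in enumerate(novel_list, start=1):
        rec.mirna_id = f"PC-{idx}"
    return list(known.values()) + list(variants.values()) + list(conserved.values()) + novel_list + unmapped


def extract_candidate_precursor(
    genome: dict[str, str],
    locus: tuple[str, int, int, str],
    flank: int = DEFAULT_FLANK,
) -> tuple[tuple[str, tuple[int, int]], tuple[str, tuple[int, int]]]:
    """Two candidate precursor windows around a mature locus.

    Window A extends ``flank`` nt upstream of the mature (mature on the 3'
    arm), window B extends ``flank`` nt downstream (mature on the 5' arm);
    both are strand-corrected so the mature appears in sense orientation, and
    clipped at contig bounds.  Each window is returned with the mature's
    half-open interval in window coordinates.
    """
    chrom, start, end, strand = locus
    if chrom not in genome:
        raise ValueError(f"unknown contig {chrom}")
    contig = genome[chrom]
    if not (0 <= start < end <= len(contig)):
        raise ValueError(f"locus {locus} outside contig bounds")
    if strand == "+":
        a_lo, a_hi = max(0, start - flank), end
        b_lo, b_hi = start, min(len(contig), end + flank)
        win_a = contig[a_lo:a_hi]
        win_b = contig[b_lo:b_hi]
        mat_a = (start - a_lo, end - a_lo)
        mat_b = (0, end - start)
    else:
        # minus strand: upstream in transcript orientation is higher genomic coord
        a_lo, a_hi = start, min(len(contig), end + flank)
        b_lo, b_hi = max(0, start - flank), end
        win_a = revcomp(contig[a_lo:a_hi])
        win_b = revcomp(contig[b_lo:b_hi])
        mat_a = (a_hi - end, a_hi - start)
        mat_b = (0, end - start)
    return (win_a, mat_a), (win_b, mat_b)


def window_genomic_locus(
    locus: tuple[str, int, int, str], flank: int, which: str, contig_len: int
) -> tuple[str, int, int, str]:
    """Genomic coordinates of window A/B from extract_candidate_precursor."""
    chrom, start, end, strand = locus
    upstream = (which == "A") == (strand == "+")
    if upstream:
        return (chrom, max(0, start - flank), end, strand)
    return (chrom, start, min(contig_len, end + flank), strand)


def write_gff3(path: str | Path, features: list[dict]) -> None:
    """Write features (0-based half-open internally) as 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        f["chrom"],
                        f.get("source", "follimir"),
                        f.get("type", "miRNA_primary_transcript"),
                        str(f["start"] + 1),
                        str(f["end"]),
                        ".",
                        f.get("strand", "+"),
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )
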