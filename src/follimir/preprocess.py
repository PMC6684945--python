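"""Read cleaning: adapter trimming, unique-tag collapsing, length retention,
RNA-family classification and composition/length summaries.

All sequences are held internally in the uppercase DNA alphabet (U -> T).
Cleaning is exact and deterministic: the 3' adapter is removed by the longest
exact suffix/prefix overlap, "junk" and low-complexity tags are dropped by
fixed documented rules, and only unique tags of 18-26 nt are retained.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 26
DEFAULT_MIN_OVERLAP = 6

# fixed precedence when a tag matches several contaminant families
FAMILY_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "mRNA", "other")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class UniqueTag:
    """A distinct cleaned read sequence with its per-sample counts."""

    sequence: str
    counts: dict[str, int]
    family: str | None = None  # contaminant family, None until classified

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TrimResult:
    insert: str | None  # None for rejected adaptor dimers
    trimmed: bool


def trim_adapter(read: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> TrimResult:
    """Remove the longest read suffix that exactly matches an adapter prefix.

    An empty insert (the read was adapter from its first base) is an adaptor
    dimer and is rejected.  Reads without a qualifying overlap pass through
    flagged untrimmed.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = normalize(read)
    adapter = normalize(adapter)
    for k in range(min(len(read), len(adapter)), min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            insert = read[:-k]
            if not insert:
                return TrimResult(None, True)
            return TrimResult(insert, True)
    return TrimResult(read, False)


def is_low_complexity(tag: str) -> bool:
    """Junk/low-complexity rule: non-ACGT character, >= 80% one nucleotide,
    or a homopolymer run of >= 10."""
    if not tag:
        raise ValueError("empty sequence")
    tag = normalize(tag)
    if set(tag) - set("ACGT"):
        return True
    counts = Counter(tag)
    if max(counts.values()) / len(tag) >= 0.8:
        return True
    run, prev = 1, tag[0]
    for c in tag[1:]:
        run = run + 1 if c == prev else 1
        prev = c
        if run >= 10:
            return True
    return False


def collapse_unique(reads_per_sample: dict[str, list[str]]) -> list[UniqueTag]:
    """Collapse reads into unique tags with per-sample counts.

    Tag order is deterministic: by decreasing total count, then sequence.
    """
    samples = list(reads_per_sample)
    counters = {s: Counter(map(normalize, reads)) for s, reads in reads_per_sample.items()}
    seqs = set()
    for c in counters.values():
        seqs.update(c)
    tags = [
        UniqueTag(seq, {s: counters[s].get(seq, 0) for s in samples})
        for seq in seqs
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def length_filter(
    tags: list[UniqueTag],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[UniqueTag]:
    """Retain tags whose length lies in [min_len, max_len], bounds inclusive."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [t for t in tags if min_len <= t.length <= max_len]


def classify_rna_family(
    tags: list[UniqueTag],
    contaminants: dict[str, list[str]] | None = None,
) -> list[UniqueTag]:
    """Assign each tag a contaminant family or leave it unannotated.

    A tag belongs to a family if it occurs as an exact substring of any
    reference sequence of that family, on either strand.  Families are tried
    in the fixed precedence order rRNA > tRNA > snRNA > snoRNA > mRNA > other;
    the first hit wins.  Family-annotated tags are excluded from miRNA
    discovery downstream.
    """
    refs = {
        fam: [normalize(s) for s in (contaminants or {}).get(fam, [])]
        for fam in FAMILY_ORDER
    }
    for tag in tags:
        tag.family = None
        rc = revcomp(tag.sequence)
        for fam in FAMILY_ORDER:
            if any(tag.sequence in ref or rc in ref for ref in refs[fam]):
                tag.family = fam
                break
    return tags


@dataclass
class CompositionSummary:
    """Per-group read counts and percentages by RNA category."""

    counts: pd.DataFrame  # index: category, columns: group
    percentages: pd.DataFrame

    def __post_init__(self):
        totals = self.percentages.sum(axis=0)
        assert ((totals - 100.0).abs() < 1e-9).all() or (self.counts.sum(axis=0) == 0).any()


def composition_summary(
    tags: list[UniqueTag],
    groups: dict[str, list[str]],
    mirna_sequences: set[str] | None = None,
) -> CompositionSummary:
    """Read-count composition per group over the categories of the family screen.

    Tags in ``mirna_sequences`` (known after classification) are counted as
    miRNA; family-flagged tags under their family; the rest as unannotated.
    """
    categories = ["miRNA", *FAMILY_ORDER, "unannotated"]
    mirna_sequences = mirna_sequences or set()
    data = {g: dict.fromkeys(categories, 0) for g in groups}
    for tag in tags:
        if tag.sequence in mirna_sequences:
            cat = "miRNA"
        elif tag.family is not None:
            cat = tag.family
        else:
            cat = "unannotated"
        for g, samples in groups.items():
            data[g][cat] += sum(tag.counts.get(s, 0) for s in samples)
    counts = pd.DataFrame(data).loc[categories]
    totals = counts.sum(axis=0)
    pct = 100.0 * counts / totals.replace(0, pd.NA)
    pct = pct.fillna(0.0)
    # degenerate all-zero group: keep percentage sum at 0 rather than NaN
    return CompositionSummary(counts, pct)


def length_histogram(
    tags: list[UniqueTag],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[int, int]:
    """Total read counts per tag length; all lengths in range always present."""
    hist = dict.fromkeys(range(min_len, max_len + 1), 0)
    for t in tags:
        hist[t.length] = hist.get(t.length, 0) + t.total
    return hist


@dataclass
class PreprocessStats:
    """Read accounting through the cleaning stages (count conservation)."""

    input_reads: int = 0
    dimer_rejected: int = 0
    low_complexity: int = 0
    length_filtered: int = 0
    retained: int = 0
    untrimmed: int = 0  # subset of retained/filtered that had no adapter

    def conserved(self) -> bool:
        return self.input_reads == (
            self.dimer_rejected + self.low_complexity + self.length_filtered + self.retained
        )


def read_fastq(path: str | Path) -> list[str]:
    """Sequences of a (possibly gzipped) FASTQ file."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def preprocess_sample(
    reads: list[str],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    stats: PreprocessStats | None = None,
) -> list[str]:
    """Trim + junk-filter one sample's reads (length filter happens on tags)."""
    stats = stats if stats is not None else PreprocessStats()
    out = []
    for read in reads:
        stats.input_reads += 1
        res = trim_adapter(read, adapter, min_overlap)
        if res.insert is None:
            stats.dimer_rejected += 1
            continue
        if not res.trimmed:
            stats.untrimmed += 1
        if is_low_complexity(res.insert):
            stats.low_complexity += 1
            continue
        out.append(res.insert)
    return out


def preprocess_samples(
    reads_per_sample: dict[str, list[str]],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[UniqueTag], PreprocessStats]:
    """Full cleaning of a sample set: trim, junk-filter, collapse, length-filter."""
    stats = PreprocessStats()
    cleaned = {
        s: preprocess_sample(reads, adapter, min_overlap, stats)
        for s, reads in reads_per_sample.items()
    }
    tags = collapse_unique(cleaned)
    kept = length_filter(tags, min_len, max_len)
    kept_total = sum(t.total for t in kept)
    all_total = sum(t.total for t in tags)
    stats.length_filtered = all_total - kept_total
    stats.retained = kept_total
    return kept, stats


def tag_table(tags: list[UniqueTag], samples: list[str]) -> pd.DataFrame:
    rows = [
        {
            "sequence": t.sequence,
            "length": t.length,
            **{s: t.counts.get(s, 0) for s in samples},
            "family": t.family or "",
        }
        for t in tags
    ]
    return pd.DataFrame(rows)
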