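"""Synthetic small RNA-seq study generator.

Emulates the statistical structure of a two-stage (IIIa vs IIIb) ovarian
follicle small RNA-seq experiment so every pipeline stage can be tested
without downloads:

* a toy genome with planted hairpin loci: known precursors (annotated mature
  arms), other-species-only conserved precursors, true novel hairpins, and
  non-folding decoy loci;
* a heavy-tailed (log-normal) miRNA abundance law so a handful of miRNAs
  dominates the library, with a dominant 22-nt mature length mode in the
  18-26 nt range;
* negative-binomial replicate counts (var = mu + dispersion * mu^2) with a
  configurable fraction of miRNAs spiked at a true fold change between the
  groups;
* FASTQ reads built as mature sequence + 3' adapter with optional per-base
  substitution errors, plus contaminant reads drawn from rRNA/tRNA/snRNA/
  snoRNA decoy references.

Everything is a pure function of :class:`SimConfig`; identical seeds yield
byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fold as _fold
from . import criteria as _criteria
from .preprocess import revcomp

# mature length law: dominant 22-nt mode inside the 18-26 nt retention range
LENGTH_LAW = {18: 0.01, 19: 0.02, 20: 0.06, 21: 0.15, 22: 0.45, 23: 0.15, 24: 0.08, 25: 0.05, 26: 0.03}

# GC-rich arm composition guarantees deeply negative stem energies
_ARM_P = {"A": 0.15, "C": 0.35, "G": 0.35, "T": 0.15}

STEM_EXTRA = 3  # arm length = mature length + STEM_EXTRA
LOOP_LEN = 8
NOVEL_COUNT_FLOOR = 600.0  # keeps planted novels above the 100-count refinement floor

CONTAMINANT_SHAPE = {"rRNA": [1500], "tRNA": [76, 76, 76, 76], "snRNA": [150, 150], "snoRNA": [110, 110]}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    seed: int = 0
    n_known: int = 30
    n_conserved: int = 8
    n_novel: int = 6
    n_decoy: int = 4
    genome_length: int = 60_000
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter
    reads_per_sample: int = 30_000
    replicates_per_group: int = 3
    nb_dispersion: float = 0.1
    de_fraction: float = 0.15
    de_fold_change: float = 4.0
    contaminant_fraction: float = 0.3
    seq_error_rate: float = 0.001
    arm_variant_every: int = 5  # every k-th known precursor also expresses its opposite arm

    def validate(self) -> None:
        if min(self.n_known, self.n_conserved, self.n_novel, self.n_decoy) < 0:
            raise ValueError("locus counts must be >= 0")
        if self.de_fold_change <= 1:
            raise ValueError("de_fold_change must be > 1")
        for name in ("de_fraction", "contaminant_fraction", "seq_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        n_loci = self.n_known + self.n_conserved + self.n_novel + self.n_decoy
        if self.genome_length < 150 * max(n_loci, 1):
            raise ValueError("genome_length too small to place all loci without overlap")

    @property
    def samples(self) -> list[str]:
        r = self.replicates_per_group
        return [f"IIIa_{i+1}" for i in range(r)] + [f"IIIb_{i+1}" for i in range(r)]

    @property
    def groups(self) -> dict[str, list[str]]:
        r = self.replicates_per_group
        return {
            "IIIa": [f"IIIa_{i+1}" for i in range(r)],
            "IIIb": [f"IIIb_{i+1}" for i in range(r)],
        }


@dataclass
class TruthEntry:
    """Ground truth for one planted locus / expressed small RNA."""

    entry_id: str
    tier: str  # known | known_arm_variant | conserved_novel | novel | decoy
    mature_seq: str
    arm: str
    precursor_seq: str
    precursor_locus: tuple[str, int, int, str] | None
    mature_locus: tuple[str, int, int, str] | None
    source_precursor: str = ""
    mean_abundance: float = 0.0
    fold_change: float = 1.0  # IIIb over IIIa true ratio
    spiked: bool = False


@dataclass
class GroundTruth:
    entries: list[TruthEntry] = field(default_factory=list)

    def by_tier(self, *tiers: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.tier in tiers]

    def mirnas(self) -> list[TruthEntry]:
        return self.by_tier("known", "known_arm_variant", "conserved_novel", "novel")

    def table(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "entry_id": e.entry_id,
                    "tier": e.tier,
                    "mature_seq": e.mature_seq,
                    "arm": e.arm,
                    "locus": "" if e.precursor_locus is None else
                    f"{e.precursor_locus[0]}:{e.precursor_locus[1]}-{e.precursor_locus[2]}({e.precursor_locus[3]})",
                    "mean_abundance": e.mean_abundance,
                    "fold_change": e.fold_change,
                    "spiked": e.spiked,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    same_species: list
    other_species: list
    contaminants: dict[str, list[str]]
    truth: GroundTruth
    config: SimConfig


def _rand_seq(rng: np.random.Generator, n: int, probs: dict[str, float] | None = None) -> str:
    bases = np.array(list("ACGT"))
    p = None if probs is None else np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=n, p=p))


def _draw_length(rng: np.random.Generator) -> int:
    ls = np.array(list(LENGTH_LAW))
    ps = np.array(list(LENGTH_LAW.values()))
    return int(rng.choice(ls, p=ps))


def _make_hairpin(rng: np.random.Generator, mature_len: int, arm: str) -> tuple[str, tuple[int, int], str]:
    """Build arm + loop + revcomp(arm); return (precursor, mature interval, mature seq).

    For a 5p mature the mature occupies the first ``mature_len`` nt; for a 3p
    mature it occupies the last ``mature_len`` nt, so that the window
    construction of the classifier covers the full hairpin from either side.
    """
    L = mature_len + STEM_EXTRA
    stem = _rand_seq(rng, L, _ARM_P)
    loop = _rand_seq(rng, LOOP_LEN)
    pre = stem + loop + revcomp(stem)
    if arm == "5p":
        iv = (0, mature_len)
    else:
        iv = (len(pre) - mature_len, len(pre))
    return pre, iv, pre[iv[0] : iv[1]]


def _hairpin_passes(pre: str, mature_iv: tuple[int, int]) -> bool:
    try:
        st = _fold.fold_mfe(pre)
        seg = _fold.annotate_stemloop(st)
        metrics = _fold.measure(st, seg, mature_iv)
    except (_fold.NotHairpinError, ValueError):
        return False
    return _criteria.evaluate_criteria(metrics).passed


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Build the genome, precursor references, contaminants and ground truth."""
    from .refmap import PrecursorRecord, MatureInterval

    config.validate()
    rng = np.random.default_rng([0, config.seed])
    truth = GroundTruth()
    same_species: list[PrecursorRecord] = []
    other_species: list[PrecursorRecord] = []
    planted: list[tuple[str, str]] = []  # (label, plus-strand genomic segment)

    def build_locus(label: str, tier: str, require_pass: bool | None) -> tuple[str, tuple[int, int], str, str]:
        """A hairpin (or decoy) satisfying its construction guarantee."""
        for _ in range(50):
            mlen = _draw_length(rng)
            arm = "5p" if rng.random() < 0.5 else "3p"
            if tier == "decoy":
                L = mlen + STEM_EXTRA
                stem = _rand_seq(rng, L, _ARM_P)
                loop = _rand_seq(rng, LOOP_LEN)
                shuffled = "".join(rng.permutation(list(stem)))
                pre = stem + loop + shuffled
                iv = (0, mlen)
                mature = pre[iv[0] : iv[1]]
                if not _hairpin_passes(pre, iv):
                    return pre, iv, mature, arm
                continue  # reshuffle until the screen rejects it
            pre, iv, mature = _make_hairpin(rng, mlen, arm)
            if require_pass is None or _hairpin_passes(pre, iv) == require_pass:
                return pre, iv, mature, arm
        raise RuntimeError(f"could not construct locus {label} satisfying its guarantee")

    # known precursors (annotated mature arms) -------------------------------
    for k in range(config.n_known):
        pre, iv, mature, arm = build_locus(f"dre-mir-s{k+1}", "known", None)
        rec = PrecursorRecord(
            id=f"dre-mir-s{k+1}",
            species="dre",
            sequence=pre,
            matures=[MatureInterval(iv[0], iv[1], arm)],
        )
        same_species.append(rec)
        planted.append((rec.id, pre))
        truth.entries.append(
            TruthEntry(f"dre-mir-s{k+1}-{arm}", "known", mature, arm, pre, None, None, rec.id)
        )
        # a subset of known precursors also expresses the unannotated arm
        if config.arm_variant_every and (k + 1) % config.arm_variant_every == 0:
            other_arm = "3p" if arm == "5p" else "5p"
            L = len(mature) + STEM_EXTRA
            if other_arm == "3p":
                vs, ve = len(pre) - L + 1, len(pre) - L + 1 + (len(mature) - 1)
            else:
                vs, ve = 1, len(mature)
            vseq = pre[vs:ve]
            label = "p3" if other_arm == "3p" else "p5"
            truth.entries.append(
                TruthEntry(f"dre-mir-s{k+1}-{label}", "known_arm_variant", vseq, other_arm, pre, None, None, rec.id)
            )

    # conserved (other-species-only) precursors ------------------------------
    for k in range(config.n_conserved):
        pre, iv, mature, arm = build_locus(f"xsp-mir-c{k+1}", "conserved_novel", None)
        rec = PrecursorRecord(
            id=f"mir-c{k+1}",
            species="xsp",
            sequence=pre,
            matures=[MatureInterval(iv[0], iv[1], arm)],
        )
        other_species.append(rec)
        planted.append((f"conserved-{rec.id}", pre))
        truth.entries.append(
            TruthEntry(f"xsp-mir-c{k+1}", "conserved_novel", mature, arm, pre, None, None, rec.id)
        )

    # novel hairpin loci (pass the screen by construction) -------------------
    for k in range(config.n_novel):
        pre, iv, mature, arm = build_locus(f"novel-{k+1}", "novel", True)
        planted.append((f"novel-{k+1}", pre))
        truth.entries.append(TruthEntry(f"novel-{k+1}", "novel", mature, arm, pre, None, None))

    # decoy loci (fail the screen by construction) ---------------------------
    for k in range(config.n_decoy):
        pre, iv, mature, arm = build_locus(f"decoy-{k+1}", "decoy", False)
        planted.append((f"decoy-{k+1}", pre))
        truth.entries.append(TruthEntry(f"decoy-{k+1}", "decoy", mature, arm, pre, None, None))

    # place loci on a random genome, both strands eligible -------------------
    genome_arr = np.array(list(_rand_seq(rng, config.genome_length)))
    occupied: list[tuple[int, int]] = []
    label_locus: dict[str, tuple[str, int, int, str]] = {}
    for label, pre in planted:
        for _ in range(200):
            start = int(rng.integers(0, config.genome_length - len(pre)))
            end = start + len(pre)
            if all(end + 10 <= s or start >= e + 10 for s, e in occupied):
                break
        else:
            raise RuntimeError(f"could not place locus {label} without overlap")
        strand = "+" if rng.random() < 0.5 else "-"
        segment = pre if strand == "+" else revcomp(pre)
        genome_arr[start:end] = list(segment)
        occupied.append((start, end))
        label_locus[label] = ("chr1", start, end, strand)
    genome = {"chr1": "".join(genome_arr)}

    # back-fill genomic loci into records and truth
    for rec in same_species:
        rec.locus = label_locus[rec.id]
    for e in truth.entries:
        key = {
            "known": e.source_precursor,
            "known_arm_variant": e.source_precursor,
            "conserved_novel": f"conserved-{e.source_precursor}",
            "novel": e.entry_id,
            "decoy": e.entry_id,
        }[e.tier]
        chrom, s, en, strand = label_locus[key]
        e.precursor_locus = (chrom, s, en, strand)
        off = e.precursor_seq.find(e.mature_seq)
        if strand == "+":
            e.mature_locus = (chrom, s + off, s + off + len(e.mature_seq), "+")
        else:
            e.mature_locus = (chrom, en - off - len(e.mature_seq), en - off, "-")

    # contaminant RNA-family references --------------------------------------
    contaminants = {
        fam: [_rand_seq(rng, n) for n in sizes] for fam, sizes in CONTAMINANT_SHAPE.items()
    }
    return ReferenceBundle(genome, same_species, other_species, contaminants, truth, config)


def simulate_counts(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Negative-binomial replicate counts under a heavy-tailed abundance law.

    Mean abundances are log-normal(mu=0, sigma=2), scaled so the expected
    miRNA read total per sample is (1 - contaminant_fraction) *
    reads_per_sample; planted novel/decoy loci are floored at a level that
    keeps them clear of the 100-count refinement rule.  An exact
    round(de_fraction * n_miRNA) subset of miRNAs is spiked, alternately up
    and down by ``de_fold_change`` in group IIIb.
    """
    rng = np.random.default_rng([1, config.seed])
    entries = truth.entries
    n = len(entries)
    raw = rng.lognormal(mean=0.0, sigma=2.0, size=n)
    target_total = (1.0 - config.contaminant_fraction) * config.reads_per_sample
    means = raw / raw.sum() * target_total
    for i, e in enumerate(entries):
        if e.tier in ("novel", "decoy"):
            means[i] = max(means[i], NOVEL_COUNT_FLOOR)
    for i, e in enumerate(entries):
        e.mean_abundance = float(means[i])
        e.fold_change = 1.0
        e.spiked = False

    mirna_idx = [i for i, e in enumerate(entries) if e.tier != "decoy"]
    n_spiked = int(round(config.de_fraction * len(mirna_idx)))
    spiked = rng.choice(mirna_idx, size=n_spiked, replace=False) if n_spiked else np.array([], dtype=int)
    for rank, i in enumerate(np.sort(spiked)):
        fc = config.de_fold_change if rank % 2 == 0 else 1.0 / config.de_fold_change
        entries[i].fold_change = float(fc)
        entries[i].spiked = True

    r = config.replicates_per_group
    cols = config.samples
    mat = np.zeros((n, 2 * r), dtype=int)
    for i, e in enumerate(entries):
        for g, gmean in enumerate((e.mean_abundance, e.mean_abundance * e.fold_change)):
            for j in range(r):
                mat[i, g * r + j] = _nb_draw(rng, gmean, config.nb_dispersion)
    df = pd.DataFrame(mat, index=[e.entry_id for e in entries], columns=cols)
    df.index.name = "mirna_id"
    return df


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


@dataclass
class SynthesisLog:
    """Per-sample provenance of emitted reads."""

    mirna_reads: dict[str, int]
    contaminant_reads: dict[str, int]
    fastq_paths: dict[str, Path]


def synthesize_reads(
    counts: pd.DataFrame,
    bundle: ReferenceBundle,
    config: SimConfig,
    outdir: str | Path,
) -> SynthesisLog:
    """Write one FASTQ per sample: mature + adapter reads plus contaminants."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([2, config.seed])
    seq_by_id = {e.entry_id: e.mature_seq for e in bundle.truth.entries}
    for entry_id in counts.index:
        if entry_id not in seq_by_id:
            raise ValueError(f"count row {entry_id} not present in the reference bundle")
    if any(seq.startswith(config.adapter[:6]) for seq in seq_by_id.values()):
        import warnings

        warnings.warn("adapter prefix collides with a mature sequence prefix; trimming may over-trim")

    fam_refs = [s for fam in bundle.contaminants.values() for s in fam]
    log = SynthesisLog({}, {}, {})
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = "ACGT"

    def mutate(read: str) -> str:
        if config.seq_error_rate <= 0:
            return read
        n_err = rng.binomial(len(read), config.seq_error_rate)
        if n_err == 0:
            return read
        pos = rng.choice(len(read), size=n_err, replace=False)
        chars = list(read)
        for p in pos:
            chars[p] = bases[(base_idx[chars[p]] + int(rng.integers(1, 4))) % 4]
        return "".join(chars)

    for sample in counts.columns:
        reads: list[str] = []
        for entry_id, c in counts[sample].items():
            if c > 0:
                reads.extend([seq_by_id[entry_id] + config.adapter] * int(c))
        n_cont = int(rng.binomial(config.reads_per_sample, config.contaminant_fraction)) if fam_refs else 0
        for _ in range(n_cont):
            ref = fam_refs[int(rng.integers(len(fam_refs)))]
            flen = _draw_length(rng)
            start = int(rng.integers(0, len(ref) - flen))
            reads.append(ref[start : start + flen] + config.adapter)
        order = rng.permutation(len(reads))
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i, k in enumerate(order):
                read = mutate(reads[k])
                fh.write(f"@{sample}_read{i}\n{read}\n+\n{'I' * len(read)}\n")
        log.mirna_reads[sample] = int(counts[sample].sum())
        log.contaminant_reads[sample] = n_cont
        log.fastq_paths[sample] = path
    return log


# ---------------------------------------------------------------------------
# toy target-prediction / enrichment resources for the end-to-end demo
# ---------------------------------------------------------------------------

PANEL_GENES = ("lhcgr", "paqr7b", "pgrmc1")


def generate_target_resources(
    truth: GroundTruth, config: SimConfig, n_filler_genes: int = 12
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Toy transcript set and term->gene map for the target/enrichment stages.

    Each oocyte-maturation panel gene carries a perfect complementary site for
    two spiked miRNAs (so both the seed and the complementarity predictor hit
    it); filler genes are random sequence.
    """
    rng = np.random.default_rng([3, config.seed])
    mirnas = truth.mirnas()
    spiked = [e for e in mirnas if e.spiked] or mirnas[: min(3, len(mirnas))]
    transcripts: dict[str, str] = {}
    for gi, gene in enumerate(PANEL_GENES):
        seq = _rand_seq(rng, 400)
        for k in range(2):
            e = spiked[(gi + k) % len(spiked)]
            site = revcomp(e.mature_seq)
            pos = 50 + 120 * k
            seq = seq[:pos] + site + seq[pos + len(site):]
        transcripts[gene] = seq
    for k in range(n_filler_genes):
        transcripts[f"gene{k+1}"] = _rand_seq(rng, 400)
    genes = list(transcripts)
    terms = {
        "TERM:oocyte_maturation": list(PANEL_GENES),
        "TERM:background_a": genes[: len(genes) // 2],
        "TERM:background_b": [g for i, g in enumerate(genes) if i % 2 == 0],
    }
    return transcripts, terms


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA/GFF3/TSV files; returns the path map."""
    from .refmap import write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_fasta(name: str, records: list[tuple[str, str]]) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        paths[name] = p

    write_fasta("genome.fa", list(bundle.genome.items()))
    write_fasta("precursors.fa", [(r.id, r.sequence) for r in bundle.same_species])
    write_fasta("other_precursors.fa", [(r.id, r.sequence) for r in bundle.other_species])
    write_fasta(
        "contaminants.fa",
        [(f"{fam}_{i+1}", s) for fam, seqs in bundle.contaminants.items() for i, s in enumerate(seqs)],
    )

    sidecars = []
    for r in bundle.same_species + bundle.other_species:
        for m in r.matures:
            sidecars.append({"precursor_id": r.id, "mature_start": m.start, "mature_end": m.end, "arm": m.arm})
    pd.DataFrame(sidecars).to_csv(outdir / "matures.tsv", sep="\t", index=False)
    paths["matures.tsv"] = outdir / "matures.tsv"

    feats = [
        {
            "chrom": e.precursor_locus[0],
            "start": e.precursor_locus[1],
            "end": e.precursor_locus[2],
            "strand": e.precursor_locus[3],
            "attributes": {"ID": e.entry_id, "tier": e.tier},
        }
        for e in bundle.truth.entries
        if e.precursor_locus is not None
    ]
    write_gff3(outdir / "loci.gff3", feats)
    paths["loci.gff3"] = outdir / "loci.gff3"

    bundle.truth.table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth.tsv"] = outdir / "truth.tsv"
    return paths
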