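"""End-to-end orchestration: simulate -> preprocess -> classify -> discover ->
differential expression -> targets -> enrichment.

Each stage writes plain TSV/FASTA/GFF3 outputs into the run directory and the
run finishes with a JSON manifest (stage list, seed, sha256 checksums).
Re-running with the same configuration and seed reproduces every table
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import criteria as crit
from . import diffexp as de_mod
from . import refmap
from . import simulate as sim_mod
from . import targets as tg
from .fold import NotHairpinError, fold_mfe, annotate_stemloop, measure
from .preprocess import (
    classify_rna_family,
    composition_summary,
    length_histogram,
    preprocess_samples,
    read_fastq,
    tag_table,
)

log = logging.getLogger("follimir")

STAGES = ("simulate", "preprocess", "classify", "discover", "de", "targets", "enrich")


@dataclass
class PipelineConfig:
    """Run configuration: simulation stanza plus every module threshold."""

    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    thresholds: crit.CriteriaThresholds = field(default_factory=crit.CriteriaThresholds)
    alpha: float = de_mod.DEFAULT_ALPHA
    fc_hi: float = de_mod.DEFAULT_FC_HI
    fc_lo: float = de_mod.DEFAULT_FC_LO
    fdr: bool = False
    end_window: int = refmap.DEFAULT_END_WINDOW
    flank: int = refmap.DEFAULT_FLANK
    outdir: Path = Path("follimir_run")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        simcfg = sim_mod.SimConfig(**raw.pop("simulate", {}))
        thr = crit.CriteriaThresholds(**raw.pop("thresholds", {}))
        cfg = cls(sim=simcfg, thresholds=thr, **raw)
        cfg.outdir = Path(cfg.outdir)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    seed: int
    stages: list[str]
    checksums: dict[str, str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, stop_after: str = "enrich") -> dict:
    """Run the pipeline through ``stop_after`` and return the stage results.

    The returned dict maps stage names to their in-memory products (bundle,
    tags, classified records, verdicts, DE tables, ...), which is what the
    tests and the acceptance measurements consume; files land in
    ``config.outdir``.
    """
    logging.basicConfig(level=config.log_level)
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"stages_run": []}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)
        return path

    def stage_done(name: str) -> bool:
        results["stages_run"].append(name)
        return STAGES.index(stop_after) <= STAGES.index(name)

    try:
        # ------------------------------------------------------------ simulate
        bundle = sim_mod.generate_reference(config.sim)
        counts = sim_mod.simulate_counts(config.sim, bundle.truth)
        synth = sim_mod.synthesize_reads(counts, bundle, config.sim, outdir / "reads")
        for p in sim_mod.write_bundle(bundle, outdir / "reference").values():
            written.append(p)
        emit("true_counts.tsv", counts, index=True)
        results.update(bundle=bundle, true_counts=counts, synthesis=synth)
        if stage_done("simulate"):
            return _finish(results, config, written, outdir)

        # ---------------------------------------------------------- preprocess
        reads = {s: read_fastq(p) for s, p in synth.fastq_paths.items()}
        tags, stats = preprocess_samples(reads, config.sim.adapter)
        classify_rna_family(tags, bundle.contaminants)
        samples = config.sim.samples
        emit("tags.tsv", tag_table(tags, samples))
        hist = length_histogram(tags)
        emit("length_histogram.tsv", pd.DataFrame(hist.items(), columns=["length", "reads"]))
        results.update(tags=tags, preprocess_stats=stats)
        if stage_done("preprocess"):
            return _finish(results, config, written, outdir)

        # ------------------------------------------------------------ classify
        classified = refmap.classify_cascade(
            tags,
            bundle.same_species,
            bundle.other_species,
            bundle.genome,
            end_window=config.end_window,
        )
        mirna_tag_seqs = {
            t for r in classified if r.tier != "unmapped" for t in r.member_tags
        }
        comp = composition_summary(tags, config.sim.groups, mirna_tag_seqs)
        emit("composition.tsv", comp.percentages, index=True)
        rows = [
            {
                "mirna_id": r.mirna_id,
                "mature_seq": r.mature_seq,
                "tier": r.tier,
                "source": r.source,
                **r.counts,
            }
            for r in classified
        ]
        emit("classification.tsv", pd.DataFrame(rows))
        results.update(classified=classified, composition=comp)
        if stage_done("classify"):
            return _finish(results, config, written, outdir)

        # ------------------------------------------------------------ discover
        genome = bundle.genome
        contig_len = {c: len(s) for c, s in genome.items()}
        known_loci = [r.locus for r in bundle.same_species if r.locus is not None]
        candidates, verdicts = [], []
        for r in classified:
            if r.tier not in ("conserved_novel", "novel_candidate") or r.locus is None:
                continue
            windows = refmap.extract_candidate_precursor(genome, r.locus, config.flank)
            per_window = []
            for w, (wseq, wmat) in enumerate(windows):
                try:
                    st = fold_mfe(wseq)
                    seg = annotate_stemloop(st)
                    met = measure(st, seg, wmat)
                    v = crit.evaluate_criteria(met, config.thresholds, r.mirna_id, w)
                except (NotHairpinError, ValueError):
                    v = crit.CandidateVerdict.not_hairpin(r.mirna_id, w)
                per_window.append(v)
            chosen = crit.pick_window(*per_window)
            verdicts.append(chosen)
            wlabel = "A" if chosen.window == 0 else "B"
            locus = refmap.window_genomic_locus(r.locus, config.flank, wlabel, contig_len[r.locus[0]])
            candidates.append(crit.Candidate(r.mirna_id, r.mature_seq, chosen, locus, r.counts))
        retained = crit.refine(
            candidates, known_loci, config.sim.groups, config.thresholds.min_count_all_replicates
        )
        emit("verdicts.tsv", crit.verdict_table(verdicts))
        refmap.write_gff3(
            outdir / "novel_precursors.gff3",
            [
                {
                    "chrom": c.precursor_locus[0],
                    "start": c.precursor_locus[1],
                    "end": c.precursor_locus[2],
                    "strand": c.precursor_locus[3],
                    "attributes": {"ID": c.candidate_id},
                }
                for c in retained
            ],
        )
        written.append(outdir / "novel_precursors.gff3")
        results.update(candidates=candidates, retained=retained, verdicts=verdicts)
        if stage_done("discover"):
            return _finish(results, config, written, outdir)

        # ------------------------------------------------------------------ de
        retained_ids = {c.candidate_id for c in retained}
        keep_tiers = ("known", "known_arm_variant")
        matrix_rows = [
            r
            for r in classified
            if r.tier in keep_tiers
            or (r.tier in ("conserved_novel", "novel_candidate") and r.mirna_id in retained_ids)
        ]
        count_matrix = pd.DataFrame(
            {r.mirna_id: r.counts for r in matrix_rows}
        ).T[config.sim.samples]
        count_matrix.index.name = "mirna_id"
        cpm = de_mod.normalize(count_matrix)
        de = de_mod.t_test_de(cpm, config.sim.groups)
        calls = de_mod.call_significant(de, config.alpha, config.fc_hi, config.fc_lo, config.fdr)
        emit("counts.tsv", count_matrix, index=True)
        emit("de.tsv", de_mod.de_table(de, config.alpha), index=True)
        emit("heatmap_matrix.tsv", de_mod.zscore_matrix(cpm), index=True)
        results.update(count_matrix=count_matrix, cpm=cpm, de=de, calls=calls)
        if stage_done("de"):
            return _finish(results, config, written, outdir)

        # ------------------------------------------------------------- targets
        transcripts, term_map = sim_mod.generate_target_resources(bundle.truth, config.sim)
        seq_of = {r.mirna_id: r.mature_seq for r in matrix_rows}
        sig_ids = list(pd.concat([calls.up, calls.down]).index)
        seed_sites, comp_sites = [], []
        for mid in sig_ids:
            seed_sites += tg.seed_targets(mid, seq_of[mid], transcripts)
            comp_sites += tg.complementarity_targets(mid, seq_of[mid], transcripts)
        pairs = tg.intersect_predictions(seed_sites, comp_sites)
        emit(
            "target_pairs.tsv",
            pd.DataFrame(
                [{"mirna_id": m, "transcript_id": t, "n_sites": len(s)} for (m, t), s in pairs.items()]
            ),
        )
        results.update(transcripts=transcripts, term_map=term_map, target_pairs=pairs)
        if stage_done("targets"):
            return _finish(results, config, written, outdir)

        # -------------------------------------------------------------- enrich
        universe = set(transcripts)
        query = {t for (_, t) in pairs}
        enr = tg.hypergeom_enrich(query, term_map, universe) if query else []
        emit(
            "enrichment.tsv",
            pd.DataFrame(
                [
                    {"term": e.term_id, "term_size": e.term_size, "overlap": e.overlap, "p": e.p, "significant": e.significant}
                    for e in enr
                ]
            ),
        )
        link = tg.link_de_to_targets(de.loc[sig_ids], pairs)
        emit("key_gene_links.tsv", link)
        results.update(enrichment=enr, key_gene_links=link)
        stage_done("enrich")
        return _finish(results, config, written, outdir)
    except Exception:
        for p in written:
            if p.exists() and p.suffix != ".partial":
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise


def _finish(results: dict, config: PipelineConfig, written: list[Path], outdir: Path) -> dict:
    manifest = RunManifest(
        seed=config.sim.seed,
        stages=results["stages_run"],
        checksums={str(p.relative_to(outdir)): _sha256(p) for p in written if p.exists()},
    )
    manifest.write(outdir / "manifest.json")
    results["manifest"] = manifest
    return results
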