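"""Structural acceptance criteria and refinement rules for novel-miRNA calls.

A candidate precursor passes the structural screen when all eleven measured
quantities fall on the accepting side of their inclusive thresholds:

1.  largest bulge in the stem              <= 12 nt
2.  base pairs in the stem                 >= 16
3.  free energy                            <= -15 kcal/mol
4.  hairpin length (stems + terminal loop) >= 50 nt
5.  terminal loop length                   <= 20 nt
6.  largest bulge in the mature region     <= 8 nt
7.  biased errors in one mature bulge      <= 4
8.  biased bulges in the mature region     <= 2
9.  errors (unpaired nt) in mature region  <= 7
10. base pairs in the mature region        >= 12
11. percent of mature region in the stem   >= 80

Retained candidates are then refined: precursors overlapping a known
precursor locus on the same strand are dropped, identical (mature sequence,
count vector) duplicates are collapsed to the lowest-energy precursor, and a
candidate must reach the count floor (default 100) in every replicate of at
least one of the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .fold import HairpinMetrics

CRITERIA_ORDER = (
    "stem_bulge_max_nt",
    "stem_bp",
    "free_energy",
    "hairpin_len",
    "loop_len",
    "mature_bulge_max_nt",
    "mature_biased_errors_max",
    "mature_biased_bulges",
    "mature_errors",
    "mature_bp",
    "mature_pct_in_stem",
)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Inclusive thresholds of the structural screen and the count refinement."""

    stem_bulge_max: int = 12
    stem_bp_min: int = 16
    energy_max: float = -15.0
    hairpin_len_min: int = 50
    loop_len_max: int = 20
    mature_bulge_max: int = 8
    mature_biased_errors_max: int = 4
    mature_biased_bulges_max: int = 2
    mature_errors_max: int = 7
    mature_bp_min: int = 12
    mature_pct_in_stem_min: float = 80.0
    min_count_all_replicates: int = 100


@dataclass
class CandidateVerdict:
    """Outcome of the 11-criterion screen for one candidate window."""

    candidate_id: str
    checks: dict[str, bool]
    passed: bool
    failing: list[str]
    energy: float
    metrics: HairpinMetrics | None = None
    window: int | None = None  # which of the two windows (0/1) this refers to
    flags: dict = field(default_factory=dict)

    @classmethod
    def not_hairpin(cls, candidate_id: str, window: int | None = None) -> "CandidateVerdict":
        """Verdict for a window that did not fold into a single stem-loop."""
        checks = {name: False for name in CRITERIA_ORDER}
        return cls(
            candidate_id=candidate_id,
            checks=checks,
            passed=False,
            failing=list(CRITERIA_ORDER),
            energy=0.0,
            metrics=None,
            window=window,
            flags={"not_hairpin": True},
        )


def evaluate_criteria(
    metrics: HairpinMetrics,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    candidate_id: str = "",
    window: int | None = None,
) -> CandidateVerdict:
    """Apply all eleven structural criteria (no short-circuit) to one window."""
    t = thresholds
    checks = {
        "stem_bulge_max_nt": metrics.stem_bulge_max_nt <= t.stem_bulge_max,
        "stem_bp": metrics.stem_bp >= t.stem_bp_min,
        "free_energy": metrics.free_energy <= t.energy_max,
        "hairpin_len": metrics.hairpin_len >= t.hairpin_len_min,
        "loop_len": metrics.loop_len <= t.loop_len_max,
        "mature_bulge_max_nt": metrics.mature_bulge_max_nt <= t.mature_bulge_max,
        "mature_biased_errors_max": metrics.mature_biased_errors_max <= t.mature_biased_errors_max,
        "mature_biased_bulges": metrics.mature_biased_bulges <= t.mature_biased_bulges_max,
        "mature_errors": metrics.mature_errors <= t.mature_errors_max,
        "mature_bp": metrics.mature_bp >= t.mature_bp_min,
        "mature_pct_in_stem": metrics.mature_pct_in_stem >= t.mature_pct_in_stem_min,
    }
    failing = [k for k in CRITERIA_ORDER if not checks[k]]
    return CandidateVerdict(
        candidate_id=candidate_id,
        checks=checks,
        passed=not failing,
        failing=failing,
        energy=metrics.free_energy,
        metrics=metrics,
        window=window,
    )


def pick_window(verdict_a: CandidateVerdict, verdict_b: CandidateVerdict) -> CandidateVerdict:
    """Choose the better of the two window arrangements for one locus.

    A passing window beats a failing one; among two passing windows the lower
    free energy wins; among two failing windows, fewer failed criteria then
    lower energy.
    """
    a, b = verdict_a, verdict_b
    if a.passed != b.passed:
        return a if a.passed else b
    if a.passed:
        return a if a.energy <= b.energy else b
    if len(a.failing) != len(b.failing):
        return a if len(a.failing) < len(b.failing) else b
    return a if a.energy <= b.energy else b


def _loci_overlap(a, b) -> bool:
    """>= 1 bp overlap on the same contig and strand; 0-based half-open."""
    return (
        a[0] == b[0]
        and a[3] == b[3]
        and max(a[1], b[1]) < min(a[2], b[2])
    )


@dataclass
class Candidate:
    """A novel/conserved-novel candidate entering refinement."""

    candidate_id: str
    mature_seq: str
    verdict: CandidateVerdict
    precursor_locus: tuple[str, int, int, str] | None  # (chrom, start, end, strand)
    counts: dict[str, int]


def refine(
    candidates: list[Candidate],
    known_precursor_loci: list[tuple[str, int, int, str]],
    groups: dict[str, list[str]],
    min_count: int = 100,
) -> list[Candidate]:
    """Apply the three refinement rules to structurally passing candidates.

    (1) drop candidates whose chosen precursor window overlaps a known
    precursor locus on the same strand; (2) collapse candidates with an
    identical (mature sequence, count vector) to the lowest-energy precursor;
    (3) keep only candidates with at least ``min_count`` in every replicate
    of one of the groups.
    """
    out = []
    for c in candidates:
        if not c.verdict.passed:
            c.verdict.flags["refine"] = "failed_structure"
            continue
        if c.precursor_locus is not None and any(
            _loci_overlap(c.precursor_locus, k) for k in known_precursor_loci
        ):
            c.verdict.flags["refine"] = "overlaps_known"
            continue
        out.append(c)

    # rule (2): dedupe identical (mature sequence, counts), lowest energy wins
    best: dict[tuple, Candidate] = {}
    for c in out:
        key = (c.mature_seq, tuple(sorted(c.counts.items())))
        prev = best.get(key)
        if prev is None or c.verdict.energy < prev.verdict.energy:
            if prev is not None:
                prev.verdict.flags["refine"] = "duplicate"
            best[key] = c
        else:
            c.verdict.flags["refine"] = "duplicate"
    deduped = list(best.values())

    # rule (3): count floor in all replicates of either group
    retained = []
    for c in deduped:
        ok = any(
            all(c.counts.get(s, 0) >= min_count for s in samples)
            for samples in groups.values()
        )
        if ok:
            retained.append(c)
        else:
            c.verdict.flags["refine"] = "below_count_floor"
    return retained


def verdict_table(verdicts: list[CandidateVerdict]):
    """Verdicts as a tidy DataFrame (one row per candidate, one column per criterion)."""
    import pandas as pd

    rows = []
    for v in verdicts:
        row = {"candidate_id": v.candidate_id, "window": v.window}
        row.update({k: v.checks[k] for k in CRITERIA_ORDER})
        row["energy"] = v.energy
        row["passed"] = v.passed
        row["flags"] = ";".join(f"{k}={val}" for k, val in v.flags.items())
        rows.append(row)
    return pd.DataFrame(rows)
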