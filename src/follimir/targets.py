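"""miRNA target prediction (two simplified methods), their intersection, and
hypergeometric over-representation analysis.

The two predictors are deliberately lightweight stand-ins for the seed-based
and complementarity-based families of target algorithms: a canonical
seed-match scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer site types over miRNA
positions 2-7) and a position-weighted local-complementarity score with a
duplex-energy gate.  Their scores are not comparable to any published tool;
only the per-transcript intersection of the two methods is consumed
downstream, mirroring common dual-prediction practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import normalize as _norm, revcomp
from .fold import duplex_energy

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# complementarity-method scoring (positions are 1-based on the miRNA)
MATCH_SCORE = 5.0
GU_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_SCORE = -8.0
SEED_WEIGHT = 2.0  # multiplier for miRNA positions 2-8
DEFAULT_SCORE_MIN = 80.0
DEFAULT_ENERGY_MAX = -14.0


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer | complementarity
    position: int  # 0-based start on the transcript
    method: str  # "seed" | "complementarity"
    score: float | None = None
    energy: float | None = None


def seed_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
) -> list[TargetSite]:
    """Canonical seed-match sites of one miRNA over a transcript set.

    The 6mer core is the reverse complement of miRNA positions 2-7.  A site
    is upgraded by a match to position 8 (m8) on its 5' side and/or an A in
    the transcript opposite position 1 (A1) on its 3' side: both -> 8mer,
    m8 only -> 7mer-m8, A1 only -> 7mer-A1, neither -> 6mer.  Overlapping
    core matches are reported left to right, non-overlapping.
    """
    m = _norm(mirna_seq)
    if len(m) < 8:
        raise ValueError("miRNA must be >= 8 nt for seed classification")
    core = revcomp(m[1:7])
    m8 = COMPLEMENT[m[7]]
    sites = []
    for tid, seq in transcripts.items():
        seq = _norm(seq)
        pos, last_end = 0, -1
        while (pos := seq.find(core, pos)) >= 0:
            if pos < last_end:
                pos += 1
                continue
            has_m8 = pos > 0 and seq[pos - 1] == m8
            has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
            site_type = {
                (True, True): "8mer",
                (True, False): "7mer-m8",
                (False, True): "7mer-A1",
                (False, False): "6mer",
            }[(has_m8, has_a1)]
            start = pos - 1 if has_m8 else pos
            sites.append(TargetSite(mirna_id, tid, site_type, start, "seed"))
            last_end = pos + 6
            pos += 1
    return sites


def complementarity_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    score_min: float = DEFAULT_SCORE_MIN,
    energy_max: float = DEFAULT_ENERGY_MAX,
) -> list[TargetSite]:
    """Position-weighted local complementarity sites with a duplex-energy gate.

    A Smith-Waterman local alignment of the reverse-complemented miRNA
    against each transcript (match +5, G:U +2, mismatch -3, gap -8; miRNA
    positions 2-8 doubled) proposes sites; a site is kept when its score
    reaches ``score_min`` and the stacking energy of the implied duplex is at
    most ``energy_max`` kcal/mol.  Non-overlapping sites are extracted best
    first.
    """
    m = _norm(mirna_seq)
    L = len(m)
    # row k of the DP aligns reverse-complement position k, i.e. miRNA
    # position (L - 1 - k); seed weighting follows the miRNA position.
    weights = np.array([SEED_WEIGHT if 2 <= (L - k + 1) <= 8 else 1.0 for k in range(1, L + 1)])
    mr = revcomp(m)
    sites: list[TargetSite] = []
    for tid, seq in transcripts.items():
        seq = _norm(seq)
        n = len(seq)
        H = np.zeros((L + 1, n + 1))
        for k in range(1, L + 1):
            # row k aligns miRNA position (L - k + 1), written as m[L - k]
            row_scores = np.array(
                [
                    MATCH_SCORE if COMPLEMENT[m[L - k]] == seq[j]
                    else GU_SCORE if {m[L - k], seq[j]} == {"G", "T"}
                    else MISMATCH_SCORE
                    for j in range(n)
                ]
            ) * weights[k - 1]
            prev = H[k - 1]
            cur = H[k]
            for j in range(1, n + 1):
                cur[j] = max(
                    0.0,
                    prev[j - 1] + row_scores[j - 1],
                    prev[j] + GAP_SCORE,
                    cur[j - 1] + GAP_SCORE,
                )
        col_best = H.max(axis=0)
        used = np.zeros(n + 1, bool)
        order = np.argsort(-col_best)
        for j in order:
            if col_best[j] < score_min:
                break
            lo = max(0, j - L - 4)
            if used[lo : j + 1].any():
                continue
            start = max(0, j - L)
            window = seq[start:j]
            e = duplex_energy(m, window)
            if e <= energy_max:
                sites.append(
                    TargetSite(mirna_id, tid, "complementarity", int(start), "complementarity", float(col_best[j]), float(e))
                )
                used[lo : j + 1] = True
    return sites


def intersect_predictions(
    seed_sites: list[TargetSite],
    comp_sites: list[TargetSite],
) -> dict[tuple[str, str], list[TargetSite]]:
    """(miRNA, transcript) pairs supported by both methods, with merged sites."""
    seed_pairs = {(s.mirna_id, s.transcript_id) for s in seed_sites}
    comp_pairs = {(s.mirna_id, s.transcript_id) for s in comp_sites}
    both = seed_pairs & comp_pairs
    out: dict[tuple[str, str], list[TargetSite]] = {pair: [] for pair in sorted(both)}
    for s in seed_sites + comp_sites:
        key = (s.mirna_id, s.transcript_id)
        if key in both:
            out[key].append(s)
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap: int
    p: float
    significant: bool


def hypergeom_enrich(
    query: set[str] | list[str],
    term_map: dict[str, list[str]],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of a gene set per term.

    p = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|term|, n=|query|);
    terms with p <= alpha are flagged significant; results sorted by p.
    """
    universe = set(universe)
    query = set(query)
    if offenders := sorted(query - universe):
        raise ValueError(f"query genes outside the universe: {offenders}")
    N, n = len(universe), len(query)
    results = []
    for term, genes in term_map.items():
        genes = set(genes) & universe
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, len(genes), n)) if k > 0 else 1.0
        p = min(p, 1.0)
        results.append(EnrichmentResult(term, len(genes), k, p, p <= alpha))
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def link_de_to_targets(
    de_calls: pd.DataFrame,
    predictions: dict[tuple[str, str], list[TargetSite]],
    panel: tuple[str, ...] = ("lhcgr", "paqr7b", "pgrmc1"),
    mean_cols: tuple[str, str] = ("mean_IIIa", "mean_IIIb"),
) -> pd.DataFrame:
    """Join DE miRNAs to their predicted panel-gene targets (key-gene table).

    One row per DE miRNA with at least one predicted target in the panel:
    group mean counts, regulation direction, and the targeted panel genes.
    """
    targeted: dict[str, set[str]] = {}
    for (mirna, gene) in predictions:
        if gene in panel:
            targeted.setdefault(mirna, set()).add(gene)
    rows = []
    for mirna, row in de_calls.iterrows():
        genes = targeted.get(mirna)
        if not genes:
            continue
        rows.append(
            {
                "mirna_id": mirna,
                mean_cols[0]: row[mean_cols[0]],
                mean_cols[1]: row[mean_cols[1]],
                "direction": "up" if row["fold_change"] > 1 else "down",
                "target_genes": ", ".join(sorted(genes)),
            }
        )
    return pd.DataFrame(rows, columns=["mirna_id", *mean_cols, "direction", "target_genes"])
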