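"""Two-group differential expression of miRNA counts and the ddCt calculator.

Counts are normalized by library size to counts per million (CPM) and each
miRNA is tested with a two-sided pooled-variance (Student's) t-test between
the IIIa and IIIb replicate groups; significance is raw p <= alpha (0.05 by
default, matching the screen this pipeline models), with an optional
Benjamini-Hochberg FDR behind a flag.  "Strong" calls additionally require
fold change > 2 or < 1/2 (IIIb over IIIa).

The qPCR helper implements relative quantification: dCt against a reference
gene (U6), ddCt against the baseline-group mean dCt, relative level
2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_FC_HI = 2.0
DEFAULT_FC_LO = 0.5


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization; every column then sums to 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return counts * 1e6 / totals


def t_test_de(
    normalized: pd.DataFrame,
    groups: dict[str, list[str]],
    welch: bool = False,
) -> pd.DataFrame:
    """Per-miRNA two-sided t-test between the two groups of a normalized matrix.

    Returns a table with group means, fold change (second group over first),
    log2 fold change, t statistic and p value.  Zero-variance miRNAs with
    equal means get t = 0, p = 1; a zero first-group mean with nonzero second
    yields an infinite fold change and an undefined (NaN) log2 fold change.
    """
    (ga, a_samples), (gb, b_samples) = groups.items()
    if min(len(a_samples), len(b_samples)) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = normalized[a_samples].to_numpy(float)
    b = normalized[b_samples].to_numpy(float)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate & np.isclose(mean_a, mean_b), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / np.where(mean_a > 0, mean_a, 1.0), np.inf)
        fc = np.where((mean_a == 0) & (mean_b == 0), np.nan, fc)
        log2fc = np.where(np.isfinite(fc) & (fc > 0), np.log2(np.where(fc > 0, fc, 1.0)), np.nan)

    out = pd.DataFrame(
        {
            f"mean_{ga}": mean_a,
            f"mean_{gb}": mean_b,
            "fold_change": fc,
            "log2_fc": log2fc,
            "t": t,
            "p": p,
        },
        index=normalized.index,
    )
    out.index.name = normalized.index.name or "mirna_id"
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class SignificanceCalls:
    up: pd.DataFrame
    down: pd.DataFrame
    strong_up: pd.DataFrame
    strong_down: pd.DataFrame

    @property
    def strong(self) -> pd.DataFrame:
        return pd.concat([self.strong_up, self.strong_down])


def call_significant(
    de: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc_hi: float = DEFAULT_FC_HI,
    fc_lo: float = DEFAULT_FC_LO,
    fdr: bool = False,
) -> SignificanceCalls:
    """Split a DE table into up/down and strong (beyond the FC gates) calls.

    Significant means p <= alpha (inclusive); strong-up additionally requires
    fold change > fc_hi and strong-down fold change < fc_lo (both strict, the
    gates themselves are not calls).  Lists are sorted by p.
    """
    de = de.copy()
    de["significant"] = (bh_fdr(de["p"].to_numpy()) if fdr else de["p"]) <= alpha
    sig = de[de["significant"]].sort_values("p")
    up = sig[sig["fold_change"] > 1]
    down = sig[sig["fold_change"] < 1]
    return SignificanceCalls(
        up=up,
        down=down,
        strong_up=up[up["fold_change"] > fc_hi],
        strong_down=down[down["fold_change"] < fc_lo],
    )


def de_table(de: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Volcano-ready output columns: log2 FC, -log10 p, significance flag."""
    out = de.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out["significant"] = out["p"] <= alpha
    return out


def zscore_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scored matrix (heatmap-ready); zero-variance rows become 0."""
    mu = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=0).replace(0, np.nan)
    return normalized.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def delta_delta_ct(
    qpcr: pd.DataFrame,
    reference_gene: str = "U6",
    baseline_group: str = "IIIa",
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    ``qpcr`` columns: gene, sample, group, Ct.  Per target gene and sample,
    dCt = Ct(gene) - Ct(reference in the same sample); ddCt subtracts the
    baseline group's mean dCt; relative level = 2^(-ddCt), so the baseline
    group's geometric-mean level is 1.
    """
    required = {"gene", "sample", "group", "Ct"}
    if missing := required - set(qpcr.columns):
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    ref = qpcr[qpcr["gene"] == reference_gene].set_index("sample")["Ct"]
    targets = qpcr[qpcr["gene"] != reference_gene].copy()
    absent = sorted(set(targets["sample"]) - set(ref.index))
    if absent:
        raise ValueError(f"reference gene {reference_gene!r} missing for sample(s): {absent}")
    targets["dCt"] = targets["Ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()
    rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        base = sub.loc[sub["group"] == baseline_group, "dCt"]
        if base.empty:
            raise ValueError(f"no baseline ({baseline_group}) measurements for {gene}")
        ddct = sub["dCt"] - base.mean()
        sub = sub.assign(ddCt=ddct, relative_level=np.power(2.0, -ddct))
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def group_mean_levels(rel: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic group means of the relative levels per gene."""
    return rel.pivot_table(index="gene", columns="group", values="relative_level", aggfunc="mean")
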