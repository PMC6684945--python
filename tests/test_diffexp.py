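"""CPM normalization, the two-group t-test, significance calls and ddCt."""

import math

import numpy as np
import pandas as pd
import pytest

from follimir.diffexp import (
    call_significant,
    delta_delta_ct,
    group_mean_levels,
    normalize,
    t_test_de,
    zscore_matrix,
)

GROUPS = {"IIIa": ["IIIa_1", "IIIa_2", "IIIa_3"], "IIIb": ["IIIb_1", "IIIb_2", "IIIb_3"]}


def pooled_t(a, b):
    """Closed-form pooled-variance Student's t and its two-sided p (oracle)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (sum(b) / nb - sum(a) / na) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * tdist.sf(abs(t), na + nb - 2)


class TestNormalize:
    def test_cpm_arithmetic(self):
        m = pd.DataFrame({"s": [500, 500]}, index=["a", "b"])
        out = normalize(m)
        assert out.loc["a", "s"] == pytest.approx(5e5)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(1, 1000, (50, 6)), columns=GROUPS["IIIa"] + GROUPS["IIIb"])
        out = normalize(m)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_proportional_columns_become_identical(self):
        m = pd.DataFrame({"x": [10, 30, 60], "y": [20, 60, 120]})
        out = normalize(m)
        assert np.allclose(out["x"], out["y"])

    def test_zero_total_sample_named(self):
        m = pd.DataFrame({"good": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            normalize(m)


class TestTTest:
    def test_matches_closed_form(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6]], columns=GROUPS["IIIa"] + GROUPS["IIIb"], index=["m1"]
        ).astype(float)
        de = t_test_de(m, GROUPS)
        t_exp, p_exp = pooled_t([1, 2, 3], [4, 5, 6])
        assert de.loc["m1", "t"] == pytest.approx(t_exp, abs=1e-9)
        assert abs(de.loc["m1", "t"]) == pytest.approx(3.674, abs=1e-3)
        assert de.loc["m1", "p"] == pytest.approx(p_exp, abs=1e-9)
        assert de.loc["m1", "p"] == pytest.approx(0.0213, abs=2e-4)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(100, 20, (20, 6)), columns=GROUPS["IIIa"] + GROUPS["IIIb"])
        de = t_test_de(m, GROUPS)
        for i in range(20):
            t_exp, p_exp = pooled_t(list(m.iloc[i, :3]), list(m.iloc[i, 3:]))
            assert de["t"].iloc[i] == pytest.approx(t_exp, abs=1e-9)
            assert de["p"].iloc[i] == pytest.approx(p_exp, abs=1e-9)

    def test_identical_groups_p_one(self):
        m = pd.DataFrame([[5, 5, 5, 5, 5, 5]], columns=GROUPS["IIIa"] + GROUPS["IIIb"]).astype(float)
        de = t_test_de(m, GROUPS)
        assert de["p"].iloc[0] == 1.0 and de["t"].iloc[0] == 0.0

    def test_zero_baseline_mean_gives_infinite_fc(self):
        m = pd.DataFrame([[0, 0, 0, 5, 6, 7]], columns=GROUPS["IIIa"] + GROUPS["IIIb"]).astype(float)
        de = t_test_de(m, GROUPS)
        assert np.isinf(de["fold_change"].iloc[0])
        assert np.isnan(de["log2_fc"].iloc[0])

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(100, 20, (10, 6)), columns=GROUPS["IIIa"] + GROUPS["IIIb"])
        shuffled = m[["IIIa_2", "IIIa_3", "IIIa_1", "IIIb_3", "IIIb_1", "IIIb_2"]]
        a = t_test_de(m, GROUPS)
        b = t_test_de(shuffled, GROUPS)
        assert np.allclose(a["t"], b["t"]) and np.allclose(a["p"], b["p"])

    def test_replicate_requirement(self):
        m = pd.DataFrame([[1, 2]], columns=["IIIa_1", "IIIb_1"])
        with pytest.raises(ValueError):
            t_test_de(m, {"IIIa": ["IIIa_1"], "IIIb": ["IIIb_1"]})


class TestCalls:
    def frame(self, rows):
        return pd.DataFrame(
            [
                {"mean_IIIa": 100, "mean_IIIb": 100 * fc, "fold_change": fc, "log2_fc": np.log2(fc), "t": 0, "p": p}
                for p, fc in rows
            ],
            index=[f"m{i}" for i in range(len(rows))],
        )

    def test_rule_application(self):
        calls = call_significant(self.frame([(0.04, 3.0)]))
        assert list(calls.up.index) == ["m0"] and list(calls.strong_up.index) == ["m0"]

    def test_insignificant_large_fold_change_excluded(self):
        # emulates a strongly down-regulated miRNA excluded at p = 0.095
        calls = call_significant(self.frame([(0.095, 0.11)]))
        assert calls.down.empty and calls.strong_down.empty

    def test_significant_but_not_strong(self):
        calls = call_significant(self.frame([(0.04, 1.5)]))
        assert list(calls.up.index) == ["m0"] and calls.strong_up.empty

    def test_alpha_boundary_inclusive_fc_gates_strict(self):
        calls = call_significant(self.frame([(0.05, 2.0), (0.050001, 4.0), (0.01, 0.5)]))
        assert list(calls.up.index) == ["m0"]  # p = 0.05 is significant
        assert calls.strong_up.empty  # FC = 2 does not clear the > 2 gate
        assert list(calls.down.index) == ["m2"] and calls.strong_down.empty  # FC = 0.5 not < 1/2

    def test_strong_subset_of_significant(self):
        rng = np.random.default_rng(3)
        rows = [(float(p), float(fc)) for p, fc in zip(rng.uniform(0, 0.2, 50), rng.lognormal(0, 1, 50))]
        calls = call_significant(self.frame(rows))
        assert set(calls.strong.index) <= set(calls.up.index) | set(calls.down.index)


class TestDeltaDeltaCt:
    def qpcr(self, ct_by_group):
        rows = []
        for group, cts in ct_by_group.items():
            for i, ct in enumerate(cts):
                sample = f"{group}_{i+1}"
                rows.append({"gene": "mir-x", "sample": sample, "group": group, "Ct": ct})
                rows.append({"gene": "U6", "sample": sample, "group": group, "Ct": 18.0})
        return pd.DataFrame(rows)

    def test_equal_dct_gives_unit_levels(self):
        rel = delta_delta_ct(self.qpcr({"IIIa": [25, 25, 25], "IIIb": [25, 25, 25]}))
        assert np.allclose(rel["relative_level"], 1.0)

    def test_ddct_minus_two_gives_four(self):
        rel = delta_delta_ct(self.qpcr({"IIIa": [25, 25, 25], "IIIb": [23, 23, 23]}))
        b = rel[rel["group"] == "IIIb"]
        assert np.allclose(b["ddCt"], -2.0)
        assert np.allclose(b["relative_level"], 4.0)

    def test_baseline_geometric_mean_is_one(self):
        rel = delta_delta_ct(self.qpcr({"IIIa": [24.0, 25.5, 26.0], "IIIb": [23, 22, 24]}))
        base = rel[rel["group"] == "IIIa"]["relative_level"]
        assert np.exp(np.log(base).mean()) == pytest.approx(1.0)
        means = group_mean_levels(rel)
        assert means.loc["mir-x", "IIIb"] > 0

    def test_missing_reference_rejected(self):
        df = self.qpcr({"IIIa": [25, 25, 25], "IIIb": [25, 25, 25]})
        df = df[~((df["gene"] == "U6") & (df["sample"] == "IIIb_2"))]
        with pytest.raises(ValueError, match="IIIb_2"):
            delta_delta_ct(df)


def test_zscore_rows_centered():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.normal(10, 3, (5, 6)), columns=GROUPS["IIIa"] + GROUPS["IIIb"])
    z = zscore_matrix(m)
    assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)
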