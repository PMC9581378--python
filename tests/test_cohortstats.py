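"""Histology classifiers, screening rules and nonparametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from liversig import InputError, cohortstats
from liversig.datasets import (
    reference_comorbidity_counts,
    reference_histology_frequencies,
)

from conftest import midranks


class TestClassifiers:
    @pytest.mark.parametrize(
        "label,expected",
        [("1a", 1), ("1b", 1), ("1c", 1), ("0", 0), ("1", 1), ("4", 4), ("F2", 2)],
    )
    def test_collapse_fibrosis(self, label, expected):
        assert cohortstats.collapse_fibrosis(label) == expected

    def test_collapse_fibrosis_unknown_label(self):
        with pytest.raises(InputError):
            cohortstats.collapse_fibrosis("5")

    @pytest.mark.parametrize(
        "total,expected",
        [(0, "NAS0-1"), (1, "NAS0-1"), (2, "NAS2-3"), (3, "NAS2-3"),
         (4, "NAS4-6"), (6, "NAS4-6")],
    )
    def test_nas_group(self, total, expected):
        assert cohortstats.nas_group(total) == expected

    @pytest.mark.parametrize("total", [7, 8, -1, 9])
    def test_nas_group_outside_bins(self, total):
        with pytest.raises(InputError):
            cohortstats.nas_group(total)

    @pytest.mark.parametrize(
        "s,i,b,expected",
        [(2, 1, 1, True), (0, 1, 1, False), (1, 1, 0, False),
         (1, 0, 1, False), (3, 3, 2, True)],
    )
    def test_nash_rule(self, s, i, b, expected):
        assert cohortstats.nash_classify(s, i, b) is expected

    @pytest.mark.parametrize(
        "fib4,nfs,te,expected",
        [
            (1.40, -2.0, 5.0, True),   # FIB-4 arm
            (1.0, -2.0, 6.9, False),   # all below
            (1.0, -2.0, 7.0, True),    # inclusive elastography boundary
            (1.30, -2.0, 5.0, True),   # inclusive FIB-4 boundary
            (1.0, -1.455, 5.0, True),  # inclusive NFS boundary
            (None, None, 8.0, True),   # single score suffices
        ],
    )
    def test_eligibility(self, fib4, nfs, te, expected):
        assert cohortstats.eligibility(fib4, nfs, te) is expected

    def test_eligibility_all_missing_refused(self):
        with pytest.raises(InputError):
            cohortstats.eligibility(None, None, None)

    def test_body_composition(self):
        lean, fat_pct = cohortstats.body_composition(100.0, 40.0, 5.0)
        assert (lean, fat_pct) == (55.0, 40.0)
        assert cohortstats.body_composition(150.0, 0.0, 0.0) == (150.0, 0.0)
        with pytest.raises(InputError):
            cohortstats.body_composition(100.0, 90.0, 20.0)
        with pytest.raises(InputError):
            cohortstats.body_composition(0.0, 0.0, 0.0)


def exact_kw_p(groups):
    """Full-enumeration permutation p value for the KW statistic.

    Independent of the implementation: H is recomputed from midranks via
    the textbook rank formula for every partition of the pooled data.
    """
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    ranks = midranks(pooled)
    _, cnt = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(cnt**3 - cnt) / (n**3 - n)

    def h_of(parts):
        h = sum(ranks[list(idx)].sum() ** 2 / len(idx) for idx in parts)
        return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / tie_corr

    obs_parts = np.split(np.arange(n), np.cumsum(sizes)[:-1])
    h_obs = h_of([tuple(p) for p in obs_parts])
    count = total = 0

    def rec(remaining, chosen):
        nonlocal count, total
        if len(chosen) == len(sizes) - 1:
            total += 1
            count += h_of(chosen + [tuple(sorted(remaining))]) >= h_obs - 1e-12
            return
        k = sizes[len(chosen)]
        for combo in itertools.combinations(sorted(remaining), k):
            rec(remaining - set(combo), chosen + [combo])

    rec(set(range(n)), [])
    return count / total


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = cohortstats.kruskal_wallis([[1, 2], [1, 2]])
        assert h == pytest.approx(0.0)

    def test_hand_computed_value(self):
        h, _ = cohortstats.kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_matches_scipy_with_ties(self):
        groups = [[1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 7.0], [4.0, 4.0, 9.0, 1.0]]
        h, p = cohortstats.kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_chi2_p_close_to_exact_enumeration(self):
        """Three groups of n=4 with group shifts (the test's operating
        regime): chi-square p within 0.02 of the full-enumeration p."""
        rng = np.random.default_rng(2)
        for rep in range(4):
            groups = [
                rng.normal(loc=shift, size=4) for shift in (0.0, 2.5, 4.0)
            ]
            _, p_chi2 = cohortstats.kruskal_wallis(groups)
            p_exact = exact_kw_p(groups)
            assert abs(p_chi2 - p_exact) < 0.02

    def test_chi2_p_reasonable_in_mid_range(self):
        """Without shifts the discrete null makes mid-range p values
        agree only coarsely with chi-square at these tiny sizes."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=4) for _ in range(3)]
        _, p_chi2 = cohortstats.kruskal_wallis(groups)
        p_exact = exact_kw_p(groups)
        assert abs(p_chi2 - p_exact) < 0.1

    def test_degenerate_all_identical_refused(self):
        with pytest.raises(InputError):
            cohortstats.kruskal_wallis([[3, 3], [3, 3]])

    @given(st.sampled_from(["identity", "exp", "cube", "logistic"]))
    def test_invariance_under_monotone_transform(self, name):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=5), rng.normal(size=6), rng.normal(size=4)]
        fns = {
            "identity": lambda x: x,
            "exp": np.exp,
            "cube": lambda x: x**3,
            "logistic": lambda x: 1 / (1 + np.exp(-x)),
        }
        h1, _ = cohortstats.kruskal_wallis(groups)
        h2, _ = cohortstats.kruskal_wallis([fns[name](g) for g in groups])
        assert h1 == pytest.approx(h2)


class TestDunn:
    def test_duplicated_group_z_zero(self):
        data = np.array([1.0, 4.0, 2.0, 8.0])
        out = cohortstats.dunn_posthoc({"ref": data, "dup": data.copy()}, "ref")
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_brute_force_rank_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=7)
        b = rng.normal(loc=1.0, size=5)
        out = cohortstats.dunn_posthoc({"ref": a, "grp": b}, "ref")
        pooled = np.concatenate([a, b])
        r = midranks(pooled)
        n = len(pooled)
        var = n * (n + 1) / 12.0  # no ties in continuous draws
        z_expected = (r[7:].mean() - r[:7].mean()) / np.sqrt(
            var * (1 / 5 + 1 / 7)
        )
        assert abs(out.loc["grp vs ref", "z"] - z_expected) < 1e-12

    def test_z_increases_with_shift(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=6)
        b0 = rng.normal(size=6)
        zs = []
        for shift in [0.0, 1.0, 2.0, 5.0]:
            out = cohortstats.dunn_posthoc({"ref": a, "grp": b0 + shift}, "ref")
            zs.append(out["z"].iloc[0])
        assert all(z2 >= z1 for z1, z2 in zip(zs, zs[1:]))

    def test_two_group_z_squared_equals_kw_h(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=rng.integers(4, 9))
            b = rng.normal(size=rng.integers(4, 9))
            h, _ = cohortstats.kruskal_wallis([a, b])
            out = cohortstats.dunn_posthoc({"a": a, "b": b}, "a")
            assert out["z"].iloc[0] ** 2 == pytest.approx(h, rel=1e-9)

    def test_missing_reference_refused(self):
        with pytest.raises(InputError):
            cohortstats.dunn_posthoc({"a": [1, 2]}, "zzz")


class TestSpearman:
    def test_monotone_perfect_correlation(self):
        x = np.array([1.0, 3.0, 4.0, 9.0, 12.0])
        rho, p = cohortstats.spearman(x, np.exp(x / 5))
        assert rho == pytest.approx(1.0)
        rho_rev, _ = cohortstats.spearman(x, -x)
        assert rho_rev == pytest.approx(-1.0)

    def test_tied_fixture_matches_rank_pearson(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 7.0, 6.0]
        rho, _ = cohortstats.spearman(x, y)
        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho)
        _, p = cohortstats.spearman(x, y)
        assert p == pytest.approx(ref_p, rel=1e-9)

    def test_exact_permutation_option(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p_exact = cohortstats.spearman(x, y, exact=True)
        # p = P(|rho_perm| >= |rho_obs|) under uniform permutations
        assert 0 < p_exact <= 1
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)

    def test_constant_vector_refused(self):
        with pytest.raises(InputError):
            cohortstats.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_short_input_refused(self):
        with pytest.raises(InputError):
            cohortstats.spearman([1, 2, 3], [1, 2, 3])


class TestSummaries:
    def make_sheet(self):
        rng = np.random.default_rng(9)
        rows = []
        for g, n, shift in [("NAS0-1", 8, 0.0), ("NAS2-3", 12, 0.0), ("NAS4-6", 6, 30.0)]:
            for i in range(n):
                rows.append(
                    {
                        "participant_id": f"P{g}{i}",
                        "nas_group": g,
                        "steatosis": 1,
                        "alt": rng.normal(30 + shift, 3),
                        "age": rng.normal(50, 8),
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_shift_detected(self):
        summary, _ = cohortstats.summarize_cohort(self.make_sheet())
        alt_row = summary[summary["variable"] == "alt"].iloc[0]
        age_row = summary[summary["variable"] == "age"].iloc[0]
        assert alt_row["kw_p"] < 0.05
        assert age_row["kw_p"] > 0.05

    def test_frequency_rows_sum_to_group_sizes(self):
        _, freq = cohortstats.summarize_cohort(self.make_sheet())
        steat = freq[freq["variable"] == "steatosis"]
        assert steat["NAS0-1"].sum() == 8
        assert steat["NAS2-3"].sum() == 12
        assert steat["NAS4-6"].sum() == 6

    def test_single_participant_group_degenerate_iqr(self):
        sheet = pd.DataFrame(
            {
                "participant_id": ["P1", "P2", "P3"],
                "nas_group": ["A", "A", "B"],
                "val": [1.0, 3.0, 7.0],
            }
        )
        summary, _ = cohortstats.summarize_cohort(sheet)
        b_cell = summary[summary["variable"] == "val"]["B"].iloc[0]
        assert b_cell == "7 (7;7)"


class TestFilterCount:
    def test_fibrosis_stage_ge1_total(self):
        freq = reference_histology_frequencies()
        n = cohortstats.filter_count(
            freq, lambda grade: int(grade) >= 1, variable="fibrosis_stage"
        )
        assert n == 8

    def test_nash_yes_total(self):
        freq = reference_histology_frequencies()
        assert cohortstats.filter_count(
            freq, lambda g: g == "yes", variable="nash"
        ) == 5

    def test_comorbidity_totals(self):
        com = reference_comorbidity_counts()
        t2d = cohortstats.filter_count(com, lambda g: g == "yes", variable="type2_diabetes")
        htn = cohortstats.filter_count(com, lambda g: g == "yes", variable="hypertension")
        assert (t2d, htn) == (10, 12)

    def test_histology_marginals_sum_to_cohort(self):
        freq = reference_histology_frequencies()
        for var in freq["variable"].unique():
            assert cohortstats.filter_count(freq, lambda g: True, variable=var) == 26

    def test_sheet_predicate_and_empty(self):
        sheet = pd.DataFrame(
            {"participant_id": ["P1", "P2"], "fibrosis_stage": [0, 2]}
        )
        n = cohortstats.filter_count(sheet, lambda row: row["fibrosis_stage"] >= 1)
        assert n == 1
        assert cohortstats.filter_count(sheet.iloc[0:0], lambda row: True) == 0

    def test_unknown_variable_refused(self):
        with pytest.raises(InputError):
            cohortstats.filter_count(
                reference_histology_frequencies(), lambda g: True, variable="nope"
            )
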