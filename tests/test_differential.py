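"""Differential abundance: ANOVA/BH against brute force, DAP set logic,
effect-size concordance, peptide mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from csfnet.differential import (
    DAPTable,
    anova_bh,
    bh_adjust,
    compare_dap_sets,
    effectsize_concordance,
    map_peptides_to_sequence,
    oneway_anova,
)
from csfnet.exceptions import InsufficientOverlapError


def make_matrix(rows, columns=None):
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    columns = columns or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"P{i}|G{i}" for i in range(arr.shape[0])],
                        columns=columns)


def groups_series(labels, columns):
    return pd.Series(labels, index=columns)


class TestAnovaBH:
    def test_closed_form_two_group_example(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6]])
        g = groups_series(list("AAABBB"), m.columns)
        t = anova_bh(m, g, [("A", "B")])[0]
        assert t.table["F"].iloc[0] == pytest.approx(13.5)
        assert t.table["p"].iloc[0] == pytest.approx(0.0213, abs=2e-4)
        assert t.table["log2_diff"].iloc[0] == pytest.approx(3.0)
        assert t.table["direction"].iloc[0] == "up"

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.standard_normal((10, 12)))
        g = groups_series(["A"] * 6 + ["B"] * 6, m.columns)
        t1 = anova_bh(m, g, [("A", "B")])[0]
        t2 = anova_bh(m + 7.0, g, [("A", "B")])[0]
        assert np.allclose(t1.table["F"], t2.table["F"])
        assert np.allclose(t1.table["p"], t2.table["p"])

    @pytest.mark.parametrize("seed", range(10))
    def test_f_equals_squared_pooled_t(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(7), rng.standard_normal(5) + 0.5
        m = make_matrix([np.concatenate([a, b])])
        g = groups_series(["A"] * 7 + ["B"] * 5, m.columns)
        res = anova_bh(m, g, [("A", "B")])[0]
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.table["F"].iloc[0] == pytest.approx(t_stat**2, abs=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_insufficient_group_reported_untested(self):
        m = make_matrix([[1.0, np.nan, np.nan, 4.0, 5.0, 6.0]])
        g = groups_series(list("AAABBB"), m.columns)
        t = anova_bh(m, g, [("A", "B")])[0]
        assert np.isnan(t.table["p"].iloc[0])
        assert t.table["direction"].iloc[0] == "untested"

    def test_unknown_group_label_rejected(self):
        m = make_matrix([[1, 2, 3, 4]])
        g = groups_series(list("AABB"), m.columns)
        with pytest.raises(KeyError):
            anova_bh(m, g, [("A", "C")])

    def test_multigroup_matches_scipy(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.standard_normal((5, 15)))
        g = groups_series(["A"] * 5 + ["B"] * 5 + ["C"] * 5, m.columns)
        res = oneway_anova(m, g)
        for i in range(5):
            f, p = stats.f_oneway(m.iloc[i, :5], m.iloc[i, 5:10], m.iloc[i, 10:])
            assert res["F"].iloc[i] == pytest.approx(f, abs=1e-10)
            assert res["p"].iloc[i] == pytest.approx(p, abs=1e-12)


def bh_oracle(p):
    """Literal step-up procedure."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        q[idx] = prev
    return q


class TestBH:
    def test_worked_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.04, 0.50]))
        assert q == pytest.approx([0.04, 0.04, 0.0533333, 0.50], abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_exhaustive_reference(self, pvals):
        p = np.array(pvals)
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_q_dominates_p_and_is_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCompareDapSets:
    def _table(self, pvals):
        idx = [f"P{i}|G{i}" for i in range(len(pvals))]
        return DAPTable(("A", "B"), pd.DataFrame({
            "log2_diff": 1.0, "F": 1.0, "p": pvals, "q": pvals,
            "direction": "up", "n_A": 3, "n_B": 3}, index=idx))

    def test_identical_tables_all_shared(self):
        t = self._table([0.01, 0.2, 0.04])
        membership, counts = compare_dap_sets([t, t])
        assert counts.get("11", 0) == 2 and counts.get("10", 0) == 0

    def test_disjoint_sets(self):
        a = self._table([0.01, 0.01, 0.01, 0.9, 0.9])
        b = self._table([0.9, 0.9, 0.9, 0.01, 0.01])
        _, counts = compare_dap_sets([a, b])
        assert counts.get("11", 0) == 0
        assert counts["10"] == 3 and counts["01"] == 2

    def test_empty_significance_boundary(self):
        a = self._table([0.01, 0.9])
        b = self._table([0.9, 0.9])
        _, counts = compare_dap_sets([a, b])
        assert counts.get("01", 0) == 0 and counts.get("11", 0) == 0


class TestConcordance:
    def _table(self, diffs, pvals=None):
        idx = [f"P{i}|G{i}" for i in range(len(diffs))]
        p = pvals if pvals is not None else [0.01] * len(diffs)
        return DAPTable(("A", "B"), pd.DataFrame({
            "log2_diff": diffs, "F": 1.0, "p": p, "q": p,
            "direction": "up", "n_A": 3, "n_B": 3}, index=idx))

    def test_identity_and_antisymmetry(self):
        t = self._table([1, 2, 3, -1, -2, 0.5])
        r = effectsize_concordance(t, t)
        assert r.bicor_r == pytest.approx(1.0)
        assert r.quadrant_counts["a_up_b_down"] == 0
        flipped = self._table([-1, -2, -3, 1, 2, -0.5])
        r2 = effectsize_concordance(t, flipped)
        assert r2.bicor_r == pytest.approx(-1.0)
        assert r2.quadrant_counts["both_up"] == 0 and r2.quadrant_counts["both_down"] == 0

    def test_six_protein_toy_quadrants_and_oracle(self):
        def bicor_oracle(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)

            def weighted(v):
                med = np.median(v)
                u = (v - med) / (9 * np.median(np.abs(v - med)))
                return (v - med) * (1 - u**2) ** 2 * (np.abs(u) < 1)

            a, b = weighted(x), weighted(y)
            return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))

        a = self._table([1, 2, 3, -1, -2, 0.5])
        b = self._table([0.9, 2.2, 2.7, -1.2, -1.8, -0.4])
        r = effectsize_concordance(a, b)
        assert r.quadrant_counts == {"both_up": 3, "both_down": 2,
                                     "a_up_b_down": 1, "a_down_b_up": 0}
        expected = bicor_oracle([1, 2, 3, -1, -2, 0.5], [0.9, 2.2, 2.7, -1.2, -1.8, -0.4])
        assert r.bicor_r == pytest.approx(expected, abs=1e-6)
        assert r.n_shared == 6

    def test_restricts_to_jointly_significant(self):
        a = self._table([1, 2, 3, 4, 5, 6], [0.01] * 5 + [0.9])
        b = self._table([1, 2, 3, 4, 5, -6], [0.01] * 6)
        r = effectsize_concordance(a, b)
        assert r.n_shared == 5  # the discordant protein is not significant in a
        assert r.quadrant_counts["a_up_b_down"] == 0

    def test_too_few_shared_raises(self):
        a = self._table([1, 2], [0.01, 0.9])
        b = self._table([1, 2], [0.01, 0.01])
        with pytest.raises(InsufficientOverlapError):
            effectsize_concordance(a, b)


class TestPeptideMapping:
    def test_exact_coordinates(self):
        out = map_peptides_to_sequence(["CDE"], "ABCDEFG")
        assert out.iloc[0][["start", "end"]].tolist() == [3, 5]

    def test_unmatched_flagged(self):
        out = map_peptides_to_sequence(["WWW"], "ABCDEFG")
        assert not out["mapped"].iloc[0]
        assert out["start"].isna().iloc[0]

    def test_repeated_occurrence_ascending(self):
        out = map_peptides_to_sequence(["AB"], "ABCDAB")
        assert out["start"].tolist() == [1, 5]

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            map_peptides_to_sequence([""], "ABCDEFG")
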