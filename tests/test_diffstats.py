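"""Protein roll-up, gated tests, BH correction and fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vitreomics.annotation import Assignment, TheoreticalPeptide
from vitreomics.diffstats import (
    bh_adjust,
    differential_test,
    fold_change,
    protein_abundance_matrix,
    results_frame,
    summarize_results,
)


def brute_force_bh(pvals, m_total):
    """Direct step-up definition: adj(i) = min_{rank j >= rank i} p_(j)*m/j."""
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    out = [0.0] * len(pvals)
    for pos, i in enumerate(order):
        vals = [
            pvals[order[q]] * m_total / (q + 1)
            for q in range(pos, len(order))
        ]
        out[i] = min(1.0, min(vals))
    return out


class TestBhAdjust:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            n = int(rng.integers(1, 25))
            p = rng.uniform(1e-8, 1.0, n)
            m = n + int(rng.integers(0, 10))
            assert np.allclose(bh_adjust(p, m), brute_force_bh(list(p), m), atol=1e-12)

    def test_statsmodels_padding_crosscheck(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 0.2, 12)
        m = 40
        padded = np.concatenate([p, np.ones(m - p.size)])
        expected = multipletests(padded, method="fdr_bh")[1][: p.size]
        assert np.allclose(bh_adjust(p, m), expected, atol=1e-12)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_adjusted_at_least_raw_and_order_invariant(self, p):
        adj = bh_adjust(p)
        assert all(a >= r - 1e-15 for a, r in zip(adj, p))
        rev = bh_adjust(p[::-1])
        assert np.allclose(adj[::-1], rev, atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.5], [float("nan")]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_m_total_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m_total=1)


class TestDifferentialTest:
    def test_permuted_identical_groups_give_p_one(self):
        p, _ = differential_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert p == 1.0

    def test_constant_equal_groups_give_p_one(self):
        p, used = differential_test([5.0] * 4, [5.0] * 4)
        assert p == 1.0 and used == "t"

    def test_unequal_variance_routes_to_ranksum(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 10, 20)
        y = rng.normal(0, 0.1, 20)
        _, used = differential_test(x, y)
        assert used == "ranksum"

    def test_equal_variance_routes_to_t(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        _, used = differential_test(x, y)
        assert used == "t"

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            differential_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_power_at_two_sd_shift(self):
        """Location shift of 2 SD at n=(20,15): power >= 0.9."""
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(500):
            x = rng.normal(2.0, 1.0, 20)
            y = rng.normal(0.0, 1.0, 15)
            p, _ = differential_test(x, y)
            hits += p < 0.05
        assert hits / 500 >= 0.9


class TestFoldChange:
    def test_identical_groups(self):
        f, _ = fold_change([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert f == pytest.approx(1.0)

    @given(
        st.floats(min_value=0.1, max_value=100.0),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(3, 0.5, 8)
        y = rng.lognormal(3, 0.5, 6)
        f1, sd1 = fold_change(x, y)
        f2, sd2 = fold_change(x * c, y * c)
        assert f1 == pytest.approx(f2, rel=1e-9)
        assert sd1 == pytest.approx(sd2, rel=1e-9)

    def test_zero_control_mean_flagged(self):
        with pytest.raises(ValueError):
            fold_change([1.0, 2.0], [0.0, 0.0])


def _assignment(cid, seq, prot):
    return Assignment(
        consensus_id=cid,
        peptide=TheoreticalPeptide(seq, prot, 0, monoisotopic_mass=1000.0),
        mass_error_ppm=0.0,
        charge_consistent=True,
    )


class TestProteinMatrix:
    def _matrix(self, values, sids):
        df = pd.DataFrame(values, columns=sids, index=["c1", "c2"])
        df.insert(0, "frequency", 1.0)
        df.insert(0, "time", 30.0)
        df.insert(0, "mass", 1000.0)
        return df

    def test_mean_of_detected_peptides(self):
        mat = self._matrix([[2.0, np.nan], [4.0, np.nan]], ["a", "b"])
        asg = [_assignment("c1", "AAK", "P1"), _assignment("c2", "GGK", "P1")]
        table = protein_abundance_matrix(asg, mat, {"a": "case", "b": "control"})
        assert table.loc["P1", "a"] == pytest.approx(3.0)
        assert table.loc["P1", "b"] == 0.0  # undetected -> 0 by convention

    def test_unlabelled_sample_is_manifest_error(self):
        mat = self._matrix([[2.0, 3.0], [4.0, 5.0]], ["a", "b"])
        with pytest.raises(KeyError):
            protein_abundance_matrix(
                [_assignment("c1", "AAK", "P1")], mat, {"a": "case"}
            )


class TestSummarize:
    def _labels(self, n_case, n_ctrl):
        return {f"c{i}": "case" for i in range(n_case)} | {
            f"k{i}": "control" for i in range(n_ctrl)
        }

    def test_null_cohort_false_positive_envelope(self):
        """97 null proteins: raw p < 0.05 count inside the binomial 99% band."""
        rng = np.random.default_rng(31)
        labels = self._labels(20, 15)
        table = pd.DataFrame(
            rng.lognormal(8, 0.4, (97, 35)),
            index=[f"P{i}" for i in range(97)],
            columns=list(labels),
        )
        results = summarize_results(table, labels)
        n_sig = sum(r.significant_raw for r in results)
        assert 0 <= n_sig <= 12

    def test_spiked_protein_ranks_first(self):
        """A fold-4 spike attains the smallest raw p in >=90% of replicates."""
        rng = np.random.default_rng(37)
        labels = self._labels(20, 15)
        wins = 0
        for _ in range(50):
            vals = rng.lognormal(8, 0.4, (20, 35))
            vals[0, :20] *= 4.0
            table = pd.DataFrame(
                vals, index=[f"P{i}" for i in range(20)], columns=list(labels)
            )
            results = summarize_results(table, labels)
            wins += results[0].protein == "P0"
        assert wins >= 45

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(41)
        labels = self._labels(5, 5)
        table = pd.DataFrame(
            rng.lognormal(5, 0.5, (10, 10)),
            index=[f"P{i}" for i in range(10)],
            columns=list(labels),
        )
        res = summarize_results(table, labels)
        adj = [r.adj_p for r in res]  # res sorted by raw p
        assert adj == sorted(adj)
        assert all(r.adj_p >= r.raw_p for r in res)

    def test_empty_label_intersection_gives_empty_report(self):
        table = pd.DataFrame({"s1": [1.0]}, index=["P1"])
        assert summarize_results(table, {"x": "case"}) == []

    def test_results_frame_columns(self):
        labels = self._labels(3, 3)
        table = pd.DataFrame(
            np.ones((2, 6)) + np.arange(6) * 0.01,
            index=["P1", "P2"],
            columns=list(labels),
        )
        df = results_frame(summarize_results(table, labels))
        assert list(df.columns) == [
            "protein", "fold_change", "fold_sd", "raw_p", "adj_p",
            "test_used", "significant_adj",
        ]
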