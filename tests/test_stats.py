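"""Median polish, differential testing, BH/Fisher oracles, CV and KSEA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mistraq import stats as mst


def bh_oracle(pvalues):
    """Step-up BH by the textbook formula."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted


def hypergeom_oracle(a, b, c, d):
    """Upper-tail P(X >= a) by direct summation of hypergeometric terms."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    total = 0
    for k in range(a, min(K, n) + 1):
        if n - k > N - K:
            continue
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom


class TestMedianPolish:
    def test_additive_matrix_sample_summaries(self):
        matrix = pd.DataFrame(
            [[10.0, 11.0], [12.0, 13.0]], columns=["s1", "s2"]
        )
        summary = mst.summarize_protein(matrix)
        assert summary["s1"] == pytest.approx(11.0)
        assert summary["s2"] == pytest.approx(12.0)

    def test_single_precursor_passthrough(self):
        matrix = pd.DataFrame([[9.5, 10.5, 11.0]], columns=["a", "b", "c"])
        summary = mst.summarize_protein(matrix)
        assert summary.to_numpy() == pytest.approx([9.5, 10.5, 11.0])

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(10, 1, size=(4, 6)))
        shifted = matrix + 2.5
        a = mst.summarize_protein(matrix)
        b = mst.summarize_protein(shifted)
        assert b.to_numpy() == pytest.approx(a.to_numpy() + 2.5)

    def test_all_missing_sample_is_nan(self):
        matrix = pd.DataFrame(
            [[10.0, np.nan], [12.0, np.nan]], columns=["s1", "s2"]
        )
        summary = mst.summarize_protein(matrix)
        assert np.isfinite(summary["s1"])
        assert np.isnan(summary["s2"])

    def test_decomposition_reconstructs(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(5, 4))
        overall, row, col, resid = mst.median_polish(X, max_iter=50)
        recon = overall + row[:, None] + col[None, :] + resid
        assert recon == pytest.approx(X, abs=1e-9)


class TestDifferential:
    def _matrix(self, a_vals, b_vals):
        data = {f"a{i}": [v] for i, v in enumerate(a_vals)}
        data.update({f"b{i}": [v] for i, v in enumerate(b_vals)})
        return pd.DataFrame(data, index=["feat"])

    def test_exact_fold_change_and_t(self):
        m = self._matrix([9.9, 10.0, 10.1], [10.9, 11.0, 11.1])
        res = mst.differential(
            m, [c for c in m if c.startswith("a")],
            [c for c in m if c.startswith("b")],
        )
        assert res.loc["feat", "log2fc"] == pytest.approx(1.0)
        # independent pooled-t computation via scipy
        t, p = sps.ttest_ind(
            [10.9, 11.0, 11.1], [9.9, 10.0, 10.1], equal_var=True
        )
        assert res.loc["feat", "p"] == pytest.approx(p)

    def test_identical_groups(self):
        m = self._matrix([10.0, 10.0], [10.0, 10.0])
        res = mst.differential(m, ["a0", "a1"], ["b0", "b1"])
        assert res.loc["feat", "log2fc"] == 0.0
        assert res.loc["feat", "p"] == 1.0

    def test_insufficient_replication_gives_nan_p(self):
        m = self._matrix([10.0], [11.0, 11.2])
        res = mst.differential(m, ["a0"], ["b0", "b1"])
        assert np.isnan(res.loc["feat", "p"])
        assert res.loc["feat", "log2fc"] == pytest.approx(1.1)

    def test_bh_worked_example(self):
        adj = mst.bh_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    @given(
        st.lists(
            st.floats(min_value=1e-8, max_value=1.0),
            min_size=1,
            max_size=20,
        )
    )
    def test_bh_oracle_equivalence(self, pvalues):
        assert mst.bh_adjust(pvalues) == pytest.approx(bh_oracle(pvalues))

    @given(
        st.lists(
            st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=20
        )
    )
    def test_bh_monotone_and_dominates_raw(self, pvalues):
        adj = mst.bh_adjust(pvalues)
        p = np.asarray(pvalues)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestAdjustPhosphosite:
    def _site(self, fc, se, df=10.0):
        return pd.DataFrame(
            {"log2fc": [fc], "se": [se], "df": [df]}, index=["PROT1:10"]
        )

    def _protein(self, fc, se, df=10.0):
        return pd.DataFrame(
            {"log2fc": [fc], "se": [se], "df": [df]}, index=["PROT1"]
        )

    def test_difference_and_quadrature(self):
        res = mst.adjust_phosphosite(
            self._site(1.2, 0.1),
            self._protein(0.5, 0.1),
            {"PROT1:10": "PROT1"},
        )
        assert res.loc["PROT1:10", "log2fc"] == pytest.approx(0.7)
        assert res.loc["PROT1:10", "se"] == pytest.approx(
            math.sqrt(0.02), abs=1e-6
        )
        # equal variances: Satterthwaite df = 2 * df
        assert res.loc["PROT1:10", "df"] == pytest.approx(20.0)
        assert res.loc["PROT1:10", "corrected"].item()

    def test_null_protein_leaves_fc(self):
        res = mst.adjust_phosphosite(
            self._site(0.8, 0.1), self._protein(0.0, 0.1), {"PROT1:10": "PROT1"}
        )
        assert res.loc["PROT1:10", "log2fc"] == pytest.approx(0.8)

    def test_site_equal_to_protein_is_zero(self):
        res = mst.adjust_phosphosite(
            self._site(0.6, 0.1), self._protein(0.6, 0.1), {"PROT1:10": "PROT1"}
        )
        assert res.loc["PROT1:10", "log2fc"] == pytest.approx(0.0)

    def test_unquantified_protein_passes_through(self):
        res = mst.adjust_phosphosite(
            self._site(0.9, 0.1),
            pd.DataFrame(columns=["log2fc", "se", "df"]),
            {"PROT1:10": "PROT1"},
        )
        assert res.loc["PROT1:10", "log2fc"] == pytest.approx(0.9)
        assert not res.loc["PROT1:10", "corrected"].item()


class TestCvDistribution:
    def test_worked_example(self):
        m = pd.DataFrame([[100.0, 110.0, 90.0]], columns=list("abc"))
        cv, median = mst.cv_distribution(m, list("abc"))
        assert cv.iloc[0] == pytest.approx(10.0)
        assert median == pytest.approx(10.0)

    def test_constant_replicates(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]], columns=list("abc"))
        cv, _ = mst.cv_distribution(m, list("abc"))
        assert cv.iloc[0] == 0.0

    def test_single_replicate_skipped(self):
        m = pd.DataFrame(
            [[5.0, np.nan, np.nan]], columns=list("abc"), index=["x"]
        )
        cv, median = mst.cv_distribution(m, list("abc"))
        assert len(cv) == 0 and np.isnan(median)


class TestFisher:
    def test_worked_example_vs_oracle(self):
        # kinase: 10 substrates, 5 regulated; background 100 sites with 10
        # regulated in total
        a, b, c, d = 5, 5, 5, 85
        assert mst.fisher_upper_tail(a, b, c, d) == pytest.approx(
            hypergeom_oracle(a, b, c, d), rel=1e-10
        )

    def test_matches_scipy_fisher(self):
        table = [[4, 6], [8, 42]]
        expected = sps.fisher_exact(table, alternative="greater")[1]
        assert mst.fisher_upper_tail(4, 6, 8, 42) == pytest.approx(expected)

    @given(
        st.integers(0, 12),
        st.integers(0, 12),
        st.integers(0, 12),
        st.integers(0, 12),
    )
    def test_oracle_equivalence_random_tables(self, a, b, c, d):
        assert mst.fisher_upper_tail(a, b, c, d) == pytest.approx(
            hypergeom_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestKsea:
    def _inputs(self, n_sites=100, n_sub=10, n_reg_sub=5, n_reg_other=5):
        sites = [f"P{i}:1" for i in range(n_sites)]
        fc = np.zeros(n_sites)
        adj = np.ones(n_sites)
        for i in range(n_reg_sub):
            fc[i], adj[i] = 2.0, 0.001
        for i in range(n_sub, n_sub + n_reg_other):
            fc[i], adj[i] = 2.0, 0.001
        results = pd.DataFrame(
            {"log2fc": fc, "adj_p": adj}, index=sites
        )
        annotations = pd.DataFrame(
            {
                "kinase": ["KIN_A"] * n_sub,
                "protein": [f"P{i}" for i in range(n_sub)],
                "site": [1] * n_sub,
            }
        )
        return results, annotations

    def test_enriched_kinase_p_equals_hypergeometric_tail(self):
        results, annotations = self._inputs()
        out = mst.ksea(results, annotations)
        row = out[(out["kinase_id"] == "KIN_A") & (out["direction"] == "up")]
        assert row["p"].iloc[0] == pytest.approx(
            hypergeom_oracle(5, 5, 5, 85), rel=1e-9
        )
        assert row["n_regulated"].iloc[0] == 5
        assert row["reported"].item()

    def test_background_rate_not_enriched(self):
        # substrate regulation rate equals background: 1/10 vs 10/100
        results, annotations = self._inputs(n_reg_sub=1, n_reg_other=9)
        out = mst.ksea(results, annotations)
        row = out[(out["kinase_id"] == "KIN_A") & (out["direction"] == "up")]
        assert row["p"].iloc[0] > 0.2
        assert not row["reported"].item()

    def test_min_regulated_gate(self):
        # overwhelming signal but only 3 regulated substrates -> excluded
        results, annotations = self._inputs(
            n_sites=400, n_sub=3, n_reg_sub=3, n_reg_other=2
        )
        out = mst.ksea(results, annotations)
        row = out[(out["kinase_id"] == "KIN_A") & (out["direction"] == "up")]
        assert row["adj_p"].iloc[0] < 0.05
        assert not row["reported"].item()

    def test_planted_signature_ranks_first(self, small_result, small_config):
        from mistraq import simulate as sim

        rec = sim.recovery_suite(small_result, small_config)
        planted = rec["ksea"][small_config.planted_kinase_strain]
        assert planted["planted_kinase_rank"] == 1
        assert planted["planted_kinase_reported"]

    def test_zscore_mode_flags_shifted_substrates(self):
        rng = np.random.default_rng(5)
        sites = [f"P{i}:1" for i in range(200)]
        fc = rng.normal(0, 0.2, 200)
        fc[:15] += 1.5
        results = pd.DataFrame(
            {"log2fc": fc, "adj_p": np.ones(200)}, index=sites
        )
        annotations = pd.DataFrame(
            {
                "kinase": ["KIN_A"] * 15 + ["KIN_B"] * 15,
                "protein": [f"P{i}" for i in range(30)],
                "site": [1] * 30,
            }
        )
        out = mst.ksea(results, annotations, method="zscore")
        pa = out[out["kinase_id"] == "KIN_A"]["p"].iloc[0]
        pb = out[out["kinase_id"] == "KIN_B"]["p"].iloc[0]
        assert pa < 1e-6 < pb
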