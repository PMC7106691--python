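"""Normalization, paired testing, FDR control and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

import himpairs as hp
from himpairs.prefilter import bh_adjust
from conftest import paired_design


# ---------------------------------------------------------------------------
# independent oracles, written as literal transcriptions of the definitions
# ---------------------------------------------------------------------------

def tmm_factors_oracle(X: np.ndarray) -> np.ndarray:
    """Literal per-gene-loop transcription of the trimmed-mean-of-M-values
    definition, structured independently of the vectorized implementation."""
    n_samp = X.shape[1]
    lib = X.sum(axis=0)
    uq = np.array([np.quantile(X[:, k], 0.75) / lib[k] for k in range(n_samp)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for k in range(n_samp):
        m_vals, a_vals, weights = [], [], []
        for g in range(X.shape[0]):
            o, r = X[g, k], X[g, ref]
            if o <= 0 or r <= 0:
                continue
            m = np.log2((o / lib[k]) / (r / lib[ref]))
            a = 0.5 * np.log2((o / lib[k]) * (r / lib[ref]))
            w = (lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r)
            if np.isfinite(m) and np.isfinite(a) and np.isfinite(w):
                m_vals.append(m); a_vals.append(a); weights.append(w)
        m_vals, a_vals, weights = map(np.asarray, (m_vals, a_vals, weights))
        if m_vals.size == 0 or np.max(np.abs(m_vals)) < 1e-6:
            factors.append(1.0)
            continue
        n = m_vals.size
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        rm, ra = stats.rankdata(m_vals), stats.rankdata(a_vals)
        keep = [(rm[i] >= lo_m) and (rm[i] <= n + 1 - lo_m)
                and (ra[i] >= lo_a) and (ra[i] <= n + 1 - lo_a) for i in range(n)]
        keep = np.asarray(keep)
        num = sum(m_vals[i] / weights[i] for i in range(n) if keep[i])
        den = sum(1.0 / weights[i] for i in range(n) if keep[i])
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force step-up: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = running
    return q


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5.0, 10.0, 100.0, 3.0])
        expr = hp.ExpressionMatrix(np.tile(col[:, None], (1, 4)),
                                   list("abcd"), [f"s{i}" for i in range(4)], "mRNA")
        np.testing.assert_allclose(hp.tmm_factors(expr), np.ones(4), atol=1e-12)

    def test_library_size_invariance(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(40, size=50).astype(float) + 1
        # a column that is an exact multiple of the reference has identical
        # composition: all M-values are zero and its factor is exactly 1
        X = np.column_stack([col, 2 * col])
        expr = hp.ExpressionMatrix(X, [f"g{i}" for i in range(50)],
                                   ["s0", "s1"], "mRNA")
        np.testing.assert_allclose(hp.tmm_factors(expr), [1.0, 1.0], atol=1e-12)
        # with unrelated columns present the invariance is approximate (the
        # precision weights depend on library depth)
        base = rng.poisson(40, size=(50, 3)).astype(float) + 1
        doubled = np.column_stack([base, 2 * base[:, 0]])
        expr4 = hp.ExpressionMatrix(doubled, [f"g{i}" for i in range(50)],
                                    [f"s{i}" for i in range(4)], "mRNA")
        f = hp.tmm_factors(expr4)
        np.testing.assert_allclose(f[3], f[0], rtol=2e-2)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(11)
        X = rng.negative_binomial(4, 0.08, size=(20, 4)).astype(float)
        X[0, 1] = 0  # exercise the zero-exclusion rule
        expr = hp.ExpressionMatrix(X, [f"g{i}" for i in range(20)],
                                   [f"s{i}" for i in range(4)], "mRNA")
        np.testing.assert_allclose(hp.tmm_factors(expr), tmm_factors_oracle(X), atol=1e-8)

    def test_matches_edger_reference(self, tmp_path):
        import subprocess
        rng = np.random.default_rng(42)
        X = rng.negative_binomial(5, 0.05, size=(200, 6)).astype(float)
        X[rng.random(X.shape) < 0.1] = 0
        np.savetxt(tmp_path / "c.tsv", X, delimiter="\t", fmt="%d")
        script = (f'suppressMessages(library(edgeR));'
                  f'X<-as.matrix(read.table("{tmp_path}/c.tsv"));'
                  f'cat(format(calcNormFactors(X,method="TMM"),digits=15))')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        expr = hp.ExpressionMatrix(X, [f"g{i}" for i in range(200)],
                                   [f"s{i}" for i in range(6)], "mRNA")
        np.testing.assert_allclose(hp.tmm_factors(expr), ref, atol=1e-8)

    def test_geometric_mean_one_and_global_rescale_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(60, size=(80, 5)).astype(float) + 1
        expr = hp.ExpressionMatrix(X, [f"g{i}" for i in range(80)],
                                   [f"s{i}" for i in range(5)], "mRNA")
        f = hp.tmm_factors(expr)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12
        scaled = hp.ExpressionMatrix(3.0 * X, expr.feature_ids, expr.sample_ids, "mRNA")
        np.testing.assert_allclose(hp.tmm_factors(scaled), f, rtol=1e-9)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            hp.tmm_factors(hp.ExpressionMatrix(np.ones((3, 1)), list("abc"), ["s"], "mRNA"))
        X = np.ones((3, 2)); X[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            hp.tmm_factors(hp.ExpressionMatrix(X, list("abc"), ["s1", "s2"], "mRNA"))


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def test_log_transform_values_and_round_trip():
    expr = hp.ExpressionMatrix(np.array([[0.0, 3.0, 7.0]]), ["g"],
                               ["s1", "s2", "s3"], "mRNA")
    logm = hp.log_transform(expr, base=2, pseudocount=1)
    np.testing.assert_allclose(logm.values, [[0.0, 2.0, 3.0]])
    back = hp.prefilter.inverse_log_transform(logm, base=2, pseudocount=1)
    np.testing.assert_allclose(back.values, expr.values, atol=1e-12)
    with pytest.raises(ValueError, match="pseudocount"):
        hp.log_transform(expr, pseudocount=0)
    with pytest.raises(ValueError, match="already"):
        hp.log_transform(logm)


# ---------------------------------------------------------------------------
# paired t-test + BH
# ---------------------------------------------------------------------------

class TestPairedTTest:
    def _log_matrix(self, vals, design):
        return hp.ExpressionMatrix(vals, [f"g{i}" for i in range(vals.shape[0])],
                                   design.sample_ids, "mRNA", scale="log")

    def test_matches_textbook_formula_and_scipy(self):
        design = paired_design(10)
        rng = np.random.default_rng(2)
        vals = rng.normal(8, 1, size=(100, 20))
        expr = self._log_matrix(vals, design)
        table = hp.paired_ttest(expr, design)
        t_idx, n_idx = design.pair_indices()
        d = vals[:, t_idx] - vals[:, n_idx]
        t_manual = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(10))
        p_manual = 2 * stats.t.sf(np.abs(t_manual), df=9)
        np.testing.assert_allclose(table["t_stat"], t_manual, rtol=1e-12)
        np.testing.assert_allclose(table["p_value"], p_manual, rtol=1e-12)
        t_sp, p_sp = stats.ttest_rel(vals[:, t_idx], vals[:, n_idx], axis=1)
        np.testing.assert_allclose(table["t_stat"], t_sp, rtol=1e-10)
        np.testing.assert_allclose(table["p_value"], p_sp, rtol=1e-10)
        np.testing.assert_allclose(table["fdr"], bh_oracle(p_manual), rtol=1e-12)

    def test_label_swap_negates_t_and_preserves_p(self):
        design = paired_design(6)
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, size=(30, 12))
        expr = self._log_matrix(vals, design)
        flipped = hp.PairedDesign(design.sample_ids, design.patient_ids,
                                  1 - design.status)
        a = hp.paired_ttest(expr, design)
        b = hp.paired_ttest(expr, flipped)
        np.testing.assert_allclose(a["t_stat"], -b["t_stat"], rtol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-12)

    def test_zero_variance_difference_is_flagged_not_nan(self):
        design = paired_design(5)
        vals = np.zeros((2, 10))
        vals[0, design.status == 1] = 1.0  # d = (1,1,...,1): constant, sd 0
        vals[1] = np.random.default_rng(0).normal(size=10)
        expr = self._log_matrix(vals, design)
        table = hp.paired_ttest(expr, design)
        assert bool(table.loc[0, "degenerate"])
        assert table.loc[0, "p_value"] == 1.0
        assert not bool(table.loc[0, "passes"])
        assert np.isfinite(table["t_stat"]).all()

    def test_fold_change_uses_raw_medians_with_infinity_sentinel(self):
        design = paired_design(4)
        raw_vals = np.array([[8.0] * 4 + [2.0] * 4, [5.0] * 4 + [0.0] * 4])
        t_idx, n_idx = design.pair_indices()
        raw = np.zeros((2, 8))
        raw[:, t_idx] = raw_vals[:, :4]
        raw[:, n_idx] = raw_vals[:, 4:]
        raw_m = hp.ExpressionMatrix(raw, ["g0", "g1"], design.sample_ids, "mRNA")
        logm = hp.log_transform(raw_m)
        table = hp.paired_ttest(logm, design, raw=raw_m)
        assert table.loc[0, "fold_change"] == pytest.approx(4.0)
        assert np.isposinf(table.loc[1, "fold_change"])

    def test_null_p_values_are_uniform(self):
        design = paired_design(10)
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, size=(5000, 20))
        table = hp.paired_ttest(self._log_matrix(vals, design), design)
        ks = stats.kstest(table["p_value"], "uniform")
        assert ks.pvalue > 0.01


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
       st.randoms(use_true_random=False))
def test_bh_matches_brute_force_step_up(pvals, _):
    p = np.array(pvals)
    np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12, atol=1e-15)


class TestSelectSignificant:
    def _table(self, fdrs):
        return pd.DataFrame({"feature_id": [f"g{i}" for i in range(len(fdrs))],
                             "fdr": fdrs, "degenerate": [False] * len(fdrs)})

    def test_threshold_is_strict(self):
        sel = hp.select_significant(self._table([0.01, 0.049, 0.05, 0.2]), 0.05)
        assert sel == ["g0", "g1"]

    def test_empty_and_permissive_thresholds(self):
        assert hp.select_significant(self._table([]), 0.05) == []
        assert len(hp.select_significant(self._table([0.3, 0.9, 0.5]), 1.0)) == 3

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(0)
        table = self._table(rng.uniform(0, 1, 50))
        prev: set = set()
        for thr in (0.01, 0.05, 0.2, 0.5, 1.0):
            sel = set(hp.select_significant(table, thr))
            assert prev <= sel
            prev = sel
        sub = table[table["feature_id"].isin(prev)].reset_index(drop=True)
        assert set(hp.select_significant(sub, 1.0)) == prev


# ---------------------------------------------------------------------------
# sparse features
# ---------------------------------------------------------------------------

class TestDropSparse:
    def _with_missing(self, miss_frac):
        vals = np.ones((3, 20))
        n_missing = int(round(miss_frac * 20))
        vals[0, :n_missing] = np.nan
        return hp.ExpressionMatrix(vals, list("abc"), [f"s{i}" for i in range(20)],
                                   "miRNA", allow_missing=True)

    def test_mostly_missing_feature_is_dropped(self):
        out = hp.drop_sparse_features(self._with_missing(0.95), 0.9)
        assert out.feature_ids == ["b", "c"]

    def test_fully_observed_matrix_unchanged(self):
        expr = self._with_missing(0.0)
        out = hp.drop_sparse_features(expr, 0.9)
        assert out.feature_ids == expr.feature_ids
        np.testing.assert_array_equal(out.values, expr.values)

    def test_zero_threshold_drops_any_missing(self):
        out = hp.drop_sparse_features(self._with_missing(0.05), 0.0)
        assert out.feature_ids == ["b", "c"]

    def test_leftover_missing_needs_explicit_zero_fill(self):
        expr = self._with_missing(0.5)
        with pytest.raises(ValueError, match="zero-fill"):
            hp.drop_sparse_features(expr, 0.9)
        out = hp.drop_sparse_features(expr, 0.9, fill_missing_with_zero=True)
        assert out.values[0, 0] == 0.0
        vals = np.full((2, 4), np.nan)
        allna = hp.ExpressionMatrix(vals, ["a", "b"], [f"s{i}" for i in range(4)],
                                    "miRNA", allow_missing=True)
        with pytest.raises(ValueError, match="all features"):
            hp.drop_sparse_features(allna, 0.5)


# ---------------------------------------------------------------------------
# dependence diagnostic
# ---------------------------------------------------------------------------

class TestDependence:
    def test_copied_tissue_vectors_give_unit_correlation(self):
        design = paired_design(6)
        rng = np.random.default_rng(1)
        vals = np.zeros((1, 12))
        t_idx, n_idx = design.pair_indices()
        x = rng.normal(size=6)
        vals[0, t_idx] = x
        vals[0, n_idx] = x
        expr = hp.ExpressionMatrix(vals, ["g"], design.sample_ids, "mRNA", scale="log")
        rep = hp.dependence_report(expr, design, 0.3)
        assert rep.table.loc[0, "r"] == pytest.approx(1.0)

    def test_null_fraction_matches_direct_recomputation_and_theory(self):
        design = paired_design(30)
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(200, 60))
        expr = hp.ExpressionMatrix(vals, [f"g{i}" for i in range(200)],
                                   design.sample_ids, "mRNA", scale="log")
        rep = hp.dependence_report(expr, design, 0.3)
        t_idx, n_idx = design.pair_indices()
        direct = np.array([np.corrcoef(vals[i, t_idx], vals[i, n_idx])[0, 1]
                           for i in range(200)])
        np.testing.assert_allclose(rep.table["r"], direct, atol=1e-12)
        assert rep.fraction_below == pytest.approx((np.abs(direct) < 0.3).mean())
        # Pr(|r| < 0.3) under the null with n=30: r^2 ~ Beta(1/2, (n-2)/2)
        expected = stats.beta.cdf(0.09, 0.5, 14.0)
        assert abs(rep.fraction_below - expected) < 3 * np.sqrt(expected * (1 - expected) / 200)

    def test_degenerate_feature_flagged_and_excluded(self):
        design = paired_design(4)
        vals = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        expr = hp.ExpressionMatrix(vals, ["flat", "ok"], design.sample_ids,
                                   "mRNA", scale="log")
        rep = hp.dependence_report(expr, design, 1.0)
        assert bool(rep.table.loc[0, "degenerate"])
        assert rep.fraction_below == 1.0  # only the non-degenerate feature counts
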