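"""Everything upstream of the hierarchical submodels.

Between-sample TMM normalization, log transform, paired differential testing
with Benjamini-Hochberg FDR control, raw-scale fold changes, sparse-feature
dropping, and the tumor/normal dependence diagnostic that justifies treating
the two tissue groups as independent in the clinical submodel.

Conventions: the paired t-test runs on normalized, log-transformed values,
while fold changes come from raw-scale medians; BH adjustment is applied per
feature kind (mRNAs and miRNAs separately) unless tables are pooled
explicitly.  "FDR < threshold" is a strict inequality throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, PairedDesign

logger = logging.getLogger(__name__)

DIFFEXPR_COLUMNS = ["feature_id", "t_stat", "p_value", "fdr", "fold_change", "passes", "degenerate"]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pairwise_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> float:
    """Trimmed, precision-weighted mean of gene-wise log fold changes of one
    column against the reference column.

    Genes with a zero in either column are excluded; M-values (log2 ratio of
    library-size-scaled proportions) are trimmed 30% on each side, A-values
    (average log abundance) 5% on each side, and the kept M-values averaged
    with inverse-asymptotic-variance (delta-method binomial) weights.
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample TMM scaling factors (geometric mean rescaled to 1).

    The reference sample is the column whose upper quartile of library-size-
    scaled counts is closest to the mean upper quartile; each remaining
    column's factor is the trimmed weighted mean of its gene-wise M-values
    against that reference.
    """
    if expr.scale != "raw":
        raise ValueError("tmm_factors expects raw counts/intensities")
    X = expr.values
    if X.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        zeros = [s for s, l in zip(expr.sample_ids, lib) if l == 0]
        raise ValueError(f"all-zero sample column(s): {', '.join(zeros)}")
    uq = np.array([np.quantile(X[:, k], 0.75) for k in range(X.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_pairwise_factor(X[:, k], X[:, ref], lib[k], lib[ref])
        for k in range(X.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize_tmm(expr: ExpressionMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """Divide each column by its effective library size (library size x TMM
    factor), rescaled by the geometric-mean effective library size so values
    stay on the original magnitude."""
    if factors is None:
        factors = tmm_factors(expr)
    factors = np.asarray(factors, dtype=float)
    lib = expr.values.sum(axis=0)
    eff = lib * factors
    scaled = expr.values / eff * np.exp(np.mean(np.log(eff)))
    return ExpressionMatrix(scaled, expr.feature_ids, expr.sample_ids, expr.feature_kind, scale="normalized")


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def log_transform(expr: ExpressionMatrix, base: float = 2, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value -> log_base(value + pseudocount); renders count distributions
    fairly symmetric ahead of linear modeling."""
    if expr.scale == "log":
        raise ValueError("matrix is already on the log scale")
    if np.any(expr.values < 0):
        raise ValueError("log transform requires nonnegative values")
    if pseudocount == 0 and np.any(expr.values == 0):
        raise ValueError("zero values need a positive pseudocount")
    vals = np.log(expr.values + pseudocount) / np.log(base)
    return ExpressionMatrix(vals, expr.feature_ids, expr.sample_ids, expr.feature_kind, scale="log")


def inverse_log_transform(expr: ExpressionMatrix, base: float = 2, pseudocount: float = 1.0) -> ExpressionMatrix:
    if expr.scale != "log":
        raise ValueError("matrix is not on the log scale")
    vals = np.power(float(base), expr.values) - pseudocount
    vals[np.abs(vals) < 1e-300] = 0.0
    return ExpressionMatrix(vals, expr.feature_ids, expr.sample_ids, expr.feature_kind, scale="normalized")


# ---------------------------------------------------------------------------
# paired differential expression
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def paired_ttest(
    expr: ExpressionMatrix,
    design: PairedDesign,
    raw: ExpressionMatrix | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-feature paired t-test of tumor vs matched normal values.

    Operates on the (log-scale) matrix column-aligned with ``design``; the
    within-patient difference vector d = tumor - normal gives
    t = mean(d) / (sd(d)/sqrt(n)) with a two-sided p from t_{n-1}, BH-adjusted
    across all features of the matrix.  Fold changes are computed from the
    optional raw-scale matrix as median(tumor)/median(normal).

    Zero-variance difference vectors are flagged degenerate, reported with
    p = 1 and excluded from the passing set.
    """
    if expr.sample_ids != design.sample_ids:
        raise ValueError("expression matrix must be column-aligned with the design (see align_design)")
    t_idx, n_idx = design.pair_indices()
    n = t_idx.size
    if n < 3:
        raise ValueError("paired t-test requires at least 3 complete pairs")
    d = expr.values[:, t_idx] - expr.values[:, n_idx]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    t_stat = np.zeros(expr.n_features)
    np.divide(mean, sd / np.sqrt(n), out=t_stat, where=~degenerate)
    p = np.ones(expr.n_features)
    p[~degenerate] = 2.0 * stats.t.sf(np.abs(t_stat[~degenerate]), df=n - 1)
    fdr = bh_adjust(p)

    fold = np.full(expr.n_features, np.nan)
    fc_degenerate = np.zeros(expr.n_features, dtype=bool)
    if raw is not None:
        raw = raw.reorder_samples(design.sample_ids).subset_features(expr.feature_ids)
        med_t = np.median(raw.values[:, t_idx], axis=1)
        med_n = np.median(raw.values[:, n_idx], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = med_t / med_n
        zero_n = med_n == 0
        fc_degenerate = zero_n
        fold[zero_n & (med_t > 0)] = np.inf  # signed sentinel, never clipped
        fold[zero_n & (med_t == 0)] = np.nan

    passes = (fdr < fdr_threshold) & ~degenerate
    table = pd.DataFrame({
        "feature_id": expr.feature_ids,
        "t_stat": t_stat,
        "p_value": p,
        "fdr": fdr,
        "fold_change": fold,
        "passes": passes,
        "degenerate": degenerate,
    })
    table.attrs["fdr_threshold"] = fdr_threshold
    table.attrs["fc_degenerate"] = fc_degenerate
    return table


def select_significant(table: pd.DataFrame, threshold: float | None = None) -> list[str]:
    """Feature IDs with FDR strictly below the threshold, ordered by ascending
    FDR then ID; degenerate features never qualify."""
    if threshold is None:
        threshold = table.attrs.get("fdr_threshold", 0.05)
    if len(table) == 0:
        return []
    ok = (table["fdr"] < threshold) & ~table["degenerate"]
    sub = table.loc[ok, ["feature_id", "fdr"]]
    sub = sub.sort_values(["fdr", "feature_id"], kind="mergesort")
    return sub["feature_id"].tolist()


# ---------------------------------------------------------------------------
# sparse features
# ---------------------------------------------------------------------------

def drop_sparse_features(
    expr: ExpressionMatrix,
    max_missing_fraction: float,
    fill_missing_with_zero: bool = False,
) -> ExpressionMatrix:
    """Remove features whose missing-cell fraction exceeds the threshold.

    Remaining missing cells must be resolved explicitly: pass
    ``fill_missing_with_zero=True`` to zero-fill them, otherwise any leftover
    missingness is an error (no silent imputation).
    """
    miss = np.isnan(expr.values).mean(axis=1)
    keep = miss <= max_missing_fraction
    if not np.any(keep):
        raise ValueError("all features exceed the missing-value threshold")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("drop_sparse_features removed %d feature(s)", n_dropped)
    vals = expr.values[keep, :].copy()
    if np.any(np.isnan(vals)):
        if not fill_missing_with_zero:
            raise ValueError(
                "missing cells remain after sparse-feature dropping; "
                "set fill_missing_with_zero=True to zero-fill them explicitly"
            )
        vals[np.isnan(vals)] = 0.0
    return ExpressionMatrix(
        vals, [f for f, k in zip(expr.feature_ids, keep) if k],
        list(expr.sample_ids), expr.feature_kind, expr.scale, allow_missing=False,
    )


# ---------------------------------------------------------------------------
# tumor/normal dependence diagnostic
# ---------------------------------------------------------------------------

@dataclass
class DependenceReport:
    """Per-feature Pearson correlation between the tumor and matched normal
    vectors across patients, and the share of (non-degenerate) features whose
    |r| falls below the threshold.  A small fraction_below supports modeling
    the two tissue groups as independent."""

    table: pd.DataFrame  # feature_id, r, degenerate
    fraction_below: float
    threshold: float


def dependence_report(
    expr: ExpressionMatrix, design: PairedDesign, threshold: float = 0.3
) -> DependenceReport:
    if expr.sample_ids != design.sample_ids:
        raise ValueError("expression matrix must be column-aligned with the design")
    t_idx, n_idx = design.pair_indices()
    if t_idx.size < 3:
        raise ValueError("dependence diagnostic requires at least 3 pairs")
    T = expr.values[:, t_idx]
    N = expr.values[:, n_idx]
    Tc = T - T.mean(axis=1, keepdims=True)
    Nc = N - N.mean(axis=1, keepdims=True)
    st = np.sqrt((Tc ** 2).sum(axis=1))
    sn = np.sqrt((Nc ** 2).sum(axis=1))
    degenerate = (st == 0) | (sn == 0)
    r = np.zeros(expr.n_features)
    ok = ~degenerate
    r[ok] = (Tc[ok] * Nc[ok]).sum(axis=1) / (st[ok] * sn[ok])
    r = np.clip(r, -1.0, 1.0)
    table = pd.DataFrame({"feature_id": expr.feature_ids, "r": r, "degenerate": degenerate})
    if ok.sum() == 0:
        frac = float("nan")
    else:
        frac = float((np.abs(r[ok]) < threshold).mean())
    return DependenceReport(table=table, fraction_below=frac, threshold=threshold)
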