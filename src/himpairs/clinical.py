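"""Clinical submodel: lasso-logistic regression of disease status and the
pair-emission rule.

The design matrix contains, per mediated mRNA j, its mechanistic linear
predictor eta_j and residual e_j, plus one column per orphan mRNA and orphan
miRNA (log-scale values):

    logit P(Y=1) = beta_0 + sum beta_eta_j eta_j + sum beta_e_j e_j
                   + sum beta_k mRNAbar_k + sum beta_l miRNAbar_l

Selection of eta_j means the disease effect of mRNA_j is modulated by its
associated miRNAs, so (mRNA_j, m) is emitted for every miRNA m in the
mechanistic support of mRNA_j; selection of e_j means the effect acts
through factors other than those miRNAs, and no pairs are emitted for it.
All columns share a single penalty; the intercept is unpenalized; nonzero is
tested exactly (lasso zeros are exact).  Samples are treated as independent —
the tumor/normal dependence diagnostic motivates dropping random effects —
but CV folds are still assigned at the patient level to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .containers import ExpressionMatrix, PairedDesign, PipelineConfig
from .mechanistic import MechanisticResult, make_folds
from .prefilter import bh_adjust

logger = logging.getLogger(__name__)

ROLE_ETA = "ETA"
ROLE_RESID = "RESID"
ROLE_ORPHAN_MRNA = "ORPHAN_MRNA"
ROLE_ORPHAN_MIRNA = "ORPHAN_MIRNA"

N_LAMBDA_LOGISTIC = 60
LAMBDA_MIN_RATIO_LOGISTIC = 1e-3
COEF_CAP = 50.0  # |standardized coefficient| beyond this signals (near-)separation


@dataclass
class ClinicalDesignMatrix:
    """Standardized clinical design matrix with column-role metadata."""

    values: np.ndarray                 # samples x columns, standardized
    roles: list[tuple[str, str]]       # (role, molecule id) per column
    y: np.ndarray                      # binary outcome per sample
    sample_ids: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def columns_with_role(self, role: str) -> list[str]:
        return [mol for r, mol in self.roles if r == role]

    def check_invariants(self, mech: MechanisticResult) -> None:
        etas = self.columns_with_role(ROLE_ETA)
        resids = self.columns_with_role(ROLE_RESID)
        assert sorted(etas) == sorted(mech.mediated_mrnas)
        assert sorted(resids) == sorted(mech.mediated_mrnas)
        counts = {}
        for r, mol in self.roles:
            counts[(r, mol)] = counts.get((r, mol), 0) + 1
        assert all(v == 1 for v in counts.values())


@dataclass
class ClinicalFit:
    """Coefficients of the lasso-logistic clinical submodel, on the
    standardized column scale, with the penalty that produced them."""

    intercept: float
    coefs: np.ndarray
    roles: list[tuple[str, str]]
    lambda_used: float
    separation_capped: bool = False

    def nonzero(self, role: str) -> list[str]:
        return [mol for (r, mol), c in zip(self.roles, self.coefs) if r == role and c != 0.0]

    def coef_of(self, role: str, molecule: str) -> float:
        for (r, mol), c in zip(self.roles, self.coefs):
            if r == role and mol == molecule:
                return float(c)
        raise KeyError((role, molecule))


@dataclass
class PairSet:
    """Emitted miRNA-mRNA pairs plus the disease-associated molecules that
    were selected outside the eta channel."""

    pairs: list[tuple[str, str, float, float]]  # (mirna, mrna, alpha, beta_eta)
    selected_etas: list[str] = field(default_factory=list)
    selected_resids: list[str] = field(default_factory=list)
    selected_orphan_mrnas: list[str] = field(default_factory=list)
    selected_orphan_mirnas: list[str] = field(default_factory=list)

    @property
    def summary(self) -> tuple[int, int, int]:
        """(n_pairs, n_distinct_mrna, n_distinct_mirna)."""
        return (len(self.pairs),
                len({j for _, j, _, _ in self.pairs}),
                len({m for m, _, _, _ in self.pairs}))

    @property
    def pair_ids(self) -> set[tuple[str, str]]:
        return {(m, j) for m, j, _, _ in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["mirna_id", "mrna_id", "alpha", "beta_eta"])

    def check_invariants(self, mech: MechanisticResult) -> None:
        support = {f.mrna_id: set(f.support) for f in mech.fits}
        for m, j, _, _ in self.pairs:
            assert m in support.get(j, set()), f"pair ({m}, {j}) outside mechanistic support"
        expected = {(m, j) for j in self.selected_etas for m in support[j]}
        assert self.pair_ids == expected


def build_design(
    mech: MechanisticResult,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    design: PairedDesign,
) -> ClinicalDesignMatrix:
    """Assemble the clinical design matrix from mechanistic fits and the
    log-scale matrices of orphan molecules.

    Every mediated mRNA contributes exactly one eta and one residual column;
    every orphan mRNA/miRNA one raw (log-scale) column.  Columns are
    standardized for penalization; zero-variance columns are kept with sd
    treated as 1 (they can never be selected).
    """
    if design.sample_ids != mech.sample_ids:
        raise ValueError("design and mechanistic result are not sample-aligned")
    for expr in (mrna, mirna):
        if expr.sample_ids != mech.sample_ids:
            raise ValueError("expression matrices are not sample-aligned with the mechanistic result")

    cols: list[np.ndarray] = []
    roles: list[tuple[str, str]] = []
    for j in mech.mediated_mrnas:
        fit = mech.fit_for(j)
        if fit.eta is None or fit.resid is None:
            raise ValueError(f"mediated mRNA {j} lacks an eta or residual vector")
        cols.append(np.asarray(fit.eta, dtype=float))
        roles.append((ROLE_ETA, j))
        cols.append(np.asarray(fit.resid, dtype=float))
        roles.append((ROLE_RESID, j))
    for k in mech.orphan_mrnas:
        cols.append(mrna.row(k))
        roles.append((ROLE_ORPHAN_MRNA, k))
    for l in mech.orphan_mirnas:
        cols.append(mirna.row(l))
        roles.append((ROLE_ORPHAN_MIRNA, l))

    n = len(mech.sample_ids)
    M = np.column_stack(cols) if cols else np.empty((n, 0))
    means = M.mean(axis=0) if M.size else np.empty(0)
    sds = M.std(axis=0) if M.size else np.empty(0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    Z = (M - means) / sds_safe if M.size else M
    return ClinicalDesignMatrix(Z, roles, design.y, list(design.sample_ids), means, sds_safe)


def _deviance(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _logistic_lasso(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """One lasso-logistic fit, penalty scaled as (1/n) loss + lam * ||w||_1."""
    n = y.size
    model = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
                               tol=1e-10, max_iter=20000, fit_intercept=True,
                               random_state=0)
    model.fit(Z, y)
    return float(model.intercept_[0]), model.coef_[0].copy()


def fit_clinical(
    dm: ClinicalDesignMatrix,
    config: PipelineConfig,
    design: PairedDesign | None = None,
) -> ClinicalFit:
    """Fit the lasso-logistic clinical submodel with cross-validated penalty.

    The lambda grid is geometric from the all-zero penalty down to
    ``LAMBDA_MIN_RATIO_LOGISTIC`` of it; the CV criterion is validation
    binomial deviance; folds are patient-level when a design is given.  If
    the selected fit shows runaway coefficients (perfect separation as the
    penalty vanishes) the path is capped at the smallest stable penalty with
    a logged warning.
    """
    y = dm.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("clinical submodel requires both outcome classes present")
    if dm.n_columns == 0:
        p1 = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return ClinicalFit(float(np.log(p1 / (1 - p1))), np.empty(0), list(dm.roles), float("inf"))

    Z = dm.values
    n = y.size
    ybar = y.mean()
    lam_max = np.max(np.abs(Z.T @ (y - ybar))) / n
    if lam_max <= 0 or not np.isfinite(lam_max):
        lam_max = 1.0
    lambdas = lam_max * np.logspace(0, np.log10(LAMBDA_MIN_RATIO_LOGISTIC), N_LAMBDA_LOGISTIC)

    rng = np.random.default_rng(stable_clinical_seed(config.seed))
    groups = np.array(design.patient_ids) if design is not None else None
    if n < 2 * config.cv_folds:
        folds = [np.array([i]) for i in range(n)]
    else:
        folds = make_folds(n, config.cv_folds, rng, groups=groups)

    dev = np.full((len(folds), lambdas.size), np.nan)
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        if np.unique(y[train]).size < 2:
            continue
        for i, lam in enumerate(lambdas):
            b0, w = _logistic_lasso(Z[train], y[train], lam)
            prob = 1.0 / (1.0 + np.exp(-(b0 + Z[test] @ w)))
            dev[k, i] = _deviance(prob, y[test]) / test.size
    valid = ~np.all(np.isnan(dev), axis=0)
    cv_mean = np.nanmean(dev[:, valid], axis=0)
    with np.errstate(invalid="ignore"):
        cv_se = np.nanstd(dev[:, valid], axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(dev[:, valid]), axis=0))
    lams = lambdas[valid]

    i_min = int(np.argmin(cv_mean))
    if config.lambda_rule == "cv_min":
        lam = float(lams[i_min])
    else:
        bound = cv_mean[i_min] + cv_se[i_min]
        lam = float(lams[np.flatnonzero(cv_mean <= bound)[0]])

    b0, w = _logistic_lasso(Z, y, lam)
    capped = False
    while np.max(np.abs(w), initial=0.0) > COEF_CAP and lam < lam_max:
        # runaway coefficients: walk back up the path to the smallest stable penalty
        capped = True
        larger = lambdas[lambdas > lam]
        if larger.size == 0:
            break
        lam = float(larger[-1])
        b0, w = _logistic_lasso(Z, y, lam)
    if capped:
        logger.warning("fit_clinical: near-separation detected; lambda path capped at %.4g", lam)
    return ClinicalFit(b0, w, list(dm.roles), lam, separation_capped=capped)


def stable_clinical_seed(seed: int) -> int:
    # distinct stream from the per-mRNA mechanistic seeds
    return (int(seed) * 2654435761 + 13) % (2 ** 31)


def emit_pairs(fit: ClinicalFit, mech: MechanisticResult) -> PairSet:
    """Apply the pair-emission rule.

    For every mediated mRNA j whose eta coefficient is exactly nonzero, emit
    (m, j) for all miRNAs m in the mechanistic support of j (some of those
    miRNAs may not be individually relevant — the rule is deliberately
    inclusive).  Molecules selected through residual or orphan columns are
    reported separately as disease-associated but not paired.
    """
    selected_etas = fit.nonzero(ROLE_ETA)
    pairs: list[tuple[str, str, float, float]] = []
    for j in selected_etas:
        mfit = mech.fit_for(j)
        beta = fit.coef_of(ROLE_ETA, j)
        for m in mfit.support:
            pairs.append((m, j, mfit.alphas[m], beta))
    ps = PairSet(
        pairs=pairs,
        selected_etas=selected_etas,
        selected_resids=fit.nonzero(ROLE_RESID),
        selected_orphan_mrnas=fit.nonzero(ROLE_ORPHAN_MRNA),
        selected_orphan_mirnas=fit.nonzero(ROLE_ORPHAN_MIRNA),
    )
    ps.check_invariants(mech)
    return ps


# ---------------------------------------------------------------------------
# pairwise-correlation comparator
# ---------------------------------------------------------------------------

def correlation_baseline(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Exhaustive pairwise Pearson screening: every miRNA x mRNA correlation
    across samples, BH-adjusted over all pairs, kept when |r| exceeds the
    correlation threshold AND the FDR is below the FDR threshold.

    A simple stand-in for component-based correlation analyses used as
    comparators to the hierarchical model.
    """
    if mrna.sample_ids != mirna.sample_ids:
        raise ValueError("matrices are not sample-aligned")
    n = mrna.n_samples
    if n < 3:
        raise ValueError("correlation baseline requires at least 3 samples")

    def _standardize(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        C = V - V.mean(axis=1, keepdims=True)
        s = np.sqrt((C ** 2).sum(axis=1))
        degen = s == 0
        C[degen] = 0.0
        s[degen] = 1.0
        return C / s[:, None], degen

    Zm, degen_m = _standardize(mirna.values.copy())
    Zg, degen_g = _standardize(mrna.values.copy())
    R = np.clip(Zm @ Zg.T, -1.0, 1.0)  # miRNA x mRNA
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R ** 2))
    P = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    P[~np.isfinite(tstat)] = 0.0           # |r| == 1
    P[degen_m, :] = 1.0
    P[:, degen_g] = 1.0
    fdr = bh_adjust(P.ravel()).reshape(P.shape)
    kept = (np.abs(R) > config.correlation_threshold) & (fdr < config.fdr_threshold)
    mi_ids = np.repeat(mirna.feature_ids, mrna.n_features)
    g_ids = np.tile(mrna.feature_ids, mirna.n_features)
    return pd.DataFrame({
        "mirna_id": mi_ids,
        "mrna_id": g_ids,
        "r": R.ravel(),
        "p_value": P.ravel(),
        "fdr": fdr.ravel(),
        "kept": kept.ravel(),
    })


def overlap_pairs(pairset: PairSet, baseline: pd.DataFrame) -> dict[str, int]:
    """Shared-pair counts between the hierarchical-model pair set and the
    correlation comparator's kept pairs."""
    kept = {(m, j) for m, j in zip(baseline.loc[baseline["kept"], "mirna_id"],
                                   baseline.loc[baseline["kept"], "mrna_id"])}
    him = pairset.pair_ids
    return {"him": len(him), "baseline": len(kept), "shared": len(him & kept)}
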