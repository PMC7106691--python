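"""Mechanistic submodel: one lasso-penalized linear regression per mRNA.

Each significant mRNA j is regressed on the full panel of significant miRNAs,

    mRNA_j = alpha_0 + alpha_1 miRNA_1 + ... + alpha_p miRNA_p + e_j,

with the miRNA-explained part eta_j = alpha_0 + X alpha (the linear
predictor) and the residual e_j = mRNA_j - eta_j.  The decomposition
mRNA_j = eta_j + e_j is exact by construction.  The penalty is chosen by
k-fold cross-validation on a glmnet-style geometric lambda grid; predictors
are standardized internally and coefficients reported on the original scale;
the intercept is never penalized.  p > n is expected and handled natively.

Cross-validation folds are assigned at the patient level (both samples of a
patient share a fold) and seeded per mRNA from a stable hash of its ID, so
results do not depend on iteration order or parallelization.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .containers import ExpressionMatrix, PairedDesign, PipelineConfig

logger = logging.getLogger(__name__)

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 0.01


def stable_seed(key: str, seed: int) -> int:
    """Deterministic per-key seed: CRC32 of the key XOR the master seed."""
    return (zlib.crc32(key.encode("utf8")) ^ int(seed)) % (2 ** 31)


@dataclass
class MechanisticFit:
    """Lasso decomposition of one mRNA into its miRNA-explained linear
    predictor and residual."""

    mrna_id: str
    alpha0: float
    alphas: dict[str, float]           # miRNA id -> original-scale coefficient (nonzero only)
    eta: np.ndarray                    # per-sample linear predictor
    resid: np.ndarray                  # per-sample residual; y == eta + resid exactly
    lambda_used: float
    support: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.support = [m for m, a in self.alphas.items() if a != 0.0]
        self.alphas = {m: a for m, a in self.alphas.items() if a != 0.0}


@dataclass
class MechanisticResult:
    """All per-mRNA fits plus the induced partition of significant molecules.

    ``mediated_mrnas`` have nonempty miRNA support; ``orphan_mrnas`` passed
    the prefilter but attracted no miRNA; ``orphan_mirnas`` passed the
    prefilter but entered no support set.  Orphans feed the clinical submodel
    directly."""

    fits: list[MechanisticFit]
    mediated_mrnas: list[str]
    orphan_mrnas: list[str]
    orphan_mirnas: list[str]
    candidate_pairs: list[tuple[str, str]]   # (mirna_id, mrna_id)
    sample_ids: list[str]

    def fit_for(self, mrna_id: str) -> MechanisticFit:
        for f in self.fits:
            if f.mrna_id == mrna_id:
                return f
        raise KeyError(mrna_id)

    def summary(self) -> tuple[int, int, int]:
        """(total pairs, #distinct mRNAs in pairs, #distinct miRNAs in pairs) —
        the 'selected pairs (#mRNA) (#miRNA)' reporting convention."""
        mrnas = {j for _, j in self.candidate_pairs}
        mirnas = {m for m, _ in self.candidate_pairs}
        return (len(self.candidate_pairs), len(mrnas), len(mirnas))

    def check_invariants(self) -> None:
        assert set(self.mediated_mrnas).isdisjoint(self.orphan_mrnas)
        n_pairs = sum(len(f.support) for f in self.fits)
        assert len(self.candidate_pairs) == n_pairs
        used = set().union(*(set(f.support) for f in self.fits)) if self.fits else set()
        assert set(m for m, _ in self.candidate_pairs) == used


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = N_LAMBDA,
                min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    """Geometric grid from the smallest lambda that zeroes every coefficient
    down to ``min_ratio`` times it (X assumed standardized)."""
    n = y.size
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / n
    if lam_max <= 0 or not np.isfinite(lam_max):
        lam_max = 1.0
    return lam_max * np.logspace(0, np.log10(min_ratio), n_lambda)


def make_folds(n_samples: int, n_folds: int, rng: np.random.Generator,
               groups: np.ndarray | None = None) -> list[np.ndarray]:
    """Test-index arrays for k-fold CV; with ``groups`` (patient labels) all
    samples of a group share a fold."""
    if groups is None:
        idx = rng.permutation(n_samples)
        return [np.sort(part) for part in np.array_split(idx, n_folds)]
    uniq = list(dict.fromkeys(groups.tolist()))
    order = rng.permutation(len(uniq))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for pos, gi in enumerate(order):
        g = uniq[gi]
        folds[pos % n_folds].extend(np.flatnonzero(groups == g).tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f) > 0]


def _cv_lasso_mse(Z: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                  folds: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error (over folds) of validation MSE per lambda."""
    n = y.size
    mse = np.zeros((len(folds), lambdas.size))
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        Zt, yt = Z[train], y[train]
        mu_x = Zt.mean(axis=0)
        mu_y = yt.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Zt - mu_x, yt - mu_y, alphas=lambdas,
                                     max_iter=20000, tol=1e-9)
        pred = (Z[test] - mu_x) @ coefs + mu_y
        mse[k] = ((pred - y[test][:, None]) ** 2).mean(axis=0)
    mean = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else np.zeros_like(mean)
    return mean, se


def choose_lambda(lambdas: np.ndarray, cv_mean: np.ndarray, cv_se: np.ndarray,
                  rule: str) -> float:
    """cv_min: CV-error minimiser; cv_1se: largest lambda whose CV error is
    within one standard error of the minimum (lambdas must be descending)."""
    i_min = int(np.argmin(cv_mean))
    if rule == "cv_min":
        return float(lambdas[i_min])
    bound = cv_mean[i_min] + cv_se[i_min]
    ok = np.flatnonzero(cv_mean <= bound)
    return float(lambdas[ok[0]])  # grid is descending: first index = largest lambda


def fit_one_mrna(
    y: np.ndarray,
    X: np.ndarray,
    mirna_ids: list[str],
    config: PipelineConfig,
    mrna_id: str = "mRNA",
    groups: np.ndarray | None = None,
    lambda_override: float | None = None,
) -> MechanisticFit:
    """Fit the lasso regression of one mRNA on the miRNA panel.

    Parameters
    ----------
    y : per-sample log mRNA vector.
    X : samples x miRNAs log matrix (original scale; standardized internally).
    groups : optional per-sample patient labels for patient-level CV folds.
    lambda_override : skip cross-validation and fit at this penalty.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape if X.ndim == 2 else (y.size, 0)
    if p != len(mirna_ids):
        raise ValueError("X columns must match mirna_ids")
    if p == 0 or np.std(y) == 0:
        eta = np.full(y.shape, y.mean())
        return MechanisticFit(mrna_id, float(y.mean()), {}, eta, y - eta,
                              lambda_used=float("inf"))

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    live = sd > 0
    sd_safe = np.where(live, sd, 1.0)
    Z = (X - mu) / sd_safe
    Z[:, ~live] = 0.0

    if lambda_override is not None:
        lam = float(lambda_override)
    else:
        lambdas = lambda_grid(Z, y)
        rng = np.random.default_rng(stable_seed(mrna_id, config.seed))
        if n < 2 * config.cv_folds:
            logger.info("fit_one_mrna(%s): n=%d < 2*cv_folds, falling back to leave-one-out CV", mrna_id, n)
            folds = [np.array([i]) for i in range(n)]
        else:
            folds = make_folds(n, config.cv_folds, rng, groups=groups)
        cv_mean, cv_se = _cv_lasso_mse(Z, y, lambdas, folds)
        lam = choose_lambda(lambdas, cv_mean, cv_se, config.lambda_rule)

    if lam == 0.0:
        # unpenalized limit: plain least squares on the standardized design
        A = np.column_stack([np.ones(n), Z])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept, coef_std = sol[0], sol[1:]
    else:
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=100000, tol=1e-10)
        with warnings.catch_warnings():
            # tiny duality gaps near machine precision can trip the stock
            # convergence warning without affecting the solution
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Z, y)
        intercept, coef_std = float(model.intercept_), model.coef_
    coef = np.zeros(p)
    coef[live] = coef_std[live] / sd_safe[live]
    alpha0 = float(intercept - mu @ coef)
    eta = alpha0 + X @ coef
    resid = y - eta
    alphas = {m: float(c) for m, c in zip(mirna_ids, coef) if c != 0.0}
    return MechanisticFit(mrna_id, alpha0, alphas, eta, resid, lambda_used=lam)


def kkt_violation(y: np.ndarray, X: np.ndarray, fit: MechanisticFit,
                  mirna_ids: list[str]) -> float:
    """Largest violation of the lasso stationarity conditions at lambda_used,
    evaluated on the standardized predictors (the penalized scale).

    For zero coefficients |g_j| must not exceed lambda; for nonzero ones
    g_j must equal lambda * sign(coef), where g = Z^T r / n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    mu, sd = X.mean(axis=0), X.std(axis=0)
    live = sd > 0
    Z = np.zeros_like(X)
    Z[:, live] = (X[:, live] - mu[live]) / sd[live]
    coef_std = np.array([fit.alphas.get(m, 0.0) for m in mirna_ids]) * np.where(live, sd, 1.0)
    r = y - y.mean() - (Z - Z.mean(axis=0)) @ coef_std
    g = Z.T @ r / n
    lam = fit.lambda_used
    viol = np.where(coef_std == 0.0, np.maximum(np.abs(g) - lam, 0.0),
                    np.abs(g - lam * np.sign(coef_std)))
    viol[~live] = 0.0
    return float(np.max(viol)) if viol.size else 0.0


def fit_all(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    config: PipelineConfig,
    design: PairedDesign | None = None,
) -> MechanisticResult:
    """Fit the mechanistic submodel for every (significant) mRNA in ``mrna``
    against every miRNA in ``mirna`` and partition the molecules.

    Both matrices must be log scale and column-aligned to the same samples.
    When a design is supplied, CV folds are assigned at the patient level so
    a patient's tumor and normal samples never straddle a fold boundary.
    """
    if mrna.sample_ids != mirna.sample_ids:
        raise ValueError("mRNA and miRNA matrices are not column-aligned to the same samples")
    if mrna.scale != "log" or mirna.scale != "log":
        raise ValueError("mechanistic submodel expects log-scale matrices")
    groups = None
    if design is not None:
        if design.sample_ids != mrna.sample_ids:
            raise ValueError("design is not aligned with the expression matrices")
        groups = np.array(design.patient_ids)

    X = mirna.values.T  # samples x miRNAs
    mirna_ids = list(mirna.feature_ids)
    fits = []
    for j, mrna_id in enumerate(mrna.feature_ids):
        fits.append(fit_one_mrna(mrna.values[j, :], X, mirna_ids, config,
                                 mrna_id=mrna_id, groups=groups))
    mediated = [f.mrna_id for f in fits if f.support]
    orphan_mrnas = [f.mrna_id for f in fits if not f.support]
    used = set()
    pairs: list[tuple[str, str]] = []
    for f in fits:
        for m in f.support:
            pairs.append((m, f.mrna_id))
            used.add(m)
    orphan_mirnas = [m for m in mirna_ids if m not in used]
    result = MechanisticResult(fits, mediated, orphan_mrnas, orphan_mirnas,
                               pairs, list(mrna.sample_ids))
    result.check_invariants()
    return result
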