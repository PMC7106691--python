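"""Synthetic paired tumor/normal miRNA/mRNA data with known ground truth.

The generator mirrors the statistical structure the hierarchical model
assumes.  On the log2 scale, each miRNA fluctuates around a baseline with
Gaussian noise; disease-shifted miRNAs gain a tumor-only shift.  Each mRNA
is a sparse linear combination of (centered) miRNA levels plus residual
noise, so disease signal reaches an mRNA either through its regulator
miRNAs (the eta channel: its regulators are shifted, with shift signs
aligned to the regulatory coefficients so contributions add) or directly
through its residual (the e channel).  Log abundances are exponentiated,
scaled by per-sample library sizes, and rounded to counts, giving
overdispersed count noise through the lognormal layer while keeping the
log-scale linear model exactly correct.

True pairs are the nonzero regulatory coefficients of eta-channel mRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, PairedDesign

PRESETS: dict[str, dict] = {
    # the study conditions; 'default' carries the canonical recovery setting
    # (5 eta-channel mRNAs x 3 disjoint regulators = 15 true pairs); the
    # residual and direct-miRNA disease channels default to zero here and are
    # switched on via make_truth overrides where a scenario needs them
    "null": dict(n_patients=30, n_mrna=200, n_mirna=60, n_eta_mrnas=0,
                 regulators_per_mrna=0, n_resid_mrnas=0, n_direct_mirnas=0,
                 n_background_mrnas=0, effect_size=0.0, noise_sd=0.5),
    "easy": dict(n_patients=30, n_mrna=200, n_mirna=60, n_eta_mrnas=5,
                 regulators_per_mrna=3, n_resid_mrnas=0, n_direct_mirnas=0,
                 n_background_mrnas=20, effect_size=2.0, noise_sd=0.25),
    "default": dict(n_patients=30, n_mrna=200, n_mirna=60, n_eta_mrnas=5,
                    regulators_per_mrna=3, n_resid_mrnas=0, n_direct_mirnas=0,
                    n_background_mrnas=20, effect_size=1.5, noise_sd=0.5),
    "hard": dict(n_patients=30, n_mrna=200, n_mirna=60, n_eta_mrnas=5,
                 regulators_per_mrna=3, n_resid_mrnas=0, n_direct_mirnas=0,
                 n_background_mrnas=20, effect_size=0.75, noise_sd=0.8),
}


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``A`` is the sparse mRNA x miRNA regulatory coefficient matrix (the true
    alphas, acting on centered log2 miRNA levels).  Disease effects flow
    through three disjoint channels: ``disease_eta_mrnas`` (tumor shift on
    their regulator miRNAs), ``disease_resid_mrnas`` (tumor shift on the
    mRNA residual) and ``disease_mirnas`` (direct tumor shift; includes the
    eta-channel regulators).  True pairs are the nonzero entries of A
    restricted to eta-channel mRNAs.
    """

    A: np.ndarray
    mrna_ids: list[str]
    mirna_ids: list[str]
    disease_eta_mrnas: list[str]
    disease_resid_mrnas: list[str]
    disease_mirnas: list[str]
    mirna_shift: np.ndarray      # per-miRNA tumor log2 shift
    mrna_resid_shift: np.ndarray  # per-mRNA tumor log2 shift on the residual channel
    effect_size: float
    noise_sd: float
    n_patients: int
    seed: int
    mrna_baseline: np.ndarray = field(repr=False, default=None)
    mirna_baseline: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.A.shape != (len(self.mrna_ids), len(self.mirna_ids)):
            raise ValueError("regulatory matrix A has inconsistent dimensions")
        if self.mirna_shift.shape != (len(self.mirna_ids),):
            raise ValueError("mirna_shift has inconsistent dimensions")
        if self.mrna_resid_shift.shape != (len(self.mrna_ids),):
            raise ValueError("mrna_resid_shift has inconsistent dimensions")
        if set(self.disease_eta_mrnas) & set(self.disease_resid_mrnas):
            raise ValueError("eta- and residual-channel mRNA sets must be disjoint")

    @property
    def true_pairs(self) -> set[tuple[str, str]]:
        """{(mirna_id, mrna_id)} for nonzero A entries of eta-channel mRNAs."""
        j_idx = {j: i for i, j in enumerate(self.mrna_ids)}
        out = set()
        for j in self.disease_eta_mrnas:
            for m_i in np.flatnonzero(self.A[j_idx[j]]):
                out.add((self.mirna_ids[m_i], j))
        return out


def make_truth(preset: str = "default", seed: int = 1, **overrides) -> SimulationTruth:
    """Draw a ground-truth configuration for a named preset.

    Regulator miRNAs of distinct eta-channel mRNAs are disjoint, and
    background-regulated (non-disease) mRNAs draw their regulators only from
    non-disease miRNAs, so the truth pair labels are unambiguous.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {', '.join(sorted(PRESETS))}")
    params = dict(PRESETS[preset])
    params.update(overrides)
    n_mrna, n_mirna = params["n_mrna"], params["n_mirna"]
    k = params["regulators_per_mrna"]
    n_eta, n_resid = params["n_eta_mrnas"], params["n_resid_mrnas"]
    n_direct, n_bg = params["n_direct_mirnas"], params["n_background_mrnas"]
    effect, sd = params["effect_size"], params["noise_sd"]
    if n_eta * k + n_direct > n_mirna:
        raise ValueError("not enough miRNAs for the requested regulator/direct counts")
    if n_eta + n_resid + n_bg > n_mrna:
        raise ValueError("not enough mRNAs for the requested channel sizes")

    rng = np.random.default_rng(seed)
    mrna_ids = [f"mRNA_{i:04d}" for i in range(n_mrna)]
    mirna_ids = [f"miR_{i:03d}" for i in range(n_mirna)]

    mrna_order = rng.permutation(n_mrna)
    eta_j = mrna_order[:n_eta]
    resid_j = mrna_order[n_eta:n_eta + n_resid]
    bg_j = mrna_order[n_eta + n_resid:n_eta + n_resid + n_bg]
    mirna_order = rng.permutation(n_mirna)
    reg_m = mirna_order[:n_eta * k]
    direct_m = mirna_order[n_eta * k:n_eta * k + n_direct]
    free_m = mirna_order[n_eta * k + n_direct:]

    A = np.zeros((n_mrna, n_mirna))
    mirna_shift = np.zeros(n_mirna)
    for b, j in enumerate(eta_j):
        regs = reg_m[b * k:(b + 1) * k]
        coefs = rng.uniform(0.5, 1.0, size=k) * rng.choice([-1.0, 1.0], size=k)
        A[j, regs] = coefs
        # the mediated tumor effect of mRNA_j totals `effect` log2 units,
        # split equally over its regulators: alpha_m * delta_m = effect / k,
        # so shift signs align with the coefficients and contributions add
        mirna_shift[regs] = (effect / k) / coefs
    mirna_shift[direct_m] = effect * rng.choice([-1.0, 1.0], size=n_direct)
    if n_bg and free_m.size:
        n_bg_reg = min(2, free_m.size)
        for j in bg_j:
            regs = rng.choice(free_m, size=n_bg_reg, replace=False)
            A[j, regs] = rng.uniform(0.5, 1.0, size=n_bg_reg) * rng.choice([-1.0, 1.0], size=n_bg_reg)

    mrna_resid_shift = np.zeros(n_mrna)
    mrna_resid_shift[resid_j] = effect * rng.choice([-1.0, 1.0], size=n_resid)

    return SimulationTruth(
        A=A,
        mrna_ids=mrna_ids,
        mirna_ids=mirna_ids,
        disease_eta_mrnas=[mrna_ids[j] for j in np.sort(eta_j)],
        disease_resid_mrnas=[mrna_ids[j] for j in np.sort(resid_j)],
        disease_mirnas=[mirna_ids[m] for m in np.sort(np.flatnonzero(mirna_shift != 0))],
        mirna_shift=mirna_shift,
        mrna_resid_shift=mrna_resid_shift,
        effect_size=effect,
        noise_sd=sd,
        n_patients=params["n_patients"],
        seed=int(seed),
        mrna_baseline=rng.uniform(4.0, 12.0, size=n_mrna),
        mirna_baseline=rng.uniform(4.0, 10.0, size=n_mirna),
    )


def simulate_dataset(
    truth: SimulationTruth,
    equal_library_sizes: bool = False,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PairedDesign, SimulationTruth]:
    """Generate paired raw count matrices and their design from a truth.

    Samples are ordered patient-by-patient, tumor then normal.  With
    ``equal_library_sizes`` the per-sample library scaling is switched off
    (isolates model behavior from normalization).
    """
    rng = np.random.default_rng([truth.seed, 1])
    n_pat = truth.n_patients
    n_samp = 2 * n_pat
    n_mrna, n_mirna = len(truth.mrna_ids), len(truth.mirna_ids)
    sd = truth.noise_sd

    patients = [f"P{i + 1:03d}" for i in range(n_pat)]
    sample_ids = []
    patient_ids = []
    status = []
    for p in patients:
        for suffix, y in (("T", 1), ("N", 0)):
            sample_ids.append(f"{p}_{suffix}")
            patient_ids.append(p)
            status.append(y)
    design = PairedDesign(sample_ids, patient_ids, np.array(status))
    y = np.array(status, dtype=float)

    # log2 miRNA levels: baseline + noise + tumor shift
    mi_log = (truth.mirna_baseline[:, None]
              + rng.normal(0.0, sd, size=(n_mirna, n_samp))
              + truth.mirna_shift[:, None] * y[None, :])
    # log2 mRNA levels: baseline + A (centered miRNA) + residual noise + residual-channel shift
    mi_centered = mi_log - truth.mirna_baseline[:, None] - truth.mirna_shift[:, None] * 0.5
    g_log = (truth.mrna_baseline[:, None]
             + truth.A @ mi_centered
             + rng.normal(0.0, sd, size=(n_mrna, n_samp))
             + truth.mrna_resid_shift[:, None] * y[None, :])

    if equal_library_sizes:
        lib = np.ones(n_samp)
    else:
        lib = 2.0 ** rng.uniform(-1.0, 1.0, size=n_samp)

    mrna_counts = np.rint(np.clip(2.0 ** g_log * lib[None, :], 0, None))
    mirna_counts = np.rint(np.clip(2.0 ** mi_log * lib[None, :], 0, None))
    mrna = ExpressionMatrix(mrna_counts, truth.mrna_ids, sample_ids, "mRNA", scale="raw")
    mirna = ExpressionMatrix(mirna_counts, truth.mirna_ids, sample_ids, "miRNA", scale="raw")
    return mrna, mirna, design, truth


@dataclass
class RecoveryScore:
    """Set-overlap metrics of an estimated pair set against the truth."""

    precision: float
    recall: float
    f1: float
    mrna_recall: float
    mirna_recall: float
    n_estimated: int
    n_true: int
    empty_estimate: bool = False  # precision reported as 1 by convention


def score_recovery(estimated_pairs: set[tuple[str, str]] | list, truth: SimulationTruth) -> RecoveryScore:
    """Precision/recall/F1 over (mirna, mrna) pairs plus molecule-level recall.

    An empty estimate against a nonempty truth gets precision 1 by convention
    (flagged via ``empty_estimate``); recall 1 when the truth itself is empty.
    """
    est = set(estimated_pairs)
    true = truth.true_pairs
    tp = len(est & true)
    empty = len(est) == 0
    precision = 1.0 if empty else tp / len(est)
    recall = 1.0 if len(true) == 0 else tp / len(true)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    true_mrnas = {j for _, j in true}
    true_mirnas = {m for m, _ in true}
    est_mrnas = {j for _, j in est}
    est_mirnas = {m for m, _ in est}
    return RecoveryScore(
        precision=precision,
        recall=recall,
        f1=f1,
        mrna_recall=1.0 if not true_mrnas else len(true_mrnas & est_mrnas) / len(true_mrnas),
        mirna_recall=1.0 if not true_mirnas else len(true_mirnas & est_mirnas) / len(true_mirnas),
        n_estimated=len(est),
        n_true=len(true),
        empty_estimate=empty,
    )
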