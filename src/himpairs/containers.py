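"""Typed containers for expression matrices, paired designs and pipeline configuration.

The central objects of the package: an :class:`ExpressionMatrix` holds a
features x samples block of nonnegative expression values together with its
scale provenance (raw counts, between-sample normalized, or log), and a
:class:`PairedDesign` records which sample belongs to which patient and
whether it is tumor or matched adjacent-normal tissue.  The paired design
defines the binary disease outcome Y of the clinical submodel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

FEATURE_KINDS = ("mRNA", "miRNA")
SCALES = ("raw", "normalized", "log")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dupes.append(i)
    if dupes:
        raise ValueError(f"duplicate {what} IDs: {', '.join(sorted(dupes))}")


@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix with scale provenance.

    Parameters
    ----------
    values
        2-D float array, one row per feature, one column per sample.
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    feature_kind
        ``"mRNA"`` or ``"miRNA"``.
    scale
        ``"raw"`` (counts/intensities), ``"normalized"`` (between-sample
        scaled, still linear) or ``"log"``.
    allow_missing
        If True, NaN cells are permitted (used only between reading a file
        with missing-value sentinels and :func:`~himpairs.prefilter.drop_sparse_features`).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_kind: str
    scale: str = "raw"
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.allow_missing:
            if np.any(np.isinf(self.values)):
                raise ValueError("values contain infinities")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (missing cells only allowed with allow_missing=True)")
        if self.scale in ("raw", "normalized"):
            with np.errstate(invalid="ignore"):
                if np.any(self.values < 0):
                    raise ValueError(f"{self.scale} values must be nonnegative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.feature_index()
        missing = [f for f in ids if f not in idx]
        if missing:
            raise KeyError(f"features not present: {', '.join(missing[:5])}")
        rows = [idx[f] for f in ids]
        return ExpressionMatrix(
            self.values[rows, :], list(ids), list(self.sample_ids),
            self.feature_kind, self.scale, self.allow_missing,
        )

    def reorder_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        missing = [s for s in ids if s not in idx]
        if missing:
            raise KeyError(f"samples not present: {', '.join(missing[:5])}")
        cols = [idx[s] for s in ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.feature_ids), list(ids),
            self.feature_kind, self.scale, self.allow_missing,
        )

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_index()[feature_id], :]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class PairedDesign:
    """Sample -> (patient, tissue status) assignment for a paired design.

    ``status`` is 1 for tumor and 0 for adjacent normal.  When
    ``require_complete`` (the default), every patient must contribute exactly
    one tumor and one normal sample; the binary outcome Y of the clinical
    submodel is ``status``.
    """

    sample_ids: list[str]
    patient_ids: list[str]
    status: np.ndarray
    require_complete: bool = True

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.status = np.asarray(self.status, dtype=int)
        if not (len(self.sample_ids) == len(self.patient_ids) == self.status.size):
            raise ValueError("sample_ids, patient_ids and status must have equal length")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be binary: 1 = tumor, 0 = adjacent normal")
        if self.require_complete:
            bad = [p for p, (nt, nn) in self._patient_counts().items() if (nt, nn) != (1, 1)]
            if bad:
                raise ValueError(
                    "each patient must appear exactly twice, once per status; "
                    f"offenders: {', '.join(sorted(bad))}"
                )

    def _patient_counts(self) -> dict[str, tuple[int, int]]:
        counts: dict[str, list[int]] = {}
        for p, y in zip(self.patient_ids, self.status):
            c = counts.setdefault(p, [0, 0])
            c[1 if y == 1 else 0] += 1
        return {p: (c[1], c[0]) for p, c in counts.items()}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pairs(self) -> int:
        return sum(1 for c in self._patient_counts().values() if c == (1, 1))

    @property
    def patients(self) -> list[str]:
        seen = []
        for p in self.patient_ids:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def y(self) -> np.ndarray:
        """Binary disease outcome per sample (1 = tumor)."""
        return self.status.copy()

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (tumor, normal) aligned patient-by-patient.

        Requires a complete design.  Patients are ordered by first appearance.
        """
        tumor: dict[str, int] = {}
        normal: dict[str, int] = {}
        for i, (p, s) in enumerate(zip(self.patient_ids, self.status)):
            (tumor if s == 1 else normal)[p] = i
        pats = [p for p in self.patients if p in tumor and p in normal]
        if len(pats) < len(self.patients):
            raise ValueError("pair_indices requires a complete paired design")
        return (np.array([tumor[p] for p in pats]), np.array([normal[p] for p in pats]))

    def subset(self, sample_ids: Sequence[str], require_complete: bool = True) -> "PairedDesign":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return PairedDesign(
            [self.sample_ids[i] for i in rows],
            [self.patient_ids[i] for i in rows],
            self.status[rows],
            require_complete=require_complete,
        )


@dataclass
class PipelineConfig:
    """Tunable parameters of the full workflow.

    Attributes
    ----------
    fdr_threshold
        Strict BH-FDR cutoff for the paired t-test prefilter (default 0.05).
    log_base, pseudocount
        Log transform: value -> log_base(value + pseudocount).
    lambda_rule
        ``"cv_1se"`` (one-standard-error rule, the default) or ``"cv_min"``
        (CV-error minimiser) for both lasso submodels.  The 1-SE rule is the
        default because the pipeline's product is a selected support, and the
        CV minimiser systematically over-selects noise predictors that the
        pair-emission rule then amplifies.
    cv_folds
        Number of cross-validation folds; folds are assigned at the patient
        level when a paired design is available.
    seed
        Master seed; every stochastic step derives its stream from it.
    correlation_threshold
        |r| cutoff of the pairwise-correlation comparator (default 0.5).
    dependence_threshold
        |r| cutoff of the tumor/normal dependence diagnostic (default 0.3).
    max_missing_fraction
        Features missing in more than this fraction of samples are dropped.
    fill_missing_with_zero
        Whether remaining missing cells are zero-filled after sparse-feature
        dropping (must be set explicitly to permit missing cells).
    """

    fdr_threshold: float = 0.05
    log_base: int = 2
    pseudocount: float = 1.0
    lambda_rule: str = "cv_1se"
    cv_folds: int = 10
    seed: int = 1
    correlation_threshold: float = 0.5
    dependence_threshold: float = 0.3
    max_missing_fraction: float = 0.9
    fill_missing_with_zero: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.lambda_rule not in ("cv_min", "cv_1se"):
            raise ValueError("lambda_rule must be 'cv_min' or 'cv_1se'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 <= self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in [0, 1]")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        self.seed = int(self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
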