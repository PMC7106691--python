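"""Readers and writers for the delimited-text formats the pipeline touches.

Expression matrices are TSV/CSV with feature IDs in the first column and a
header row of sample IDs; design files are TSV with columns ``sample_id``,
``patient_id``, ``status``.  Parsing is strict: duplicate IDs, ragged rows
and non-numeric cells are hard errors that name the offending location.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, PairedDesign

logger = logging.getLogger(__name__)

#: cell contents interpreted as missing when ``allow_missing=True``
MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A"}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    feature_kind: str,
    *,
    delimiter: str | None = None,
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Read a features x samples expression matrix from delimited text.

    The first column holds feature IDs, the header row sample IDs, and the
    body numeric expression values (scale recorded as ``raw``).  With
    ``allow_missing``, empty/NA cells become NaN and must be resolved by
    :func:`himpairs.prefilter.drop_sparse_features` before modeling.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: header must contain at least one sample column")
    sample_ids = [h.strip() for h in header[1:]]
    ncol = len(header)
    feature_ids: list[str] = []
    body = np.empty((len(rows) - 1, ncol - 1), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(f"{path}: ragged row {r}: expected {ncol} fields, got {len(row)}")
        feature_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                if not allow_missing:
                    raise ValueError(
                        f"{path}: missing value at row {r}, column {c} "
                        "(pass allow_missing=True to read missing-value sentinels)"
                    )
                body[r - 2, c - 2] = np.nan
                continue
            try:
                body[r - 2, c - 2] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {r}, column {c}"
                ) from None
    return ExpressionMatrix(
        body, feature_ids, sample_ids, feature_kind, scale="raw", allow_missing=allow_missing
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, *, delimiter: str | None = None) -> None:
    """Write a matrix as delimited text; floats use 17 significant digits so a
    read/write round trip is an identity."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", newline="") as fh:
        fh.write("feature_id" + sep + sep.join(expr.sample_ids) + "\n")
        for fid, row in zip(expr.feature_ids, expr.values):
            cells = [
                "NA" if np.isnan(v) else (str(int(v)) if float(v).is_integer() else format(v, ".17g"))
                for v in row
            ]
            fh.write(fid + sep + sep.join(cells) + "\n")


def read_design(path: str | Path, *, require_complete: bool = False) -> PairedDesign:
    """Read a TSV design table with columns sample_id, patient_id, status."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty design file")
    header = [h.strip() for h in rows[0]]
    required = ["sample_id", "patient_id", "status"]
    try:
        cols = [header.index(c) for c in required]
    except ValueError:
        raise ValueError(f"{path}: design header must contain columns {required}, got {header}") from None
    samples, patients, status = [], [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) < len(header):
            raise ValueError(f"{path}: ragged design row {r}")
        samples.append(row[cols[0]].strip())
        patients.append(row[cols[1]].strip())
        tok = row[cols[2]].strip().lower()
        mapping = {"1": 1, "0": 0, "tumor": 1, "normal": 0}
        if tok not in mapping:
            raise ValueError(f"{path}: row {r}: status must be 0/1 or tumor/normal, got {tok!r}")
        status.append(mapping[tok])
    return PairedDesign(samples, patients, np.array(status), require_complete=require_complete)


def write_design(design: PairedDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpatient_id\tstatus\n")
        for s, p, y in zip(design.sample_ids, design.patient_ids, design.status):
            fh.write(f"{s}\t{p}\t{int(y)}\n")


def align_design(
    expr: ExpressionMatrix, design: PairedDesign
) -> tuple[ExpressionMatrix, PairedDesign]:
    """Align an expression matrix to a paired design.

    Columns are reordered to the design's sample order.  Samples absent from
    either side, and samples whose patient lacks a complete tumor/normal pair
    among the shared samples, are dropped together with their partner (a
    removed normal sample always takes its matched tumor sample with it), with
    a logged warning.  Fewer than 3 complete pairs is an error.
    """
    expr_samples = set(expr.sample_ids)
    shared = [s for s in design.sample_ids if s in expr_samples]
    if not shared:
        raise ValueError("expression matrix and design share no sample IDs")
    sub = design.subset(shared, require_complete=False)
    complete = {p for p, c in sub._patient_counts().items() if c == (1, 1)}
    keep = [s for s, p in zip(sub.sample_ids, sub.patient_ids) if p in complete]
    dropped = sorted(set(design.sample_ids) - set(keep))
    if dropped:
        logger.warning(
            "align_design dropped %d sample(s) without a complete tumor/normal pair "
            "in the expression matrix: %s", len(dropped), ", ".join(dropped)
        )
    aligned = design.subset(keep, require_complete=True)
    if aligned.n_pairs < 3:
        raise ValueError(
            f"only {aligned.n_pairs} complete tumor/normal pair(s) remain after alignment; "
            "at least 3 are required for paired testing"
        )
    return expr.reorder_samples(keep), aligned


def align_pair(
    mrna: ExpressionMatrix, mirna: ExpressionMatrix, design: PairedDesign
) -> tuple[ExpressionMatrix, ExpressionMatrix, PairedDesign]:
    """Align both omic matrices and the design to their common complete pairs."""
    shared = [s for s in design.sample_ids if s in set(mrna.sample_ids) & set(mirna.sample_ids)]
    if not shared:
        raise ValueError("mRNA matrix, miRNA matrix and design share no sample IDs")
    mrna2, design2 = align_design(mrna, design.subset(shared, require_complete=False))
    mirna2 = mirna.reorder_samples(design2.sample_ids)
    return mrna2, mirna2, design2


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_id_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
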