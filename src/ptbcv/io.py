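"""Delimited-text ingestion and serialization of expression studies.

A study travels as two TSV files shaped like GEO series-matrix-derived
tables: an expression matrix (genes x samples, log2 values, gene ids in the
first column) and a sample sheet (columns: sample_id, subject_id, timepoint,
outcome).  Real accessions pre-converted to this shape can be slotted in.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .cohort import OUTCOME_ALIASES, OUTCOMES, TIMEPOINTS, ExpressionStudy

logger = logging.getLogger(__name__)


def save_study(study: ExpressionStudy, expr_path, sheet_path) -> None:
    study.expr.to_csv(expr_path, sep="\t", index_label="gene")
    study.sample_sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")


def load_study(expr_path, sheet_path) -> ExpressionStudy:
    """Load a study from TSV, validating structure.

    Subjects lacking one of the two timepoints (e.g. deliveries occurring
    before the T2 collection) are dropped with a logged count, mirroring the
    study design.  Unknown timepoint tokens, duplicate sample ids, missing
    values and sheet/matrix mismatches raise errors naming the offenders.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t", index_col=0, dtype=str)
    required = {"subject_id", "timepoint", "outcome"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet lacks column(s) {sorted(missing_cols)}")
    if sheet.index.has_duplicates:
        dups = sheet.index[sheet.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:10]}")
    sheet["outcome"] = sheet["outcome"].map(
        lambda o: OUTCOME_ALIASES.get(str(o).strip(), str(o).strip())
    )
    bad_out = sorted(set(sheet["outcome"]) - set(OUTCOMES))
    if bad_out:
        raise ValueError(f"unknown outcome token(s): {bad_out}")
    bad_tp = sorted(set(sheet["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValueError(f"unknown timepoint token(s): {bad_tp}")
    matrix_samples = set(expr.columns)
    sheet_samples = set(sheet.index)
    if matrix_samples != sheet_samples:
        only_matrix = sorted(matrix_samples - sheet_samples)
        only_sheet = sorted(sheet_samples - matrix_samples)
        raise ValueError(
            "expression matrix and sample sheet disagree: "
            f"matrix-only={only_matrix[:5]}, sheet-only={only_sheet[:5]}"
        )
    if expr.isna().to_numpy().any():
        genes = expr.index[expr.isna().any(axis=1)].tolist()
        raise ValueError(f"missing expression values in gene(s) {genes[:10]}")

    counts = sheet.groupby("subject_id")["timepoint"].nunique()
    unpaired = counts.index[counts != 2]
    if len(unpaired):
        logger.warning(
            "removed %d subject(s) lacking a matched T1+T2 pair "
            "(e.g. delivery before the T2 collection): %s",
            len(unpaired), list(unpaired)[:10],
        )
        sheet = sheet[~sheet["subject_id"].isin(set(unpaired))]
        expr = expr[sheet.index]
    return ExpressionStudy(expr[sheet.index.tolist()], sheet)
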