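"""Per-subject predictor construction.

Each differentially expressed gene contributes three base features — the
log2 intensity at T1, at T2, and their difference dT = T2 - T1 — plus three
within-gene pairwise product candidates (T1*T2, T1*dT, T2*dT) flagged as
interactions.  Rows are subjects, not samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OUTCOME_CASE, ExpressionStudy

BASE_KINDS = ("T1", "T2", "dT")
INTERACTION_PAIRS = (("T1", "T2"), ("T1", "dT"), ("T2", "dT"))


@dataclass
class FeatureMatrix:
    X: pd.DataFrame            # subjects x features
    y: np.ndarray              # 1 = sPTB, 0 = term
    feature_meta: pd.DataFrame  # index feature name; gene, kind, parents

    @property
    def base_features(self) -> list[str]:
        return list(self.feature_meta.index[self.feature_meta["kind"] != "interaction"])

    @property
    def interaction_features(self) -> list[str]:
        return list(self.feature_meta.index[self.feature_meta["kind"] == "interaction"])

    def subset_subjects(self, subject_ids) -> "FeatureMatrix":
        X = self.X.loc[list(subject_ids)]
        return FeatureMatrix(X, self.y[self.X.index.get_indexer(X.index)], self.feature_meta)


def build_feature_matrix(
    study: ExpressionStudy,
    genes: list[str],
    include_interactions: bool = True,
) -> FeatureMatrix:
    """Assemble the subjects x features matrix for the given genes."""
    missing = [g for g in genes if g not in study.expr.index]
    if missing:
        raise KeyError(f"gene(s) absent from study: {missing[:10]}")
    t1, t2, is_case, subjects = study.paired_matrices(list(genes))
    dt = t2 - t1
    blocks = {"T1": t1, "T2": t2, "dT": dt}

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for i, gene in enumerate(genes):
        for kind in BASE_KINDS:
            name = f"{gene}:{kind}"
            cols[name] = blocks[kind][i]
            meta_rows.append((name, gene, kind, ""))
        if include_interactions:
            for a, b in INTERACTION_PAIRS:
                name = f"{gene}:{a}*{b}"
                cols[name] = blocks[a][i] * blocks[b][i]
                meta_rows.append((name, gene, "interaction",
                                  f"{gene}:{a}|{gene}:{b}"))
    X = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    meta = (pd.DataFrame(meta_rows, columns=["feature", "gene", "kind", "parents"])
            .set_index("feature"))
    y = is_case.astype(int)
    return FeatureMatrix(X, y, meta)
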