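import numpy as np
import pandas as pd
import pytest

from ptbcv import ExpressionStudy, SimulationConfig, simulate_cohort


def make_study_from_arrays(t1, t2, is_case, genes=None):
    """Assemble an ExpressionStudy from genes x subjects T1/T2 matrices."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    m, n = t1.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(m)]
    cols, ids, rows = [], [], []
    for j in range(n):
        subj = f"P{j:03d}"
        out = "sPTB" if is_case[j] else "term"
        for tp, mat in (("T1", t1), ("T2", t2)):
            ids.append(f"{subj}_{tp}")
            cols.append(mat[:, j])
            rows.append((subj, tp, out))
    expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
    sheet = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                         columns=["subject_id", "timepoint", "outcome"])
    return ExpressionStudy(expr, sheet)


@pytest.fixture(scope="session")
def small_null_config():
    """A quick outcome-null cohort configuration with default drift genes."""
    return SimulationConfig(n_cases=15, n_controls=30, n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_null_study(small_null_config):
    return simulate_cohort(small_null_config)
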