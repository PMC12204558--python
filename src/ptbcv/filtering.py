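"""Variance and expression-level gene filters.

A gene is kept when its overall SD (across every supplied sample, both
timepoints) lies in [sd_low, sd_high] and at most ``max_low_samples``
samples fall below the expression floor.  Because T1 and T2 live in one
complete matrix, a kept gene automatically has measurements at both
timepoints.  In leakage-safe runs the filters see training-fold samples
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import ExpressionStudy


@dataclass
class FilterConfig:
    sd_low: float = 0.001
    sd_high: float = 3.0
    expr_floor: float = 5.0
    #: absolute count, calibrated to a 240-sample training fold
    max_low_samples: int = 35
    #: if set, overrides max_low_samples with round(fraction * n_samples),
    #: for folds of a different size (35/240 ~ 0.146)
    max_low_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.sd_low < self.sd_high:
            raise ValueError("sd_low must be < sd_high")
        if self.expr_floor <= 0:
            raise ValueError("expr_floor must be > 0")
        if self.max_low_samples < 0:
            raise ValueError("max_low_samples must be >= 0")

    def low_sample_cap(self, n_samples: int) -> int:
        if self.max_low_fraction is not None:
            return int(round(self.max_low_fraction * n_samples))
        return self.max_low_samples


def filter_genes(study: ExpressionStudy, config: FilterConfig | None = None) -> list[str]:
    """Return the gene ids surviving both filters, in matrix order."""
    config = config or FilterConfig()
    x = study.expr.to_numpy()
    sd = x.std(axis=1, ddof=1)
    n_low = (x < config.expr_floor).sum(axis=1)
    cap = config.low_sample_cap(x.shape[1])
    keep = (sd >= config.sd_low) & (sd <= config.sd_high) & (n_low <= cap)
    kept = [g for g, k in zip(study.genes, keep) if k]
    if not kept:
        warnings.warn("no genes survive filtering", stacklevel=2)
    return kept
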