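"""Repeated-measures moderated differential expression.

Per gene, a four-level cell-means model (term.T1, term.T2, sPTB.T1,
sPTB.T2) is fitted by generalized least squares under compound symmetry
within subject: each subject's (T1, T2) residual pair shares one consensus
correlation rho estimated across genes.  Per-gene residual variances are
shrunk toward a scaled inverse-chi-square prior fitted by method of moments
on the log variances (empirical-Bayes moderation), and five contrasts are
tested with moderated t statistics on d0 + d_g degrees of freedom:

* sPTB vs term at T1
* sPTB vs term at T2
* T2 vs T1 within sPTB
* T2 vs T1 within term
* trajectory: (T2 - T1) in sPTB vs (T2 - T1) in term

Benjamini-Hochberg correction is applied per contrast across genes (a
pooled option is available) and a gene is called differentially expressed
when any contrast's adjusted p-value falls below alpha.

Because each subject contributes the same balanced (T1, T2) design, the GLS
cell-mean estimates coincide with ordinary per-cell sample means; the
correlation enters only through the residual variance (computed on the
whitened scale) and the contrast variance factors, which for the
within-group and trajectory contrasts shrink by (1 - rho) exactly as in a
paired-difference analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import ExpressionStudy
from .filtering import FilterConfig, filter_genes

logger = logging.getLogger(__name__)

#: contrast names, fixed order
CONTRASTS = (
    "sPTB_vs_term_T1",
    "sPTB_vs_term_T2",
    "T2_vs_T1_sPTB",
    "T2_vs_T1_term",
    "trajectory_sPTB_vs_term",
)

_D0_CAP = 1e6


# ---------------------------------------------------------------------------
# consensus within-subject correlation


def estimate_consensus_correlation(study: ExpressionStudy, genes: list[str]) -> float:
    """Estimate the consensus within-subject correlation rho_hat.

    Per gene, residuals from the four class-by-timepoint cell means are
    formed and the Pearson correlation of each subject's (T1, T2) residual
    pair is computed across subjects; the consensus is the tanh of the 10%
    trimmed mean of the atanh-transformed per-gene correlations, clipped to
    [0, 0.99].  Genes with a degenerate (zero-variance) residual column are
    excluded.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    t1, t2, is_case, subjects = study.paired_matrices(genes)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to estimate a correlation")
    r1 = _cell_residuals(t1, is_case)
    r2 = _cell_residuals(t2, is_case)
    v1 = (r1**2).sum(axis=1)
    v2 = (r2**2).sum(axis=1)
    cov = (r1 * r2).sum(axis=1)
    ok = (v1 > 0) & (v2 > 0)
    if not ok.any():
        raise ValueError("no gene has non-degenerate residuals at both timepoints")
    r = cov[ok] / np.sqrt(v1[ok] * v2[ok])
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    rho = float(np.tanh(stats.trim_mean(z, proportiontocut=0.1)))
    return float(np.clip(rho, 0.0, 0.99))


def _cell_residuals(x: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    for mask in (is_case, ~is_case):
        out[:, mask] = x[:, mask] - x[:, mask].mean(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# per-gene GLS cell-means fits


@dataclass
class GeneFits:
    """Per-gene cell means, contrast effects and residual variances."""

    genes: list[str]
    cell_means: pd.DataFrame              # genes x (term_T1, term_T2, sPTB_T1, sPTB_T2)
    effects: pd.DataFrame                 # genes x CONTRASTS
    var_factors: np.ndarray               # unscaled contrast variances (len 5)
    s2: np.ndarray                        # whitened residual variance per gene
    df_resid: int                         # n_samples - 4
    avg_expr: np.ndarray                  # mean log2 expression per gene
    rho: float
    n_case: int
    n_control: int


def fit_gene_models(study: ExpressionStudy, genes: list[str], rho_hat: float) -> GeneFits:
    """Fit the four-cell GLS model to every gene at consensus correlation rho_hat."""
    if not 0 <= rho_hat <= 0.99:
        raise ValueError("rho_hat must lie in [0, 0.99]")
    if not genes:
        raise ValueError("genes must be non-empty")
    t1, t2, is_case, subjects = study.paired_matrices(genes)
    nc = int(is_case.sum())
    nt = int((~is_case).sum())
    for label, count in (("sPTB.T1", nc), ("sPTB.T2", nc),
                         ("term.T1", nt), ("term.T2", nt)):
        if count == 0:
            raise ValueError(f"design cell {label} is empty")

    mean = {
        "term_T1": t1[:, ~is_case].mean(axis=1),
        "term_T2": t2[:, ~is_case].mean(axis=1),
        "sPTB_T1": t1[:, is_case].mean(axis=1),
        "sPTB_T2": t2[:, is_case].mean(axis=1),
    }
    cell_means = pd.DataFrame(mean, index=genes)

    effects = pd.DataFrame({
        "sPTB_vs_term_T1": mean["sPTB_T1"] - mean["term_T1"],
        "sPTB_vs_term_T2": mean["sPTB_T2"] - mean["term_T2"],
        "T2_vs_T1_sPTB": mean["sPTB_T2"] - mean["sPTB_T1"],
        "T2_vs_T1_term": mean["term_T2"] - mean["term_T1"],
        "trajectory_sPTB_vs_term": (mean["sPTB_T2"] - mean["sPTB_T1"])
                                   - (mean["term_T2"] - mean["term_T1"]),
    }, index=genes)[list(CONTRASTS)]

    # whitened residual variance under compound symmetry:
    # sum_i (r1^2 + r2^2 - 2 rho r1 r2) / (1 - rho^2), df = N - 4
    r1 = _cell_residuals(t1, is_case)
    r2 = _cell_residuals(t2, is_case)
    rss = ((r1**2 + r2**2 - 2.0 * rho_hat * r1 * r2).sum(axis=1)
           / (1.0 - rho_hat**2))
    df_resid = 2 * len(subjects) - 4
    s2 = rss / df_resid

    between = 1.0 / nc + 1.0 / nt
    var_factors = np.array([
        between,                          # sPTB vs term at T1
        between,                          # sPTB vs term at T2
        2.0 * (1.0 - rho_hat) / nc,       # T2 vs T1 within sPTB
        2.0 * (1.0 - rho_hat) / nt,       # T2 vs T1 within term
        2.0 * (1.0 - rho_hat) * between,  # trajectory
    ])
    avg_expr = np.concatenate([t1, t2], axis=1).mean(axis=1)
    return GeneFits(list(genes), cell_means, effects, var_factors, s2,
                    df_resid, avg_expr, rho_hat, nc, nt)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


@dataclass
class ModerationResult:
    d0: float
    s0_sq: float
    s2_post: np.ndarray
    df_total: np.ndarray


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone function)."""
    if y <= 0:
        return _D0_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * max(1.0, x):
            x = x_new
            break
        x = x_new
    return float(x)


def moderate_variances(s2: np.ndarray, d) -> ModerationResult:
    """Fit a scaled inverse-chi-square prior and return posterior variances.

    Method of moments on z = log(s2): with s2_g ~ s0^2 * F(d_g, d0) the mean
    and variance of z are digamma/trigamma expressions in (d_g, d0); the
    prior df d0 solves trigamma(d0/2) = var(z) - mean(trigamma(d_g/2)).  A
    non-positive right-hand side (log-variances less dispersed than pure
    chi-square noise) yields d0 at the cap, i.e. near-complete shrinkage to
    the common value; a non-finite solution falls back to d0 = 0 (no
    moderation) with a logged warning.
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 <= 0).any():
        raise ValueError("all residual variances must be > 0")
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    if (d < 1).any():
        raise ValueError("residual df must be >= 1")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    if s2.size > 1:
        e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0).mean())
    else:
        e_var = -1.0  # single gene: no ensemble spread to fit, shrink fully
    if e_var > 0:
        d0 = min(2.0 * _trigamma_inverse(e_var), _D0_CAP)
    else:
        d0 = _D0_CAP
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if not (np.isfinite(d0) and np.isfinite(s0_sq) and s0_sq > 0):
        logger.warning("empirical-Bayes moment fit failed; proceeding unmoderated")
        d0, s0_sq = 0.0, float(np.exp(e_mean))
    if d0 == 0.0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    return ModerationResult(d0, s0_sq, s2_post, d0 + d)


# ---------------------------------------------------------------------------
# testing and multiplicity


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class DETable:
    """Long-format per-(gene, contrast) moderated test results."""

    table: pd.DataFrame      # gene, contrast, effect, avg_expr, moderated_t, df_total, p, p_adj
    rho_hat: float
    d0: float
    s0_sq: float

    def significant_any_contrast(self, alpha: float = 0.05) -> list[str]:
        sig = self.table.loc[self.table["p_adj"] < alpha, "gene"]
        seen: dict[str, None] = {}
        for g in sig:
            seen.setdefault(g, None)
        return list(seen)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def test_contrasts(
    fits: GeneFits,
    moderation: ModerationResult,
    adjust: str = "per_contrast",
) -> DETable:
    """Moderated t-tests for the five contrasts with BH correction.

    ``adjust`` chooses the BH family: ``per_contrast`` (default) corrects
    across genes within each contrast; ``pooled`` corrects across all
    (gene, contrast) pairs at once.
    """
    if adjust not in ("per_contrast", "pooled"):
        raise ValueError("adjust must be 'per_contrast' or 'pooled'")
    if len(moderation.s2_post) != len(fits.genes):
        raise ValueError("fits and moderation cover different gene sets")
    frames = []
    df_total = np.minimum(moderation.df_total, 1e7)
    for j, contrast in enumerate(CONTRASTS):
        eff = fits.effects[contrast].to_numpy()
        se = np.sqrt(fits.var_factors[j] * moderation.s2_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, eff / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        frames.append(pd.DataFrame({
            "gene": fits.genes,
            "contrast": contrast,
            "effect": eff,
            "avg_expr": fits.avg_expr,
            "moderated_t": t,
            "df_total": df_total,
            "p": np.clip(p, 0.0, 1.0),
        }))
    table = pd.concat(frames, ignore_index=True)
    if adjust == "per_contrast":
        table["p_adj"] = (
            table.groupby("contrast", sort=False)["p"].transform(lambda v: bh_adjust(v.to_numpy()))
        )
    else:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return DETable(table, fits.rho, moderation.d0, moderation.s0_sq)


def select_de_genes(table: DETable, alpha: float = 0.05) -> list[str]:
    """Genes with BH-adjusted p below alpha in at least one contrast."""
    return table.significant_any_contrast(alpha)


# ---------------------------------------------------------------------------
# model-object facade


class RepeatedMeasuresDE:
    """The differential-expression stage as a fittable model.

    Bundles filtering, consensus-correlation estimation, per-gene GLS fits,
    empirical-Bayes moderation and contrast testing for one set of samples
    (typically a training fold).  Every statistic is a pure function of the
    samples supplied; nothing is cached across instances.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        filter_config: FilterConfig | None = None,
        alpha: float = 0.05,
        adjust: str = "per_contrast",
        prefiltered_genes: list[str] | None = None,
    ):
        self.study = study
        self.filter_config = filter_config or FilterConfig()
        self.alpha = alpha
        self.adjust = adjust
        self.prefiltered_genes = prefiltered_genes

    def fit(self) -> "DEResults":
        genes = (self.prefiltered_genes if self.prefiltered_genes is not None
                 else filter_genes(self.study, self.filter_config))
        if not genes:
            empty = pd.DataFrame(columns=["gene", "contrast", "effect", "avg_expr",
                                          "moderated_t", "df_total", "p", "p_adj"])
            return DEResults(self, genes, None, None,
                             DETable(empty, 0.0, 0.0, 1.0), [])
        rho_hat = estimate_consensus_correlation(self.study, genes)
        fits = fit_gene_models(self.study, genes, rho_hat)
        moderation = moderate_variances(fits.s2, fits.df_resid)
        table = test_contrasts(fits, moderation, adjust=self.adjust)
        de_genes = select_de_genes(table, self.alpha)
        return DEResults(self, genes, fits, moderation, table, de_genes)


@dataclass
class DEResults:
    model: RepeatedMeasuresDE
    filtered_genes: list[str]
    fits: GeneFits | None
    moderation: ModerationResult | None
    table: DETable
    de_genes: list[str]

    def summary(self) -> str:
        lines = [
            "Repeated-measures moderated differential expression",
            f"  genes after filtering : {len(self.filtered_genes)}",
            f"  consensus correlation : {self.table.rho_hat:.3f}",
            f"  prior df d0           : {self.table.d0:.3g}",
            f"  prior variance s0^2   : {self.table.s0_sq:.3g}",
            f"  DE genes (any contrast, BH<{self.model.alpha}) : {len(self.de_genes)}",
        ]
        if len(self.table.table):
            counts = (self.table.table[self.table.table["p_adj"] < self.model.alpha]
                      .groupby("contrast", sort=False)["gene"].count())
            for contrast in CONTRASTS:
                lines.append(f"    {contrast:<26s}: {int(counts.get(contrast, 0))}")
        return "\n".join(lines)
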