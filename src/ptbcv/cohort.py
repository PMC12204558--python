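"""Synthetic two-timepoint case-control expression cohorts.

Emulates the structure of a paired maternal-blood microarray study of
spontaneous preterm birth (sPTB): each subject contributes one sample at an
early-gestation timepoint (T1, ~17-23 weeks) and one at a later timepoint
(T2, ~28-33 weeks), expression is on the log2 RMA-like intensity scale, and
residuals within a subject are correlated across the two draws.

The generator produces cohorts with known ground truth: an outcome-null
background plus optional planted class-difference signals (at T1, at T2, or
in the T2-T1 trajectory), designated low-variance / high-variance /
low-expression gene fractions so downstream filters have work to do, and a
fraction of genes whose mean level drifts with gestational age (the same in
both classes), emulating the pervasive timepoint dependence of maternal
blood expression.  A distribution-shifted external cohort sharing the same
gene-level truth stands in for a second-site validation population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("T1", "T2")
#: canonical outcome tokens; sPTB is the positive class
OUTCOME_CASE = "sPTB"
OUTCOME_CONTROL = "term"
OUTCOMES = (OUTCOME_CASE, OUTCOME_CONTROL)
#: aliases accepted on ingestion and normalized to the canonical tokens
OUTCOME_ALIASES = {
    "case": OUTCOME_CASE,
    "sptb": OUTCOME_CASE,
    "sPTB": OUTCOME_CASE,
    "control": OUTCOME_CONTROL,
    "term": OUTCOME_CONTROL,
}

CONTRAST_KINDS = ("T1_diff", "T2_diff", "trajectory_diff")


@dataclass(frozen=True)
class SignalSpec:
    """A planted class-difference signal.

    Parameters
    ----------
    contrast_kind
        ``"T1_diff"`` shifts case samples at T1, ``"T2_diff"`` shifts case
        samples at T2, and ``"trajectory_diff"`` shifts the case T2-T1
        trajectory (realized as a shift applied at T2 only, in cases).
    n_genes
        Number of genes carrying this signal.  Signal gene sets of distinct
        specs are disjoint.
    effect_size
        Additive shift in log2 units between classes.
    """

    contrast_kind: str
    n_genes: int
    effect_size: float

    def __post_init__(self) -> None:
        if self.contrast_kind not in CONTRAST_KINDS:
            raise ValueError(f"unknown contrast_kind {self.contrast_kind!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class SimulationConfig:
    """Generative settings for a paired two-timepoint cohort.

    Defaults mirror the training-cohort structure (49 sPTB cases, 114 term
    controls, each with paired T1+T2 samples) at a desk-scale gene count.
    ``frac_timepoint`` designates genes whose mean drifts between T1 and T2
    identically in both classes (gestational-age effect, drawn once per gene
    from N(0, ``timepoint_effect_sd``)); these genes are outcome-null but are
    legitimately differentially expressed in the within-group timepoint
    contrasts.
    """

    n_cases: int = 49
    n_controls: int = 114
    n_genes: int = 5000
    baseline_mean_range: tuple[float, float] = (3.0, 12.0)
    gene_sd_range: tuple[float, float] = (0.2, 1.2)
    frac_low_variance: float = 0.02
    frac_high_variance: float = 0.02
    frac_low_expression: float = 0.06
    frac_timepoint: float = 0.10
    timepoint_effect_sd: float = 0.75
    rho_within: float = 0.5
    signals: list[SignalSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_low_variance, self.frac_high_variance,
                 self.frac_low_expression, self.frac_timepoint)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("frac_* values must lie in [0, 1]")
        if (self.frac_low_variance + self.frac_high_variance
                + self.frac_low_expression) > 1:
            raise ValueError("designated gene fractions must sum to <= 1")
        if not (0 <= self.rho_within < 1):
            raise ValueError("rho_within must lie in [0, 1)")
        if self.n_cases < 1 or self.n_controls < 1 or self.n_genes < 1:
            raise ValueError("n_cases, n_controls and n_genes must be >= 1")
        if self.baseline_mean_range[0] >= self.baseline_mean_range[1]:
            raise ValueError("baseline_mean_range must be an increasing interval")
        if self.gene_sd_range[0] >= self.gene_sd_range[1]:
            raise ValueError("gene_sd_range must be an increasing interval")
        n_special = self._n_low_var + self._n_high_var + self._n_low_expr
        n_signal = sum(s.n_genes for s in self.signals)
        if n_special + n_signal + self._n_timepoint > self.n_genes:
            raise ValueError("designated + signal genes exceed n_genes")

    @property
    def _n_low_var(self) -> int:
        return int(round(self.frac_low_variance * self.n_genes))

    @property
    def _n_high_var(self) -> int:
        return int(round(self.frac_high_variance * self.n_genes))

    @property
    def _n_low_expr(self) -> int:
        return int(round(self.frac_low_expression * self.n_genes))

    @property
    def _n_timepoint(self) -> int:
        return int(round(self.frac_timepoint * self.n_genes))


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus its sample sheet.

    ``expr`` is genes x samples; ``sample_sheet`` is indexed by sample id
    with columns ``subject_id``, ``timepoint`` (T1/T2) and ``outcome``
    (sPTB/term).  Every subject must appear at exactly both timepoints (the
    study design drops subjects delivering before the T2 draw) and the
    matrix must be complete.  ``truth`` optionally records planted
    (gene, SignalSpec) pairs.
    """

    expr: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: list[tuple[str, SignalSpec]] | None = None

    def __post_init__(self) -> None:
        sheet = self.sample_sheet
        required = {"subject_id", "timepoint", "outcome"}
        if not required.issubset(sheet.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        if list(self.expr.columns) != list(sheet.index):
            if set(self.expr.columns) != set(sheet.index):
                raise ValueError("expression columns and sample sheet disagree")
            self.sample_sheet = sheet = sheet.loc[self.expr.columns]
        if sheet.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample sheet")
        bad_tp = set(sheet["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint token(s): {sorted(bad_tp)}")
        bad_out = set(sheet["outcome"]) - set(OUTCOMES)
        if bad_out:
            raise ValueError(f"unknown outcome token(s): {sorted(bad_out)}")
        pairs = sheet.groupby("subject_id")["timepoint"].agg(["count", "nunique"])
        if ((pairs["count"] != 2) | (pairs["nunique"] != 2)).any():
            offenders = pairs.index[(pairs["count"] != 2) | (pairs["nunique"] != 2)]
            raise ValueError(
                "every subject must have exactly one T1 and one T2 sample; "
                f"offending subjects: {list(offenders)[:10]}"
            )
        per_subj = sheet.groupby("subject_id")["outcome"].nunique()
        if (per_subj != 1).any():
            raise ValueError("a subject's two samples must share one outcome label")
        if self.expr.isna().to_numpy().any():
            raise ValueError("expression matrix contains missing values")

    # -- convenience views -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_sheet["subject_id"]:
            seen.setdefault(s, None)
        return list(seen)

    def subject_outcomes(self) -> pd.Series:
        """Outcome label per subject (order of first appearance)."""
        sheet = self.sample_sheet
        return sheet.groupby("subject_id", sort=False)["outcome"].first()

    def n_by_class(self) -> tuple[int, int]:
        out = self.subject_outcomes()
        return int((out == OUTCOME_CASE).sum()), int((out == OUTCOME_CONTROL).sum())

    def paired_matrices(
        self, genes: list[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Return (T1, T2, is_case, subject_ids) with matrices genes x subjects."""
        sheet = self.sample_sheet
        subjects = self.subjects
        sample_of = sheet.index.to_series(name="sample")
        t1_ids = (sample_of[sheet["timepoint"] == "T1"]
                  .set_axis(sheet.loc[sheet["timepoint"] == "T1", "subject_id"])
                  .loc[subjects])
        t2_ids = (sample_of[sheet["timepoint"] == "T2"]
                  .set_axis(sheet.loc[sheet["timepoint"] == "T2", "subject_id"])
                  .loc[subjects])
        expr = self.expr if genes is None else self.expr.loc[genes]
        t1 = expr[t1_ids.to_numpy()].to_numpy()
        t2 = expr[t2_ids.to_numpy()].to_numpy()
        is_case = (self.subject_outcomes().loc[subjects] == OUTCOME_CASE).to_numpy()
        return t1, t2, is_case, subjects

    def subset_subjects(self, subject_ids) -> "ExpressionStudy":
        """Restrict the study to the given subjects (pairing preserved)."""
        keep = self.sample_sheet["subject_id"].isin(set(subject_ids))
        sheet = self.sample_sheet.loc[keep]
        return ExpressionStudy(self.expr[sheet.index], sheet.copy(), truth=self.truth)

    def equals(self, other: "ExpressionStudy") -> bool:
        return (self.expr.equals(other.expr)
                and self.sample_sheet.equals(other.sample_sheet))


# ---------------------------------------------------------------------------
# gene-level generative parameters


@dataclass
class _GeneParams:
    genes: list[str]
    baseline: np.ndarray
    sd: np.ndarray
    timepoint_drift: np.ndarray          # additive T2 shift, both classes
    signal_shift_t1: np.ndarray          # additive shift for case T1 samples
    signal_shift_t2: np.ndarray          # additive shift for case T2 samples
    truth: list[tuple[str, SignalSpec]]


def _gene_params(config: SimulationConfig) -> _GeneParams:
    """Draw per-gene parameters from the gene-level child stream.

    Gene parameters depend only on ``config.seed`` (via a dedicated child
    stream), so the paired cohort and any external cohort built from the
    same config share one gene universe and one generative truth.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    gene_ss, _cohort_ss, _ext_ss = root.spawn(3)
    rng = np.random.default_rng(gene_ss)

    m = config.n_genes
    width = len(str(m))
    genes = [f"G{idx:0{width}d}" for idx in range(m)]
    baseline = rng.uniform(*config.baseline_mean_range, size=m)
    sd = rng.uniform(*config.gene_sd_range, size=m)

    order = rng.permutation(m)
    lo = order[: config._n_low_var]
    hi = order[config._n_low_var: config._n_low_var + config._n_high_var]
    start = config._n_low_var + config._n_high_var
    lexp = order[start: start + config._n_low_expr]
    start += config._n_low_expr
    sd[lo] = rng.uniform(1e-5, 9e-4, size=lo.size)
    sd[hi] = rng.uniform(3.2, 4.5, size=hi.size)
    baseline[lexp] = rng.uniform(2.5, 4.5, size=lexp.size)

    drift = np.zeros(m)
    tp = order[start: start + config._n_timepoint]
    start += config._n_timepoint
    drift[tp] = rng.normal(0.0, config.timepoint_effect_sd, size=tp.size)

    shift_t1 = np.zeros(m)
    shift_t2 = np.zeros(m)
    truth: list[tuple[str, SignalSpec]] = []
    for spec in config.signals:
        chosen = order[start: start + spec.n_genes]
        start += spec.n_genes
        if spec.contrast_kind == "T1_diff":
            shift_t1[chosen] += spec.effect_size
        else:  # T2_diff and trajectory_diff both realize as a case T2 shift
            shift_t2[chosen] += spec.effect_size
        truth.extend((genes[g], spec) for g in sorted(chosen))

    shifted_means = np.concatenate([
        baseline + shift_t1, baseline + drift + shift_t2,
    ])
    if (shifted_means < 0).any():
        raise ValueError(
            "signal effect sizes drive some case cell means negative on the "
            "log2 intensity scale; clamping is not performed"
        )
    return _GeneParams(genes, baseline, sd, drift, shift_t1, shift_t2, truth)


def _assemble(
    params: _GeneParams,
    rho: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    subject_prefix: str,
    baseline_offset: np.ndarray | None = None,
) -> ExpressionStudy:
    m = len(params.genes)
    n = n_cases + n_controls
    # bivariate (T1, T2) residuals with within-subject correlation rho
    z1 = rng.standard_normal((m, n))
    z2 = rng.standard_normal((m, n))
    e1 = z1
    e2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    sd = params.sd[:, None]
    base = params.baseline if baseline_offset is None else params.baseline + baseline_offset
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True
    t1 = base[:, None] + sd * e1
    t2 = base[:, None] + params.timepoint_drift[:, None] + sd * e2
    t1[:, is_case] += params.signal_shift_t1[:, None]
    t2[:, is_case] += params.signal_shift_t2[:, None]

    width = len(str(n))
    subjects = [f"{subject_prefix}{idx:0{width}d}" for idx in range(n)]
    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    rows = []
    for j, subj in enumerate(subjects):
        for tp, mat in (("T1", t1), ("T2", t2)):
            sample_ids.append(f"{subj}_{tp}")
            cols.append(mat[:, j])
            rows.append((subj, tp, OUTCOME_CASE if is_case[j] else OUTCOME_CONTROL))
    expr = pd.DataFrame(
        np.column_stack(cols), index=params.genes, columns=sample_ids
    )
    sheet = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                         columns=["subject_id", "timepoint", "outcome"])
    return ExpressionStudy(expr, sheet, truth=list(params.truth) or None)


def simulate_cohort(config: SimulationConfig) -> ExpressionStudy:
    """Generate a paired two-timepoint cohort; deterministic given the seed."""
    params = _gene_params(config)
    root = np.random.SeedSequence(config.seed)
    _gene_ss, cohort_ss, _ext_ss = root.spawn(3)
    rng = np.random.default_rng(cohort_ss)
    return _assemble(params, config.rho_within, config.n_cases,
                     config.n_controls, rng, subject_prefix="S")


def simulate_external_cohort(
    config: SimulationConfig,
    shift: float | np.ndarray = 1.0,
    n_cases: int = 34,
    n_controls: int = 64,
    reference: ExpressionStudy | None = None,
) -> ExpressionStudy:
    """Generate a distribution-shifted external cohort on the same gene universe.

    The gene-level truth (signal genes, effects, per-gene SDs, timepoint
    drifts) is identical to :func:`simulate_cohort` for the same config;
    per-gene baselines are offset by a sampled batch/population shift.

    Parameters
    ----------
    shift
        Either the SD of a per-gene normal location offset, or an explicit
        per-gene offset vector of length ``config.n_genes``.
    reference
        If given, the generated gene universe is checked against this
        study's and a mismatch raises.
    """
    params = _gene_params(config)
    root = np.random.SeedSequence(config.seed)
    _gene_ss, _cohort_ss, ext_ss = root.spawn(3)
    rng = np.random.default_rng(ext_ss)
    if np.isscalar(shift):
        offset = rng.normal(0.0, float(shift), size=config.n_genes)
    else:
        offset = np.asarray(shift, dtype=float)
        if offset.shape != (config.n_genes,):
            raise ValueError("per-gene shift vector has the wrong length")
    study = _assemble(params, config.rho_within, n_cases, n_controls, rng,
                      subject_prefix="X", baseline_offset=offset)
    if reference is not None and list(reference.expr.index) != study.genes:
        raise ValueError("external cohort gene universe does not match reference study")
    return study


def permute_labels(study: ExpressionStudy, seed: int) -> ExpressionStudy:
    """Scramble outcome labels at the subject level.

    Both timepoint samples of a subject keep one common (permuted) label,
    class counts are preserved, expression is untouched, and any planted
    ground truth is cleared (it no longer describes the label structure).
    """
    rng = np.random.default_rng(seed)
    outcomes = study.subject_outcomes()
    permuted = pd.Series(
        rng.permutation(outcomes.to_numpy()), index=outcomes.index
    )
    sheet = study.sample_sheet.copy()
    sheet["outcome"] = permuted.loc[sheet["subject_id"]].to_numpy()
    return ExpressionStudy(study.expr, sheet, truth=None)
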