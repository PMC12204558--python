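"""End-to-end experiment orchestration.

One experiment = a repeated stratified k-fold plan over subjects (default
2 x 5 = ten outer iterations), run in one of two execution modes:

* **safe** — within each outer iteration, filtering, consensus correlation,
  differential expression, gene selection, feature construction and
  stepwise selection are computed from the training partition only; the
  held-out partition and the external cohort see nothing but a frozen
  model.
* **prone** — the leakage probe: differential expression and gene selection
  (and, by default, stepwise feature selection too; configurable) are
  computed once on *all* subjects before splitting, then the same
  cross-validation loop runs.  The only difference from safe mode is which
  rows inform preprocessing/selection, which is exactly the mechanism that
  inflates internal-test performance.

A subject-level label-permutation switch provides the scrambled-label
overfitting control.  The elastic net and random forest consume the
post-differential-expression base feature space directly (their internal
selection substitutes for the stepwise search); the logistic regressions
and the MLP consume the stepwise-selected features.  Iterations whose
differential-expression stage selects zero genes are recorded as degenerate
and scored as a no-skill constant classifier so null experiments complete.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import OUTCOME_CASE, ExpressionStudy, permute_labels
from .de import RepeatedMeasuresDE
from .features import FeatureMatrix, build_feature_matrix
from .filtering import FilterConfig
from .metrics import PerformanceReport, aggregate_folds, auroc, confusion_metrics, stability_summary
from .models import ModelConfig, internal_selection_report, predict_scores, train_model
from .sas import SASConfig, SelectionTrace, sas_select

logger = logging.getLogger(__name__)

SET_LABELS = ("training", "internal_test", "external")


# ---------------------------------------------------------------------------
# fold planning


@dataclass
class FoldPlan:
    repeats: int
    k: int
    assignments: list[dict[str, int]]   # per repeat: subject -> fold index
    stratified: bool
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.repeats * self.k

    def split(self, repeat: int, fold: int) -> tuple[list[str], list[str]]:
        assign = self.assignments[repeat]
        train = [s for s, f in assign.items() if f != fold]
        test = [s for s, f in assign.items() if f == fold]
        return train, test


def make_folds(labels: pd.Series, repeats: int = 2, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified subject-level fold assignment, deterministic given the seed.

    ``labels`` maps subject id -> outcome token.  Class proportions per fold
    are within one subject of the overall proportions.  A class smaller
    than k raises.
    """
    subjects = np.array(labels.index)
    y = (labels == OUTCOME_CASE).to_numpy().astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(f"smallest class ({min(n_pos, n_neg)}) is below k={k}")
    ss = np.random.SeedSequence(seed)
    assignments = []
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        assign: dict[str, int] = {}
        for cls in (1, 0):
            idx = rng.permutation(np.flatnonzero(y == cls))
            folds = np.arange(len(idx)) % k
            # shuffle which folds get the remainder subjects
            folds = rng.permutation(k)[folds]
            for i, f in zip(idx, folds):
                assign[str(subjects[i])] = int(f)
        assignments.append({str(s): assign[str(s)] for s in subjects})
    return FoldPlan(repeats, k, assignments, True, seed)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    leakage_mode: str = "safe"                 # safe | prone
    prone_scope: str = "de_and_sas"            # de_and_sas | de_only
    permute_labels: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    sas: SASConfig = field(default_factory=SASConfig)
    models: list[ModelConfig] = field(default_factory=lambda: [ModelConfig("LR")])
    alpha: float = 0.05
    adjust: str = "per_contrast"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leakage_mode not in ("safe", "prone"):
            raise ValueError("leakage_mode must be 'safe' or 'prone'")
        if self.prone_scope not in ("de_and_sas", "de_only"):
            raise ValueError("prone_scope must be 'de_and_sas' or 'de_only'")

    def provenance_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the experiment report


@dataclass
class ExperimentReport:
    fold_rows: pd.DataFrame
    performance: dict[tuple[str, str], PerformanceReport]
    traces: list[SelectionTrace | None]
    internal_selections: dict[str, list[list[tuple[str, int]]]]
    de_genes_per_iteration: list[list[str]]
    degenerate_iterations: list[int]
    provenance: dict

    @property
    def de_gene_counts(self) -> list[int]:
        return [len(g) for g in self.de_genes_per_iteration]

    def mean_auroc(self, family: str, set_label: str) -> float:
        return self.performance[(family, set_label)].metrics["auroc"][0]

    def sas_stability(self) -> pd.DataFrame:
        sels = [t.ranks() for t in self.traces if t is not None]
        return stability_summary(sels)

    def internal_stability(self, family: str) -> pd.DataFrame:
        return stability_summary(self.internal_selections.get(family, []))

    def performance_table(self) -> pd.DataFrame:
        rows = []
        for (family, set_label), rep in self.performance.items():
            row = {"family": family, **rep.to_row()}
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# core loop


def _evaluate(model_cfg, fitted, fm: FeatureMatrix, names: list[str],
              threshold: float) -> dict[str, float]:
    scores = predict_scores(fitted, fm.X[names].to_numpy(), names)
    out = {"auroc": auroc(scores, fm.y)}
    out.update(confusion_metrics(scores, fm.y, threshold))
    return out


def _degenerate_metrics(y: np.ndarray, threshold: float) -> dict[str, float]:
    scores = np.full(len(y), 0.5)
    out = {"auroc": 0.5}
    out.update(confusion_metrics(scores, y, threshold))
    return out


def run_pipeline(
    study: ExpressionStudy,
    external_study: ExpressionStudy | None,
    plan: FoldPlan,
    config: PipelineConfig,
) -> ExperimentReport:
    """Run the full experiment and aggregate the tabular reports."""
    t_start = time.time()
    if external_study is not None and list(external_study.expr.index) != study.genes:
        raise ValueError("training and external studies must share the gene universe")

    root = np.random.SeedSequence(config.seed)
    permute_ss, prone_ss, iter_root = root.spawn(3)
    if config.permute_labels:
        permute_seed = int(permute_ss.generate_state(1)[0] % (2**31))
        study = permute_labels_subjectwise(study, permute_seed)

    subjects = study.subjects
    outcome = study.subject_outcomes()

    # prone-mode precomputation on ALL subjects
    prone_de_genes: list[str] | None = None
    prone_trace: SelectionTrace | None = None
    if config.leakage_mode == "prone":
        deres = RepeatedMeasuresDE(study, config.filter, config.alpha,
                                   config.adjust).fit()
        prone_de_genes = deres.de_genes
        logger.info("prone mode: %d genes selected on the full cohort",
                    len(prone_de_genes))
        if config.prone_scope == "de_and_sas" and prone_de_genes:
            fm_full = build_feature_matrix(study, prone_de_genes)
            sas_seed = int(prone_ss.generate_state(1)[0] % (2**31))
            prone_trace = sas_select(
                fm_full, dataclasses.replace(config.sas, seed=sas_seed))

    iter_seeds = iter_root.spawn(plan.n_iterations)
    rows = []
    traces: list[SelectionTrace | None] = []
    internal_sel: dict[str, list[list[tuple[str, int]]]] = {}
    de_genes_per_iter: list[list[str]] = []
    degenerate: list[int] = []

    for it in range(plan.n_iterations):
        repeat, fold = divmod(it, plan.k)
        train_subj, test_subj = plan.split(repeat, fold)
        it_ss = iter_seeds[it]
        sas_seed, *model_seeds = [
            int(s.generate_state(1)[0] % (2**31)) for s in it_ss.spawn(1 + len(config.models))
        ]

        train_study = study.subset_subjects(train_subj)
        if config.leakage_mode == "safe":
            deres = RepeatedMeasuresDE(train_study, config.filter, config.alpha,
                                       config.adjust).fit()
            de_genes = deres.de_genes
        else:
            de_genes = list(prone_de_genes or [])
        de_genes_per_iter.append(de_genes)

        if not de_genes:
            degenerate.append(it)
            traces.append(None)
            for mc in config.models:
                for set_label, subj_set in (("training", train_subj),
                                            ("internal_test", test_subj),
                                            ("external", None)):
                    if set_label == "external":
                        if external_study is None:
                            continue
                        y = (external_study.subject_outcomes() == OUTCOME_CASE).to_numpy().astype(int)
                    else:
                        y = (outcome.loc[subj_set] == OUTCOME_CASE).to_numpy().astype(int)
                    rows.append({"repeat": repeat, "fold": fold, "family": mc.family,
                                 "set": set_label, "degenerate": True,
                                 **_degenerate_metrics(y, config.threshold)})
            continue

        fm_train = build_feature_matrix(train_study, de_genes)
        fm_test = build_feature_matrix(study.subset_subjects(test_subj), de_genes)
        fm_ext = (build_feature_matrix(external_study, de_genes)
                  if external_study is not None else None)

        if config.leakage_mode == "prone" and config.prone_scope == "de_and_sas":
            trace = prone_trace or SelectionTrace()
        else:
            trace = sas_select(fm_train,
                               dataclasses.replace(config.sas, seed=sas_seed))
        traces.append(trace)

        base_names = fm_train.base_features
        for mc, mseed in zip(config.models, model_seeds):
            mc_it = dataclasses.replace(mc, seed=mseed)
            names = base_names if mc.family in ("LR_ELN", "RF") else list(trace.selected)
            if not names:
                for set_label, fm in (("training", fm_train),
                                      ("internal_test", fm_test),
                                      ("external", fm_ext)):
                    if fm is None:
                        continue
                    rows.append({"repeat": repeat, "fold": fold, "family": mc.family,
                                 "set": set_label, "degenerate": True,
                                 **_degenerate_metrics(fm.y, config.threshold)})
                continue
            fitted = train_model(mc_it, fm_train.X[names].to_numpy(),
                                 fm_train.y, names)
            if fitted.has_internal_selection:
                rep = internal_selection_report(fitted)
                sel = rep[rep["selected"]]
                internal_sel.setdefault(mc.family, []).append(
                    list(zip(sel.index, sel["rank"].astype(int))))
            for set_label, fm in (("training", fm_train),
                                  ("internal_test", fm_test),
                                  ("external", fm_ext)):
                if fm is None:
                    continue
                rows.append({"repeat": repeat, "fold": fold, "family": mc.family,
                             "set": set_label, "degenerate": False,
                             **_evaluate(mc_it, fitted, fm, names, config.threshold)})

    fold_rows = pd.DataFrame(rows)
    performance: dict[tuple[str, str], PerformanceReport] = {}
    ext_pos = ext_neg = 0
    if external_study is not None:
        ext_out = external_study.subject_outcomes()
        ext_pos = int((ext_out == OUTCOME_CASE).sum())
        ext_neg = int((ext_out != OUTCOME_CASE).sum())
    for mc in config.models:
        for set_label in SET_LABELS:
            sub = fold_rows[(fold_rows["family"] == mc.family)
                            & (fold_rows["set"] == set_label)]
            if len(sub) < 2:
                continue
            fm_list = sub.drop(columns=["repeat", "fold", "family", "set",
                                        "degenerate"]).to_dict("records")
            n_pos, n_neg = ((ext_pos, ext_neg) if set_label == "external"
                            else study.n_by_class())
            performance[(mc.family, set_label)] = aggregate_folds(
                fm_list, set_label, n_pos, n_neg, config.threshold)

    provenance = {
        "config_hash": config.provenance_hash(),
        "seed": config.seed,
        "leakage_mode": config.leakage_mode,
        "prone_scope": config.prone_scope,
        "permuted": config.permute_labels,
        "n_iterations": plan.n_iterations,
        "started": t_start,
        "elapsed_s": time.time() - t_start,
    }
    return ExperimentReport(fold_rows, performance, traces, internal_sel,
                            de_genes_per_iter, degenerate, provenance)


def permute_labels_subjectwise(study: ExpressionStudy, seed: int) -> ExpressionStudy:
    """Alias kept close to the pipeline for discoverability."""
    return permute_labels(study, seed)


def run_permutation_control(
    study: ExpressionStudy,
    external_study: ExpressionStudy | None,
    plan: FoldPlan,
    config: PipelineConfig,
) -> ExperimentReport:
    """The scrambled-label control: permute outcomes, then run the pipeline.

    The resulting report juxtaposes training, internal-test and external
    AUROC; flexible families retain high training performance while test
    performance collapses to chance — the overfitting signature.
    """
    permuted_cfg = dataclasses.replace(config, permute_labels=True)
    return run_pipeline(study, external_study, plan, permuted_cfg)


# ---------------------------------------------------------------------------
# leakage audit


def leakage_canary_check(
    study: ExpressionStudy,
    plan: FoldPlan,
    config: PipelineConfig,
    iteration: int = 0,
) -> bool:
    """Verify that held-out data cannot influence safe-mode training stages.

    A canary subject from the held-out partition of ``iteration`` has its
    expression perturbed; the safe-mode run is repeated and that iteration's
    differential-expression gene list and stepwise-selection trace must be
    unchanged.  Returns True when the canary is invisible to training.
    """
    if config.leakage_mode != "safe":
        raise ValueError("the canary audit applies to safe mode")
    repeat, fold = divmod(iteration, plan.k)
    _train, test_subj = plan.split(repeat, fold)
    canary = test_subj[0]
    report_a = run_pipeline(study, None, plan, config)

    expr = study.expr.copy()
    canary_samples = study.sample_sheet.index[
        study.sample_sheet["subject_id"] == canary]
    expr[canary_samples] = expr[canary_samples] + 3.0
    perturbed = ExpressionStudy(expr, study.sample_sheet.copy(), truth=study.truth)
    report_b = run_pipeline(perturbed, None, plan, config)

    same_genes = (report_a.de_genes_per_iteration[iteration]
                  == report_b.de_genes_per_iteration[iteration])
    ta, tb = report_a.traces[iteration], report_b.traces[iteration]
    same_trace = (ta is None and tb is None) or (
        ta is not None and tb is not None and ta.selected == tb.selected)
    return bool(same_genes and same_trace)
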