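"""Stepwise additive selection (SAS) of predictive features.

A greedy forward search scored by nested cross-validated AUROC: starting
from an empty logistic regression model (score defined as 0.5), every
remaining candidate feature is scored by the mean validation AUROC of an
unregularized logistic regression over stratified inner folds; the best
candidate is admitted when its score beats the current model score by at
least epsilon (default 0.015).  A failed iteration re-draws the inner folds
and retries; three consecutive failures terminate the search, as does
reaching the feature cap (default 30).  Admitted interaction terms are
capped (default 5); once the cap is reached interaction candidates are
skipped.

Candidate scoring is vectorized: all candidates are fitted simultaneously
by a batched Newton solver for the logistic likelihood (a tiny ridge term,
1e-8, stabilizes separable folds; with a capped iteration count this plays
the role of the usual iteration-limited maximum-likelihood fit and leaves
the score ranking unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .features import FeatureMatrix

_RIDGE = 1e-8
_NEWTON_ITER = 25


@dataclass
class SASConfig:
    epsilon: float = 0.015
    patience: int = 3
    max_features: int = 30
    max_interactions: int = 5
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_interactions > self.max_features:
            raise ValueError("max_interactions must be <= max_features")


@dataclass
class SASIteration:
    iteration: int
    n_candidates: int
    best_candidate: str
    best_score: float
    admitted: bool


@dataclass
class SelectionTrace:
    iterations: list[SASIteration] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)   # model score after each admission
    termination_reason: str = "exhausted"

    def ranks(self) -> list[tuple[str, int]]:
        """Selected features with their admission rank (1 = first admitted)."""
        return [(f, i + 1) for i, f in enumerate(self.selected)]


# ---------------------------------------------------------------------------
# stratified inner folds


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Index pairs (train, val) for k stratified folds; each fold holds both classes."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < k or len(neg) < k:
        raise ValueError(f"each class needs at least {k} subjects for {k}-fold CV")
    assign = np.empty(len(y), dtype=int)
    assign[rng.permutation(pos)] = np.arange(len(pos)) % k
    assign[rng.permutation(neg)] = np.arange(len(neg)) % k
    folds = []
    for f in range(k):
        val = np.flatnonzero(assign == f)
        train = np.flatnonzero(assign != f)
        folds.append((train, val))
    return folds


# ---------------------------------------------------------------------------
# batched logistic scoring


def _fit_logistic_batch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Newton fit of C independent logistic regressions.

    X has shape (C, n, p) (intercept included as first column), y shape (n,).
    Returns beta of shape (C, p).
    """
    C, n, p = X.shape
    beta = np.zeros((C, p))
    eye = _RIDGE * np.eye(p)
    yv = y.astype(float)
    for _ in range(_NEWTON_ITER):
        eta = np.clip(np.einsum("cnp,cp->cn", X, beta), -30.0, 30.0)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-9
        grad = np.einsum("cnp,cn->cp", X, yv[None, :] - mu) - _RIDGE * beta
        hess = np.einsum("cnp,cn,cnq->cpq", X, w, X) + eye
        delta = np.linalg.solve(hess, grad[..., None])[..., 0]
        # damp enormous steps (separable folds)
        norms = np.abs(delta).max(axis=1, keepdims=True)
        scale = np.where(norms > 10.0, 10.0 / norms, 1.0)
        beta = beta + delta * scale
        if np.abs(delta).max() < 1e-8:
            break
    return beta


def _auroc_rows(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUROC for each row of ``scores`` against labels y."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores, axis=1, method="average")
    pos_rank_sum = ranks[:, y == 1].sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def score_candidates(
    X_base: np.ndarray,
    candidates: np.ndarray,
    y: np.ndarray,
    folds,
) -> np.ndarray:
    """Mean inner-validation AUROC of base-model + each candidate.

    ``X_base`` is (n, k) with the current model's features (k may be 0) and
    ``candidates`` is (n, C).  Standardization statistics come from each
    inner-training split only.
    """
    n, C = candidates.shape
    aurocs = np.zeros((len(folds), C))
    for fi, (tr, va) in enumerate(folds):
        full = np.concatenate([X_base, candidates], axis=1)
        mu = full[tr].mean(axis=0)
        sd = full[tr].std(axis=0)
        sd[sd == 0] = 1.0
        z = (full - mu) / sd
        zb, zc = z[:, : X_base.shape[1]], z[:, X_base.shape[1]:]
        k = X_base.shape[1]
        design = np.empty((C, len(tr), k + 2))
        design[:, :, 0] = 1.0
        design[:, :, 1: k + 1] = zb[tr][None, :, :]
        design[:, :, k + 1] = zc[tr].T
        beta = _fit_logistic_batch(design, y[tr])
        val = np.empty((C, len(va), k + 2))
        val[:, :, 0] = 1.0
        val[:, :, 1: k + 1] = zb[va][None, :, :]
        val[:, :, k + 1] = zc[va].T
        scores = np.einsum("cnp,cp->cn", val, beta)
        aurocs[fi] = _auroc_rows(scores, y[va])
    return aurocs.mean(axis=0)


def inner_cv_auroc(
    X_base: np.ndarray,
    candidate: np.ndarray,
    y: np.ndarray,
    folds,
) -> float:
    """Nested-CV AUROC for one candidate added to the current model."""
    return float(score_candidates(X_base, candidate.reshape(-1, 1), y, folds)[0])


# ---------------------------------------------------------------------------
# the forward search


def sas_select(features: FeatureMatrix, config: SASConfig | None = None) -> SelectionTrace:
    """Run stepwise additive selection and return the full trace."""
    config = config or SASConfig()
    y = features.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    names = list(features.X.columns)
    X_all = features.X.to_numpy()
    is_interaction = features.feature_meta.loc[names, "kind"].eq("interaction").to_numpy()
    col_of = {nm: j for j, nm in enumerate(names)}

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    trace = SelectionTrace()
    remaining = list(names)
    current_score = 0.5
    fails = 0
    n_inter = 0
    iteration = 0

    if not remaining:
        trace.termination_reason = "exhausted"
        return trace

    while remaining and len(trace.selected) < config.max_features:
        pool = [f for f in remaining
                if not (n_inter >= config.max_interactions and is_interaction[col_of[f]])]
        if not pool:
            trace.termination_reason = "exhausted"
            return trace
        iteration += 1
        folds = stratified_folds(y, config.inner_folds, rng)
        X_base = X_all[:, [col_of[f] for f in trace.selected]]
        cands = X_all[:, [col_of[f] for f in pool]]
        scores = score_candidates(X_base, cands, y, folds)
        # tie-break: higher score, then lexicographic feature id
        best_idx = min(range(len(pool)), key=lambda j: (-scores[j], pool[j]))
        best, best_score = pool[best_idx], float(scores[best_idx])
        admitted = best_score - current_score >= config.epsilon
        trace.iterations.append(
            SASIteration(iteration, len(pool), best, best_score, admitted)
        )
        if admitted:
            trace.selected.append(best)
            trace.scores.append(best_score)
            remaining.remove(best)
            if is_interaction[col_of[best]]:
                n_inter += 1
            current_score = best_score
            fails = 0
        else:
            fails += 1
            if fails >= config.patience:
                trace.termination_reason = "patience"
                return trace
    trace.termination_reason = ("max_features" if len(trace.selected) >= config.max_features
                                else "exhausted")
    return trace
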