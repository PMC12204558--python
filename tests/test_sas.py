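"""Stepwise additive selection: scoring oracles and search semantics."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from ptbcv import SASConfig, sas_select
from ptbcv.features import FeatureMatrix
from ptbcv.metrics import auroc
from ptbcv.sas import (
    _auroc_rows,
    inner_cv_auroc,
    score_candidates,
    stratified_folds,
)


def _fm(X, y, names=None, interactions=()):
    import pandas as pd

    names = names or [f"f{j}" for j in range(X.shape[1])]
    Xdf = pd.DataFrame(np.asarray(X, float), columns=names,
                       index=[f"P{i:03d}" for i in range(len(y))])
    meta = pd.DataFrame({
        "gene": ["g"] * len(names),
        "kind": ["interaction" if n in interactions else "T1" for n in names],
        "parents": [""] * len(names),
    }, index=pd.Index(names, name="feature"))
    return FeatureMatrix(Xdf, np.asarray(y, int), meta)


class TestFolds:
    def test_stratified_partition(self):
        y = np.array([1] * 12 + [0] * 23)
        folds = stratified_folds(y, 5, np.random.default_rng(0))
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val) == list(range(35))
        for tr, va in folds:
            assert set(tr) | set(va) == set(range(35))
            assert not set(tr) & set(va)
            assert y[va].sum() >= 2 and (1 - y[va]).sum() >= 4

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            stratified_folds(np.array([1, 1, 0, 0, 0, 0, 0]), 5,
                             np.random.default_rng(0))


class TestBatchedScoring:
    def test_auroc_rows_matches_scalar(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(7, 40))
        y = (rng.uniform(size=40) < 0.4).astype(int)
        rows = _auroc_rows(scores, y)
        for i in range(7):
            assert rows[i] == pytest.approx(auroc(scores[i], y))

    def test_candidate_scores_match_sklearn_fit(self):
        """Batched Newton scoring agrees with per-candidate sklearn refits."""
        rng = np.random.default_rng(2)
        n = 60
        y = (rng.uniform(size=n) < 0.5).astype(int)
        base = rng.normal(size=(n, 1)) + 0.8 * y[:, None]
        cands = rng.normal(size=(n, 4))
        cands[:, 0] += 1.2 * y
        folds = stratified_folds(y, 5, np.random.default_rng(3))
        ours = score_candidates(base, cands, y, folds)
        for c in range(4):
            per_fold = []
            for tr, va in folds:
                full = np.column_stack([base, cands[:, c]])
                mu, sd = full[tr].mean(0), full[tr].std(0)
                sd[sd == 0] = 1.0
                z = (full - mu) / sd
                clf = LogisticRegression(C=1e8, solver="lbfgs", max_iter=5000)
                clf.fit(z[tr], y[tr])
                per_fold.append(auroc(clf.decision_function(z[va]), y[va]))
            assert ours[c] == pytest.approx(np.mean(per_fold), abs=0.02)

    def test_single_candidate_helper(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 20 + [0] * 20)
        cand = rng.normal(size=40) + y
        folds = stratified_folds(y, 5, np.random.default_rng(5))
        one = inner_cv_auroc(np.empty((40, 0)), cand, y, folds)
        batch = score_candidates(np.empty((40, 0)), cand.reshape(-1, 1), y, folds)
        assert one == pytest.approx(batch[0])
        assert one > 0.75


class TestSearch:
    def test_perfect_separator_selected_first(self):
        rng = np.random.default_rng(6)
        y = np.array([1] * 15 + [0] * 15)
        X = rng.normal(size=(30, 6))
        X[:, 3] = y * 4 + rng.normal(0, 0.1, 30)
        trace = sas_select(_fm(X, y), SASConfig(seed=0))
        assert trace.selected[0] == "f3"
        assert trace.scores[0] > 0.95

    def test_pure_noise_selects_nothing_and_stops_on_patience(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 12 + [0] * 18)
        X = rng.normal(size=(30, 8))
        trace = sas_select(_fm(X, y), SASConfig(epsilon=0.15, patience=3, seed=1))
        assert trace.selected == []
        assert trace.termination_reason == "patience"
        assert len(trace.iterations) == 3
        assert not any(it.admitted for it in trace.iterations)

    def test_duplicate_feature_adds_nothing(self):
        """A copy of an admitted feature cannot clear the epsilon bar."""
        rng = np.random.default_rng(8)
        y = np.array([1] * 20 + [0] * 20)
        signal = y * 2.0 + rng.normal(0, 0.5, 40)
        X = np.column_stack([signal, signal.copy()])
        trace = sas_select(_fm(X, y, ["a", "b"]), SASConfig(seed=2))
        assert trace.selected == ["a"]

    def test_feature_cap_respected(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 25 + [0] * 25)
        # many independently informative features
        X = rng.normal(size=(50, 10)) + 1.5 * y[:, None] * rng.uniform(0.5, 1, 10)
        trace = sas_select(_fm(X, y), SASConfig(max_features=2, max_interactions=0,
                                                epsilon=1e-3, seed=3))
        assert len(trace.selected) <= 2
        if len(trace.selected) == 2:
            assert trace.termination_reason == "max_features"

    def test_interaction_cap_skips_interaction_candidates(self):
        rng = np.random.default_rng(10)
        y = np.array([1] * 20 + [0] * 20)
        X = np.column_stack([
            y * 3.0 + rng.normal(0, 0.3, 40),   # i0, interaction
            y * 2.5 + rng.normal(0, 0.3, 40),   # i1, interaction
            rng.normal(size=40),
        ])
        cfg = SASConfig(max_interactions=1, epsilon=1e-3, patience=2, seed=4)
        trace = sas_select(_fm(X, y, ["i0", "i1", "b0"],
                               interactions=("i0", "i1")), cfg)
        n_inter = sum(f in ("i0", "i1") for f in trace.selected)
        assert n_inter <= 1
        # once an interaction is in, the other never appears as a candidate
        seen_after = [it.best_candidate for it in trace.iterations
                      if it.iteration > 1]
        if n_inter == 1:
            other = "i1" if trace.selected[0] == "i0" else "i0"
            assert other not in seen_after

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 18 + [0] * 22)
        X = rng.normal(size=(40, 12)) + 0.7 * y[:, None] * rng.uniform(0, 1, 12)
        a = sas_select(_fm(X, y), SASConfig(seed=5))
        b = sas_select(_fm(X, y), SASConfig(seed=5))
        assert a.selected == b.selected
        assert [it.best_score for it in a.iterations] == [
            it.best_score for it in b.iterations]

    def test_scores_strictly_improve_by_epsilon(self):
        rng = np.random.default_rng(12)
        y = np.array([1] * 25 + [0] * 25)
        X = rng.normal(size=(50, 10)) + 0.8 * y[:, None] * rng.uniform(0, 1, 10)
        eps = 0.015
        trace = sas_select(_fm(X, y), SASConfig(epsilon=eps, seed=6))
        path = [0.5] + trace.scores
        assert all(b - a >= eps for a, b in zip(path, path[1:]))

    def test_ranks_reflect_admission_order(self):
        rng = np.random.default_rng(13)
        y = np.array([1] * 20 + [0] * 20)
        X = rng.normal(size=(40, 6)) + 1.0 * y[:, None] * rng.uniform(0.3, 1, 6)
        trace = sas_select(_fm(X, y), SASConfig(epsilon=1e-3, seed=7))
        assert trace.ranks() == [(f, i + 1) for i, f in enumerate(trace.selected)]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SASConfig(epsilon=0.0)
        with pytest.raises(ValueError):
            SASConfig(patience=0)
        with pytest.raises(ValueError):
            SASConfig(max_features=3, max_interactions=4)
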