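"""Extremely-randomized-trees learner, CV-AUC objective and forward selection.

The base learner is an ensemble of extremely randomized trees: every tree
is grown on all training samples (no bootstrap), cut-points are drawn at
random and K random splits are tested per node.  Leaves are probabilistic —
each stores the empirical proportion of disordered residues among the
training samples it receives — and the ensemble prediction is the average
of the T leaf proportions.  Defaults follow the fully-developed-trees
setting: no depth limit, minimum two samples to split, and K equal to the
square root of the current total feature count.

Feature-function subsets are scored by cross-validated AUC with folds drawn
at the protein level (residues of one protein never straddle a fold
boundary, which would leak near-identical windowed features).  The greedy
forward wrapper starts from the empty encoding and at each iteration adds
the candidate whose augmented encoding maximizes that objective; all
candidates within an iteration share the same folds so comparisons are
paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from x3dis.evaluation import roc_auc
from x3dis.feature_functions import FeatureFunctionSpec, compute_feature_block
from x3dis.protein_model import ProteinRecord


class LearnerError(ValueError):
    pass


@dataclass(frozen=True)
class ETParams:
    """Hyper-parameters of the extremely-randomized-trees ensemble.

    ``k_split=None`` means sqrt(total feature count), recomputed whenever
    the encoding changes.
    """

    n_trees: int = 1000
    k_split: int | None = None
    n_min: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise LearnerError("n_trees must be >= 1")
        if self.k_split is not None and self.k_split < 1:
            raise LearnerError("k_split must be >= 1")
        if self.n_min < 2:
            raise LearnerError("n_min must be >= 2")

    def resolve_k(self, d_total: int) -> int:
        if self.k_split is not None:
            return min(self.k_split, d_total)
        return max(1, min(d_total, round(math.sqrt(d_total))))


@dataclass(frozen=True)
class CVConfig:
    """Protein-level cross-validation settings."""

    n_folds: int = 10
    n_repeats: int = 1
    seed: int = 0
    max_redraws: int = 50

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise LearnerError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise LearnerError("n_repeats must be >= 1")


@dataclass
class TrainedModel:
    """A fitted ensemble plus its encoding and decision threshold."""

    ensemble: ExtraTreesClassifier
    encoding: tuple[FeatureFunctionSpec, ...]
    threshold: float = 0.5
    params: ETParams | None = None

    def __post_init__(self) -> None:
        if not self.encoding:
            raise LearnerError("encoding must be non-empty")
        if not 0.0 <= self.threshold <= 1.0:
            raise LearnerError("threshold must lie in [0, 1]")


@dataclass
class SelectionIteration:
    candidate_scores: dict[str, float]
    selected: FeatureFunctionSpec
    cv_auc_mean: float
    cv_auc_sd: float


@dataclass
class SelectionResult:
    iterations: list[SelectionIteration] = field(default_factory=list)

    @property
    def encoding(self) -> tuple[FeatureFunctionSpec, ...]:
        return tuple(it.selected for it in self.iterations)

    @property
    def auc_trace(self) -> list[float]:
        return [it.cv_auc_mean for it in self.iterations]

    def as_dict(self) -> dict:
        return {
            "iterations": [
                {
                    "candidate_scores": it.candidate_scores,
                    "selected": str(it.selected),
                    "cv_auc_mean": it.cv_auc_mean,
                    "cv_auc_sd": it.cv_auc_sd,
                }
                for it in self.iterations
            ],
            "encoding": [str(s) for s in self.encoding],
        }


def _labels_vector(records: Sequence[ProteinRecord]) -> np.ndarray:
    labs = []
    for rec in records:
        if rec.disorder is None:
            raise LearnerError(f"protein {rec.id!r} has no disorder labels")
        labs.append(rec.disorder.as_mask().astype(int))
    return np.concatenate(labs)


def _make_ensemble(params: ETParams, d_total: int) -> ExtraTreesClassifier:
    return ExtraTreesClassifier(
        n_estimators=params.n_trees,
        max_features=params.resolve_k(d_total),
        min_samples_split=params.n_min,
        bootstrap=False,
        random_state=params.seed,
        n_jobs=1,
    )


def train_ensemble(
    features: np.ndarray, labels: np.ndarray, params: ETParams
) -> ExtraTreesClassifier:
    """Fit the extra-trees ensemble on residue feature rows and 0/1 labels."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.shape[0] != y.shape[0]:
        raise LearnerError(
            f"feature rows ({X.shape[0]}) != labels ({y.shape[0]})"
        )
    if np.unique(y).size < 2:
        raise LearnerError("training set contains a single class")
    if not np.isfinite(X).all():
        raise LearnerError("features contain missing or non-finite values")
    ensemble = _make_ensemble(params, X.shape[1])
    ensemble.fit(X, y)
    return ensemble


def predict_disorder_proba(ensemble: ExtraTreesClassifier, features: np.ndarray) -> np.ndarray:
    """Per-residue disorder probability: mean of the per-tree leaf proportions."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != ensemble.n_features_in_:
        raise LearnerError(
            f"feature count {X.shape[1]} does not match model "
            f"({ensemble.n_features_in_})"
        )
    pos = list(ensemble.classes_).index(1)
    return ensemble.predict_proba(X)[:, pos]


def calibrate_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing balanced accuracy on held-out residues.

    Candidate cuts are 0, 1 and the midpoints of consecutive sorted unique
    probabilities; ties favour the smallest cut (higher sensitivity).  A
    residue is called disordered when its probability exceeds the cut.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).ravel()
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise LearnerError("calibration split contains a single class")
    uniq = np.unique(p)
    cuts = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best_theta, best_bal = 0.0, -1.0
    for theta in cuts:
        calls = p > theta
        sens = (calls & (y == 1)).sum() / n_pos
        spec = (~calls & (y == 0)).sum() / n_neg
        bal = (sens + spec) / 2.0
        if bal > best_bal + 1e-12:
            best_bal, best_theta = bal, theta
    return float(best_theta)


class FeatureCache:
    """Per-(protein, spec) feature blocks, computed once per corpus.

    Forward selection re-evaluates the same candidate blocks against many
    encodings and folds; caching them makes each evaluation a column stack
    plus an ensemble fit.
    """

    def __init__(self, records: Sequence[ProteinRecord]):
        self.records = list(records)
        self._blocks: dict[FeatureFunctionSpec, np.ndarray] = {}
        self.row_slices: list[slice] = []
        start = 0
        for rec in self.records:
            self.row_slices.append(slice(start, start + rec.n))
            start += rec.n
        self.n_rows = start

    def block(self, spec: FeatureFunctionSpec) -> np.ndarray:
        if spec not in self._blocks:
            self._blocks[spec] = np.vstack(
                [compute_feature_block(spec, rec) for rec in self.records]
            )
        return self._blocks[spec]

    def matrix(self, encoding: Sequence[FeatureFunctionSpec]) -> np.ndarray:
        return np.hstack([self.block(s) for s in encoding])


def _protein_folds(
    records: Sequence[ProteinRecord],
    labels_per_protein: list[np.ndarray],
    cv: CVConfig,
    rng: np.random.Generator,
) -> list[list[np.ndarray]]:
    """Protein-index folds, re-drawn until each test fold has both classes."""
    n = len(records)
    if n < cv.n_folds:
        raise LearnerError(f"{n} proteins cannot fill {cv.n_folds} folds")
    for _ in range(cv.max_redraws):
        perm = rng.permutation(n)
        folds = [perm[k :: cv.n_folds] for k in range(cv.n_folds)]
        ok = True
        for fold in folds:
            y = np.concatenate([labels_per_protein[j] for j in fold])
            if y.sum() == 0 or y.sum() == y.size:
                ok = False
                break
        if ok:
            return [folds]
    raise LearnerError(
        "could not draw protein folds with both classes in every test fold"
    )


def cross_validated_auc(
    records: Sequence[ProteinRecord],
    encoding: Sequence[FeatureFunctionSpec],
    params: ETParams,
    cv: CVConfig,
    cache: FeatureCache | None = None,
    max_train_residues: int | None = None,
) -> tuple[float, float]:
    """Mean and sd of per-fold test AUC under protein-level cross-validation.

    ``max_train_residues`` optionally subsamples the pooled training
    residues of each fold (seeded), a scaling control for large corpora;
    test folds are always scored in full.
    """
    if cache is None:
        cache = FeatureCache(records)
    labels_pp = [rec.disorder.as_mask().astype(int) for rec in records]
    rng = np.random.default_rng(cv.seed)
    X = cache.matrix(encoding)
    aucs: list[float] = []
    for rep in range(cv.n_repeats):
        (folds,) = _protein_folds(records, labels_pp, cv, rng)
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(records)), test_idx)
            tr_rows = np.concatenate(
                [np.arange(cache.row_slices[j].start, cache.row_slices[j].stop)
                 for j in train_idx]
            )
            te_rows = np.concatenate(
                [np.arange(cache.row_slices[j].start, cache.row_slices[j].stop)
                 for j in test_idx]
            )
            y_tr = np.concatenate([labels_pp[j] for j in train_idx])
            y_te = np.concatenate([labels_pp[j] for j in test_idx])
            if max_train_residues is not None and tr_rows.size > max_train_residues:
                sub_rng = np.random.default_rng((cv.seed, rep, k, 7919))
                sel = sub_rng.choice(tr_rows.size, max_train_residues, replace=False)
                # keep both classes after subsampling
                if y_tr[sel].sum() in (0, sel.size):
                    continue_pos = np.flatnonzero(y_tr == 1)[:5]
                    sel = np.union1d(sel, continue_pos)
                tr_rows, y_tr = tr_rows[sel], y_tr[sel]
            fold_params = ETParams(
                n_trees=params.n_trees,
                k_split=params.k_split,
                n_min=params.n_min,
                seed=int(np.random.default_rng((params.seed, rep, k)).integers(2**31)),
            )
            ensemble = train_ensemble(X[tr_rows], y_tr, fold_params)
            probs = predict_disorder_proba(ensemble, X[te_rows])
            aucs.append(roc_auc(probs, y_te))
    arr = np.asarray(aucs)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def forward_select(
    records: Sequence[ProteinRecord],
    candidates: Sequence[FeatureFunctionSpec],
    params: ETParams,
    cv: CVConfig,
    n_iterations: int,
    cache: FeatureCache | None = None,
    max_train_residues: int | None = None,
) -> SelectionResult:
    """Greedy forward feature-function selection maximizing CV AUC.

    Iteration t scores every remaining candidate c by the cross-validated
    AUC of (current encoding + c) and appends the argmax; ties break toward
    the earliest candidate in the given order.  Fold draws are shared by
    all candidates of one iteration (seeded per iteration from cv.seed) so
    candidate comparisons are paired.
    """
    if not candidates:
        raise LearnerError("no candidates to select from")
    if n_iterations < 1:
        raise LearnerError("n_iterations must be >= 1")
    if n_iterations > len(candidates):
        raise LearnerError("more iterations than candidates")
    if cache is None:
        cache = FeatureCache(records)
    remaining = list(candidates)
    result = SelectionResult()
    current: list[FeatureFunctionSpec] = []
    for t in range(n_iterations):
        iter_cv = CVConfig(
            n_folds=cv.n_folds,
            n_repeats=cv.n_repeats,
            seed=int(np.random.default_rng((cv.seed, t)).integers(2**31)),
            max_redraws=cv.max_redraws,
        )
        scores: dict[str, float] = {}
        best: tuple[float, int] | None = None
        sds: dict[str, float] = {}
        for j, cand in enumerate(remaining):
            mean, sd = cross_validated_auc(
                records, current + [cand], params, iter_cv,
                cache=cache, max_train_residues=max_train_residues,
            )
            scores[str(cand)] = mean
            sds[str(cand)] = sd
            if best is None or mean > best[0] + 1e-12:
                best = (mean, j)
        mean, j = best
        chosen = remaining.pop(j)
        current.append(chosen)
        result.iterations.append(
            SelectionIteration(
                candidate_scores=scores,
                selected=chosen,
                cv_auc_mean=mean,
                cv_auc_sd=sds[str(chosen)],
            )
        )
    return result


def train_classifier(
    records: Sequence[ProteinRecord],
    encoding: Sequence[FeatureFunctionSpec],
    params: ETParams,
    calibration_fraction: float = 0.2,
    seed: int = 0,
) -> TrainedModel:
    """Train with threshold calibration: fit the ensemble on 80% of the
    training proteins and pick the balanced-accuracy-optimal decision
    threshold on the held-out 20%.
    """
    if not 0.0 < calibration_fraction < 1.0:
        raise LearnerError("calibration_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cache = FeatureCache(records)
    labels_pp = [rec.disorder.as_mask().astype(int) for rec in records]
    n = len(records)
    n_cal = max(1, int(round(calibration_fraction * n)))
    for _ in range(50):
        perm = rng.permutation(n)
        cal_idx, fit_idx = perm[:n_cal], perm[n_cal:]
        y_fit = np.concatenate([labels_pp[j] for j in fit_idx])
        y_cal = np.concatenate([labels_pp[j] for j in cal_idx])
        if 0 < y_fit.sum() < y_fit.size and 0 < y_cal.sum() < y_cal.size:
            break
    else:
        raise LearnerError("could not split with both classes on each side")
    X = cache.matrix(encoding)
    rows = lambda idx: np.concatenate(
        [np.arange(cache.row_slices[j].start, cache.row_slices[j].stop) for j in idx]
    )
    ensemble = train_ensemble(X[rows(fit_idx)], y_fit, params)
    probs_cal = predict_disorder_proba(ensemble, X[rows(cal_idx)])
    theta = calibrate_threshold(probs_cal, y_cal)
    return TrainedModel(
        ensemble=ensemble, encoding=tuple(encoding), threshold=theta, params=params
    )


def predict_records(
    model: TrainedModel, records: Sequence[ProteinRecord]
) -> "pd.DataFrame":
    """Per-residue probabilities and O/D calls for a corpus."""
    import pandas as pd

    from x3dis.feature_functions import featurize

    fm = featurize(records, model.encoding)
    probs = predict_disorder_proba(model.ensemble, fm.to_numpy())
    calls = np.where(probs > model.threshold, "D", "O")
    return pd.DataFrame(
        {"probability": probs, "call": calls}, index=fm.index
    ).reset_index()
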