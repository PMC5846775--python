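"""Exhaustive biomarker-panel search with two-class LDA.

Every subset of 2-5 candidate proteases is evaluated as a linear
discriminant classifier of, e.g., IBS versus HC samples: for each of 100
replicates the samples are split into stratified random training and test
sets, the LDA is fit on the training set and scored on the held-out
samples, and the panel's figure of merit is the mean proportion of correct
predictions.  Panels are ranked by that mean; single proteins and panel
discriminant scores both feed a threshold-sweep ROC whose area under the
curve equals the Mann-Whitney pair-counting statistic.

LDA here is the classical pooled-covariance discriminant with equal class
priors (the clinical groups are nearly balanced) and a small ridge term
lambda = 1e-6 * trace(Sigma)/p added for small-sample stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ValidationError


@dataclass
class LdaModel:
    """Two-class linear discriminant: score(x) = x.w + b.

    Positive scores classify to ``classes[1]``; ties (score exactly 0) go
    to the first class in label order.
    """

    classes: tuple
    feature_ids: tuple[str, ...]
    w: np.ndarray
    b: float
    means: np.ndarray  # 2 x p
    pooled_cov: np.ndarray

    def score(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = self._check(X)
        return X @ self.w + self.b

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        s = self.score(X)
        return np.where(s > 0, self.classes[1], self.classes[0])

    def _check(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_ids) - set(X.columns)
            if missing:
                raise ValidationError(f"feature mismatch, missing {sorted(missing)}")
            X = X[list(self.feature_ids)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_ids):
                raise ValidationError("feature mismatch: wrong number of columns")
        return X


@dataclass
class PanelResult:
    """Replicate accuracies of one candidate panel."""

    panel: tuple[str, ...]
    accuracies: np.ndarray
    rank: int | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies.max())


@dataclass
class ROCResult:
    """Threshold-sweep ROC curve and its area."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    description: str = ""


def enumerate_subsets(candidate_ids, k_min: int = 2, k_max: int = 5) -> list[tuple[str, ...]]:
    """All candidate subsets of size k_min..k_max, lexicographic within size."""
    ids = sorted(candidate_ids)
    if not ids:
        raise ValidationError("no candidate proteins")
    if not 1 <= k_min <= k_max <= len(ids):
        raise ValidationError(f"need 1 <= k_min <= k_max <= {len(ids)}")
    out: list[tuple[str, ...]] = []
    for k in range(k_min, k_max + 1):
        out.extend(combinations(ids, k))
    return out


def lda_fit(
    X: np.ndarray | pd.DataFrame,
    labels,
    ridge: float | None = None,
    priors: tuple[float, float] = (0.5, 0.5),
) -> LdaModel:
    """Fit the pooled-covariance two-class discriminant.

    ``ridge=None`` adds the default lambda = 1e-6 * trace(Sigma)/p;
    ``ridge=0`` disables regularization and raises on a singular pooled
    covariance.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = tuple(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        feature_ids = tuple(f"f{j}" for j in range(Xa.shape[1]))
    y = np.asarray(labels)
    classes = tuple(sorted(pd.unique(y).tolist(), key=str))
    if len(classes) != 2:
        raise ValidationError(f"exactly 2 classes required, got {classes}")
    masks = [y == c for c in classes]
    if any(m.sum() < 2 for m in masks):
        raise ValidationError("each class needs >= 2 samples")
    p = Xa.shape[1]
    means = np.vstack([Xa[m].mean(axis=0) for m in masks])
    n0, n1 = masks[0].sum(), masks[1].sum()
    resid = np.vstack([Xa[m] - means[i] for i, m in enumerate(masks)])
    pooled = resid.T @ resid / (n0 + n1 - 2)
    lam = 1e-6 * np.trace(pooled) / p if ridge is None else ridge
    sigma = pooled + lam * np.eye(p)
    try:
        w = np.linalg.solve(sigma, means[1] - means[0])
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular pooled covariance; pass ridge > 0 to regularize"
        ) from exc
    b = -0.5 * (means[0] + means[1]) @ w + np.log(priors[1] / priors[0])
    return LdaModel(
        classes=classes, feature_ids=feature_ids, w=w, b=float(b),
        means=means, pooled_cov=sigma,
    )


def make_splits(
    labels, n_rep: int = 100, train_frac: float = 2.0 / 3.0, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test splits, shared across all panels.

    Evaluating every candidate panel on the same replicate splits (common
    random numbers) makes panel comparisons paired: accuracy differences
    between panels then reflect the panels, not split luck.  The sequence
    is a deterministic function of (labels, n_rep, train_frac, seed).
    """
    y = np.asarray(labels)
    classes = tuple(sorted(pd.unique(y).tolist(), key=str))
    if len(classes) != 2:
        raise ValidationError("two classes required")
    if any(int((y == c).sum()) < 3 for c in classes):
        raise ValidationError("each class needs >= 3 samples to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    return [_stratified_split(rng, y, classes, train_frac) for _ in range(n_rep)]


def _stratified_split(rng, y, classes, train_frac):
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        n_c = len(idx)
        n_train = int(np.clip(round(train_frac * n_c), 2, n_c - 1))
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_split_accuracy(
    features: pd.DataFrame,
    labels,
    panel,
    n_rep: int = 100,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> PanelResult:
    """Mean held-out accuracy of one panel over stratified random splits.

    Splits are stratified so that both classes appear in every training set
    (with at least 2 training and 1 test sample per class).  Pass
    precomputed ``splits`` (see :func:`make_splits`) to evaluate several
    panels on identical replicates; otherwise the sequence is generated
    from ``seed`` alone, so it is the same for every panel.
    """
    panel = tuple(panel)
    missing = set(panel) - set(features.columns)
    if missing:
        raise ValidationError(f"unknown panel members: {sorted(missing)}")
    y = np.asarray(labels)
    if splits is None:
        splits = make_splits(y, n_rep=n_rep, train_frac=train_frac, seed=seed)
    X = features[list(panel)].to_numpy(dtype=float)
    acc = np.empty(len(splits))
    for rep, (tr, te) in enumerate(splits):
        model = lda_fit(X[tr], y[tr])
        pred = model.predict(X[te])
        acc[rep] = float(np.mean(pred == y[te]))
    return PanelResult(panel=panel, accuracies=acc)


def search_panels(
    features: pd.DataFrame,
    labels,
    k_min: int = 2,
    k_max: int = 5,
    n_rep: int = 100,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> list[PanelResult]:
    """Evaluate every k_min..k_max subset of the candidate columns.

    All subsets are scored on the same replicate splits so the leaderboard
    ranks panels, not split luck.
    """
    splits = make_splits(labels, n_rep=n_rep, train_frac=train_frac, seed=seed)
    results = [
        repeated_split_accuracy(features, labels, subset, splits=splits)
        for subset in enumerate_subsets(features.columns, k_min, k_max)
    ]
    return rank_panels(results)


def rank_panels(results: list[PanelResult]) -> list[PanelResult]:
    """Leaderboard: mean accuracy desc, then smaller panel, then ids."""
    if not results:
        raise ValidationError("no panel results to rank")
    ordered = sorted(
        results, key=lambda r: (-r.mean_accuracy, len(r.panel), r.panel)
    )
    for i, r in enumerate(ordered):
        r.rank = i + 1
    return ordered


def roc_auc(scores, labels, description: str = "") -> ROCResult:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    The positive class is label 1 (or True).  The resulting AUC equals the
    Mann-Whitney pair statistic (#{score+ > score-} + 0.5 #ties) / (n+ n-).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = np.sum(pred & y) / n_pos
        fpr[i] = np.sum(pred & ~y) / n_neg
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, one_minus_specificity=fpr,
        auc=auc, description=description,
    )


def panel_score(model: LdaModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Continuous discriminant score per sample (ROC input for panels)."""
    return model.score(features)


def roc_for_panel(
    features: pd.DataFrame, labels, panel, positive_class=None
) -> ROCResult:
    """ROC of the full-data-fit discriminant score of one panel.

    For a single-protein "panel" the score is a monotone transform of the
    protein abundance itself, so the AUC is identical either way.
    """
    panel = tuple(panel)
    model = lda_fit(features[list(panel)], labels)
    scores = model.score(features[list(panel)])
    y = np.asarray(labels)
    pos = model.classes[1] if positive_class is None else positive_class
    return roc_auc(scores if pos == model.classes[1] else -scores, y == pos,
                   description="+".join(panel))
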