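"""Interpretability analyses over the residue-pair feature space.

Quantifies which complementarity features carry the predictive information:

* plug-in mutual information (base-2, equal-frequency binning) between each
  of the 30 features and the true or network-predicted labels;
* ROC AUC separation between value distributions of two groups;
* feature-subset ablation: retraining the classifier on every non-empty
  subset of {shape, electrostatic, hydropathy} rows;
* PCA of the standardised feature matrix with explained-variance ratios
  (EVR = λ_i / Σλ_j), scree-elbow component selection and loadings;
* residue-class-specific decision thresholds maximising the F1-score per
  chemical pair class, compared against the universal cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .features import FEATURE_ROWS
from .network import (
    CIRNet,
    ClassifierConfig,
    PredictionSet,
    UNIVERSAL_THRESHOLD,
    apply_threshold,
    train,
)
from .residues import PAIR_CLASSES

__all__ = [
    "mutual_information",
    "mi_ranking",
    "stratified_auc",
    "ablation_experiment",
    "pca_evr",
    "PCAReport",
    "class_thresholds",
    "ThresholdReport",
    "feature_names",
    "pearson_correlations",
    "FEATURE_SUBSETS",
]

#: All non-empty subsets of the three complementarity kinds.
FEATURE_SUBSETS = (
    ("shape",),
    ("electrostatic",),
    ("hydropathy",),
    ("shape", "electrostatic"),
    ("shape", "hydropathy"),
    ("electrostatic", "hydropathy"),
    ("shape", "electrostatic", "hydropathy"),
)


def feature_names(rows=FEATURE_ROWS, n_neighbors: int = 10) -> list[str]:
    """Flat names for the feature matrix entries, e.g. 'shape_n0'."""
    return [f"{row}_n{j}" for row in rows for j in range(n_neighbors)]


def default_bins(n: int) -> int:
    """Equal-frequency bin count ⌈√(n/5)⌉ capped at 32."""
    return int(min(32, max(2, np.ceil(np.sqrt(n / 5)))))


def _discretize(values: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.digitize(values, edges)


def mutual_information(
    values: np.ndarray,
    target: np.ndarray,
    bins: int | None = None,
) -> float:
    """Plug-in mutual information in bits between a feature and a binary target.

    MI(X, Y) = Σ_x Σ_y p(x, y) log2[ p(x, y) / (p(x) p(y)) ]

    The feature is discretised into equal-frequency bins (default
    ⌈√(n/5)⌉, capped at 32); empty cells are skipped, so the estimate is
    non-negative by construction.  Against a balanced binary target, 1 bit
    means a fully informative feature.  A constant feature returns 0 with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    target = np.asarray(target)
    if len(values) != len(target):
        raise ValueError("feature and target lengths differ")
    if len(values) < 50:
        raise ValueError("need at least 50 samples for the MI estimate")
    if len(np.unique(target)) < 2:
        raise ValueError("target must contain both classes")
    if np.ptp(values) == 0:
        warnings.warn("constant feature: MI = 0")
        return 0.0
    bins = bins or default_bins(len(values))
    x = _discretize(values, bins)
    _, y = np.unique(target, return_inverse=True)
    joint = np.zeros((x.max() + 1, y.max() + 1))
    np.add.at(joint, (x, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mi_ranking(
    features: np.ndarray,
    true_labels: np.ndarray,
    nn_scores: np.ndarray,
    threshold: float = UNIVERSAL_THRESHOLD,
    names: list[str] | None = None,
    bins: int | None = None,
    binary_nn: bool = True,
) -> pd.DataFrame:
    """MI of every feature against the true labels and the network labels.

    ``features`` is (n, 30) in the flat ordering of :func:`feature_names`.
    Network predictions are binarised at the universal cut-off (set
    ``binary_nn=False`` to rank against the continuous scores instead,
    discretised like any feature).  Returns a tidy frame sorted by
    ``mi_true`` with rank columns for both targets.
    """
    features = np.asarray(features, dtype=float)
    names = names or feature_names()
    if features.shape[1] != len(names):
        raise ValueError("feature count does not match names")
    nn_target = (np.asarray(nn_scores) > threshold).astype(int) if binary_nn else None
    rows = []
    for j, name in enumerate(names):
        kind, neigh = name.rsplit("_n", 1)
        mi_t = mutual_information(features[:, j], true_labels, bins)
        if binary_nn:
            mi_n = mutual_information(features[:, j], nn_target, bins)
        else:
            b = bins or default_bins(len(features))
            mi_n = mutual_information(features[:, j], _discretize(np.asarray(nn_scores), b), bins)
        rows.append({"feature": name, "kind": kind, "neighbor": int(neigh),
                     "mi_true": mi_t, "mi_nn": mi_n})
    df = pd.DataFrame(rows)
    df["rank_true"] = df["mi_true"].rank(ascending=False, method="first").astype(int)
    df["rank_nn"] = df["mi_nn"].rank(ascending=False, method="first").astype(int)
    return df.sort_values("rank_true").reset_index(drop=True)


def stratified_auc(
    values: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    smaller_is_positive: bool = True,
) -> float:
    """ROC AUC of a value separating group A (positive) from group B.

    By default smaller values score as positive — the complementarity
    convention, where a smaller descriptor distance means a more
    complementary (interacting-like) pair.
    """
    values = np.asarray(values, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise ValueError("both groups must be non-empty")
    sel = group_a | group_b
    y = group_a[sel].astype(int)
    score = -values[sel] if smaller_is_positive else values[sel]
    return float(roc_auc_score(y, score))


def _accuracy_threshold(scores, labels, grid_step: float = 0.01):
    """Threshold maximising accuracy on (scores, labels); ties -> lower."""
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    accs = [(np.mean((scores > t).astype(int) == labels), -t) for t in thresholds]
    best = max(accs)
    return -best[1]


def ablation_experiment(
    x: np.ndarray,
    y: np.ndarray,
    repetitions: int = 100,
    subsets=FEATURE_SUBSETS,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/test the classifier on every feature-row subset, repeatedly.

    Each repetition draws a fresh 70/15/15 train/validation/test split,
    trains on the selected rows only, picks the decision threshold that
    maximises validation accuracy (the universal-cut-off analogue for that
    run), and records the test accuracy.  Returns one row per
    (subset, repetition).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    base = config or ClassifierConfig()
    row_index = {name: i for i, name in enumerate(FEATURE_ROWS)}
    records = []
    for rep in range(repetitions):
        rng = np.random.default_rng(seed + 1000 * rep)
        order = rng.permutation(len(x))
        n_tr = int(0.70 * len(x))
        n_va = int(0.15 * len(x))
        tr, va, te = (
            order[:n_tr],
            order[n_tr : n_tr + n_va],
            order[n_tr + n_va :],
        )
        for subset in subsets:
            rows = [row_index[s] for s in subset]
            xs = x[:, rows, :]
            cfg = ClassifierConfig(**{**base.__dict__, "seed": base.seed + rep})
            model = CIRNet(cfg, input_shape=xs.shape[1:])
            train(model, xs[tr], y[tr], xs[va], y[va])
            s_va, _ = model.forward(xs[va])
            thr = _accuracy_threshold(s_va, y[va])
            s_te, _ = model.forward(xs[te])
            acc = float(np.mean((s_te > thr).astype(int) == y[te]))
            records.append(
                {"subset": "+".join(subset), "repetition": rep,
                 "threshold": thr, "accuracy": acc}
            )
    return pd.DataFrame(records)


@dataclass
class PCAReport:
    """Eigenvalues, explained-variance ratios and loadings of the feature PCA."""

    eigenvalues: np.ndarray
    evr: np.ndarray
    cumulative_evr: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    n_selected: int
    feature_names: list[str] = field(default_factory=list)


def pca_evr(features: np.ndarray, names: list[str] | None = None, max_components: int = 10) -> PCAReport:
    """PCA of the standardised feature matrix with scree-elbow selection.

    Features are standardised to zero mean and unit variance (so the
    decomposition reflects the correlation structure); EVR_i = λ_i / Σ_j λ_j.
    The selected component count is the position of the largest consecutive
    eigenvalue drop (capped at ``max_components``).  Zero-variance features
    are dropped with a warning.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more samples than features for a stable PCA")
    names = list(names or feature_names())
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
        x = x[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    pca = PCA()
    pca.fit(z)
    lam = pca.explained_variance_
    evr = lam / lam.sum()
    drops = lam[:-1] - lam[1:]
    d = int(np.argmax(drops)) + 1 if len(drops) else 1
    return PCAReport(
        eigenvalues=lam,
        evr=evr,
        cumulative_evr=np.cumsum(evr),
        loadings=pca.components_.T,
        n_selected=min(d, max_components),
        feature_names=names,
    )


def _f1(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores > threshold
    tp = np.sum(pred & (labels == 1))
    fp = np.sum(pred & (labels == 0))
    fn = np.sum(~pred & (labels == 1))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def f1_maximizing_threshold(
    scores: np.ndarray, labels: np.ndarray, grid_step: float = 0.01
) -> tuple[float, float]:
    """Grid search for the F1-maximising threshold; ties go to the lower
    threshold (favouring sensitivity).  Returns (threshold, F1)."""
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    best_t, best_f1 = 0.0, -1.0
    for t in thresholds:
        f1 = _f1(scores, labels, t)
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


@dataclass
class ThresholdReport:
    """Per-pair-class decision thresholds and the two global confusion matrices."""

    per_class: pd.DataFrame
    thresholds: dict
    confusion_universal: dict
    confusion_class_specific: dict
    universal_threshold: float = UNIVERSAL_THRESHOLD


def class_thresholds(
    predictions: PredictionSet,
    universal: float = UNIVERSAL_THRESHOLD,
    grid_step: float = 0.01,
) -> ThresholdReport:
    """Residue-class-specific decision thresholds.

    For each chemical pair class with both labels present, finds the
    F1-maximising threshold by grid search (step 0.01), and reports the
    class ROC AUC plus the F1 under the universal and the class-specific
    cut-off.  Classes with a single label fall back to the universal
    threshold.  Also returns the global confusion matrices (fraction
    convention) under both threshold schemes.
    """
    scores, labels, classes = predictions.scores, predictions.labels, predictions.classes
    rows = []
    thresholds: dict = {}
    for cls in PAIR_CLASSES:
        sel = classes == cls
        if not sel.any():
            continue
        s, l = scores[sel], labels[sel]
        if len(np.unique(l)) < 2:
            thresholds[cls] = universal
            rows.append({"pair_class": cls, "n": int(sel.sum()), "auc": np.nan,
                         "threshold": universal,
                         "f1_universal": _f1(s, l, universal),
                         "f1_class": _f1(s, l, universal)})
            continue
        t, f1c = f1_maximizing_threshold(s, l, grid_step)
        thresholds[cls] = t
        rows.append({
            "pair_class": cls,
            "n": int(sel.sum()),
            "auc": float(roc_auc_score(l, s)),
            "threshold": t,
            "f1_universal": _f1(s, l, universal),
            "f1_class": f1c,
        })
    return ThresholdReport(
        per_class=pd.DataFrame(rows),
        thresholds=thresholds,
        confusion_universal=apply_threshold(predictions, universal),
        confusion_class_specific=apply_threshold(predictions, thresholds),
        universal_threshold=universal,
    )


def pearson_correlations(direct_features: np.ndarray) -> pd.DataFrame:
    """Pairwise Pearson r (with two-sided p-values) between the three direct
    complementarities (neighbor-0 shape, electrostatic, hydropathy)."""
    x = np.asarray(direct_features, dtype=float)
    if x.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of direct complementarities")
    rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            r, p = stats.pearsonr(x[:, i], x[:, j])
            rows.append({"feature_a": FEATURE_ROWS[i], "feature_b": FEATURE_ROWS[j],
                         "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
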