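"""CHIR-dose labeling, classification, Deviation Scores and validation.

A batch's optimal concentration range [c1, c2] at a given CHIR duration is
the span of concentrations whose mean fraction of reporter-positive cells
reaches 20%. Each concentration c is classed low / optimal / high relative
to that range, with a signed distance::

    dCHIR(c) = c - c1  (c < c1);  0  (c1 <= c <= c2);  c - c2  (c > c2)

A linear logistic model predicts the class of each well from its 21-D
stream features (or a 4-D ANOVA-selected subset); per-concentration
predictions are pooled into a Deviation Score
(N_high - N_low) / N_c in [-1, 1], whose sign and size track dCHIR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

CLASSES = ("low", "optimal", "high")
DEFAULT_EFFICIENCY_THRESHOLD = 0.20

#: Regularization presets. The penalty strength lambda maps to sklearn's
#: C = 1 / lambda. liblinear handles the l1/l2 presets; the elastic-net
#: cross-batch preset requires saga.
REG_PRESETS: dict[str, dict] = {
    # l1_ratio 1 = pure l1, 0 = pure l2, in between = elastic net
    "21feat-24h": {"l1_ratio": 1.0, "C": 4.0, "solver": "liblinear"},
    "21feat-36h": {"l1_ratio": 1.0, "C": 8.0, "solver": "liblinear"},
    "21feat-48h": {"l1_ratio": 1.0, "C": 8.0, "solver": "liblinear"},
    "4feat": {"l1_ratio": 0.0, "C": 10.0, "solver": "liblinear"},
    "cross-batch": {"l1_ratio": 0.1, "C": 20.0, "solver": "saga"},
}


@dataclass(frozen=True)
class DoseLabeling:
    """Optimal range and per-concentration classes for one batch/duration."""

    c1: float
    c2: float
    duration: float
    classes: dict[float, str]
    delta_chir: dict[float, float]

    def class_of(self, c: float) -> str:
        if c < self.c1:
            return "low"
        if c > self.c2:
            return "high"
        return "optimal"


def delta_chir(c: float, c1: float, c2: float) -> float:
    """Signed distance of a concentration from the optimal range [c1, c2]."""
    if c < c1:
        return c - c1
    if c > c2:
        return c - c2
    return 0.0


def label_doses(
    records: pd.DataFrame,
    duration: float,
    efficiency_threshold: float = DEFAULT_EFFICIENCY_THRESHOLD,
    efficiency_column: str = "positive_fraction",
) -> DoseLabeling:
    """Identify the optimal concentration range and label every concentration.

    Concentrations whose mean reporter-positive fraction is >= the threshold
    (20% by default) form the optimal range [c1, c2] (min/max qualifying
    concentration; a non-contiguous qualifying set triggers a warning).
    """
    sub = records[records["chir_h"] == duration]
    if not len(sub):
        raise ValueError(f"no records at duration {duration}")
    col = efficiency_column if efficiency_column in sub.columns else "efficiency_index"
    means = sub.groupby("chir_um")[col].mean()
    qualifying = means[means >= efficiency_threshold].index.to_numpy(dtype=float)
    if len(qualifying) == 0:
        raise ValueError(
            f"no optimal range: no concentration reaches a mean {col} of "
            f"{efficiency_threshold} at duration {duration}"
        )
    c1, c2 = float(qualifying.min()), float(qualifying.max())
    inside = {float(c) for c in means.index if c1 <= c <= c2}
    if inside - {float(c) for c in qualifying}:
        logger.warning("qualifying concentrations are non-contiguous; using [min, max]")
    concentrations = sorted(float(c) for c in means.index)
    classes = {}
    deltas = {}
    for c in concentrations:
        d = delta_chir(c, c1, c2)
        deltas[c] = d
        classes[c] = "low" if d < 0 else ("high" if d > 0 else "optimal")
    return DoseLabeling(c1=c1, c2=c2, duration=duration, classes=classes, delta_chir=deltas)


# ---------------------------------------------------------------------------
# classifier


def train_dose_classifier(
    X: np.ndarray,
    y: np.ndarray,
    preset: str = "21feat-24h",
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> LogisticRegression:
    """Linear logistic dose classifier with inverse-frequency class weights.

    ``preset`` names the regularization configuration (kind and strength);
    class imbalance is handled by reweighting so each class contributes
    equally to the loss.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    cfg = REG_PRESETS[preset]
    model = LogisticRegression(
        class_weight="balanced",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        **cfg,
    )
    if len(np.unique(y)) > 2:
        # one-vs-rest multiclass scheme, consistent with macro-averaged AUC
        from sklearn.multiclass import OneVsRestClassifier

        model = OneVsRestClassifier(model)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def select_features_anova(X: np.ndarray, y: np.ndarray, k: int = 4) -> np.ndarray:
    """Indices of the k features with the largest one-way ANOVA F statistics.

    Ties are broken toward the lower feature index. Used to find the few
    stream features that generalize across batches (post-phase optical flow
    and cell brightness, mid-phase brightness, post-phase circumference in
    the cardiac application).
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the number of features {X.shape[1]}")
    F, _ = f_classif(X, np.asarray(y))
    F = np.nan_to_num(F, nan=-np.inf)
    order = np.argsort(-F, kind="stable")  # stable sort => lower index wins ties
    return np.sort(order[:k])


@dataclass(frozen=True)
class DeviationResult:
    """Per-concentration prediction counts and Deviation Scores."""

    concentrations: tuple[float, ...]
    counts: dict[float, dict[str, int]]
    scores: dict[float, float] = field(default_factory=dict)


def deviation_scores(predictions: np.ndarray, concentrations: np.ndarray) -> DeviationResult:
    """Deviation Score per concentration: (N_high - N_low) / N_c in [-1, 1].

    N_c counts the wells at concentration c; concentrations with no wells are
    omitted. A score of +1 means every well was predicted overdosed, -1
    underdosed, 0 balanced or optimal.
    """
    predictions = np.asarray(predictions)
    concentrations = np.asarray(concentrations, dtype=float)
    if predictions.shape[0] != concentrations.shape[0]:
        raise ValueError("every well needs a prediction and a concentration")
    counts: dict[float, dict[str, int]] = {}
    scores: dict[float, float] = {}
    for c in np.unique(concentrations):
        sel = predictions[concentrations == c]
        n_c = len(sel)
        tally = {cls: int((sel == cls).sum()) for cls in CLASSES}
        counts[float(c)] = {"N": n_c, **tally}
        scores[float(c)] = (tally["high"] - tally["low"]) / n_c
    return DeviationResult(
        concentrations=tuple(sorted(scores)), counts=counts, scores=scores
    )


def evaluate_classifier(model, X: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Accuracy plus macro-averaged precision, recall, F1 and one-vs-rest AUC.

    Macro averaging is the unweighted mean over the classes present in
    ``y``; classes absent from ``y`` are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pred = model.predict(X)
    proba = model.predict_proba(X)
    present = [c for c in model.classes_ if (y == c).any()]
    missing = set(model.classes_) - set(present)
    if missing:
        logger.warning("classes absent from y skipped in macro averages: %s", sorted(missing))
    precisions, recalls, f1s, aucs = [], [], [], []
    for cls in present:
        tp = float(((pred == cls) & (y == cls)).sum())
        fp = float(((pred == cls) & (y != cls)).sum())
        fn = float(((pred != cls) & (y == cls)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        col = list(model.classes_).index(cls)
        if len(np.unique(y == cls)) == 2:
            aucs.append(roc_auc_score((y == cls).astype(int), proba[:, col]))
    return {
        "accuracy": float((pred == y).mean()),
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "f1": float(np.mean(f1s)),
        "auc": float(np.mean(aucs)) if aucs else float("nan"),
    }


# ---------------------------------------------------------------------------
# cross-batch validation and duration choice


def cross_batch_validate(
    tables: dict[str, pd.DataFrame],
    feature_columns: list[str],
    label_column: str = "dose_class",
    preset: str = "cross-batch",
    n_selected: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-batch-out validation of the Deviation Score.

    In each round one batch is held out; ANOVA feature selection and the
    elastic-net logistic model are refit on the remaining batches, and the
    held-out wells' predictions are pooled into per-concentration Deviation
    Scores. Returns the (batch, concentration, score, true dCHIR) table and
    the pooled Pearson r between score and dCHIR.
    """
    if len(tables) < 2:
        raise ValueError("cross-batch validation needs at least two batches")
    rows = []
    for test_batch, test_table in tables.items():
        train = pd.concat([t for b, t in tables.items() if b != test_batch], ignore_index=True)
        Xtr = train[feature_columns].to_numpy(dtype=float)
        ytr = train[label_column].to_numpy()
        sel = select_features_anova(Xtr, ytr, k=min(n_selected, len(feature_columns)))
        model = train_dose_classifier(Xtr[:, sel], ytr, preset=preset, seed=seed)
        Xte = test_table[feature_columns].to_numpy(dtype=float)[:, sel]
        pred = model.predict(Xte)
        result = deviation_scores(pred, test_table["chir_um"].to_numpy(dtype=float))
        truth = test_table.groupby("chir_um")["delta_chir"].first()
        for c in result.concentrations:
            rows.append(
                {
                    "batch": test_batch,
                    "chir_um": c,
                    "deviation_score": result.scores[c],
                    "delta_chir": float(truth.loc[c]),
                }
            )
    out = pd.DataFrame(rows)
    r = float(pearsonr(out["deviation_score"], out["delta_chir"])[0])
    return out, r


def choose_duration(scores_per_duration: dict[float, float]) -> float:
    """Duration whose Deviation Score is closest to 0 (ties -> shorter)."""
    if not scores_per_duration:
        raise ValueError("need at least one duration with a score")
    return min(sorted(scores_per_duration), key=lambda d: (abs(scores_per_duration[d]), d))
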