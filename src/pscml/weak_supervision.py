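"""Weakly supervised fate-region localization and compound ranking.

Whole-well images are tiled into patches; patches are labeled positive when
the annotated fate-committed ("dark gray") area reaches a threshold fraction
(30% in the cardiac-progenitor application; 20% against a binarized SOX17
mask in the endoderm application), negative when the annotation is all
black, and discarded otherwise. A small CNN (the desk backbone; any model
exposing class probabilities, last-convolutional-layer activations and
their gradients satisfies the contract) classifies patches, and
gradient-weighted class-activation mapping converts positive predictions
into localization heatmaps::

    alpha_k = (1/Z) sum_ij  d y+ / d A^k_ij,     heatmap = ReLU(sum_k alpha_k A^k)

where A^k are the activations of the convolutional layer before global
average pooling and y+ the pre-softmax positive score. Heatmaps are
normalized to 0-255 per patch, binarized at 10, and reconstructed into
whole-well predictions (means for heatmaps, logical OR for binaries). The
predicted positive-region fraction per well ranks compounds in screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.morphology import closing, disk
from skimage.transform import resize

from pscml import nn
from pscml.well_io import (
    MASK_BLACK,
    MASK_DARK_GRAY,
    MASK_LIGHT_GRAY,
    RegionMask,
    WellImage,
    crop_patches,
    reconstruct,
)

logger = logging.getLogger(__name__)

CAM_BINARY_THRESHOLD = 10  # on the 0-255 normalized heatmap scale
DEFAULT_POSITIVE_FRAC = 0.30
DE_POSITIVE_FRAC = 0.20


@dataclass
class PatchDataset:
    """Labeled image patches for weakly supervised training."""

    patches: list[np.ndarray]
    labels: np.ndarray  # 1 = positive, 0 = negative
    sources: list[str]
    origins: list[tuple[int, int]]
    positive_frac: float
    positive_code: int

    def __len__(self) -> int:
        return len(self.patches)


def build_patch_dataset(
    images: list[WellImage],
    masks: list[RegionMask | np.ndarray],
    patch: int,
    overlap: float,
    positive_frac: float = DEFAULT_POSITIVE_FRAC,
    positive_code: int = MASK_DARK_GRAY,
) -> PatchDataset:
    """Tile wells and label patches from their annotation masks.

    Positive: the fraction of ``positive_code`` pixels is >= ``positive_frac``.
    Negative: the patch's annotation contains only black. Anything else is
    discarded (ambiguous commitment). For binarized-fluorescence masks pass
    ``positive_code=255`` and ``positive_frac=0.20``.
    """
    out_patches, labels, sources, origins = [], [], [], []
    for img, mask in zip(images, masks):
        lab = mask.labels if isinstance(mask, RegionMask) else np.asarray(mask)
        if lab.shape != img.shape:
            raise ValueError("image and mask shapes differ")
        img_tiles = crop_patches(img, patch, overlap)
        for (tile, origin) in img_tiles:
            mtile = lab[origin[0] : origin[0] + patch, origin[1] : origin[1] + patch]
            frac_pos = float((mtile == positive_code).mean())
            if frac_pos >= positive_frac:
                label = 1
            elif (mtile == MASK_BLACK).all():
                label = 0
            else:
                continue
            out_patches.append(tile)
            labels.append(label)
            sources.append(img.well_id)
            origins.append(origin)
    return PatchDataset(
        patches=out_patches,
        labels=np.asarray(labels, dtype=np.int64),
        sources=sources,
        origins=origins,
        positive_frac=positive_frac,
        positive_code=positive_code,
    )


def mask_from_fluorescence(
    fluor: WellImage | np.ndarray, threshold: float = 0.5, closing_radius: int = 5
) -> np.ndarray:
    """Binary nuclear-reporter mask: threshold then morphological closing.

    Nuclear-localized reporters (SOX17) label scattered nuclei; closing with
    a disc bridges sub-``2*radius`` gaps into contiguous cell regions.
    """
    px = fluor.pixels if isinstance(fluor, WellImage) else np.asarray(fluor, dtype=float)
    return closing(px > threshold, disk(closing_radius)).astype(bool)


# ---------------------------------------------------------------------------
# desk CNN backbone


class PatchCNN:
    """Small convolutional patch classifier exposing the Grad-CAM contract.

    Three conv blocks, global average pooling, and a linear head. The
    activations of the last convolutional ReLU (before pooling) and the
    gradient of any logit with respect to them are available to callers.
    Input patches are float images in [0, 1]; class order is
    (negative, positive).
    """

    def __init__(self, channels: tuple[int, int, int] = (8, 16, 16), seed: int = 0):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.features = nn.Sequential(
            nn.Conv2d(1, c1, 3, rng=rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(c1, c2, 3, rng=rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(c2, c3, 3, rng=rng), nn.ReLU(),
        )
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(c3, 2, rng=rng)
        self.n_channels = c3

    # --- training plumbing -------------------------------------------------
    @property
    def params(self):
        return self.features.params + self.head.params

    @property
    def grads(self):
        return self.features.grads + self.head.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of (n, H, W) or (n, 1, H, W) patches."""
        if x.ndim == 3:
            x = x[:, None]
        self._A = self.features(x - 0.5)
        return self.head(self.gap(self._A))

    def backward(self, dlogits: np.ndarray, through_features: bool = True) -> np.ndarray:
        """Backpropagate a logit gradient; returns dLoss/dA (the last conv
        activations) and, when ``through_features``, continues into the
        convolutional stack to accumulate parameter gradients."""
        dA = self.gap.backward(self.head.backward(dlogits))
        if through_features:
            self.features.backward(dA)
        return dA

    # --- inference contract ------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x))

    def activations_and_gradient(self, patch: np.ndarray, class_index: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """(A, dY/dA) for one patch: last-conv activations and the gradient
        of the pre-softmax score of ``class_index`` with respect to them."""
        logits = self.forward(patch[None])
        dlogits = np.zeros_like(logits)
        dlogits[0, class_index] = 1.0
        dA = self.backward(dlogits, through_features=False)
        return self._A[0], dA[0]


@dataclass
class TrainConfig:
    """Patch-classifier training configuration.

    The desk preset trains the small CNN in minutes on a CPU; the paper
    preset records the full-scale settings (ResNeSt-101, 300 epochs,
    batch 6, lr 3e-5) for fidelity runs with a GPU backbone.
    """

    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def paper(cls) -> "TrainConfig":
        return cls(epochs=300, batch_size=6, lr=3e-5)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: float = float("nan")


def train_patch_classifier(
    dataset: PatchDataset,
    backbone: PatchCNN | None = None,
    config: TrainConfig | None = None,
) -> tuple[PatchCNN, TrainHistory]:
    """Train a binary patch classifier with an 80/20 train/validation split.

    Classes are reweighted by inverse frequency. The backbone defaults to
    the desk CNN; any object with the same forward/backward surface works.
    """
    config = config or TrainConfig()
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both positive and negative patches")
    model = backbone or PatchCNN(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    X = np.stack(dataset.patches).astype(np.float64)
    y = labels
    idx = rng.permutation(len(X))
    n_val = max(1, int(round(config.val_fraction * len(X))))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    counts = np.bincount(y[train_idx], minlength=2).astype(float)
    weights = counts.sum() / (2.0 * np.maximum(counts, 1.0))

    opt = nn.Adam(model.params, model.grads, lr=config.lr)
    history = TrainHistory()
    for _ in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            logits = model.forward(X[batch])
            loss, dlogits = nn.cross_entropy_grad(logits, y[batch], weights=weights)
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / max(1, n_batches))
    val_pred = np.concatenate(
        [
            model.predict_proba(X[val_idx[s : s + 64]]).argmax(axis=1)
            for s in range(0, len(val_idx), 64)
        ]
    )
    history.val_accuracy = float((val_pred == y[val_idx]).mean())
    return model, history


# ---------------------------------------------------------------------------
# Grad-CAM


@dataclass
class CamResult:
    heatmap: np.ndarray  # patch-shaped, >= 0
    normalized8: np.ndarray  # 0-255 scale
    binary: np.ndarray  # normalized8 > threshold
    score: float  # pre-softmax positive-class score


def gradcam(model: PatchCNN, patch: np.ndarray, threshold: int = CAM_BINARY_THRESHOLD) -> CamResult:
    """Gradient-weighted class-activation map of one patch.

    Channel weights are the spatial means of the positive-logit gradient;
    the weighted activation sum is rectified, upsampled to patch size,
    normalized to 0-255 (an all-zero map stays zero) and binarized at
    ``threshold``. Patches predicted negative get an all-zero map.
    """
    patch = np.asarray(patch, dtype=np.float64)
    proba = model.predict_proba(patch[None])[0]
    if proba[1] <= proba[0]:
        zero = np.zeros(patch.shape)
        return CamResult(heatmap=zero, normalized8=zero.copy(), binary=zero > 0, score=float("-inf"))
    A, dA = model.activations_and_gradient(patch, class_index=1)
    alpha = dA.mean(axis=(1, 2))  # (1/Z) sum_ij dY+/dA_kij
    cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    cam = resize(cam, patch.shape, order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    normalized8 = 255.0 * cam / peak if peak > 0 else cam.copy()
    logits = model.forward(patch[None])[0]
    return CamResult(
        heatmap=cam,
        normalized8=normalized8,
        binary=normalized8 > threshold,
        score=float(logits[1]),
    )


def predict_regions(
    model: PatchCNN,
    whole: WellImage,
    patch: int,
    overlap: float,
    threshold: int = CAM_BINARY_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Whole-well heatmap, binary fate-region mask and positive fraction.

    Per-patch class-activation maps are normalized and binarized at patch
    level (as in the per-patch protocol), then reconstructed: heatmaps by
    mean over overlaps, binaries by logical OR.
    """
    tiles = crop_patches(whole, patch, overlap)
    heatmaps, binaries, origins = [], [], []
    for tile, origin in tiles:
        cam = gradcam(model, tile, threshold=threshold)
        heatmaps.append(cam.normalized8)
        binaries.append(cam.binary)
        origins.append(origin)
    heat = reconstruct(heatmaps, origins, whole.shape, aggregator="mean")
    binary = reconstruct(binaries, origins, whole.shape, aggregator="any_positive")
    return heat, binary, float(binary.mean())


# ---------------------------------------------------------------------------
# evaluation


def segmentation_metrics(
    pred: np.ndarray, gt: RegionMask | np.ndarray, mode: str = "cpc"
) -> dict[str, float]:
    """Pixel-level segmentation metrics against an annotation mask.

    In ``cpc`` mode the ground-truth positives are the dark-gray and
    light-gray annotation codes; in ``binary`` mode any nonzero pixel.
    Returns accuracy, precision, recall, F1, specificity and IoU by the
    standard confusion-matrix formulas, plus a ``discarded`` flag set for
    degenerate images (ground truth all positive or all negative).
    """
    pred = np.asarray(pred, dtype=bool)
    if isinstance(gt, RegionMask):
        lab = gt.labels
    else:
        lab = np.asarray(gt)
    if lab.shape != pred.shape:
        raise ValueError("prediction and ground-truth shapes differ")
    if mode == "cpc":
        positives = np.isin(lab, (MASK_DARK_GRAY, MASK_LIGHT_GRAY))
    elif mode == "binary":
        positives = lab.astype(bool)
    else:
        raise ValueError(f"unknown mode: {mode}")
    tp = float((pred & positives).sum())
    tn = float((~pred & ~positives).sum())
    fp = float((pred & ~positives).sum())
    fn = float((~pred & positives).sum())
    discarded = positives.all() or not positives.any()
    return {
        "accuracy": (tn + tp) / (tn + fn + tp + fp),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "f1": tp / (tp + (fn + fp) / 2.0) if tp + fn + fp else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "iou": tp / (tp + fp + fn) if tp + fp + fn else 0.0,
        "discarded": bool(discarded),
    }


def rank_wells(
    fractions: pd.DataFrame,
    top_k: int = 40,
    candidate_threshold: float = 0.40,
    control_column: str = "control",
) -> pd.DataFrame:
    """Rank screened wells by predicted fate-region fraction.

    Compound wells are sorted descending (ties broken by well id); the top-k
    are flagged as initial candidates and wells at or above the fraction
    threshold as threshold candidates. Control wells (nonempty
    ``control_column``) are carried through unranked.
    """
    df = fractions.copy()
    if not ((df["fraction"] >= 0) & (df["fraction"] <= 1)).all():
        raise ValueError("fractions must lie in [0, 1]")
    if control_column not in df.columns:
        df[control_column] = ""
    is_control = df[control_column].astype(str).str.len() > 0
    ranked = df[~is_control].sort_values(
        ["fraction", "well_id"], ascending=[False, True], kind="stable"
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked["top_k"] = ranked["rank"] <= top_k
    ranked["above_threshold"] = ranked["fraction"] >= candidate_threshold
    controls = df[is_control].copy()
    controls["rank"] = np.nan
    controls["top_k"] = False
    controls["above_threshold"] = controls["fraction"] >= candidate_threshold
    return pd.concat([ranked, controls], ignore_index=True)
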