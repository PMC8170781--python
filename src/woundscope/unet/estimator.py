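"""The trainable segmenters: iCD (cell/border/background) and iDSD
(monolayer/gap) as one sklearn-style estimator, plus the iCD
postprocessing that turns a 3-class map into individual cell detections.

Postprocessing follows the published recipe: median-filter the label map,
set the border class to background, binarise the cell class, take
8-connected components and drop components below the minimal plausible
cell area — which also removes small artifacts automatically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator

from ..cellscale import CellDetection
from ..core import remove_small_components
from ..segment_adaptive import mask_to_detections
from .augment import augment
from .loss import TverskyConfig, one_hot, tversky_loss
from .network import TrainConfig, UNet, UNetConfig

__all__ = ["UNetSegmenter", "postprocess_icd", "normalize_image", "train", "predict", "predict_idsd"]


def normalize_image(frame: np.ndarray) -> np.ndarray:
    """Per-image min-max normalisation to [0, 1]."""
    frame = np.asarray(frame, dtype=np.float32)
    lo, hi = float(frame.min()), float(frame.max())
    if hi - lo < 1e-12:
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


def postprocess_icd(
    labels3: np.ndarray,
    min_cell_area_px2: int = 50,
    median_kernel: int = 3,
    frame_idx: int = 0,
) -> tuple[list[CellDetection], np.ndarray]:
    """3-class map -> (cell detections, binary cell mask).

    Median filter -> border class to background -> cell class to 1 ->
    8-connected components -> small components removed.
    """
    labels3 = np.asarray(labels3)
    if median_kernel and median_kernel > 1:
        labels3 = ndi.median_filter(labels3, size=median_kernel)
    binary = labels3 == 1  # borders (2) and background (0) both -> 0
    binary = remove_small_components(binary, min_cell_area_px2)
    return mask_to_detections(binary, frame_idx), binary


class UNetSegmenter(BaseEstimator):
    """U-net semantic segmentation with Tversky loss, sklearn-style.

    With ``n_classes=3`` this is the cell/border/background segmenter from
    which individual cells are extracted (:meth:`detect`); with
    ``n_classes=2`` it segments monolayer vs gap directly.

    Fitted attributes: ``net_`` (the network), ``weights_`` (flat list of
    arrays) and ``loss_history_`` (per-epoch mean Tversky loss).
    """

    def __init__(
        self,
        n_classes: int = 3,
        n_stages: int = 3,
        base_features: int = 32,
        dropout_rate: float = 0.5,
        alpha: float = 0.3,
        beta: float = 0.7,
        smooth: float = 1e-6,
        lr: float = 0.001,
        lr_decay_per_epoch: float = 0.9,
        batch_size: int = 30,
        epochs: int = 10,
        augmentations_per_image: int = 0,
        shuffle_each_epoch: bool = True,
        seed: int = 0,
    ):
        self.n_classes = n_classes
        self.n_stages = n_stages
        self.base_features = base_features
        self.dropout_rate = dropout_rate
        self.alpha = alpha
        self.beta = beta
        self.smooth = smooth
        self.lr = lr
        self.lr_decay_per_epoch = lr_decay_per_epoch
        self.batch_size = batch_size
        self.epochs = epochs
        self.augmentations_per_image = augmentations_per_image
        self.shuffle_each_epoch = shuffle_each_epoch
        self.seed = seed

    # -- config plumbing ---------------------------------------------------
    def _unet_config(self) -> UNetConfig:
        return UNetConfig(self.n_stages, self.base_features, self.n_classes, self.dropout_rate)

    def _tversky_config(self) -> TverskyConfig:
        return TverskyConfig(self.alpha, self.beta, self.smooth)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr,
            lr_decay_per_epoch=self.lr_decay_per_epoch,
            batch_size=self.batch_size,
            epochs=self.epochs,
            augmentations_per_image=self.augmentations_per_image,
            shuffle_each_epoch=self.shuffle_each_epoch,
            seed=self.seed,
        )

    # -- training ----------------------------------------------------------
    def fit(self, X, y) -> "UNetSegmenter":
        """Train on images ``X`` (N, H, W) and label maps ``y`` (N, H, W).

        Images are min-max normalised per image; all patches of one call
        must share a shape divisible by ``2**n_stages``.  With
        ``augmentations_per_image`` > 0 the training set is expanded with
        random skew/rotation/translation/brightness variants.
        """
        X = [normalize_image(im) for im in X]
        y = [np.asarray(lab) for lab in y]
        if len(X) == 0:
            raise ValueError("empty training set")
        if any(im.shape != lab.shape for im, lab in zip(X, y)):
            raise ValueError("image/label shapes differ")
        if self.augmentations_per_image > 0:
            extra_im, extra_lab = [], []
            for i, (im, lab) in enumerate(zip(X, y)):
                for aim, alab in augment(im, lab, self.augmentations_per_image, seed=self.seed + i):
                    extra_im.append(aim)
                    extra_lab.append(alab)
            X = X + extra_im
            y = y + extra_lab
        mult = 2**self.n_stages
        for im in X:
            if im.shape[0] % mult or im.shape[1] % mult:
                raise ValueError(f"training patch edges must divide {mult}")
        images = np.stack(X)[:, None].astype(np.float32)
        targets = one_hot(np.stack(y), self.n_classes)
        self.net_ = UNet(self._unet_config(), seed=self.seed)
        self.loss_history_ = self.net_.fit(images, targets, self._tversky_config(), self._train_config())
        self.weights_ = self.net_.get_weights()
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, frame: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (C, H, W); any frame size (the
        frame is reflect-padded to the next valid size and cropped back)."""
        self._check_fitted()
        return self.net_.predict_proba(normalize_image(frame))

    def predict(self, frame: np.ndarray) -> np.ndarray:
        """Argmax class labels, same shape as the input frame."""
        return self.predict_proba(frame).argmax(axis=0).astype(np.uint8)

    def detect(
        self,
        frame: np.ndarray,
        frame_idx: int = 0,
        min_cell_area_px2: int = 50,
        median_kernel: int = 3,
    ) -> list[CellDetection]:
        """Segment one frame and extract individual cell detections
        (3-class models only)."""
        if self.n_classes != 3:
            raise ValueError("detect() requires the 3-class cell segmenter")
        dets, _ = postprocess_icd(self.predict(frame), min_cell_area_px2, median_kernel, frame_idx)
        return dets

    def score(self, X, y) -> float:
        """Mean Tversky index (1 - loss) over frames; higher is better."""
        losses = []
        for frame, lab in zip(X, y):
            probs = self.predict_proba(frame)
            losses.append(tversky_loss(probs[None], one_hot(np.asarray(lab)[None], self.n_classes), self._tversky_config()))
        return 1.0 - float(np.mean(losses))

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise ValueError("this UNetSegmenter is not fitted yet")

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON config sidecar."""
        self._check_fitted()
        path = Path(path)
        np.savez(path, **{f"w{i}": w for i, w in enumerate(self.weights_)})
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"params": self.get_params(), "loss_history": getattr(self, "loss_history_", [])}))

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta["params"])
        est.net_ = UNet(est._unet_config(), seed=est.seed)
        with np.load(path) as data:
            weights = [data[f"w{i}"] for i in range(len(data.files))]
        est.net_.set_weights(weights)
        est.weights_ = est.net_.get_weights()
        est.loss_history_ = meta.get("loss_history", [])
        return est


# -- thin functional wrappers ----------------------------------------------


def train(images, labels, unet_cfg: UNetConfig | None = None, tversky_cfg: TverskyConfig | None = None, train_cfg: TrainConfig | None = None):
    """Functional training entry point; returns (estimator, loss history)."""
    unet_cfg = unet_cfg or UNetConfig()
    tversky_cfg = tversky_cfg or TverskyConfig()
    train_cfg = train_cfg or TrainConfig()
    est = UNetSegmenter(
        n_classes=unet_cfg.n_classes,
        n_stages=unet_cfg.n_stages,
        base_features=unet_cfg.base_features,
        dropout_rate=unet_cfg.dropout_rate,
        alpha=tversky_cfg.alpha,
        beta=tversky_cfg.beta,
        smooth=tversky_cfg.smooth,
        lr=train_cfg.lr,
        lr_decay_per_epoch=train_cfg.lr_decay_per_epoch,
        batch_size=train_cfg.batch_size,
        epochs=train_cfg.epochs,
        augmentations_per_image=train_cfg.augmentations_per_image,
        shuffle_each_epoch=train_cfg.shuffle_each_epoch,
        seed=train_cfg.seed,
    )
    est.fit(images, labels)
    return est, est.loss_history_


def predict(frame: np.ndarray, estimator: UNetSegmenter) -> np.ndarray:
    """Label map for one frame."""
    return estimator.predict(frame)


def predict_idsd(frame: np.ndarray, estimator: UNetSegmenter) -> np.ndarray:
    """2-class monolayer(1)/gap(0) mask from a direct-scratch model."""
    if estimator.n_classes != 2:
        raise ValueError("predict_idsd requires a 2-class model")
    return estimator.predict(frame)
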