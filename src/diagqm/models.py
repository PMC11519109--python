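"""Learned reconstruction and lesion-detection stages (desk scale).

Both stages are small two-level convolutional encoder-decoders (numpy,
slice-wise) behind pluggable contracts:

* the reconstruction model maps an aliased, min/max-normalised volume to a
  de-aliased volume on the same grid, trained to maximise SSIM against the
  fully sampled image (loss = 1 - mean SSIM);
* the detection model maps a z-normalised volume to a voxelwise likelihood
  heatmap in [0, 1], trained with weighted binary cross-entropy
  (background 0.05 / lesion 0.95) against the ground-truth labelmap.

A deterministic, training-free surrogate detector (multi-scale
centre-surround response to hypointense blobs) is provided so the FROC
machinery can be exercised without any training.

Detection models are trained once on fully sampled images and *never*
retrained per acceleration condition: re-training would let the detector
normalise reconstruction hallucinations and mask the diagnostic effect
being measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import Adam, UNet2D
from ._ssim import ssim_value, ssim_value_and_grad
from .splits import make_split_manifest
from .volume import ImageVolume, LesionSet

__all__ = [
    "ReconTrainConfig",
    "DetectTrainConfig",
    "SurrogateParams",
    "Heatmap",
    "ReconModel",
    "DetectModel",
    "DetectorEnsemble",
    "train_reconstructor",
    "reconstruct",
    "train_detector",
    "predict_heatmap",
    "surrogate_detect",
]


# --------------------------------------------------------------------------
# configs and containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReconTrainConfig:
    """Training protocol of the reconstruction stage.

    Batch size 12, Adam at 4e-4 and the SSIM loss are the reference
    protocol; ``model_scale`` (channel width) and ``epochs`` govern desk
    scale.  Augmentations: rotation (prob 0.25, +-30 deg), additive normal
    noise on the input (prob 0.60, sd drawn from 0-0.003), mirroring
    (prob 0.50).
    """

    loss: str = "ssim"
    batch_size: int = 12
    learning_rate: float = 4e-4
    optimizer: str = "adam"
    early_stopping_patience: int = 5
    rotation_prob: float = 0.25
    rotation_degrees: float = 30.0
    noise_prob: float = 0.60
    noise_scale: float = 0.003
    mirror_prob: float = 0.50
    model_scale: int = 8
    epochs: int = 20
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.rotation_prob, self.noise_prob, self.mirror_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss != "ssim":
            raise ValueError("only the SSIM loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only Adam is supported")


@dataclass(frozen=True)
class DetectTrainConfig:
    """Training protocol of the detection stage.

    Weighted BCE with class weights 0.05 (background) / 0.95 (lesion);
    five-fold cross-validation inside an 80% development split.
    Augmentations: rotation (prob 0.10, +-30 deg), additive normal noise
    (prob 0.30, sd 0-0.001 of the instance sd), horizontal flip (prob 0.50).
    """

    class_weights: tuple[float, float] = (0.05, 0.95)
    rotation_prob: float = 0.10
    rotation_degrees: float = 30.0
    noise_prob: float = 0.30
    noise_multiplier: float = 0.001
    flip_prob: float = 0.50
    n_folds: int = 5
    train_fraction: float = 0.80
    batch_size: int = 12
    learning_rate: float = 1e-3
    model_scale: int = 8
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SurrogateParams:
    """Multi-scale centre-surround blob detector settings.

    ``scales_mm`` are centre Gaussian scales; the surround is twice the
    centre.  ``contrast_scale`` maps the raw hypointensity evidence onto
    [0, 1] (responses at or above it saturate).
    """

    scales_mm: tuple[float, ...] = (1.5, 2.5, 4.0)
    contrast_scale: float = 0.3


@dataclass(frozen=True)
class Heatmap:
    """Voxelwise likelihood of a clinically significant lesion, in [0, 1]."""

    likelihood: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.likelihood, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("heatmap must be 3D")
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError("heatmap values must lie in [0, 1]")
        object.__setattr__(self, "likelihood", np.clip(arr, 0.0, 1.0))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


# --------------------------------------------------------------------------
# augmentation helpers (training only, never at inference)
# --------------------------------------------------------------------------


def _augment_pair(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    rotation_prob: float,
    rotation_degrees: float,
    noise_prob: float,
    noise_scale: float,
    mirror_prob: float,
    nearest_target: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an (input, target) slice pair; noise on input only."""
    if rng.random() < rotation_prob:
        angle = rng.uniform(-rotation_degrees, rotation_degrees)
        x = ndimage.rotate(x, angle, reshape=False, order=1, mode="nearest")
        y = ndimage.rotate(
            y, angle, reshape=False, order=0 if nearest_target else 1, mode="nearest"
        )
    if rng.random() < mirror_prob:
        x = x[::-1].copy()
        y = y[::-1].copy()
    if rng.random() < noise_prob:
        x = x + rng.normal(scale=rng.uniform(0.0, noise_scale), size=x.shape)
    return x, y


def _as_slices(volume: ImageVolume) -> np.ndarray:
    """(H, W, Z) volume -> (Z, H, W) slice batch."""
    return np.moveaxis(volume.data, 2, 0)


# --------------------------------------------------------------------------
# reconstruction model
# --------------------------------------------------------------------------


class ReconModel:
    """Residual slice-wise encoder-decoder: output = clip(input + net(input)).

    The residual head is zero-initialised, so an untrained model is the
    identity map.
    """

    def __init__(self, model_scale: int = 8, seed: int = 0) -> None:
        self.net = UNet2D(channels=model_scale, head="linear", seed=seed)
        self.val_losses: list[float] = []

    def forward_slices(self, slices: np.ndarray) -> np.ndarray:
        return slices + self.net.forward(slices)

    def reconstruct_volume(self, volume: ImageVolume) -> ImageVolume:
        slices = _as_slices(volume)
        out = np.empty_like(slices)
        for i in range(0, slices.shape[0], 16):
            out[i : i + 16] = self.forward_slices(slices[i : i + 16])
        return volume.with_data(np.clip(np.moveaxis(out, 0, 2), 0.0, 1.0))


def _recon_loss_and_grad(
    model: ReconModel, x: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Batch SSIM loss (1 - mean SSIM) and parameter gradients."""
    pred = model.forward_slices(x)
    n = x.shape[0]
    loss = 0.0
    dpred = np.empty_like(pred)
    for i in range(n):
        s, g = ssim_value_and_grad(y[i], pred[i], data_range=1.0)
        loss += (1.0 - s) / n
        dpred[i] = -g / n
    grads = model.net.backward(dpred)  # residual: d pred/d net-output = 1
    return loss, grads


def train_reconstructor(
    pairs: Sequence[tuple[ImageVolume, ImageVolume]],
    config: ReconTrainConfig,
) -> ReconModel:
    """Train the reconstruction model on (aliased, fully sampled) pairs.

    Pairs must be voxel-aligned and preprocessed by the reconstruction
    chain (values in [0, 1]).  A held-out case fraction drives early
    stopping on the validation loss; the best-validation state is restored.
    Fully seeded: identical data + config + seed give an identical
    validation-loss trajectory.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    for aliased, target in pairs:
        if aliased.shape != target.shape:
            raise ValueError("pairs must be voxel-aligned")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(pairs))))
    order = rng.permutation(len(pairs))
    val_idx = set(order[:n_val].tolist())
    train_x = np.concatenate(
        [_as_slices(pairs[i][0]) for i in range(len(pairs)) if i not in val_idx]
    )
    train_y = np.concatenate(
        [_as_slices(pairs[i][1]) for i in range(len(pairs)) if i not in val_idx]
    )
    val_x = np.concatenate([_as_slices(pairs[i][0]) for i in sorted(val_idx)])
    val_y = np.concatenate([_as_slices(pairs[i][1]) for i in sorted(val_idx)])

    model = ReconModel(model_scale=config.model_scale, seed=config.seed)
    opt = Adam(lr=config.learning_rate)
    best_state = model.net.state_dict()
    best_val = np.inf
    stale = 0
    for _epoch in range(config.epochs):
        idx = rng.permutation(train_x.shape[0])
        for start in range(0, idx.size, config.batch_size):
            batch = idx[start : start + config.batch_size]
            xb = np.empty((batch.size, *train_x.shape[1:]))
            yb = np.empty_like(xb)
            for j, b in enumerate(batch):
                xb[j], yb[j] = _augment_pair(
                    train_x[b],
                    train_y[b],
                    rng,
                    config.rotation_prob,
                    config.rotation_degrees,
                    config.noise_prob,
                    config.noise_scale,
                    config.mirror_prob,
                )
            loss, grads = _recon_loss_and_grad(model, xb, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {_epoch}; "
                    "lower the learning rate or check the input range"
                )
            opt.step(model.net.params, grads)
        val_pred = model.forward_slices(val_x)
        val_loss = float(
            np.mean([1.0 - ssim_value(val_y[i], val_pred[i]) for i in range(val_x.shape[0])])
        )
        model.val_losses.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.net.state_dict()
            stale = 0
        else:
            stale += 1
            if stale > config.early_stopping_patience:
                break
    if config.epochs > 0:
        model.net.load_state(best_state)
    return model


def reconstruct(model: ReconModel, aliased: ImageVolume) -> ImageVolume:
    """Apply the trained reconstructor; output clipped to [0, 1], same grid."""
    return model.reconstruct_volume(aliased)


# --------------------------------------------------------------------------
# detection model
# --------------------------------------------------------------------------


class DetectModel:
    """Slice-wise encoder-decoder emitting a voxelwise lesion likelihood."""

    def __init__(self, model_scale: int = 8, seed: int = 0) -> None:
        self.net = UNet2D(channels=model_scale, head="sigmoid", kernel=5, seed=seed)
        self.val_losses: list[float] = []

    def predict_volume(self, volume: ImageVolume) -> np.ndarray:
        slices = _as_slices(volume)
        out = np.empty_like(slices)
        for i in range(0, slices.shape[0], 16):
            out[i : i + 16] = self.net.forward(slices[i : i + 16])
        return np.moveaxis(out, 0, 2)


@dataclass
class DetectorEnsemble:
    """Fold models plus the patient-level split manifest that trained them."""

    models: list[DetectModel]
    manifest: pd.DataFrame
    config: DetectTrainConfig

    @property
    def test_ids(self) -> list[str]:
        return self.manifest.loc[self.manifest.role == "test", "patient_id"].tolist()


def _weighted_bce_grad(
    pred: np.ndarray, target: np.ndarray, w_neg: float, w_pos: float
) -> tuple[float, np.ndarray]:
    """Per-voxel weighted BCE mean and its gradient wrt the pre-sigmoid input.

    The gradient returned is with respect to the logits z (pred = sigmoid(z)),
    which is numerically stable: dL/dz = (w_pos*t*(p-1) + w_neg*(1-t)*p)/N.
    """
    eps = 1e-12
    n = pred.size
    loss = -(
        w_pos * target * np.log(pred + eps) + w_neg * (1 - target) * np.log(1 - pred + eps)
    ).sum() / n
    dz = (w_pos * target * (pred - 1.0) + w_neg * (1 - target) * pred) / n
    return float(loss), dz


def train_detector(
    cohort: Sequence[tuple[ImageVolume, LesionSet]],
    config: DetectTrainConfig,
    patient_ids: Sequence[str] | None = None,
    sites: Sequence[str] | None = None,
) -> DetectorEnsemble:
    """Train one detection model per cross-validation fold.

    The cohort is split 80/20 (site-stratified) into development and test
    patients; the development patients are partitioned into ``n_folds``
    disjoint folds, and one model is trained per fold on the other folds'
    slices.  The best epoch per fold is kept by validation loss.  Test
    patients never enter any training fold.
    """
    labels = [int(les.n_lesions > 0) for _, les in cohort]
    if len(set(labels)) < 2:
        raise ValueError("cohort must contain both positive and negative patients")
    if patient_ids is None:
        patient_ids = [f"case_{i:05d}" for i in range(len(cohort))]
    manifest = make_split_manifest(
        patient_ids,
        sites,
        train_fraction=config.train_fraction,
        n_folds=config.n_folds,
        seed=config.seed,
    )
    by_id = dict(zip(patient_ids, cohort))
    fold_of = dict(
        zip(
            manifest.loc[manifest.role == "train", "patient_id"],
            manifest.loc[manifest.role == "train", "fold"],
        )
    )
    rng = np.random.default_rng(config.seed + 1)
    w_neg, w_pos = config.class_weights
    models: list[DetectModel] = []
    for fold in range(config.n_folds):
        train_ids = [p for p, f in fold_of.items() if f != fold]
        val_ids = [p for p, f in fold_of.items() if f == fold]
        tx = np.concatenate([_as_slices(by_id[p][0]) for p in train_ids])
        ty = np.concatenate(
            [_as_slices(by_id[p][1].labelmap > 0).astype(float) for p in train_ids]
        )
        vx = np.concatenate([_as_slices(by_id[p][0]) for p in val_ids])
        vy = np.concatenate(
            [_as_slices(by_id[p][1].labelmap > 0).astype(float) for p in val_ids]
        )
        model = DetectModel(model_scale=config.model_scale, seed=config.seed + fold)
        opt = Adam(lr=config.learning_rate)
        best_state = model.net.state_dict()
        best_val = np.inf
        for _epoch in range(config.epochs):
            idx = rng.permutation(tx.shape[0])
            for start in range(0, idx.size, config.batch_size):
                batch = idx[start : start + config.batch_size]
                xb = np.empty((batch.size, *tx.shape[1:]))
                yb = np.empty_like(xb)
                for j, b in enumerate(batch):
                    xb[j], yb[j] = _augment_pair(
                        tx[b],
                        ty[b],
                        rng,
                        config.rotation_prob,
                        config.rotation_degrees,
                        config.noise_prob,
                        config.noise_multiplier * max(tx[b].std(), 1.0),
                        config.flip_prob,
                        nearest_target=True,
                    )
                pred = model.net.forward(xb)
                loss, dz = _weighted_bce_grad(pred, yb, w_neg, w_pos)
                if not np.isfinite(loss):
                    raise RuntimeError(f"NaN/inf detection loss at epoch {_epoch}")
                # backward expects d(loss)/d(sigmoid output); feed dz through
                # the identity by inverting the sigmoid derivative
                sig_deriv = np.clip(pred * (1 - pred), 1e-12, None)
                grads = model.net.backward(dz / sig_deriv)
                opt.step(model.net.params, grads)
            val_pred = np.concatenate(
                [model.net.forward(vx[i : i + 16]) for i in range(0, vx.shape[0], 16)]
            )
            val_loss, _ = _weighted_bce_grad(val_pred, vy, w_neg, w_pos)
            model.val_losses.append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = model.net.state_dict()
        if config.epochs > 0:
            model.net.load_state(best_state)
        models.append(model)
    return DetectorEnsemble(models=models, manifest=manifest, config=config)


def predict_heatmap(
    model: DetectModel | DetectorEnsemble | Sequence[DetectModel],
    volume: ImageVolume,
    provenance: str = "",
) -> Heatmap:
    """Voxelwise lesion likelihood; ensembles average fold models voxelwise."""
    if isinstance(model, DetectModel):
        members: Sequence[DetectModel] = [model]
    elif isinstance(model, DetectorEnsemble):
        members = model.models
    else:
        members = list(model)
    acc = np.zeros(volume.shape)
    for m in members:
        acc += m.predict_volume(volume)
    return Heatmap(acc / len(members), spacing=volume.spacing, provenance=provenance)


# --------------------------------------------------------------------------
# surrogate detector (training-free)
# --------------------------------------------------------------------------


def surrogate_detect(
    volume: ImageVolume, params: SurrogateParams = SurrogateParams()
) -> Heatmap:
    """Deterministic blob-evidence heatmap for hypointense lesions.

    Multi-scale centre-surround response: at each scale the centre-smoothed
    image is subtracted from the surround-smoothed image, so voxels darker
    than their surroundings score positively.  The maximal response across
    scales is divided by ``contrast_scale`` and clipped to [0, 1] — the map
    is monotone in lesion contrast until saturation.  A constant volume
    yields a zero (no-evidence) heatmap.
    """
    data = volume.data
    best = np.zeros_like(data)
    for scale_mm in params.scales_mm:
        sigma_c = tuple(scale_mm / s for s in volume.spacing)
        sigma_s = tuple(2.0 * scale_mm / s for s in volume.spacing)
        center = ndimage.gaussian_filter(data, sigma_c, mode="nearest")
        surround = ndimage.gaussian_filter(data, sigma_s, mode="nearest")
        np.maximum(best, surround - center, out=best)
    best[best < 1e-9] = 0.0  # filter round-off on (near-)constant inputs
    evidence = np.clip(best / params.contrast_scale, 0.0, 1.0)
    return Heatmap(evidence, spacing=volume.spacing, provenance="surrogate")
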