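"""Three-phase semi-supervised training of the nest autoencoder.

Phase 1 trains the reconstruction variant with mean squared error on patches
from *all* images, labeled or not — the inputs are their own targets, so no
masks are needed.  Phase 2 transfers the encoder into a fresh segmentation
variant, freezes it, resets the decoder, and trains with binary cross-entropy
on labeled patches only.  Phase 3 unfreezes the encoder and fine-tunes the
whole network at a halved base learning rate.  Every phase checkpoints the
weights at the smallest validation loss (ties broken toward the earlier
epoch).

The per-epoch learning rate follows the decay curve
``lr(e) = -log10(0.01 e + 0.1) * base`` clamped below by a small floor: it
starts at exactly ``base`` (epoch 0) and decays to the floor at epoch 90.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from ._nn import Adam
from .model import (CAEModel, ContractError, build_architecture, initialize,
                    set_encoder_frozen, transfer_encoder)
from .patching import DataError, Patch

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters shared by all phases."""

    batch_size: int = 64
    base_lr_main: float = 1e-3
    base_lr_finetune: float = 5e-4
    epochs_per_phase: tuple[int, int, int] = (50, 40, 20)
    lr_floor: float = 1e-6
    seed: int = 0
    threshold: float = 0.5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ContractError("batch_size must be >= 1")
        if any(e < 1 for e in self.epochs_per_phase):
            raise ContractError("epochs must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ContractError("threshold must lie in (0, 1)")


@dataclass
class PhaseResult:
    """Loss history and best-validation checkpoint of one phase."""

    phase: str
    train_loss_history: list[float]
    val_loss_history: list[float]
    best_epoch: int
    checkpoint: CAEModel

    def write_history(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "lr", "train_loss", "val_loss"])
            base = (TrainConfig.base_lr_finetune if self.phase == "finetune"
                    else TrainConfig.base_lr_main)
            for e, (tr, va) in enumerate(zip(self.train_loss_history,
                                             self.val_loss_history)):
                w.writerow([e, lr_schedule(e, base), tr, va])


def lr_schedule(epoch: int, base: float, floor: float = 1e-6) -> float:
    """Decaying learning rate ``max(floor, -log10(0.01*epoch + 0.1) * base)``.

    Equals ``base`` at epoch 0, reaches the floor at epoch 90 and stays
    there; nonincreasing in ``epoch``.
    """
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if base <= 0:
        raise ValueError("base learning rate must be positive")
    return max(floor, -np.log10(0.01 * epoch + 0.1) * base)


def mse_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean of squared elementwise differences (float64)."""
    x = np.asarray(x, np.float64)
    x_hat = np.asarray(x_hat, np.float64)
    if x.shape != x_hat.shape:
        raise ContractError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    d = x - x_hat
    return float(np.mean(d * d))


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped for safety."""
    y = np.asarray(y, np.float64)
    p = np.asarray(p, np.float64)
    if y.shape != p.shape:
        raise ContractError(f"shape mismatch {y.shape} vs {p.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# -- patch tensors -----------------------------------------------------------

def patches_to_inputs(patches: list[Patch]) -> np.ndarray:
    """Stack patch RGB tiles into an (N, 128, 128, 3) float32 tensor."""
    if not patches:
        raise DataError("empty patch set")
    return np.stack([p.rgb for p in patches]).astype(np.float32)


def patches_to_targets(patches: list[Patch]) -> np.ndarray:
    """Stack patch masks into an (N, 128, 128, 1) float32 tensor."""
    if any(p.mask is None for p in patches):
        raise DataError("segmentation targets require labeled patches")
    return np.stack([p.mask for p in patches]).astype(np.float32)[..., None]


def labeled_only(patches: list[Patch]) -> list[Patch]:
    return [p for p in patches if p.mask is not None]


# -- core loop ----------------------------------------------------------------

def _batch_loss_and_head_grad(kind: str, y_pred: np.ndarray, y_true: np.ndarray,
                              scale_to: int):
    """Per-batch loss and gradient w.r.t. the head's pre-activation.

    ``kind='mse'`` assumes a ReLU head trained on mean squared error;
    ``kind='bce'`` assumes a sigmoid head, for which the pre-activation
    gradient collapses to (p - y) / n.
    """
    n = y_pred.size
    if kind == "mse":
        d = y_pred - y_true
        loss = float(np.dot(d.ravel(), d.ravel())) / n
        d *= 2.0 / n
        d *= (y_pred > 0)  # ReLU head gradient
        return loss, d.astype(np.float32, copy=False)
    p = np.clip(y_pred, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log1p(-p)))
    d = (y_pred - y_true) / n
    return loss, d.astype(np.float32, copy=False)


def _eval_loss(model: CAEModel, X: np.ndarray, Y: np.ndarray, kind: str,
               batch_size: int, forward) -> float:
    total = 0.0
    for i in range(0, len(X), batch_size):
        y_pred = forward(X[i : i + batch_size], False)
        if kind == "mse":
            d = y_pred - Y[i : i + batch_size]
            total += float(np.dot(d.ravel(), d.ravel()))
        else:
            p = np.clip(y_pred, _EPS, 1.0 - _EPS)
            yt = Y[i : i + batch_size]
            total += float(-np.sum(yt * np.log(p) + (1.0 - yt) * np.log1p(-p)))
    return total / Y.size


def _train_loop(model: CAEModel, X: np.ndarray, Y: np.ndarray,
                Xval: np.ndarray, Yval: np.ndarray, kind: str, base_lr: float,
                epochs: int, config: TrainConfig, phase: str,
                shuffle_seed: int, forward=None) -> PhaseResult:
    """Adam/minibatch loop with best-validation checkpointing.

    ``forward`` lets phase 2 train the decoder on precomputed latent codes;
    it defaults to the full model forward.
    """
    if len(X) == 0:
        raise DataError("empty training set")
    fwd = forward if forward is not None else model.forward
    rng = np.random.default_rng(shuffle_seed)
    optim = Adam(model.layers, config.adam_beta1, config.adam_beta2)
    train_hist, val_hist = [], []
    best_val, best_epoch, best_state = np.inf, -1, model.state_dict()
    for epoch in range(epochs):
        lr = lr_schedule(epoch, base_lr, config.lr_floor)
        perm = rng.permutation(len(X))
        epoch_loss = 0.0
        for i in range(0, len(X), config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = X[idx], Y[idx]
            y_pred = fwd(xb, True)
            loss, d_pre = _batch_loss_and_head_grad(kind, y_pred, yb, xb.shape[0])
            model.backward(d_pre)
            optim.step(model.layers, lr)
            epoch_loss += loss * len(idx)
        train_hist.append(epoch_loss / len(X))
        val_hist.append(_eval_loss(model, Xval, Yval, kind,
                                   config.batch_size, fwd))
        if val_hist[-1] < best_val:  # strict: ties keep the earlier epoch
            best_val, best_epoch = val_hist[-1], epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return PhaseResult(phase, train_hist, val_hist, best_epoch, model)


# -- the three phases ---------------------------------------------------------

def train_phase1_reconstruction(model: CAEModel, train_patches: list[Patch],
                                val_patches: list[Patch], config: TrainConfig
                                ) -> PhaseResult:
    """Unsupervised pretraining: reconstruct every patch (labeled or not)."""
    config.validate()
    if model.spec.variant != "reconstruction":
        raise ContractError("phase 1 requires the reconstruction variant")
    X = patches_to_inputs(train_patches)
    Xval = patches_to_inputs(val_patches)
    return _train_loop(model, X, X, Xval, Xval, "mse", config.base_lr_main,
                       config.epochs_per_phase[0], config, "reconstruction",
                       shuffle_seed=config.seed + 11)


def train_phase2_segmentation(pretrained: CAEModel, train_patches: list[Patch],
                              val_patches: list[Patch], config: TrainConfig
                              ) -> PhaseResult:
    """Frozen-encoder segmentation training on labeled patches.

    The encoder (through the 16x16x64 code) is copied from the phase-1
    checkpoint and frozen; the decoder is re-initialised and trained with
    BCE.  Because the encoder is fixed, each patch's latent code is
    precomputed once and the loop runs on the decoder only — numerically
    identical to running the full forward every step.
    """
    config.validate()
    train_patches = labeled_only(train_patches)
    val_patches = labeled_only(val_patches)
    if not train_patches or not val_patches:
        raise DataError("phase 2 requires labeled patches in train and val")
    model = transfer_encoder(pretrained, "segmentation", seed=config.seed + 23)
    set_encoder_frozen(model, True)

    X = patches_to_inputs(train_patches)
    Y = patches_to_targets(train_patches)
    Xval = patches_to_inputs(val_patches)
    Yval = patches_to_targets(val_patches)

    def encode_all(data: np.ndarray) -> np.ndarray:
        codes = []
        for i in range(0, len(data), config.batch_size):
            x = data[i : i + config.batch_size].astype(np.float32)
            for layer in model.encoder_layers():
                x = layer.forward(x, train=False)
            codes.append(x.copy())
        return np.concatenate(codes)

    C, Cval = encode_all(X), encode_all(Xval)

    def decoder_forward(code_batch, train):
        x = code_batch
        for layer in model.decoder_layers():
            x = layer.forward(x, train=train)
        return x

    return _train_loop(model, C, Y, Cval, Yval, "bce", config.base_lr_main,
                       config.epochs_per_phase[1], config, "segmentation",
                       shuffle_seed=config.seed + 37, forward=decoder_forward)


def train_phase3_finetune(model: CAEModel, train_patches: list[Patch],
                          val_patches: list[Patch], config: TrainConfig
                          ) -> PhaseResult:
    """Unfreeze everything and fine-tune end to end at the halved base LR."""
    config.validate()
    if model.spec.variant != "segmentation":
        raise ContractError("phase 3 requires the segmentation variant")
    train_patches = labeled_only(train_patches)
    val_patches = labeled_only(val_patches)
    if not train_patches or not val_patches:
        raise DataError("phase 3 requires labeled patches in train and val")
    set_encoder_frozen(model, False)
    X = patches_to_inputs(train_patches)
    Y = patches_to_targets(train_patches)
    Xval = patches_to_inputs(val_patches)
    Yval = patches_to_targets(val_patches)
    return _train_loop(model, X, Y, Xval, Yval, "bce", config.base_lr_finetune,
                       config.epochs_per_phase[2], config, "finetune",
                       shuffle_seed=config.seed + 53)


def run_semi_supervised(train_patches: list[Patch], val_patches: list[Patch],
                        config: TrainConfig
                        ) -> tuple[CAEModel, dict[str, PhaseResult]]:
    """Full protocol: reconstruction -> frozen-encoder segmentation -> fine-tune.

    Phase 1 consumes every patch (the reconstruction target is the input
    itself); phases 2 and 3 consume labeled patches only.  Returns the
    phase-3 best-validation model and all three phase results.
    """
    config.validate()
    recon = initialize(CAEModel.from_spec(build_architecture("reconstruction")),
                       seed=config.seed)
    r1 = train_phase1_reconstruction(recon, train_patches, val_patches, config)
    r2 = train_phase2_segmentation(r1.checkpoint, train_patches, val_patches,
                                   config)
    r3 = train_phase3_finetune(r2.checkpoint, train_patches, val_patches,
                               config)
    return r3.checkpoint, {"reconstruction": r1, "segmentation": r2,
                           "finetune": r3}


def train_supervised_baseline(train_patches: list[Patch],
                              val_patches: list[Patch], config: TrainConfig,
                              epochs: int | None = None) -> CAEModel:
    """Segmentation-from-scratch control: same architecture and budget, no
    reconstruction pretraining and no encoder freezing."""
    config.validate()
    model = initialize(CAEModel.from_spec(build_architecture("segmentation")),
                       seed=config.seed)
    train_patches = labeled_only(train_patches)
    val_patches = labeled_only(val_patches)
    if not train_patches or not val_patches:
        raise DataError("supervised baseline requires labeled patches")
    X = patches_to_inputs(train_patches)
    Y = patches_to_targets(train_patches)
    Xval = patches_to_inputs(val_patches)
    Yval = patches_to_targets(val_patches)
    n_epochs = epochs if epochs is not None else sum(config.epochs_per_phase)
    result = _train_loop(model, X, Y, Xval, Yval, "bce", config.base_lr_main,
                         n_epochs, config, "supervised",
                         shuffle_seed=config.seed + 71)
    return result.checkpoint
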