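"""Beta-VAE over time-frequency images.

The encoder maps a 64x64 scalogram to an 8-dimensional Gaussian latent
(mean and log-variance); the decoder reconstructs the image from a sampled
latent. Training minimizes

    loss = reconstruction + beta * KL(q(z|x) || N(0, I)),

with beta = 0.1 and the reconstruction criterion either a perceptual
distance (feature-space L2 under a fixed, seed-deterministic extractor) or
plain MSE. The backbone is a residual fully-connected encoder/decoder of
configurable width and depth; the "small" variant is sized for single-CPU
training. Stratified sampling caps each subject's contribution per epoch,
and time-axis flips augment the training stream. The checkpoint with the
lowest validation loss is returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, exp, relu, sigmoid, tanh

__all__ = [
    "VaeConfig",
    "LatentCode",
    "LossBreakdown",
    "TrainedVae",
    "init_params",
    "vae_forward",
    "vae_loss",
    "train_vae",
    "encode_latent",
    "reconstruction_error",
]

IMG_SHAPE = (64, 64)
IMG_DIM = IMG_SHAPE[0] * IMG_SHAPE[1]
_PERCEPTUAL_SEED = 20240501  # fixed: extractor weights are part of the loss definition


@dataclass(frozen=True)
class VaeConfig:
    latent_dim: int = 8
    beta: float = 0.1
    epochs: int = 80
    batch_size: int = 512
    lr: float = 3e-4
    per_subject_cap: int = 2500
    flip_prob: float = 0.5
    width: int = 256
    n_blocks: int = 8
    criterion: str = "perceptual"  # or "mse"

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.per_subject_cap < 1:
            raise ValueError("per_subject_cap must be >= 1")

    @staticmethod
    def small(**overrides) -> "VaeConfig":
        """Desk-scale variant: narrow, shallow, short schedule.

        The learning rate is raised relative to the full configuration
        because the small variant takes far fewer optimizer steps, and the
        reconstruction criterion is plain MSE, which is better conditioned
        at this scale than the feature-space distance.
        """
        defaults = dict(width=128, n_blocks=1, epochs=120, batch_size=32, lr=3e-3,
                        criterion="mse")
        defaults.update(overrides)
        return VaeConfig(**defaults)

    def to_dict(self) -> dict:
        return {
            "latent_dim": self.latent_dim,
            "beta": self.beta,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "lr": self.lr,
            "per_subject_cap": self.per_subject_cap,
            "flip_prob": self.flip_prob,
            "width": self.width,
            "n_blocks": self.n_blocks,
            "criterion": self.criterion,
        }

    @staticmethod
    def from_dict(d: dict) -> "VaeConfig":
        return VaeConfig(**d)


@dataclass
class LatentCode:
    """Per-event posterior: mean vector and per-dimension log variance."""

    mu: np.ndarray
    logvar: np.ndarray
    subject: str = ""
    event_id: str = ""


@dataclass
class LossBreakdown:
    recon: float
    kl: float
    total: float
    total_tensor: Tensor | None = None


# ---------------------------------------------------------------------------
# parameters and forward passes
# ---------------------------------------------------------------------------

def _he(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)


def init_params(config: VaeConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    w = config.width
    params: dict[str, np.ndarray] = {
        "enc_in_W": _he(rng, IMG_DIM, w),
        "enc_in_b": np.zeros(w),
        "enc_mu_W": _he(rng, w, config.latent_dim) * 0.1,
        "enc_mu_b": np.zeros(config.latent_dim),
        "enc_lv_W": _he(rng, w, config.latent_dim) * 0.1,
        "enc_lv_b": np.zeros(config.latent_dim),
        "dec_in_W": _he(rng, config.latent_dim, w),
        "dec_in_b": np.zeros(w),
        "dec_out_W": _he(rng, w, IMG_DIM) * 0.1,
        "dec_out_b": np.zeros(IMG_DIM),
    }
    for side in ("enc", "dec"):
        for i in range(config.n_blocks):
            params[f"{side}_blk{i}_W1"] = _he(rng, w, w)
            params[f"{side}_blk{i}_b1"] = np.zeros(w)
            params[f"{side}_blk{i}_W2"] = _he(rng, w, w) * 0.1
            params[f"{side}_blk{i}_b2"] = np.zeros(w)
    return params


def _blocks(h, params, config: VaeConfig, side: str):
    for i in range(config.n_blocks):
        inner = relu(h @ params[f"{side}_blk{i}_W1"] + params[f"{side}_blk{i}_b1"])
        h = relu(h + inner @ params[f"{side}_blk{i}_W2"] + params[f"{side}_blk{i}_b2"])
    return h


def _encode_t(x: Tensor, params, config: VaeConfig):
    h = relu(x @ params["enc_in_W"] + params["enc_in_b"])
    h = _blocks(h, params, config, "enc")
    mu = h @ params["enc_mu_W"] + params["enc_mu_b"]
    raw = h @ params["enc_lv_W"] + params["enc_lv_b"]
    logvar = 4.0 * tanh(raw * 0.25)  # soft clamp keeps exp(logvar) stable
    return mu, logvar


def _decode_t(z: Tensor, params, config: VaeConfig) -> Tensor:
    h = relu(z @ params["dec_in_W"] + params["dec_in_b"])
    h = _blocks(h, params, config, "dec")
    return sigmoid(h @ params["dec_out_W"] + params["dec_out_b"])


class _PerceptualExtractor:
    """Fixed feature extractor: 4x4 average pooling plus a seeded random
    nonlinear projection. Deterministic by construction; the same weights
    ship with every install."""

    def __init__(self, n_features: int = 128):
        rng = np.random.default_rng(_PERCEPTUAL_SEED)
        pool = np.zeros((IMG_DIM, 256))
        for r in range(16):
            for c in range(16):
                block = np.zeros(IMG_SHAPE)
                block[r * 4 : (r + 1) * 4, c * 4 : (c + 1) * 4] = 1.0 / 16.0
                pool[:, r * 16 + c] = block.ravel()
        self.pool = pool
        self.proj = rng.standard_normal((256, n_features)) / np.sqrt(256)
        self.bias = rng.uniform(-0.5, 0.5, n_features)

    def features(self, x: Tensor) -> tuple[Tensor, Tensor]:
        pooled = x @ self.pool
        return pooled, relu(pooled @ self.proj + self.bias)


_EXTRACTOR: _PerceptualExtractor | None = None


def _extractor() -> _PerceptualExtractor:
    global _EXTRACTOR
    if _EXTRACTOR is None:
        _EXTRACTOR = _PerceptualExtractor()
    return _EXTRACTOR


def vae_loss(reconstruction, target, mu, logvar, beta: float,
             criterion: str = "mse") -> LossBreakdown:
    """Reconstruction + beta * KL, with the analytic Gaussian KL.

    KL per sample is -1/2 sum_d (1 + logvar_d - mu_d^2 - exp(logvar_d)),
    averaged over the batch. Accepts numpy arrays or autograd Tensors; with
    Tensors, ``total_tensor`` supports backprop.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    is_tensor = isinstance(reconstruction, Tensor)
    as_t = lambda v: v if isinstance(v, Tensor) else Tensor(np.atleast_2d(v))
    r, t, m, lv = as_t(reconstruction), as_t(target), as_t(mu), as_t(logvar)
    if r.data.shape != t.data.shape:
        raise ValueError("reconstruction/target shape mismatch")

    # reconstruction error is summed per sample and averaged over the batch,
    # matching the per-sample summed KL — the standard beta-VAE scaling
    n_batch = r.data.shape[0]
    if criterion == "mse":
        recon = ((r - t) ** 2).sum() * (1.0 / n_batch)
    elif criterion == "perceptual":
        ext = _extractor()
        pr, fr = ext.features(r)
        pt, ft = ext.features(t)
        recon = (((pr - pt) ** 2).sum() + ((fr - ft) ** 2).sum()) * (1.0 / n_batch)
    else:
        raise ValueError(f"unknown reconstruction criterion {criterion!r}")

    kl_per_sample = (1.0 + lv - m**2 - exp(lv)).sum(axis=1) * (-0.5)
    kl = kl_per_sample.mean()
    total = recon + beta * kl
    return LossBreakdown(
        recon=float(recon.data),
        kl=float(kl.data),
        total=float(total.data),
        total_tensor=total if is_tensor else None,
    )


# ---------------------------------------------------------------------------
# trained model wrapper
# ---------------------------------------------------------------------------

@dataclass
class TrainedVae:
    config: VaeConfig
    params: dict[str, np.ndarray]
    history: dict = field(default_factory=dict)

    def _flatten(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[np.newaxis]
        if x.shape[1:] != IMG_SHAPE:
            raise ValueError(f"expected images of shape {IMG_SHAPE}, got {x.shape[1:]}")
        return x.reshape(len(x), IMG_DIM)

    def encode(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log variance; no sampling (inference mode)."""
        x = Tensor(self._flatten(images))
        mu, logvar = _encode_t(x, {k: Tensor(v) for k, v in self.params.items()}, self.config)
        return mu.data, logvar.data

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        out = _decode_t(Tensor(z), {k: Tensor(v) for k, v in self.params.items()}, self.config)
        return out.data.reshape(len(z), *IMG_SHAPE)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        mu, _ = self.encode(images)
        return self.decode(mu)


def vae_forward(model: TrainedVae, image: np.ndarray):
    """(reconstruction, mu, logvar) at inference: decoding the posterior mean."""
    x = np.asarray(image, dtype=np.float64)
    single = x.ndim == 2
    mu, logvar = model.encode(x)
    recon = model.decode(mu)
    if single:
        return recon[0], mu[0], logvar[0]
    return recon, mu, logvar


def encode_latent(model: TrainedVae, image: np.ndarray,
                  subject: str = "", event_id: str = "") -> LatentCode:
    mu, logvar = model.encode(image)
    if np.asarray(image).ndim == 2:
        mu, logvar = mu[0], logvar[0]
    return LatentCode(mu=mu, logvar=logvar, subject=subject, event_id=event_id)


def reconstruction_error(model: TrainedVae, images: np.ndarray,
                         criterion: str | None = None) -> np.ndarray:
    """Per-image reconstruction error under the configured criterion."""
    criterion = criterion or model.config.criterion
    x = np.asarray(images, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[np.newaxis]
    recon = model.reconstruct(x)
    flat_r = recon.reshape(len(x), IMG_DIM)
    flat_t = x.reshape(len(x), IMG_DIM)
    if criterion == "mse":
        err = np.sum((flat_r - flat_t) ** 2, axis=1)
    elif criterion == "perceptual":
        ext = _extractor()
        pr, fr = ext.features(Tensor(flat_r))
        pt, ft = ext.features(Tensor(flat_t))
        err = np.sum((pr.data - pt.data) ** 2, axis=1) + np.sum(
            (fr.data - ft.data) ** 2, axis=1
        )
    else:
        raise ValueError(f"unknown reconstruction criterion {criterion!r}")
    return err[0] if single else err


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _choose_validation(subjects: np.ndarray, rng: np.random.Generator,
                       sites: dict[str, str] | None = None) -> set[str]:
    """Validation split: 10 subjects per site when available, else 20%."""
    unique = sorted(set(subjects))
    if sites:
        by_site: dict[str, list[str]] = {}
        for s in unique:
            by_site.setdefault(sites.get(s, ""), []).append(s)
        val: set[str] = set()
        for members in by_site.values():
            k = 10 if len(members) > 10 else max(1, len(members) // 5)
            val.update(rng.choice(members, size=k, replace=False).tolist())
        if val and len(val) < len(unique):
            return val
    k = max(1, int(round(0.2 * len(unique))))
    if k >= len(unique):
        raise ValueError("not enough subjects for a validation split")
    return set(rng.choice(unique, size=k, replace=False).tolist())


def _batch_loss(params_t, config, x_np, rng, train: bool):
    x = Tensor(x_np)
    mu, logvar = _encode_t(x, params_t, config)
    if train:
        eps = Tensor(rng.standard_normal(mu.data.shape))
        z = mu + exp(logvar * 0.5) * eps
    else:
        z = mu
    recon = _decode_t(z, params_t, config)
    return vae_loss(recon, x, mu, logvar, config.beta, config.criterion)


def train_vae(
    images: np.ndarray,
    subject_ids,
    config: VaeConfig,
    seed: int = 0,
    val_subjects: set[str] | None = None,
    sites: dict[str, str] | None = None,
) -> TrainedVae:
    """Train a beta-VAE with per-subject capped stratified sampling.

    ``val_subjects`` fixes the subject-wise validation split; when absent a
    split is drawn (10 subjects per site when available, else 20% of
    subjects). The checkpoint with the lowest validation loss is returned,
    along with the training curve and per-epoch per-subject sample counts
    in ``history``.
    """
    images = np.asarray(images, dtype=np.float64)
    subject_ids = np.asarray([str(s) for s in subject_ids])
    if images.ndim != 3 or len(images) != len(subject_ids):
        raise ValueError("images must be (n, 64, 64) with one subject id per image")
    rng = np.random.default_rng(seed)
    if val_subjects is None:
        val_subjects = _choose_validation(subject_ids, rng, sites)
    val_subjects = {str(s) for s in val_subjects}
    val_mask = np.isin(subject_ids, sorted(val_subjects))
    if not val_mask.any():
        raise ValueError("empty validation set")
    if val_mask.all():
        raise ValueError("empty training set")

    flat = images.reshape(len(images), IMG_DIM)
    train_idx_by_subject = {
        s: np.flatnonzero((subject_ids == s) & ~val_mask)
        for s in sorted(set(subject_ids) - val_subjects)
    }
    val_x = flat[val_mask]

    params_t = {k: Tensor.param(v.copy()) for k, v in init_params(config, seed).items()}
    opt = _Adam(params_t, config.lr)

    history: dict = {"train_loss": [], "val_loss": [], "sampled_per_subject": []}
    best_val = np.inf
    best_params = {k: v.data.copy() for k, v in params_t.items()}
    best_epoch = -1

    for epoch in range(config.epochs):
        chosen: list[np.ndarray] = []
        counts: dict[str, int] = {}
        for s, idx in train_idx_by_subject.items():
            take = min(len(idx), config.per_subject_cap)
            sel = rng.choice(idx, size=take, replace=False)
            chosen.append(sel)
            counts[s] = int(take)
        order = np.concatenate(chosen)
        rng.shuffle(order)
        history["sampled_per_subject"].append(counts)

        epoch_losses = []
        for b0 in range(0, len(order), config.batch_size):
            batch_idx = order[b0 : b0 + config.batch_size]
            xb = flat[batch_idx].copy()
            flips = rng.random(len(xb)) < config.flip_prob
            if flips.any():
                imgs = xb[flips].reshape(-1, *IMG_SHAPE)
                xb[flips] = imgs[:, :, ::-1].reshape(-1, IMG_DIM)
            loss = _batch_loss(params_t, config, xb, rng, train=True)
            loss.total_tensor.backward()
            opt.step()
            epoch_losses.append(loss.total)
        history["train_loss"].append(float(np.mean(epoch_losses)))

        val_loss = _batch_loss(params_t, config, val_x, rng, train=False).total
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.data.copy() for k, v in params_t.items()}
            best_epoch = epoch

    history["best_epoch"] = best_epoch
    history["val_subjects"] = sorted(val_subjects)
    return TrainedVae(config=config, params=best_params, history=history)
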