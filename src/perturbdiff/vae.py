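"""Gaussian VAE compressing expression profiles into a low-dimensional latent.

The encoder is an MLP predicting the posterior mean and log-variance of the
latent z for each profile; the decoder maps z back to expression space with a
linear output layer (expression values are real-valued, roughly centred after
quantile normalisation, so no output squashing is applied).

Training objective (per batch of N samples, latent dimension d):

    L = (1/N) Σ_i ||x_i − x̂_i||²  +  k · (1/N) Σ_i Σ_j (μ_ij² + σ_ij² − log σ_ij² − 1)

The KL term is written without the conventional 1/2 factor; the weight ``k``
(default 1) can absorb constant factors, and ``kl_half=True`` switches to the
standard Gaussian KL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ._nn import Adam, Sequential, mlp
from .data_io import ExpressionMatrix

__all__ = ["VaeParams", "LatentPosterior", "GaussianVAE", "vae_loss", "train_vae"]


@dataclass(frozen=True)
class VaeParams:
    input_dim: int
    latent_dim: int = 256
    encoder_hidden: tuple = (128, 128)
    decoder_hidden: tuple = (128, 128)
    kl_weight: float = 1.0
    kl_half: bool = False
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.latent_dim < self.input_dim:
            raise ValueError("latent_dim must satisfy 0 < latent_dim < input_dim")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z|x): mean and log-variance per sample."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must share a shape")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("posterior parameters must be finite")


def reparameterize(post: LatentPosterior, noise: np.ndarray) -> np.ndarray:
    """z = μ + exp(½·logvar) ⊙ ε for caller-supplied ε ~ N(0, I)."""
    if noise.shape != post.mu.shape:
        raise ValueError(f"noise shape {noise.shape} != posterior {post.mu.shape}")
    return post.mu + np.exp(0.5 * post.logvar) * noise


def vae_loss(x: np.ndarray, xhat: np.ndarray, post: LatentPosterior,
             k: float = 1.0, kl_half: bool = False) -> Dict[str, float]:
    """Reconstruction + weighted KL, returned with its components.

    recon = mean over samples of the squared error summed over genes;
    kl    = mean over samples of Σ_dims (μ² + σ² − log σ² − 1), halved when
    ``kl_half``. total = recon + k·kl exactly.
    """
    if x.shape != xhat.shape:
        raise ValueError("x and xhat shapes differ")
    recon = float(np.mean(np.sum((x - xhat) ** 2, axis=1)))
    var = np.exp(post.logvar)
    kl_per_sample = np.sum(post.mu ** 2 + var - post.logvar - 1.0, axis=1)
    kl = float(np.mean(kl_per_sample))
    if kl_half:
        kl *= 0.5
    for name, value in (("recon", recon), ("kl", kl)):
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite {name} term in VAE loss")
    return {"recon": recon, "kl": kl, "total": recon + k * kl}


class GaussianVAE:
    """MLP encoder/decoder pair with explicit-gradient training."""

    def __init__(self, params: VaeParams):
        params.validate()
        self.params = params
        rng = np.random.default_rng(params.seed)
        d, g = params.latent_dim, params.input_dim
        self.encoder: Sequential = mlp(
            [g, *params.encoder_hidden, 2 * d], rng)
        self.decoder: Sequential = mlp(
            [d, *params.decoder_hidden, g], rng)

    # -- inference ---------------------------------------------------------
    def encode(self, x: np.ndarray) -> LatentPosterior:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.params.input_dim:
            raise ValueError(
                f"input has {x.shape[1]} genes, encoder expects {self.params.input_dim}")
        if not np.all(np.isfinite(x)):
            raise ValueError("encoder input must be finite")
        h = self.encoder.forward(x)
        d = self.params.latent_dim
        return LatentPosterior(h[:, :d], h[:, d:])

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.params.latent_dim:
            raise ValueError(
                f"latent has {z.shape[1]} dims, decoder expects {self.params.latent_dim}")
        return self.decoder.forward(z)

    # -- training ----------------------------------------------------------
    def _train_step(self, x: np.ndarray, eps: np.ndarray, opt: Adam,
                    ) -> Dict[str, float]:
        n = x.shape[0]
        post = self.encode(x)
        z = reparameterize(post, eps)
        xhat = self.decoder.forward(z)
        losses = vae_loss(x, xhat, post, self.params.kl_weight, self.params.kl_half)

        opt.zero_grad()
        g_xhat = 2.0 * (xhat - x) / n
        g_z = self.decoder.backward(g_xhat)
        k = self.params.kl_weight * (0.5 if self.params.kl_half else 1.0)
        var = np.exp(post.logvar)
        g_mu = g_z + k * 2.0 * post.mu / n
        g_logvar = g_z * 0.5 * (z - post.mu) + k * (var - 1.0) / n
        self.encoder.backward(np.concatenate([g_mu, g_logvar], axis=1))
        opt.step()
        return losses

    def fit(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        return train_vae_inplace(self, matrix)

    # -- checkpointing -----------------------------------------------------
    def weight_arrays(self):
        return self.encoder.weight_arrays() + self.decoder.weight_arrays()

    def set_weight_arrays(self, arrays) -> None:
        n_enc = len(self.encoder.weight_arrays())
        self.encoder.set_weight_arrays(arrays[:n_enc])
        self.decoder.set_weight_arrays(arrays[n_enc:])


def train_vae_inplace(model: GaussianVAE, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Seeded minibatch training; returns the per-epoch loss log."""
    p = model.params
    x = matrix.values
    if x.shape[0] == 0:
        raise ValueError("cannot train on an empty matrix")
    rng = np.random.default_rng(p.seed + 1)
    opt = Adam([model.encoder, model.decoder], lr=p.learning_rate)
    log = []
    for epoch in range(p.epochs):
        order = rng.permutation(x.shape[0])
        sums = {"recon": 0.0, "kl": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, x.shape[0], p.batch_size):
            batch = x[order[start:start + p.batch_size]]
            eps = rng.standard_normal((batch.shape[0], p.latent_dim))
            losses = model._train_step(batch, eps, opt)
            if not np.isfinite(losses["total"]):
                raise FloatingPointError(
                    f"VAE training diverged at epoch {epoch} (loss={losses['total']})")
            for key in sums:
                sums[key] += losses[key]
            n_batches += 1
        log.append({"epoch": epoch,
                    **{k: v / n_batches for k, v in sums.items()}})
    return pd.DataFrame(log)


def train_vae(matrix: ExpressionMatrix, params: VaeParams,
              ) -> Tuple[GaussianVAE, pd.DataFrame]:
    """Train a fresh VAE on ``matrix``; fully determined by ``params.seed``."""
    model = GaussianVAE(params)
    history = train_vae_inplace(model, matrix)
    return model, history
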