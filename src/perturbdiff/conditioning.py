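"""Condition-vector construction and the conditional denoising network.

The condition vector c fuses four branches — basal (paired-control) expression
through an MLP, a fixed-width compound feature vector, and dose and time
scalars through independently parameterised MLPs — concatenated and compressed
by a fusion MLP τ. The denoiser consumes (z_t, timestep embedding, c) and
emits the reverse-step mean μθ and the variance-interpolation vector
s ∈ [0,1]^d (sigmoid output, so the bound holds by construction).

Compound featurization is pluggable: the default backend hashes circular
substructures (a folded Morgan fingerprint, unit-normalised); a table backend
loads externally precomputed per-SMILES embeddings from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from ._nn import Linear, Sequential, Tanh, mlp, sigmoid

__all__ = [
    "ConditionInputs", "ConditionConfig", "MorganFeaturizer", "TableFeaturizer",
    "featurize_compound", "ConditionEncoder", "embed_conditions",
    "TimestepEmbedding", "Denoiser", "DenoiserOutput", "denoise",
    "DoseTimeTransform", "FeaturizationError",
]


class FeaturizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# compound featurizers


class MorganFeaturizer:
    """Hashed circular-substructure fingerprint folded to ``output_dim``.

    Deterministic and canonicalisation-invariant: two SMILES spellings of the
    same molecule give the same vector. Vectors are unit-normalised so cosine
    similarity between compounds is directly meaningful.
    """

    name = "hashed"

    def __init__(self, output_dim: int = 64, radius: int = 2):
        self.output_dim = int(output_dim)
        self.radius = int(radius)
        self._cache: Dict[str, np.ndarray] = {}

    def featurize(self, smiles: str) -> np.ndarray:
        if smiles in self._cache:
            return self._cache[smiles]
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator
        RDLogger.DisableLog("rdApp.error")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise FeaturizationError(f"unparsable SMILES {smiles!r}")
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.output_dim)
        bits = np.array(gen.GetFingerprint(mol), dtype=float)
        norm = np.linalg.norm(bits)
        vec = bits / norm if norm > 0 else bits
        self._cache[smiles] = vec
        return vec


class TableFeaturizer:
    """Adapter for externally precomputed per-SMILES embeddings.

    Reads a CSV with columns ``smiles, v1..vk``; lookup is by canonical
    SMILES so spelling variants resolve to the same row.
    """

    name = "table"

    def __init__(self, path):
        from .data_io import canonical_smiles
        df = pd.read_csv(path)
        if "smiles" not in df.columns or df.shape[1] < 2:
            raise FeaturizationError(
                f"{path}: expected columns smiles, v1..vk")
        self.output_dim = df.shape[1] - 1
        self._table: Dict[str, np.ndarray] = {}
        for _, row in df.iterrows():
            key = canonical_smiles(str(row["smiles"])) or str(row["smiles"])
            self._table[key] = row.iloc[1:].to_numpy(dtype=float)
        self._canon = canonical_smiles

    def featurize(self, smiles: str) -> np.ndarray:
        key = self._canon(smiles) or smiles
        if key not in self._table:
            raise FeaturizationError(f"no embedding for SMILES {smiles!r}")
        return self._table[key]


def featurize_compound(smiles: str, featurizer) -> np.ndarray:
    """Fixed-width deterministic feature vector for one compound."""
    vec = np.asarray(featurizer.featurize(smiles), dtype=float)
    if vec.ndim != 1 or vec.shape[0] != featurizer.output_dim:
        raise FeaturizationError(
            f"featurizer {featurizer.name!r} returned shape {vec.shape}, "
            f"expected ({featurizer.output_dim},)")
    return vec


# ---------------------------------------------------------------------------
# dose/time scalar transforms


@dataclass
class DoseTimeTransform:
    """log10-dose standardised by train statistics; time as fraction of a day."""

    dose_mean: float = 0.0
    dose_sd: float = 1.0

    def fit_doses(self, doses: np.ndarray) -> "DoseTimeTransform":
        logd = np.log10(np.asarray(doses, dtype=float))
        self.dose_mean = float(np.mean(logd))
        self.dose_sd = float(np.std(logd)) or 1.0
        return self

    def dose(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        if np.any(d <= 0):
            raise ValueError("dose must be positive (µM)")
        return (np.log10(d) - self.dose_mean) / self.dose_sd

    @staticmethod
    def time(time) -> np.ndarray:
        t = np.asarray(time, dtype=float)
        if np.any(t <= 0):
            raise ValueError("time must be positive (h)")
        return t / 24.0


# ---------------------------------------------------------------------------
# condition encoder


@dataclass(frozen=True)
class ConditionInputs:
    basal: np.ndarray
    smiles: str
    dose: float
    time: float


@dataclass(frozen=True)
class ConditionConfig:
    n_genes: int
    compound_dim: int = 64
    basal_hidden: tuple = (64,)
    basal_dim: int = 16
    dose_hidden: tuple = (16,)
    dose_dim: int = 8
    time_hidden: tuple = (16,)
    time_dim: int = 8
    fusion_hidden: tuple = (64,)
    condition_dim: int = 32
    use_basal: bool = True
    use_compound: bool = True
    use_dose: bool = True
    use_time: bool = True


class ConditionEncoder:
    """Branch MLPs plus fusion MLP τ producing the condition vector c.

    Any branch can be ablated (``use_* = False``): its contribution is replaced
    by a zero vector of the same width, so downstream shapes never change.
    """

    def __init__(self, config: ConditionConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.basal_net = mlp([c.n_genes, *c.basal_hidden, c.basal_dim], rng)
        self.dose_net = mlp([1, *c.dose_hidden, c.dose_dim], rng)
        self.time_net = mlp([1, *c.time_hidden, c.time_dim], rng)
        concat_dim = c.basal_dim + c.compound_dim + c.dose_dim + c.time_dim
        self.fusion = mlp([concat_dim, *c.fusion_hidden, c.condition_dim], rng)
        self._widths = (c.basal_dim, c.compound_dim, c.dose_dim, c.time_dim)

    def forward(self, basal: np.ndarray, compound: np.ndarray,
                dose_t: np.ndarray, time_t: np.ndarray) -> np.ndarray:
        cfg = self.config
        n = basal.shape[0]
        hb = (self.basal_net.forward(basal) if cfg.use_basal
              else np.zeros((n, cfg.basal_dim)))
        hc = (compound if cfg.use_compound
              else np.zeros((n, cfg.compound_dim)))
        hd = (self.dose_net.forward(dose_t.reshape(-1, 1)) if cfg.use_dose
              else np.zeros((n, cfg.dose_dim)))
        ht = (self.time_net.forward(time_t.reshape(-1, 1)) if cfg.use_time
              else np.zeros((n, cfg.time_dim)))
        return self.fusion.forward(np.concatenate([hb, hc, hd, ht], axis=1))

    def backward(self, g_c: np.ndarray) -> None:
        cfg = self.config
        g = self.fusion.backward(g_c)
        wb, wc, wd, wt = self._widths
        gb, _, gd, gt = np.split(g, np.cumsum([wb, wc, wd])[:3], axis=1)
        if cfg.use_basal:
            self.basal_net.backward(gb)
        if cfg.use_dose:
            self.dose_net.backward(gd)
        if cfg.use_time:
            self.time_net.backward(gt)

    def parameters(self):
        return (self.basal_net.parameters() + self.dose_net.parameters()
                + self.time_net.parameters() + self.fusion.parameters())

    def weight_arrays(self):
        return (self.basal_net.weight_arrays() + self.dose_net.weight_arrays()
                + self.time_net.weight_arrays() + self.fusion.weight_arrays())

    def set_weight_arrays(self, arrays):
        nets = [self.basal_net, self.dose_net, self.time_net, self.fusion]
        i = 0
        for net in nets:
            k = len(net.weight_arrays())
            net.set_weight_arrays(arrays[i:i + k])
            i += k


def embed_conditions(inputs: ConditionInputs, encoder: ConditionEncoder,
                     featurizer, transform: DoseTimeTransform) -> np.ndarray:
    """Condition vector c for a single (basal, smiles, dose, time) tuple."""
    basal = np.atleast_2d(np.asarray(inputs.basal, dtype=float))
    comp = featurize_compound(inputs.smiles, featurizer)[None, :]
    dose_t = np.atleast_1d(transform.dose(inputs.dose))
    time_t = np.atleast_1d(transform.time(inputs.time))
    return encoder.forward(basal, comp, dose_t, time_t)[0]


# ---------------------------------------------------------------------------
# timestep embedding and denoiser


class TimestepEmbedding:
    """Sinusoidal encoding of the integer timestep through one linear layer."""

    def __init__(self, T: int, width: int, rng: np.random.Generator):
        if width % 2:
            raise ValueError("timestep embedding width must be even")
        t = np.arange(1, T + 1, dtype=float)[:, None]
        freqs = np.exp(-np.log(10000.0) * np.arange(width // 2) / (width // 2))
        angles = t * freqs[None, :]
        self.table = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
        self.linear = Linear(width, width, rng)
        self.T = T

    def forward(self, t_idx: np.ndarray) -> np.ndarray:
        t_idx = np.atleast_1d(np.asarray(t_idx, dtype=int))
        if np.any(t_idx < 1) or np.any(t_idx > self.T):
            raise ValueError(f"timestep outside 1..{self.T}")
        return self.linear.forward(self.table[t_idx - 1])

    def backward(self, g: np.ndarray) -> None:
        self.linear.backward(g)

    def parameters(self):
        return self.linear.parameters()

    def weight_arrays(self):
        return [self.linear.W, self.linear.b]

    def set_weight_arrays(self, arrays):
        seq = Sequential([self.linear])
        seq.set_weight_arrays(arrays)
        self.linear = seq.layers[0]


@dataclass
class DenoiserOutput:
    """Predicted reverse-step mean and variance-interpolation vector."""

    mu: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.s.shape:
            raise ValueError("mu and s must share a shape")
        if np.any(self.s < 0) or np.any(self.s > 1):
            raise ValueError("interpolation vector s must lie in [0, 1]")


class Denoiser:
    """MLP on concat(z_t, timestep embedding, c) with (μθ, s) output heads.

    The mean head is parameterised through noise prediction: the network
    emits ε̂ and the step mean is formed analytically as
    μθ = (z_t − β_t/√(1−ᾱ_t)·ε̂)/√α_t. This keeps the Gaussian-NLL loss
    weights on a manageable scale across timesteps (the forward-posterior
    variance β̃_t is ~1e-5 at small t, so a directly predicted mean would
    need unattainable precision there); set ``parameterization="mu"`` to
    predict μθ directly. Either way the forward contract is (μθ, s).
    """

    def __init__(self, latent_dim: int, condition_dim: int,
                 rng: np.random.Generator, T: int = 100,
                 hidden: tuple = (128, 128), t_embed_dim: int = 32,
                 schedule=None, parameterization: str = "eps"):
        if parameterization not in ("eps", "mu"):
            raise ValueError("parameterization must be 'eps' or 'mu'")
        if parameterization == "eps" and schedule is None:
            raise ValueError("eps parameterization needs the noise schedule")
        if schedule is not None and schedule.T != T:
            raise ValueError("schedule T differs from denoiser T")
        self.parameterization = parameterization
        self.schedule = schedule
        self.latent_dim = latent_dim
        self.condition_dim = condition_dim
        self.t_embed = TimestepEmbedding(T, t_embed_dim, rng)
        in_dim = latent_dim + t_embed_dim + condition_dim
        body_sizes = [in_dim, *hidden]
        layers = []
        for i in range(len(body_sizes) - 1):
            layers.append(Linear(body_sizes[i], body_sizes[i + 1], rng))
            layers.append(Tanh())
        self.body = Sequential(layers)
        self.head_mu = Linear(hidden[-1], latent_dim, rng, init_scale=0.1)
        self.head_s = Linear(hidden[-1], latent_dim, rng, init_scale=0.1)
        self._widths = (latent_dim, t_embed_dim, condition_dim)
        self._cache_s: Optional[np.ndarray] = None

    @property
    def T(self) -> int:
        return self.t_embed.T

    def forward(self, z_t: np.ndarray, t, c: np.ndarray) -> DenoiserOutput:
        z_t = np.atleast_2d(np.asarray(z_t, dtype=float))
        c = np.atleast_2d(np.asarray(c, dtype=float))
        t_arr = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=int)),
                                (z_t.shape[0],))
        if c.shape[0] == 1 and z_t.shape[0] > 1:
            c = np.broadcast_to(c, (z_t.shape[0], c.shape[1]))
        temb = self.t_embed.forward(t_arr)
        h = self.body.forward(np.concatenate([z_t, temb, c], axis=1))
        raw = self.head_mu.forward(h)
        if self.parameterization == "eps":
            sched = self.schedule
            beta = sched.beta_at(t_arr)[:, None]
            ab = sched.alpha_bar_at(t_arr)[:, None]
            coef = beta / (np.sqrt(1.0 - ab) * np.sqrt(1.0 - beta))
            mu = z_t / np.sqrt(1.0 - beta) - coef * raw
            self._cache_mu_coef = -coef
        else:
            mu = raw
            self._cache_mu_coef = None
        s = sigmoid(self.head_s.forward(h))
        self._cache_s = s
        return DenoiserOutput(mu=mu, s=s)

    def backward(self, g_mu: np.ndarray, g_s: np.ndarray) -> np.ndarray:
        """Backprop from (dL/dμ, dL/ds); returns dL/dc for the encoder."""
        s = self._cache_s
        g_logits = g_s * s * (1.0 - s)
        if self._cache_mu_coef is not None:
            g_mu = g_mu * self._cache_mu_coef
        g_h = self.head_mu.backward(g_mu) + self.head_s.backward(g_logits)
        g_in = self.body.backward(g_h)
        d, w, _ = self._widths
        self.t_embed.backward(g_in[:, d:d + w])
        return g_in[:, d + w:]

    def parameters(self):
        return (self.t_embed.parameters() + self.body.parameters()
                + self.head_mu.parameters() + self.head_s.parameters())

    def weight_arrays(self):
        return (self.t_embed.weight_arrays() + self.body.weight_arrays()
                + [self.head_mu.W, self.head_mu.b, self.head_s.W, self.head_s.b])

    def set_weight_arrays(self, arrays):
        n_t = len(self.t_embed.weight_arrays())
        n_b = len(self.body.weight_arrays())
        self.t_embed.set_weight_arrays(arrays[:n_t])
        self.body.set_weight_arrays(arrays[n_t:n_t + n_b])
        rest = arrays[n_t + n_b:]
        for layer, (W, b) in zip((self.head_mu, self.head_s),
                                 [(rest[0], rest[1]), (rest[2], rest[3])]):
            layer.W = W.astype(float).copy()
            layer.b = b.astype(float).copy()


def denoise(z_t: np.ndarray, t, c: np.ndarray, denoiser: Denoiser) -> DenoiserOutput:
    """One conditional denoiser evaluation; deterministic given weights."""
    return denoiser.forward(z_t, t, c)
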