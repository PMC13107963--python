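"""Model/Results facade tying the pipeline together.

``PerturbationDiffusionModel`` is constructed from paired expression data and
metadata; ``fit`` pretrains the VAE on perturbed profiles, encodes them to
latent space, and trains the conditional latent diffusion model, returning a
``PerturbationDiffusionResults`` that can generate perturbed profiles for new
conditions, compute diagnostics and print a summary table.

Latents handed to the diffusion model are the VAE posterior means,
standardised per dimension by their training mean/SD; generated latents are
de-standardised before decoding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import diffusion
from .conditioning import (ConditionConfig, ConditionEncoder, Denoiser,
                           DoseTimeTransform, MorganFeaturizer,
                           featurize_compound)
from .data_io import ExpressionMatrix, pair_records, records_from_metadata
from .vae import GaussianVAE, VaeParams, train_vae

__all__ = ["PerturbationDiffusionModel", "PerturbationDiffusionResults",
           "LdmConfig"]


@dataclass(frozen=True)
class LdmConfig:
    """Hyperparameters of the latent diffusion stage."""

    t_steps: int = 100
    beta_min: float = 1e-5
    beta_max: float = 0.01
    latent_dim: int = 8
    denoiser_hidden: tuple = (128, 128)
    t_embed_dim: int = 32
    condition: Optional[ConditionConfig] = None
    train: diffusion.DiffusionTrainConfig = field(
        default_factory=diffusion.DiffusionTrainConfig)
    sample_posterior_latents: bool = False   # z0 = posterior mean by default


class PerturbationDiffusionModel:
    """Condition-aware latent diffusion model of drug-perturbed expression.

    Parameters
    ----------
    perturbed, control : ExpressionMatrix
        Row sets referenced by the metadata's perturbed/control records; gene
        order must agree between the two.
    metadata : DataFrame
        Columns sample_id, pair_id, cell_line, smiles, dose_um, time_h, role.
    """

    def __init__(self, perturbed: ExpressionMatrix, control: ExpressionMatrix,
                 metadata: pd.DataFrame, vae_params: Optional[VaeParams] = None,
                 ldm: Optional[LdmConfig] = None, featurizer=None):
        if perturbed.gene_ids != control.gene_ids:
            raise ValueError("control/perturbed gene orders differ")
        self.perturbed = perturbed
        self.control = control
        self.metadata = metadata.copy()
        self.records = records_from_metadata(metadata)
        self.pairs = pair_records(self.records)
        if not self.pairs:
            raise ValueError("no control/perturbed pairs could be formed")
        self.ldm = ldm or LdmConfig()
        g = perturbed.n_genes
        self.featurizer = featurizer or MorganFeaturizer(output_dim=64)
        self.vae_params = vae_params or VaeParams(
            input_dim=g, latent_dim=self.ldm.latent_dim)
        if self.vae_params.latent_dim != self.ldm.latent_dim:
            raise ValueError("VAE latent_dim and LdmConfig.latent_dim differ")
        cond = self.ldm.condition or ConditionConfig(
            n_genes=g, compound_dim=self.featurizer.output_dim)
        if cond.compound_dim != self.featurizer.output_dim:
            raise ValueError("condition compound_dim != featurizer output_dim")
        self._cond_config = cond

    @classmethod
    def from_simulation(cls, config=None, **kwargs):
        """Build model and ground truth from the bundled simulator."""
        from .simulate import SimConfig, simulate_dataset
        config = config or SimConfig()
        control, perturbed, metadata, truth = simulate_dataset(config)
        model = cls(perturbed, control, metadata, **kwargs)
        model.truth = truth
        return model

    # ------------------------------------------------------------------
    def _condition_arrays(self, transform: DoseTimeTransform,
                          ) -> Dict[str, np.ndarray]:
        ctrl = self.control.to_dataframe()
        basal = np.vstack([ctrl.loc[p.control_id].to_numpy() for p in self.pairs])
        comp = np.vstack([featurize_compound(p.smiles, self.featurizer)
                          for p in self.pairs])
        dose = transform.dose(np.array([p.dose for p in self.pairs]))
        time = transform.time(np.array([p.time for p in self.pairs]))
        return {"basal": basal, "compound": comp, "dose": dose, "time": time}

    def fit(self, seed: int = 0, vae_history: bool = True,
            ) -> "PerturbationDiffusionResults":
        """Pretrain the VAE, encode latents, train the diffusion model."""
        vae_params = VaeParams(**{**asdict(self.vae_params), "seed": seed})
        target = self.perturbed.subset([p.perturbed_id for p in self.pairs])
        vae, vae_log = train_vae(target, vae_params)

        post = vae.encode(target.values)
        if self.ldm.sample_posterior_latents:
            rng = np.random.default_rng(seed + 10)
            z0 = post.mu + np.exp(0.5 * post.logvar) * rng.standard_normal(
                post.mu.shape)
        else:
            z0 = post.mu
        z_mean = z0.mean(axis=0)
        z_sd = z0.std(axis=0)
        z_sd[z_sd == 0] = 1.0
        z0s = (z0 - z_mean) / z_sd

        transform = DoseTimeTransform().fit_doses(
            np.array([p.dose for p in self.pairs]))
        conditions = self._condition_arrays(transform)
        schedule = diffusion.build_schedule(self.ldm.t_steps, self.ldm.beta_min,
                                            self.ldm.beta_max)
        rng = np.random.default_rng(seed + 20)
        encoder = ConditionEncoder(self._cond_config, rng)
        denoiser = Denoiser(self.ldm.latent_dim, self._cond_config.condition_dim,
                            rng, T=self.ldm.t_steps,
                            hidden=self.ldm.denoiser_hidden,
                            t_embed_dim=self.ldm.t_embed_dim,
                            schedule=schedule)
        train_cfg = diffusion.DiffusionTrainConfig(
            **{**asdict(self.ldm.train), "seed": seed + 30})
        diff_log = diffusion.train_diffusion(z0s, conditions, schedule, encoder,
                                             denoiser, train_cfg)
        return PerturbationDiffusionResults(
            model=self, vae=vae, encoder=encoder, denoiser=denoiser,
            schedule=schedule, transform=transform,
            latent_mean=z_mean, latent_sd=z_sd, seed=seed,
            vae_history=vae_log if vae_history else None,
            diffusion_history=diff_log)


class PerturbationDiffusionResults:
    """Fitted VAE + conditional diffusion model with generation utilities."""

    def __init__(self, model, vae: GaussianVAE, encoder, denoiser, schedule,
                 transform, latent_mean, latent_sd, seed,
                 vae_history, diffusion_history):
        self.model = model
        self.vae = vae
        self.encoder = encoder
        self.denoiser = denoiser
        self.schedule = schedule
        self.transform = transform
        self.latent_mean = latent_mean
        self.latent_sd = latent_sd
        self.seed = seed
        self.vae_history = vae_history
        self.diffusion_history = diffusion_history

    # ------------------------------------------------------------------
    def _conditions_from_frame(self, conditions: pd.DataFrame,
                               ) -> Dict[str, np.ndarray]:
        required = {"basal_sample_id", "smiles", "dose_um", "time_h"}
        missing = required - set(conditions.columns)
        if missing:
            raise ValueError(f"conditions frame missing columns {sorted(missing)}")
        ctrl = self.model.control.to_dataframe()
        basal = np.vstack([ctrl.loc[s].to_numpy()
                           for s in conditions["basal_sample_id"]])
        comp = np.vstack([featurize_compound(s, self.model.featurizer)
                          for s in conditions["smiles"]])
        return {"basal": basal, "compound": comp,
                "dose": self.transform.dose(conditions["dose_um"].to_numpy()),
                "time": self.transform.time(conditions["time_h"].to_numpy())}

    def sample_latents(self, conditions: pd.DataFrame, n_per_condition: int = 1,
                       seed: Optional[int] = None) -> np.ndarray:
        """Generate ẑ₀ draws (de-standardised), condition-major ordering."""
        cond = self._conditions_from_frame(conditions)
        z = diffusion.sample(cond, self.schedule, self.encoder, self.denoiser,
                             n=n_per_condition,
                             seed=self.seed + 40 if seed is None else seed)
        return z * self.latent_sd + self.latent_mean

    def predict(self, conditions: pd.DataFrame, n_per_condition: int = 1,
                seed: Optional[int] = None) -> ExpressionMatrix:
        """Decode generated latents into perturbed expression profiles.

        Returns one row per (condition, draw), condition-major, with sample
        ids ``gen_<row>_<draw>``.
        """
        z = self.sample_latents(conditions, n_per_condition, seed)
        x = self.vae.decode(z)
        ids = [f"gen_{i}_{j}" for i in range(len(conditions))
               for j in range(n_per_condition)]
        return ExpressionMatrix(x, ids, list(self.model.perturbed.gene_ids))

    def reconstruction(self, per_gene: bool = False):
        """VAE reconstruction diagnostics on the training pairs."""
        from .evaluate import reconstruction_metrics
        target = self.model.perturbed.subset(
            [p.perturbed_id for p in self.model.pairs])
        post = self.vae.encode(target.values)
        xhat = self.vae.decode(post.mu)
        return reconstruction_metrics(target.values, xhat, per_gene=per_gene)

    def summary(self) -> str:
        recon = self.reconstruction()
        final_nll = float(self.diffusion_history["nll"].iloc[-1])
        rows = [
            ("No. paired samples", f"{len(self.model.pairs)}"),
            ("No. genes", f"{self.model.perturbed.n_genes}"),
            ("Latent dimension", f"{self.vae.params.latent_dim}"),
            ("Diffusion timesteps T", f"{self.schedule.T}"),
            ("Beta endpoints", f"{self.schedule.beta_min:g}, "
                               f"{self.schedule.beta_max:g}"),
            ("Seed", f"{self.seed}"),
            ("VAE recon PCC (train)", f"{recon.pcc_mean:.3f} ± {recon.pcc_sd:.3f}"),
            ("VAE recon R2 (train)", f"{recon.r2_mean:.3f} ± {recon.r2_sd:.3f}"),
            ("Final diffusion NLL", f"{final_nll:.4f}"),
        ]
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Perturbation Latent Diffusion Results",
                 "=" * (width + 20)]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Persist weights, schedule and normalisation state to one .npz."""
        meta = {
            "vae_params": asdict(self.vae.params),
            "ldm": {"t_steps": self.schedule.T,
                    "beta_min": self.schedule.beta_min,
                    "beta_max": self.schedule.beta_max},
            "transform": {"dose_mean": self.transform.dose_mean,
                          "dose_sd": self.transform.dose_sd},
            "seed": self.seed,
        }
        arrays = {}
        for prefix, arrs in (("vae", self.vae.weight_arrays()),
                             ("enc", self.encoder.weight_arrays()),
                             ("den", self.denoiser.weight_arrays())):
            for i, a in enumerate(arrs):
                arrays[f"{prefix}_{i:03d}"] = a
        np.savez(path, latent_mean=self.latent_mean, latent_sd=self.latent_sd,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.latent_mean = data["latent_mean"]
            self.latent_sd = data["latent_sd"]
            for prefix, setter in (("vae", self.vae.set_weight_arrays),
                                   ("enc", self.encoder.set_weight_arrays),
                                   ("den", self.denoiser.set_weight_arrays)):
                keys = sorted(k for k in data.files if k.startswith(prefix + "_"))
                setter([data[k] for k in keys])
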