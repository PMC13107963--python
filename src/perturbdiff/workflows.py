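"""Reproducible desk-scale studies: simulate, fit, generate, evaluate.

These functions wire the simulator, the VAE, the latent diffusion model and
the evaluation statistics into self-contained, seeded studies whose outputs
are plain dictionaries of numbers. They define the package's reference
experimental protocol:

* ``vae_overfit_study`` — capacity check: overfit a small set of simulated
  profiles and report reconstruction accuracy.
* ``parameter_recovery_study`` — the full pipeline on the simulator's default
  study conditions, measuring how well generated profiles recover the known
  conditional means, gene–gene correlation structure (top-k overlap against
  its hypergeometric null k²/G) and latent dose ordering.
* ``null_overlap_study`` — calibration of the overlap statistic on
  independent noise.

Every derived seed is a small fixed offset of the caller's seed.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .conditioning import ConditionConfig
from .data_io import ExpressionMatrix
from .diffusion import DiffusionTrainConfig
from .evaluate import (correlation_overlap, reconstruction_metrics,
                       trajectory_analysis)
from .model import LdmConfig, PerturbationDiffusionModel
from .simulate import SimConfig, simulate_dataset, truth_conditional_mean
from .vae import VaeParams, train_vae

__all__ = ["vae_overfit_study", "parameter_recovery_study", "null_overlap_study",
           "default_ldm_config"]


def default_ldm_config(n_genes: int, n_steps: int = 20000) -> LdmConfig:
    """Reference LDM hyperparameters for desk-scale (G≈50, d=8) studies."""
    cond = ConditionConfig(n_genes=n_genes, compound_dim=64, condition_dim=64,
                           fusion_hidden=(128,), basal_dim=32, basal_hidden=(64,))
    return LdmConfig(denoiser_hidden=(256, 256), condition=cond,
                     train=DiffusionTrainConfig(n_steps=n_steps, batch_size=256))


def vae_overfit_study(seed: int = 0, n_profiles: int = 64, latent_dim: int = 8,
                      epochs: int = 1500) -> Dict[str, float]:
    """Overfit a small simulated profile set; report reconstruction accuracy.

    Profiles come from a small simulated screen (4 cell lines, 4 compounds),
    so they carry realistic low-dimensional structure; the check is that the
    VAE's capacity suffices to represent them at high fidelity.
    """
    config = SimConfig(n_cell_lines=4, n_compounds=4, doses=(0.1, 1.0),
                       times=(6.0, 24.0), replicates_per_condition=1, seed=seed)
    _, perturbed, _, _ = simulate_dataset(config)
    x = perturbed.values[:n_profiles]
    mat = ExpressionMatrix(x, perturbed.sample_ids[:n_profiles],
                           perturbed.gene_ids)
    params = VaeParams(input_dim=mat.n_genes, latent_dim=latent_dim,
                       epochs=epochs, seed=seed + 1)
    vae, history = train_vae(mat, params)
    xhat = vae.decode(vae.encode(x).mu)
    report = reconstruction_metrics(x, xhat)
    return {"pcc": report.pcc_mean, "r2": report.r2_mean,
            "n_profiles": n_profiles,
            "final_recon": float(history["recon"].iloc[-1]),
            "final_kl": float(history["kl"].iloc[-1])}


def parameter_recovery_study(seed: int = 0,
                             sim_config: Optional[SimConfig] = None,
                             vae_epochs: int = 500,
                             diffusion_steps: int = 20000,
                             k: int = 10,
                             trajectory_draws: int = 500,
                             trajectory_pair=("CL0", "CPD0"),
                             trajectory_time: float = 24.0) -> Dict[str, float]:
    """Full-pipeline parameter recovery on simulated study conditions.

    Fits VAE + LDM on one simulated screen, then generates one profile per
    perturbed sample under that sample's own condition (its paired control as
    the basal input, mirroring the screen's sampling design) and measures:

    * ``condition_mean_pcc`` — mean Pearson r (across genes) between each
      condition's generated mean profile and the simulator's noise-free
      conditional mean;
    * ``overlap_mean`` — mean over compounds of the top-``k``
      correlation-overlap between real and generated sample sets, with
      ``overlap_null`` = k²/G its hypergeometric chance level;
    * ``trajectory_abs_rho`` — |Spearman| of the latent dose trajectory for
      one (cell line, compound) pair at fixed time, ``trajectory_draws``
      generated samples per dose level.
    """
    sim_config = sim_config or SimConfig(seed=seed)
    model = PerturbationDiffusionModel.from_simulation(
        sim_config,
        ldm=default_ldm_config(n_genes=sim_config.n_genes,
                               n_steps=diffusion_steps))
    model.vae_params = VaeParams(
        input_dim=sim_config.n_genes, latent_dim=model.ldm.latent_dim,
        epochs=vae_epochs, encoder_hidden=(256, 256), decoder_hidden=(256, 256))
    results = model.fit(seed=seed + 1)
    truth = model.truth
    meta = model.metadata
    pert = meta[meta.role == "perturbed"].reset_index(drop=True)

    gen_cond = pert.rename(columns={"pair_id": "basal_sample_id"})
    generated = results.predict(gen_cond, n_per_condition=1, seed=seed + 2)
    x_gen = generated.values

    # per-condition mean of generated vs noise-free truth
    cond_cols = ["cell_line", "compound", "dose_um", "time_h"]
    key = pert[cond_cols].astype(str).agg("|".join, axis=1)
    gen_means = pd.DataFrame(x_gen).groupby(key.to_numpy()).mean()
    truth_means = []
    for cond_key in gen_means.index:
        cl, cpd, dose, time = cond_key.split("|")
        truth_means.append(truth_conditional_mean(
            truth, cl, cpd, float(dose), float(time)))
    truth_means = np.vstack(truth_means)
    gm = gen_means.to_numpy()
    gc = gm - gm.mean(axis=1, keepdims=True)
    tc = truth_means - truth_means.mean(axis=1, keepdims=True)
    r = (np.sum(gc * tc, axis=1)
         / np.sqrt(np.sum(gc ** 2, axis=1) * np.sum(tc ** 2, axis=1)))

    # top-k correlation overlap per compound
    pert_df = model.perturbed.to_dataframe()
    overlaps = []
    null = None
    for cpd, grp in pert.groupby("compound"):
        idx = grp.index.to_numpy()
        res = correlation_overlap(pert_df.loc[grp.sample_id].to_numpy(),
                                  x_gen[idx], compound=cpd, k=k)
        if res is not None:
            overlaps.append(res.overlap)
            null = res.null_expectation

    # latent dose trajectory at fixed time
    cl, cpd = trajectory_pair
    levels = pert[(pert.cell_line == cl) & (pert.compound == cpd)
                  & (pert.time_h == trajectory_time)]
    levels = (levels.drop_duplicates("dose_um").sort_values("dose_um")
              .rename(columns={"pair_id": "basal_sample_id"})
              .reset_index(drop=True))
    latents = results.sample_latents(levels, n_per_condition=trajectory_draws,
                                     seed=seed + 3)
    groups = list(latents.reshape(len(levels), trajectory_draws, -1))
    trajectory = trajectory_analysis(groups, levels=list(levels.dose_um))

    recon = results.reconstruction()
    return {
        "condition_mean_pcc": float(np.mean(r)),
        "condition_mean_pcc_min": float(np.min(r)),
        "n_conditions": int(gm.shape[0]),
        "overlap_mean": float(np.mean(overlaps)),
        "overlap_null": float(null),
        "n_compounds": len(overlaps),
        "overlap_k": k,
        "trajectory_abs_rho": abs(trajectory.statistic),
        "n_trajectory_draws": trajectory_draws,
        "vae_train_pcc": recon.pcc_mean,
        "n_samples": len(model.pairs),
    }


def null_overlap_study(seed: int = 0, n_draws: int = 200, n_genes: int = 300,
                       k: int = 30, n_samples: int = 40) -> Dict[str, float]:
    """Overlap statistic on pairs of independent Gaussian matrices.

    Under independence the overlap of two top-k sets follows the
    hypergeometric law with mean k²/G; the study reports the empirical mean,
    its standard error and the theoretical expectation.
    """
    rng = np.random.default_rng(seed)
    overlaps = []
    for _ in range(n_draws):
        a = rng.standard_normal((n_samples, n_genes))
        b = rng.standard_normal((n_samples, n_genes))
        res = correlation_overlap(a, b, k=k, min_samples=2)
        overlaps.append(res.overlap)
    overlaps = np.asarray(overlaps, dtype=float)
    return {"mean_overlap": float(overlaps.mean()),
            "se": float(overlaps.std(ddof=1) / np.sqrt(n_draws)),
            "expected": k ** 2 / n_genes,
            "n_draws": n_draws}
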