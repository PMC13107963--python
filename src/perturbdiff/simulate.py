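"""Synthetic paired control/perturbed expression data with known ground truth.

The simulator emulates the structure of an L1000-style perturbation screen at
desk scale: a handful of cell lines with distinct basal expression profiles,
compounds that shift whole correlated gene modules, saturating monotone dose
response, saturating time kinetics, and block-structured residual covariance.
Every draw is fully determined by ``SimConfig.seed``.

Generative model per perturbed sample i::

    x_i = basal(cell_line_i)
          + dose_response(dose_i) * time_kinetics(time_i) * effect(compound_i)
          + eps_i

where eps_i has marginal SD ``noise_sd``, correlation ``module_rho`` within a
gene module and 0 between modules. A control sample is the same cell line's
basal profile plus an independent draw of the same noise (no dose term).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "truth_conditional_mean",
           "BUILTIN_SMILES", "SimConfigError"]


class SimConfigError(ValueError):
    """A SimConfig field violates its contract; the message names the field."""


#: Real, parseable SMILES strings cycled over synthetic compounds so that
#: SMILES-validity filtering and fingerprinting are exercisable offline.
BUILTIN_SMILES = [
    "CCO",                                   # ethanol
    "CC(=O)OC1=CC=CC=C1C(=O)O",              # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",          # caffeine
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",         # ibuprofen
    "CC(=O)NC1=CC=C(O)C=C1",                 # paracetamol
    "C1=CC=C(C=C1)C(=O)O",                   # benzoic acid
    "OCC(O)CO",                              # glycerol
    "C1CCCCC1",                              # cyclohexane
    "CC(=O)C",                               # acetone
    "NCCc1ccc(O)c(O)c1",                     # dopamine
    "OC(=O)CC(O)(CC(O)=O)C(O)=O",            # citric acid
    "Nc1ncnc2n(cnc12)C",                     # 9-methyladenine
    "CCN(CC)CC",                             # triethylamine
    "Clc1ccccc1",                            # chlorobenzene
    "OC1=CC=CC=C1",                          # phenol
    "CSCCC(N)C(=O)O",                        # methionine
]


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale perturbation-screen geometry and noise/effect levels."""

    n_genes: int = 50
    n_modules: int = 5
    n_cell_lines: int = 4
    n_compounds: int = 10
    doses: tuple = (0.1, 1.0, 10.0)          # µM
    times: tuple = (6.0, 24.0)               # h
    replicates_per_condition: int = 20
    basal_spread: float = 1.0                # between-cell-line SD
    module_rho: float = 0.6                  # within-module residual correlation
    effect_scale: float = 2.0
    noise_sd: float = 0.5
    modules_per_compound: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be a positive count")
        if not (1 <= self.n_modules <= self.n_genes):
            raise SimConfigError("n_modules must satisfy 1 <= n_modules <= n_genes")
        if self.n_cell_lines < 1:
            raise SimConfigError("n_cell_lines must be a positive count")
        if self.n_compounds < 1:
            raise SimConfigError("n_compounds must be a positive count")
        doses = np.asarray(self.doses, dtype=float)
        if doses.size == 0 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise SimConfigError("doses must be strictly increasing and positive")
        times = np.asarray(self.times, dtype=float)
        if times.size == 0 or np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise SimConfigError("times must be strictly increasing and positive")
        if self.replicates_per_condition < 1:
            raise SimConfigError("replicates_per_condition must be a positive count")
        if self.basal_spread < 0:
            raise SimConfigError("basal_spread must be nonnegative")
        if not (0.0 <= self.module_rho < 1.0):
            raise SimConfigError("module_rho must lie in [0, 1)")
        if self.effect_scale < 0:
            raise SimConfigError("effect_scale must be nonnegative")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be positive")
        if not (1 <= self.modules_per_compound <= self.n_modules):
            raise SimConfigError(
                "modules_per_compound must satisfy 1 <= modules_per_compound <= n_modules")


@dataclass
class SimTruth:
    """Noise-free generative parameters of one simulated dataset."""

    basal_profiles: Dict[str, np.ndarray]
    compound_effects: Dict[str, np.ndarray]
    affected_modules: Dict[str, tuple]
    module_assignment: np.ndarray            # gene index -> module index
    dose_response: Callable[[float], float]
    time_kinetics: Callable[[float], float]
    config: SimConfig = field(repr=False, default=None)


def _dose_response_fn(doses: Sequence[float]) -> Callable[[float], float]:
    """log1p dose scaling normalized to [0, 1] over the configured grid.

    h(0) = 0 and h is monotone nondecreasing (saturating, mirroring
    pharmacological dose scaling).
    """
    d0 = float(min(doses))
    top = np.log1p(max(doses) / d0)

    def h(dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be nonnegative")
        return float(np.log1p(dose / d0) / top)

    return h


def _time_kinetics_fn(times: Sequence[float]) -> Callable[[float], float]:
    """Saturating first-order kinetics g(t) = t / (t + tau_half)."""
    tau_half = float(np.median(np.asarray(times, dtype=float)))

    def g(time: float) -> float:
        if time < 0:
            raise ValueError("time must be nonnegative")
        return float(time / (time + tau_half))

    return g


def _block_noise(rng: np.random.Generator, n: int, assignment: np.ndarray,
                 rho: float, sd: float) -> np.ndarray:
    """Zero-mean Gaussian noise, correlation rho within modules, 0 between."""
    n_modules = int(assignment.max()) + 1
    shared = rng.standard_normal((n, n_modules))
    indiv = rng.standard_normal((n, assignment.size))
    return sd * (np.sqrt(rho) * shared[:, assignment] + np.sqrt(1.0 - rho) * indiv)


def _make_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    g = config.n_genes
    assignment = (np.arange(g) * config.n_modules) // g
    basal = {
        f"CL{i}": rng.normal(0.0, config.basal_spread, size=g)
        for i in range(config.n_cell_lines)
    }
    effects: Dict[str, np.ndarray] = {}
    affected: Dict[str, tuple] = {}
    for j in range(config.n_compounds):
        name = f"CPD{j}"
        mods = tuple(sorted(rng.choice(config.n_modules,
                                       size=config.modules_per_compound,
                                       replace=False).tolist()))
        vec = np.zeros(g)
        mask = np.isin(assignment, mods)
        vec[mask] = config.effect_scale * rng.standard_normal(mask.sum())
        effects[name] = vec
        affected[name] = mods
    return SimTruth(
        basal_profiles=basal,
        compound_effects=effects,
        affected_modules=affected,
        module_assignment=assignment,
        dose_response=_dose_response_fn(config.doses),
        time_kinetics=_time_kinetics_fn(config.times),
        config=config,
    )


def truth_conditional_mean(truth: SimTruth, cell_line: str, compound: str,
                           dose: float, time: float) -> np.ndarray:
    """Noise-free expected perturbed profile for one condition.

    This is the parameter-recovery oracle: dose 0 (or zero effect) returns the
    basal profile exactly, and the displacement from basal is nondecreasing in
    dose for a fixed (cell line, compound, time).
    """
    if cell_line not in truth.basal_profiles:
        raise KeyError(f"unknown cell line {cell_line!r}")
    if compound not in truth.compound_effects:
        raise KeyError(f"unknown compound {compound!r}")
    scale = truth.dose_response(dose) * truth.time_kinetics(time)
    return truth.basal_profiles[cell_line] + scale * truth.compound_effects[compound]


def simulate_dataset(config: SimConfig):
    """Draw one paired control/perturbed dataset.

    Returns ``(control, perturbed, metadata, truth)`` where the expression
    matrices are samples×genes, metadata is a DataFrame with columns
    sample_id, pair_id, cell_line, smiles, dose_um, time_h, role, and truth
    holds the generative parameters.

    Controls are replicate basal measurements per cell line (one per replicate
    index); each perturbed sample's pair_id points at the control of its cell
    line with the same replicate index.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    cell_lines = sorted(truth.basal_profiles)
    compounds = sorted(truth.compound_effects)
    smiles_of = {c: BUILTIN_SMILES[i % len(BUILTIN_SMILES)]
                 for i, c in enumerate(compounds)}

    # controls: per cell line, one per replicate index
    ctrl_rows, ctrl_ids, ctrl_meta = [], [], []
    for cl in cell_lines:
        noise = _block_noise(rng, config.replicates_per_condition,
                             truth.module_assignment, config.module_rho,
                             config.noise_sd)
        for r in range(config.replicates_per_condition):
            sid = f"ctrl_{cl}_r{r}"
            ctrl_ids.append(sid)
            ctrl_rows.append(truth.basal_profiles[cl] + noise[r])
            ctrl_meta.append(dict(sample_id=sid, pair_id=sid, cell_line=cl,
                                  smiles="", dose_um=0.0, time_h=0.0,
                                  role="control"))

    pert_rows, pert_ids, pert_meta = [], [], []
    for cl in cell_lines:
        for cpd in compounds:
            for dose in config.doses:
                for time in config.times:
                    mean = truth_conditional_mean(truth, cl, cpd, dose, time)
                    noise = _block_noise(rng, config.replicates_per_condition,
                                         truth.module_assignment,
                                         config.module_rho, config.noise_sd)
                    for r in range(config.replicates_per_condition):
                        sid = f"pert_{cl}_{cpd}_d{dose:g}_t{time:g}_r{r}"
                        pert_ids.append(sid)
                        pert_rows.append(mean + noise[r])
                        pert_meta.append(dict(
                            sample_id=sid, pair_id=f"ctrl_{cl}_r{r}",
                            cell_line=cl, smiles=smiles_of[cpd],
                            dose_um=float(dose), time_h=float(time),
                            role="perturbed", compound=cpd))

    control = ExpressionMatrix(np.asarray(ctrl_rows), ctrl_ids, list(gene_ids))
    perturbed = ExpressionMatrix(np.asarray(pert_rows), pert_ids, list(gene_ids))
    metadata = pd.DataFrame(ctrl_meta + pert_meta)
    metadata["compound"] = metadata.get("compound", "").fillna("")
    return control, perturbed, metadata, truth
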