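"""Evaluation statistics for generated expression profiles.

Covers profile-level reconstruction accuracy (per-sample Pearson r and R²),
the top-k gene–gene correlation-overlap statistic with its hypergeometric
null expectation k²/G, correlation heatmap matrices, and ordered-condition
(dose/time) centroid trajectory analysis in latent space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport", "OverlapResult", "TrajectoryResult", "reconstruction_metrics",
    "top_k_correlated_genes", "correlation_overlap", "correlation_heatmap_matrix",
    "trajectory_analysis",
]


@dataclass
class EvalReport:
    pcc_mean: float
    pcc_sd: float
    r2_mean: float
    r2_sd: float
    n_samples: int
    n_excluded: int
    per_sample: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {"pcc_mean": self.pcc_mean, "pcc_sd": self.pcc_sd,
                "r2_mean": self.r2_mean, "r2_sd": self.r2_sd,
                "n_samples": self.n_samples, "n_excluded": self.n_excluded}


def reconstruction_metrics(true: np.ndarray, generated: np.ndarray,
                           per_gene: bool = False,
                           flatten: bool = False) -> EvalReport:
    """Per-sample Pearson r and R² between row-aligned matrices.

    R²_i = 1 − Σ_g (x_ig − x̂_ig)² / Σ_g (x_ig − x̄_i)² with x̄_i the true
    sample's own mean across genes; samples whose true profile has zero
    variance are excluded and counted. ``per_gene`` transposes the analysis
    (metrics across samples per gene); ``flatten`` computes a single pair of
    scores over the raveled matrices instead of a per-row average.
    """
    true = np.asarray(true, dtype=float)
    generated = np.asarray(generated, dtype=float)
    if true.shape != generated.shape:
        raise ValueError(f"shape mismatch {true.shape} vs {generated.shape}")
    if flatten:
        true, generated = true.reshape(1, -1), generated.reshape(1, -1)
    elif per_gene:
        true, generated = true.T, generated.T
    center = true - true.mean(axis=1, keepdims=True)
    ss_tot = np.sum(center ** 2, axis=1)
    valid = ss_tot > 0
    n_excluded = int(np.sum(~valid))
    if n_excluded:
        logger.info("reconstruction_metrics: excluded %d zero-variance rows",
                    n_excluded)
    t, g = true[valid], generated[valid]
    ss_res = np.sum((t - g) ** 2, axis=1)
    r2 = 1.0 - ss_res / ss_tot[valid]
    gc = g - g.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(tc ** 2, axis=1) * np.sum(gc ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom > 0, np.sum(tc * gc, axis=1) / denom, np.nan)
    per_sample = pd.DataFrame({"row": np.flatnonzero(valid), "pcc": pcc, "r2": r2})
    pcc_valid = pcc[np.isfinite(pcc)]
    return EvalReport(
        pcc_mean=float(np.mean(pcc_valid)) if pcc_valid.size else float("nan"),
        pcc_sd=float(np.std(pcc_valid)) if pcc_valid.size else float("nan"),
        r2_mean=float(np.mean(r2)) if r2.size else float("nan"),
        r2_sd=float(np.std(r2)) if r2.size else float("nan"),
        n_samples=int(valid.sum()), n_excluded=n_excluded,
        per_sample=per_sample)


def _abs_corr_scores(matrix: np.ndarray, score: str) -> np.ndarray:
    """Per-gene summary of absolute off-diagonal gene–gene correlation."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix.T)
    corr = np.nan_to_num(corr, nan=0.0)   # constant genes -> correlation 0
    np.fill_diagonal(corr, 0.0)
    a = np.abs(corr)
    if score == "mean":
        return a.sum(axis=1) / (a.shape[1] - 1)
    if score == "max":
        return a.max(axis=1)
    raise ValueError(f"unknown ranking score {score!r}")


def top_k_correlated_genes(matrix: np.ndarray, k: int = 30,
                           min_samples: int = 30, score: str = "mean",
                           ) -> Optional[np.ndarray]:
    """Top-k gene indices ranked by absolute gene–gene correlation.

    Each gene is scored by its mean (or max) absolute off-diagonal Pearson
    correlation across the matrix's samples; ties break by gene index. Returns
    None (with a log entry) when fewer than ``min_samples`` rows are present.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, g = matrix.shape
    if n < max(k, min_samples):
        logger.info("top_k_correlated_genes: skipped (%d < %d samples)",
                    n, max(k, min_samples))
        return None
    scores = _abs_corr_scores(matrix, score)
    order = np.argsort(-scores, kind="stable")  # stable => ties by gene index
    return order[:min(k, g)]


@dataclass
class OverlapResult:
    compound: str
    k: int
    gt_top_genes: np.ndarray
    model_top_genes: np.ndarray
    overlap: int
    null_expectation: float


def correlation_overlap(true: np.ndarray, generated: np.ndarray,
                        compound: str = "", k: int = 30,
                        min_samples: int = 30, score: str = "mean",
                        ) -> Optional[OverlapResult]:
    """|top_k(true) ∩ top_k(generated)| with null expectation k²/G."""
    true = np.asarray(true, dtype=float)
    generated = np.asarray(generated, dtype=float)
    if true.shape[1] != generated.shape[1]:
        raise ValueError("gene counts differ between matrices")
    g = true.shape[1]
    top_t = top_k_correlated_genes(true, k, min_samples, score)
    top_g = top_k_correlated_genes(generated, k, min_samples, score)
    if top_t is None or top_g is None:
        return None
    overlap = len(set(top_t.tolist()) & set(top_g.tolist()))
    return OverlapResult(compound=compound, k=k, gt_top_genes=top_t,
                         model_top_genes=top_g, overlap=overlap,
                         null_expectation=min(k, g) ** 2 / g)


def correlation_heatmap_matrix(matrix: np.ndarray,
                               genes: Sequence[int]) -> np.ndarray:
    """k×k Pearson correlation matrix over the listed genes.

    Symmetric with unit diagonal; constant genes yield 0 correlation (flagged
    in the log) but keep their unit diagonal.
    """
    matrix = np.asarray(matrix, dtype=float)
    genes = np.asarray(genes, dtype=int)
    sub = matrix[:, genes]
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        logger.info("correlation_heatmap_matrix: %d constant genes set to 0",
                    int(np.sum(sd == 0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class TrajectoryResult:
    levels: List
    centroids: np.ndarray
    projections: np.ndarray
    statistic: float


def trajectory_analysis(groups: Sequence[np.ndarray],
                        levels: Optional[Sequence] = None) -> TrajectoryResult:
    """Ordered-condition centroid trajectory statistic.

    ``groups`` are per-level embedding matrices in increasing level order.
    Each level's centroid is projected onto the first principal axis of the
    centroid set; the statistic is the Spearman correlation between level rank
    and projection. |statistic| = 1 means perfectly ordered progression.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 ordered levels for a trajectory")
    for i, grp in enumerate(groups):
        if np.asarray(grp).shape[0] < 2:
            raise ValueError(f"level {i} needs >= 2 samples")
    centroids = np.vstack([np.asarray(g, dtype=float).mean(axis=0)
                           for g in groups])
    centered = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # canonical sign (largest-magnitude component positive): the axis then
    # depends only on the centroid set, not on the order its rows arrive in
    pivot = np.argmax(np.abs(axis))
    if axis[pivot] < 0:
        axis = -axis
    proj = centered @ axis
    rho, _ = stats.spearmanr(np.arange(len(groups)), proj)
    return TrajectoryResult(
        levels=list(levels) if levels is not None else list(range(len(groups))),
        centroids=centroids, projections=proj, statistic=float(rho))
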