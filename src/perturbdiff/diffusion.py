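"""Gaussian diffusion in latent space with learned mean and bounded variance.

Forward process: a Markov chain q(z_t | z_{t-1}) = N(√(1−β_t) z_{t-1}, β_t I)
with a linear schedule β_t between fixed endpoints, equivalently in closed
form q(z_t | z_0) = N(√ᾱ_t z_0, (1−ᾱ_t) I) with ᾱ_t = Π_{s≤t}(1−β_s).

Reverse process: a conditional network predicts the step mean μθ and a
per-dimension interpolation vector s ∈ [0,1]; the step variance is
log Σθ = s·log β_t + (1−s)·log β̃_t, bounded between the forward variance β_t
(upper) and the forward-posterior variance β̃_t (lower). Training minimises
the Gaussian negative log-likelihood of a sampled forward-posterior target
z_{t-1} — a precision-weighted squared error plus a log-variance penalty —
with timesteps drawn uniformly from {1..T}.

β̃_1 is exactly 0 (the t=1 posterior is degenerate at z_0); inside the
variance interpolation only, it is clamped to β_1 so log β̃ stays finite, and
the final ancestral-sampling step returns μθ without added noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from ._nn import Adam
from .conditioning import ConditionEncoder, Denoiser, DenoiserOutput

__all__ = [
    "NoiseSchedule", "build_schedule", "forward_step", "forward_marginal",
    "posterior_target", "interpolate_variance", "nll_loss", "kl_loss",
    "DiffusionTrainConfig", "train_diffusion", "sample", "ScheduleError",
]


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSchedule:
    """Precomputed β, α, ᾱ and posterior variance β̃ for t = 1..T (1-based)."""

    T: int
    beta_min: float
    beta_max: float
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    beta_tilde: np.ndarray

    def _at(self, arr: np.ndarray, t) -> np.ndarray:
        t = np.asarray(t, dtype=int)
        if np.any(t < 1) or np.any(t > self.T):
            raise ScheduleError(f"timestep outside 1..{self.T}")
        return arr[t - 1]

    def beta_at(self, t):
        return self._at(self.beta, t)

    def alpha_bar_at(self, t):
        return self._at(self.alpha_bar, t)

    def alpha_bar_prev(self, t):
        """ᾱ_{t−1} with the convention ᾱ_0 = 1."""
        t = np.asarray(t, dtype=int)
        if np.any(t < 1) or np.any(t > self.T):
            raise ScheduleError(f"timestep outside 1..{self.T}")
        return np.where(t == 1, 1.0, self.alpha_bar[np.maximum(t - 2, 0)])

    def beta_tilde_clamped(self, t):
        """β̃_t with β̃_1 := β_1 so log β̃ is finite (variance interpolation only)."""
        t = np.asarray(t, dtype=int)
        bt = self._at(self.beta_tilde, t)
        return np.where(t == 1, self.beta[0], bt)


def build_schedule(T: int, beta_min: float = 1e-5, beta_max: float = 0.01,
                   allow_constant: bool = False) -> NoiseSchedule:
    """Linear β schedule β_t = β_min + (t−1)/(T−1)·(β_max − β_min).

    ``allow_constant`` permits β_min = β_max for degenerate-schedule checks.
    """
    if T < 2:
        raise ScheduleError("T must be >= 2")
    if not (0.0 < beta_min < 1.0 and 0.0 < beta_max < 1.0):
        raise ScheduleError("beta endpoints must lie in (0, 1)")
    if beta_min > beta_max or (beta_min == beta_max and not allow_constant):
        raise ScheduleError("require beta_min < beta_max")
    t = np.arange(T, dtype=float)
    beta = beta_min + t / (T - 1) * (beta_max - beta_min)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    alpha_bar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    beta_tilde = (1.0 - alpha_bar_prev) / (1.0 - alpha_bar) * beta
    return NoiseSchedule(T=T, beta_min=beta_min, beta_max=beta_max, beta=beta,
                         alpha=alpha, alpha_bar=alpha_bar, beta_tilde=beta_tilde)


def _col(x) -> np.ndarray:
    """Per-sample scalars broadcastable against (n, d) latents."""
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def forward_step(z_prev: np.ndarray, t, schedule: NoiseSchedule,
                 noise: np.ndarray) -> np.ndarray:
    """One forward transition: z_t = √(1−β_t) z_{t−1} + √β_t ε."""
    b = _col(schedule.beta_at(t))
    return np.sqrt(1.0 - b) * z_prev + np.sqrt(b) * noise


def forward_marginal(z0: np.ndarray, t, schedule: NoiseSchedule,
                     noise: np.ndarray) -> np.ndarray:
    """Closed-form forward draw: z_t = √ᾱ_t z_0 + √(1−ᾱ_t) ε."""
    ab = _col(schedule.alpha_bar_at(t))
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * noise


def posterior_target(z0: np.ndarray, z_t: np.ndarray, t,
                     schedule: NoiseSchedule, noise: np.ndarray) -> np.ndarray:
    """Sample from the forward posterior q(z_{t−1} | z_t, z_0).

    z_{t−1} = [√ᾱ_{t−1} β_t/(1−ᾱ_t)] z_0 + [√α_t (1−ᾱ_{t−1})/(1−ᾱ_t)] z_t
              + √β̃_t ε.  At t = 1 the coefficients force z_0 exactly.
    """
    t_arr = np.asarray(t, dtype=int)
    if np.any(t_arr < 1):
        raise ScheduleError("posterior_target needs t >= 1")
    beta = _col(schedule.beta_at(t_arr))
    ab = _col(schedule.alpha_bar_at(t_arr))
    ab_prev = _col(schedule.alpha_bar_prev(t_arr))
    alpha = 1.0 - beta
    coef0 = np.sqrt(ab_prev) * beta / (1.0 - ab)
    coeft = np.sqrt(alpha) * (1.0 - ab_prev) / (1.0 - ab)
    bt = _col(schedule._at(schedule.beta_tilde, t_arr))
    return coef0 * z0 + coeft * z_t + np.sqrt(bt) * noise


def interpolate_variance(s: np.ndarray, t, schedule: NoiseSchedule) -> np.ndarray:
    """Σθ = exp(s·log β_t + (1−s)·log β̃_t), element-wise, β̃ clamped at t=1."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("interpolation vector s must lie in [0, 1]")
    log_beta = np.log(_col(np.atleast_1d(schedule.beta_at(t))))
    log_bt = np.log(_col(np.atleast_1d(schedule.beta_tilde_clamped(t))))
    s2 = np.atleast_2d(s)
    out = np.exp(s2 * log_beta + (1.0 - s2) * log_bt)
    return out.reshape(s.shape) if s.ndim == 1 else out


def nll_loss(target: np.ndarray, output: DenoiserOutput, t,
             schedule: NoiseSchedule) -> float:
    """Gaussian NLL of the posterior target under N(μθ, Σθ).

    L = ½ · mean over batch and dims of [(z_{t−1} − μθ)²/Σθ + log Σθ].
    """
    target = np.atleast_2d(target)
    mu, s = np.atleast_2d(output.mu), np.atleast_2d(output.s)
    if target.shape != mu.shape:
        raise ValueError("target and mu shapes differ")
    sigma = interpolate_variance(s, t, schedule)
    if np.any(sigma <= 0):
        raise FloatingPointError("non-positive variance in NLL loss")
    value = 0.5 * np.mean((target - mu) ** 2 / sigma + np.log(sigma))
    if not np.isfinite(value):
        raise FloatingPointError("non-finite diffusion NLL")
    return float(value)


def kl_loss(z0: np.ndarray, z_t: np.ndarray, output: DenoiserOutput, t,
            schedule: NoiseSchedule) -> float:
    """Analytic KL(q(z_{t−1}|z_t,z_0) ‖ pθ) variant of the objective.

    Offered for comparison with the sampled-target NLL; uses the clamped β̃
    so the t=1 term stays finite.
    """
    t_arr = np.asarray(t, dtype=int)
    beta = _col(schedule.beta_at(t_arr))
    ab = _col(schedule.alpha_bar_at(t_arr))
    ab_prev = _col(schedule.alpha_bar_prev(t_arr))
    true_mean = (np.sqrt(ab_prev) * beta / (1.0 - ab) * np.atleast_2d(z0)
                 + np.sqrt(1.0 - beta) * (1.0 - ab_prev) / (1.0 - ab)
                 * np.atleast_2d(z_t))
    true_var = _col(schedule.beta_tilde_clamped(t_arr))
    sigma = interpolate_variance(np.atleast_2d(output.s), t_arr, schedule)
    mu = np.atleast_2d(output.mu)
    kl = 0.5 * (np.log(sigma) - np.log(true_var)
                + (true_var + (true_mean - mu) ** 2) / sigma - 1.0)
    return float(np.mean(kl))


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class DiffusionTrainConfig:
    n_steps: int = 4000
    batch_size: int = 192
    learning_rate: float = 1e-3
    log_every: int = 100
    objective: str = "nll"        # "nll" (sampled target) | "analytic_kl"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("nll", "analytic_kl"):
            raise ValueError("objective must be 'nll' or 'analytic_kl'")


def _nll_grads(target: np.ndarray, mu: np.ndarray, s: np.ndarray, t,
               schedule: NoiseSchedule):
    """Loss value and (dL/dμ, dL/ds) for the Gaussian-NLL reduction."""
    sigma = interpolate_variance(s, t, schedule)
    resid = target - mu
    n_elems = target.size
    loss = 0.5 * np.sum(resid ** 2 / sigma + np.log(sigma)) / n_elems
    g_mu = -resid / sigma / n_elems
    # dL/dlogΣ = ½(1 − resid²/Σ)/n ; dlogΣ/ds = log β_t − log β̃_t
    log_ratio = (np.log(_col(np.atleast_1d(schedule.beta_at(t))))
                 - np.log(_col(np.atleast_1d(schedule.beta_tilde_clamped(t)))))
    g_s = 0.5 * (1.0 - resid ** 2 / sigma) / n_elems * log_ratio
    return float(loss), g_mu, g_s


def _kl_grads(z0: np.ndarray, z_t: np.ndarray, mu: np.ndarray, s: np.ndarray,
              t, schedule: NoiseSchedule):
    """Loss and gradients for the analytic-KL objective variant."""
    t_arr = np.asarray(t, dtype=int)
    beta = _col(schedule.beta_at(t_arr))
    ab = _col(schedule.alpha_bar_at(t_arr))
    ab_prev = _col(schedule.alpha_bar_prev(t_arr))
    true_mean = (np.sqrt(ab_prev) * beta / (1.0 - ab) * z0
                 + np.sqrt(1.0 - beta) * (1.0 - ab_prev) / (1.0 - ab) * z_t)
    true_var = _col(schedule.beta_tilde_clamped(t_arr))
    sigma = interpolate_variance(s, t_arr, schedule)
    n_elems = z0.size
    diff = mu - true_mean
    kl = 0.5 * (np.log(sigma) - np.log(true_var)
                + (true_var + diff ** 2) / sigma - 1.0)
    loss = float(np.sum(kl)) / n_elems
    g_mu = diff / sigma / n_elems
    log_ratio = (np.log(beta) - np.log(true_var))
    g_s = 0.5 * (1.0 - (true_var + diff ** 2) / sigma) / n_elems * log_ratio
    return loss, g_mu, g_s


def train_diffusion(z0: np.ndarray, conditions: Dict[str, np.ndarray],
                    schedule: NoiseSchedule, encoder: ConditionEncoder,
                    denoiser: Denoiser, config: DiffusionTrainConfig,
                    ) -> pd.DataFrame:
    """Train the conditional denoiser on precomputed latents.

    ``conditions`` holds row-aligned arrays: ``basal`` (n×G), ``compound``
    (n×F), ``dose`` and ``time`` (n, already transformed). Each step samples a
    minibatch, a uniform timestep per row, builds z_t from the closed-form
    forward and the posterior target z_{t−1} with fresh noise, and applies one
    Adam update on the Gaussian NLL. Fully seeded; returns the loss log.
    """
    z0 = np.asarray(z0, dtype=float)
    n, d = z0.shape
    for key in ("basal", "compound", "dose", "time"):
        if key not in conditions or len(conditions[key]) != n:
            raise ValueError(f"conditions[{key!r}] must align with z0 rows")
    rng = np.random.default_rng(config.seed)
    opt = Adam([encoder, denoiser], lr=config.learning_rate)
    log = []
    for step in range(config.n_steps):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        t = rng.integers(1, schedule.T + 1, size=idx.size)
        eps_t = rng.standard_normal((idx.size, d))
        z_t = forward_marginal(z0[idx], t, schedule, eps_t)

        c = encoder.forward(conditions["basal"][idx], conditions["compound"][idx],
                            conditions["dose"][idx], conditions["time"][idx])
        out = denoiser.forward(z_t, t, c)
        if config.objective == "analytic_kl":
            loss, g_mu, g_s = _kl_grads(z0[idx], z_t, out.mu, out.s, t, schedule)
        else:
            eps_prev = rng.standard_normal((idx.size, d))
            target = posterior_target(z0[idx], z_t, t, schedule, eps_prev)
            loss, g_mu, g_s = _nll_grads(target, out.mu, out.s, t, schedule)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"diffusion training diverged at step {step}")
        opt.zero_grad()
        g_c = denoiser.backward(g_mu, g_s)
        encoder.backward(g_c)
        opt.step()
        if step % config.log_every == 0 or step == config.n_steps - 1:
            log.append({"step": step, "nll": loss})
    return pd.DataFrame(log)


def sample(conditions: Dict[str, np.ndarray], schedule: NoiseSchedule,
           encoder: ConditionEncoder, denoiser: Denoiser, n: int,
           seed: int = 0, trajectory: bool = False):
    """Ancestral sampling of ẑ₀, ``n`` draws per condition row.

    Starts from z_T ~ N(0, I) and iterates z_{t−1} ~ N(μθ(z_t,t,c), Σθ) for
    t = T..2; the final step returns μθ with no added noise (the true t=1
    posterior is degenerate). Returns an array of shape (n_conditions·n, d)
    ordered condition-major; with ``trajectory`` also the list of intermediate
    states.
    """
    rng = np.random.default_rng(seed)
    c = encoder.forward(conditions["basal"], conditions["compound"],
                        conditions["dose"], conditions["time"])
    c_rep = np.repeat(c, n, axis=0)
    d = denoiser.latent_dim
    z = rng.standard_normal((c_rep.shape[0], d))
    states = [z.copy()] if trajectory else None
    for t in range(schedule.T, 0, -1):
        out = denoiser.forward(z, t, c_rep)
        if t > 1:
            sigma = interpolate_variance(out.s, t, schedule)
            z = out.mu + np.sqrt(sigma) * rng.standard_normal(z.shape)
        else:
            z = out.mu
        if trajectory:
            states.append(z.copy())
    return (z, states) if trajectory else z
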