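"""Denoising diffusion probabilistic model over the latent space.

Forward process: z_t | z_{t-1} ~ N(sqrt(1-beta_t) z_{t-1}, beta_t I) with a
linear variance schedule from beta_1 = 0.001 to beta_T = 0.2, giving the
closed-form marginal z_t = sqrt(abar_t) z_0 + sqrt(bbar_t) eps.  The reverse
process is a learned Gaussian chain whose mean is parameterized through a
noise-prediction MLP with skip connections; training minimizes the simple
(unweighted) denoising objective E_t ||eps - eps_w(z_t, t)||^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from .nn import Adam, Linear, Module, sinusoidal_time_embedding

__all__ = [
    "DiffusionSchedule", "linear_schedule", "Denoiser", "q_sample",
    "ddpm_loss", "reverse_sample", "latent_recon_constant", "terminal_kl",
]


@dataclass(frozen=True)
class DiffusionSchedule:
    """beta/alpha/alpha-bar/beta-bar arrays indexed by step t = 1..T."""

    T: int
    beta: np.ndarray       # beta[t-1] = beta_t
    alpha: np.ndarray      # 1 - beta_t
    alpha_bar: np.ndarray  # prod_{s<=t} alpha_s
    beta_bar: np.ndarray   # 1 - alpha_bar_t


def linear_schedule(T: int, beta1: float = 0.001,
                    betaT: float = 0.2) -> DiffusionSchedule:
    """Linearly increasing variance schedule with the defining identities
    alpha_t = 1 - beta_t, abar_t = prod alpha_s, bbar_t = 1 - abar_t."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < beta1 <= betaT < 1):
        raise ValueError("need 0 < beta1 <= betaT < 1")
    if T == 1:
        beta = np.array([beta1])
    else:
        beta = beta1 + (betaT - beta1) * np.arange(T) / (T - 1)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    beta_bar = 1.0 - alpha_bar
    return DiffusionSchedule(T, beta, alpha, alpha_bar, beta_bar)


def q_sample(z0: np.ndarray, t: int, eps: np.ndarray,
             sched: DiffusionSchedule) -> np.ndarray:
    """Closed-form forward marginal: sqrt(abar_t) z0 + sqrt(bbar_t) eps."""
    if not 1 <= t <= sched.T:
        raise IndexError(f"t={t} outside 1..{sched.T}")
    return (np.sqrt(sched.alpha_bar[t - 1]) * z0
            + np.sqrt(sched.beta_bar[t - 1]) * eps)


class Denoiser(Module):
    """Noise-prediction MLP eps_w(z_t, t) with residual blocks and a
    sinusoidal time embedding concatenated to the input."""

    def __init__(self, latent_dim: int, hidden: int = 64, n_blocks: int = 2,
                 time_dim: int = 16, T: int = 1000, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.time_dim = time_dim
        self.T = T
        self.lin_in = Linear(latent_dim + time_dim, hidden, rng)
        self.blocks = [(Linear(hidden, hidden, rng), Linear(hidden, hidden, rng))
                       for _ in range(n_blocks)]
        self.lin_out = Linear(hidden, latent_dim, rng)
        # zero-init output so the initial model predicts eps ~ 0
        self.lin_out.W.data[:] = 0.0

    def forward(self, z_t: Tensor, t: np.ndarray) -> Tensor:
        temb = Tensor(sinusoidal_time_embedding(t, self.time_dim, self.T))
        if z_t.ndim == 1:
            z_t = z_t.reshape(1, -1)
        if temb.shape[0] == 1 and z_t.shape[0] > 1:
            temb = Tensor(np.repeat(temb.data, z_t.shape[0], axis=0))
        h = self.lin_in(concat([z_t, temb])).tanh()
        for l1, l2 in self.blocks:
            h = h + l2(l1(h).tanh())
        return self.lin_out(h)

    def predict(self, z_t: np.ndarray, t: np.ndarray | int) -> np.ndarray:
        t = np.full(np.atleast_2d(z_t).shape[0], t) if np.isscalar(t) else t
        out = self.forward(Tensor(np.atleast_2d(z_t)), np.asarray(t))
        return out.data.reshape(np.shape(z_t))


def ddpm_loss(z0_batch, denoiser: Denoiser, sched: DiffusionSchedule,
              rng: np.random.Generator) -> Tensor:
    """Monte-Carlo denoising loss: per item draw t ~ U{1..T} and eps ~ N(0,I),
    return the batch mean of ||eps - eps_w(z_t, t)||^2.

    ``z0_batch`` may be a Tensor (gradients flow into the encoder during
    joint training) or an ndarray of shape (B, d).
    """
    z0 = z0_batch if isinstance(z0_batch, Tensor) else Tensor(np.atleast_2d(z0_batch))
    B = z0.shape[0]
    t = rng.integers(1, sched.T + 1, size=B)
    eps = rng.standard_normal(z0.shape)
    sa = np.sqrt(sched.alpha_bar[t - 1])[:, None]
    sb = np.sqrt(sched.beta_bar[t - 1])[:, None]
    z_t = z0 * sa + Tensor(sb * eps)
    pred = denoiser.forward(z_t, t)
    diff = pred - Tensor(eps)
    return (diff * diff).sum(axis=1).mean()


def reverse_sample(zT: np.ndarray, denoiser: Denoiser,
                   sched: DiffusionSchedule, rng: np.random.Generator,
                   ) -> np.ndarray:
    """Ancestral sampling of the reverse chain from z_T down to z_0.

    mu_w(z_t, t) = (z_t - beta_t/sqrt(bbar_t) * eps_w(z_t, t)) / sqrt(alpha_t)
    with per-step variance sigma_t^2 = beta_t; the final step adds no noise.
    """
    z = np.atleast_2d(np.asarray(zT, dtype=np.float64)).copy()
    for t in range(sched.T, 0, -1):
        eps_hat = denoiser.predict(z, t)
        beta, alpha = sched.beta[t - 1], sched.alpha[t - 1]
        bbar = sched.beta_bar[t - 1]
        mu = (z - beta / np.sqrt(bbar) * eps_hat) / np.sqrt(alpha)
        if t > 1:
            z = mu + np.sqrt(beta) * rng.standard_normal(z.shape)
        else:
            z = mu
    return z.reshape(np.shape(zT))


def latent_recon_constant(sched: DiffusionSchedule, d: int,
                          parenthesization: str = "normalizer") -> float:
    """Expected one-step latent-reconstruction term E[C1 - eps^2/(2 alpha_1)]
    summed over dimensions; constant in z0, reported for ELBO bookkeeping
    only and excluded from gradients.

    ``normalizer`` reads C1 = log(1/sqrt(2 pi beta_1)) (the Gaussian
    normalizing constant); ``literal`` reads C1 = log(1/sqrt(2 pi)) * beta_1
    precedence-free alternative log(beta_1/sqrt(2 pi)).
    """
    beta1, alpha1 = sched.beta[0], sched.alpha[0]
    if parenthesization == "normalizer":
        c1 = np.log(1.0 / np.sqrt(2 * np.pi * beta1))
    elif parenthesization == "literal":
        c1 = np.log(beta1 / np.sqrt(2 * np.pi))
    else:
        raise ValueError("parenthesization must be 'normalizer' or 'literal'")
    return float(d * (c1 - 1.0 / (2 * alpha1)))


def terminal_kl(mu: np.ndarray, sigma: np.ndarray,
                sched: DiffusionSchedule) -> float:
    """KL[q(z_T | z_0) || N(0, I)] averaged over a batch of posterior means,
    with z_0 taken at the encoder mean; a schedule-adequacy diagnostic for
    the assumption that the forward chain terminates at the prior.

    q(z_T | z_0=mu) = N(sqrt(abar_T) mu, bbar_T I) per dimension, so
    KL = 0.5 * sum_j [abar*mu_j^2 + bbar - 1 - log(bbar)].
    """
    mu = np.atleast_2d(mu)
    abar, bbar = sched.alpha_bar[-1], sched.beta_bar[-1]
    kl = 0.5 * (abar * mu ** 2 + bbar - 1.0 - np.log(bbar)).sum(axis=1)
    return float(kl.mean())


def train_denoiser(z0: np.ndarray, denoiser: Denoiser,
                   sched: DiffusionSchedule, epochs: int, batch_size: int,
                   lr: float, seed: int, grad_clip: float = 5.0,
                   ) -> list[float]:
    """Fit the denoiser to a fixed latent cloud; returns per-epoch losses."""
    rng = np.random.default_rng(seed)
    opt = Adam(denoiser.parameters(), lr=lr)
    losses = []
    n = z0.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            loss = ddpm_loss(z0[idx], denoiser, sched, rng)
            loss.backward()
            opt.step(grad_clip=grad_clip)
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return losses
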