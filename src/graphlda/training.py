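"""Training objectives and the multi-stage optimization scheme.

The full objective (to maximize) is

    E_q [ log p(G | z0) - log q(z0 | G) - E_t ||eps - eps_w(z_t, t)||^2 ]

i.e. reconstruction + posterior entropy - latent denoising error, with the
one-step latent-reconstruction term a training constant reported separately.
Multi-stage training fits (1) the autoencoder on reconstruction + entropy,
(2) the denoiser on frozen encoder-mean latents, then (3) everything
jointly at a reduced learning rate.  Configuration variants recover the
baselines: a graph AE (no entropy, fixed sigma) and a graph VAE (standard
normal prior via a closed-form KL penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Tensor
from .backbone import (BackboneConfig, GraphAutoencoder, batch_graphs,
                       recon_loglik_batch)
from .diffusion import Denoiser, DiffusionSchedule, ddpm_loss, linear_schedule
from .molgraph import MolecularGraph, featurize
from .nn import Adam

__all__ = ["TrainConfig", "LossBreakdown", "GraphLDA", "graph_lda_loss",
           "graph_vae_loss", "train_stage1", "train_stage2", "train_stage3",
           "train", "prepare_dataset"]

VARIANTS = ("graph_lda_joint", "graph_lda_stable", "graph_ae", "graph_vae")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Full-scale defaults: stages of 100/500/100 epochs, batch size 20, Adam
    at lr 5e-5 with exponential decay (gamma 0.9) and a stage-3 lr of 1e-5.
    ``desk()`` scales the stages down for small fixture sets and raises the
    learning rate accordingly.
    """

    variant: str = "graph_lda_stable"
    stage_epochs: tuple[int, int, int] = (100, 500, 100)
    batch_size: int = 20
    lr: float = 5e-5
    lr_gamma: float = 0.9
    stage3_lr: float = 1e-5
    seed: int = 0
    grad_clip: float = 5.0
    entropy_weight: float = 1.0
    # stage-1 pretraining is a plain graph AE (reconstruction only) by
    # default; with no denoising term an unopposed entropy bonus makes
    # sigma diverge instead of learning a useful code
    stage1_entropy_weight: float = 0.0
    kl_weight: float = 1.0      # graph_vae only
    diffusion_T: int = 1000
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if any(e < 0 for e in self.stage_epochs):
            raise ValueError("epochs must be >= 0")
        if self.lr <= 0 or self.stage3_lr <= 0:
            raise ValueError("learning rates must be positive")

    @staticmethod
    def desk(**kw) -> "TrainConfig":
        base = TrainConfig(stage_epochs=(200, 60, 60), lr=2e-3,
                           lr_gamma=0.995, stage3_lr=2e-4, diffusion_T=200)
        return replace(base, **kw)


@dataclass
class LossBreakdown:
    recon: float
    entropy: float
    denoise: float
    total: float
    neg_elbo: float

    @staticmethod
    def assemble(recon: float, entropy: float, denoise: float,
                 constant: float = 0.0) -> "LossBreakdown":
        total = -recon - entropy + denoise
        return LossBreakdown(recon, entropy, denoise, total,
                             total - constant)


@dataclass
class GraphLDA:
    """Model bundle: autoencoder backbone, denoiser, noise schedule."""

    autoencoder: GraphAutoencoder
    denoiser: Denoiser
    schedule: DiffusionSchedule
    history: dict[str, list[float]] = field(default_factory=dict)

    @staticmethod
    def build(schema, backbone_config: BackboneConfig,
              train_config: TrainConfig) -> "GraphLDA":
        sched = linear_schedule(train_config.diffusion_T)
        den = Denoiser(backbone_config.latent_dim, T=train_config.diffusion_T,
                       seed=train_config.seed + 1)
        ae = GraphAutoencoder(schema, backbone_config,
                              seed=train_config.seed)
        return GraphLDA(ae, den, sched)

    def log(self, key: str, value: float) -> None:
        self.history.setdefault(key, []).append(value)


def prepare_dataset(smiles: list[str], schema, n_max: int,
                    standardize_values: bool = True) -> list[MolecularGraph]:
    """Featurize a SMILES list; z-score value-kind feature columns across
    the dataset (columns with zero spread are left untouched)."""
    graphs = [featurize(s, schema, n_max) for s in smiles]
    if standardize_values:
        _standardize_value_blocks(graphs, schema)
    return graphs


def _standardize_value_blocks(graphs: list[MolecularGraph], schema) -> None:
    for blocks, attr, offs in ((schema.atom_blocks, "node_features",
                                schema.atom_offsets()),
                               (schema.bond_blocks, "edge_features",
                                schema.bond_offsets())):
        for blk in blocks:
            if blk.kind != "value":
                continue
            lo, _ = offs[blk.name]
            vals = [getattr(g, attr)[..., lo][_valid_region(g, attr)]
                    for g in graphs]
            flat = np.concatenate([v.ravel() for v in vals])
            std = flat.std()
            if std < 1e-12:
                continue
            mean = flat.mean()
            for g in graphs:
                arr = getattr(g, attr)
                region = _valid_region(g, attr)
                arr[..., lo][region] = (arr[..., lo][region] - mean) / std


def _valid_region(g: MolecularGraph, attr: str):
    if attr == "node_features":
        return g.mask
    return np.outer(g.mask, g.mask)


# ----------------------------------------------------------------- losses

def _forward_terms(model: GraphLDA, batch, rng) -> tuple[Tensor, Tensor, Tensor]:
    """Shared forward pass: returns (recon, entropy, z0) Tensors."""
    mu, sigma = model.autoencoder.encode_batch(batch)
    eps = rng.standard_normal(mu.shape)
    z0 = mu + sigma * Tensor(eps)
    node, edge = model.autoencoder.decoder.forward(z0, batch["n_atoms"])
    recon = recon_loglik_batch(node, edge, batch,
                               model.autoencoder.schema).mean()
    ent = ((sigma * sigma * (2 * np.pi * np.e)).log() * 0.5).sum(axis=1).mean()
    return recon, ent, z0


def graph_lda_loss(batch_or_graphs, model: GraphLDA,
                   rng: np.random.Generator,
                   entropy_weight: float = 1.0) -> tuple[Tensor, LossBreakdown]:
    """Full objective on a batch: total = -recon - entropy + denoise."""
    batch = (batch_or_graphs if isinstance(batch_or_graphs, dict)
             else batch_graphs(batch_or_graphs))
    recon, ent, z0 = _forward_terms(model, batch, rng)
    den = ddpm_loss(z0, model.denoiser, model.schedule, rng)
    loss = recon * (-1.0) + ent * (-entropy_weight) + den
    bd = LossBreakdown.assemble(float(recon.data), float(ent.data),
                                float(den.data))
    if not np.isfinite(bd.total):
        raise FloatingPointError(f"non-finite loss components: {bd}")
    return loss, bd


def graph_vae_loss(batch_or_graphs, model: GraphLDA,
                   rng: np.random.Generator,
                   beta_kl: float = 1.0) -> tuple[Tensor, LossBreakdown]:
    """VAE baseline: -recon + beta * KL[q(z0|G) || N(0, I)] (closed form)."""
    batch = (batch_or_graphs if isinstance(batch_or_graphs, dict)
             else batch_graphs(batch_or_graphs))
    mu, sigma = model.autoencoder.encode_batch(batch)
    eps = rng.standard_normal(mu.shape)
    z0 = mu + sigma * Tensor(eps)
    node, edge = model.autoencoder.decoder.forward(z0, batch["n_atoms"])
    recon = recon_loglik_batch(node, edge, batch,
                               model.autoencoder.schema).mean()
    var = sigma * sigma
    kl = ((mu * mu + var - var.log() - 1.0) * 0.5).sum(axis=1).mean()
    loss = recon * (-1.0) + kl * beta_kl
    bd = LossBreakdown(float(recon.data), -float(kl.data), 0.0,
                       float(loss.data), float(loss.data))
    if not np.isfinite(bd.total):
        raise FloatingPointError(f"non-finite loss components: {bd}")
    return loss, bd


def gaussian_kl(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL[N(mu, diag sigma^2) || N(0, I)], summed over dims."""
    return float(0.5 * np.sum(mu ** 2 + sigma ** 2
                              - np.log(sigma ** 2) - 1.0))


# ------------------------------------------------------------------ stages

def _epoch_loop(graphs, loss_fn, params, config: TrainConfig, epochs: int,
                lr: float, rng: np.random.Generator, model: GraphLDA,
                log_key: str) -> None:
    opt = Adam(params, lr=lr)
    n = len(graphs)
    batches_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    initial = None
    for epoch in range(epochs):
        opt.lr = lr * config.lr_gamma ** epoch
        order = rng.permutation(n)
        epoch_total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            opt.zero_grad()
            loss, bd = loss_fn(batch, rng)
            loss.backward()
            opt.step(grad_clip=config.grad_clip)
            epoch_total += float(loss.data)
        epoch_mean = epoch_total / batches_per_epoch
        model.log(log_key, epoch_mean)
        if initial is None:
            initial = abs(epoch_mean) + 1.0
        if not np.isfinite(epoch_mean) or epoch_mean > 10 * initial:
            raise FloatingPointError(
                f"{log_key} diverged at epoch {epoch}: {epoch_mean:.3g}")


def train_stage1(model: GraphLDA, graphs: list[MolecularGraph],
                 config: TrainConfig) -> GraphLDA:
    """Pre-train the backbone on reconstruction (+ entropy) only."""
    rng = np.random.default_rng(config.seed)
    ew = config.stage1_entropy_weight if config.variant != "graph_ae" else 0.0

    def loss_fn(batch, r):
        recon, ent, _ = _forward_terms(model, batch, r)
        loss = recon * (-1.0) + ent * (-ew)
        bd = LossBreakdown.assemble(float(recon.data), float(ent.data), 0.0)
        if not np.isfinite(bd.total):
            raise FloatingPointError(f"non-finite loss: {bd}")
        return loss, bd

    _epoch_loop(graphs, loss_fn, model.autoencoder.parameters(), config,
                config.stage_epochs[0], config.lr, rng, model, "stage1_loss")
    return model


def train_stage2(model: GraphLDA, graphs: list[MolecularGraph],
                 config: TrainConfig) -> GraphLDA:
    """Train the denoiser on frozen encoder-mean latents."""
    rng = np.random.default_rng(config.seed + 2)
    z0 = model.autoencoder.encode_means(graphs)
    opt = Adam(model.denoiser.parameters(), lr=config.lr)
    n = len(z0)
    for epoch in range(config.stage_epochs[1]):
        opt.lr = config.lr * config.lr_gamma ** epoch
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = ddpm_loss(z0[idx], model.denoiser, model.schedule, rng)
            loss.backward()
            opt.step(grad_clip=config.grad_clip)
            total += float(loss.data)
        model.log("stage2_loss",
                  total / max(1, int(np.ceil(n / config.batch_size))))
    return model


def train_stage3(model: GraphLDA, graphs: list[MolecularGraph],
                 config: TrainConfig, epochs: int | None = None,
                 log_key: str = "stage3_neg_elbo") -> GraphLDA:
    """Joint fine-tuning of encoder, decoder and denoiser on the full
    objective at the stage-3 learning rate; logs the negative ELBO."""
    rng = np.random.default_rng(config.seed + 3)
    params = (model.autoencoder.parameters() + model.denoiser.parameters())

    def loss_fn(batch, r):
        return graph_lda_loss(batch, model, r,
                              entropy_weight=config.entropy_weight)

    _epoch_loop(graphs, loss_fn, params, config,
                config.stage_epochs[2] if epochs is None else epochs,
                config.stage3_lr, rng, model, log_key)
    return model


def train(smiles: list[str], schema, backbone_config: BackboneConfig,
          config: TrainConfig) -> GraphLDA:
    """End-to-end training entry point for all variants."""
    graphs = prepare_dataset(smiles, schema, backbone_config.n_max)
    model = GraphLDA.build(schema, backbone_config, config)
    if config.variant == "graph_vae":
        rng = np.random.default_rng(config.seed)

        def loss_fn(batch, r):
            return graph_vae_loss(batch, model, r, beta_kl=config.kl_weight)

        _epoch_loop(graphs, loss_fn, model.autoencoder.parameters(), config,
                    sum(config.stage_epochs), config.lr, rng, model,
                    "vae_loss")
    elif config.variant == "graph_ae":
        ae_config = replace(config, stage_epochs=(sum(config.stage_epochs), 0, 0))
        train_stage1(model, graphs, ae_config)
    elif config.variant == "graph_lda_joint":
        # joint training from random initialization, equal total epochs
        joint = replace(config, stage3_lr=config.lr)
        train_stage3(model, graphs, joint, epochs=sum(config.stage_epochs),
                     log_key="joint_neg_elbo")
    else:  # graph_lda_stable
        train_stage1(model, graphs, config)
        train_stage2(model, graphs, config)
        train_stage3(model, graphs, config)
    return model


def reconstruction_rate(model: GraphLDA,
                        graphs: list[MolecularGraph]) -> float:
    """Fraction of graphs whose decoded canonical SMILES matches the input."""
    hits = sum(model.autoencoder.reconstruct(g) == g.smiles for g in graphs)
    return hits / len(graphs)


def smoothed(values: list[float], window: int = 10) -> float:
    """Mean of the trailing `window` entries (loss-curve smoothing)."""
    tail = values[-window:] if len(values) >= window else values
    return float(np.mean(tail))
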