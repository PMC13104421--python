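# graphlda

Molecular representation learning with a **graph latent-diffusion
autoencoder** (Graph LDA), plus the statistical machinery to ask whether a
learned representation actually generalizes: WAIC/WBIC evaluation of
property-prediction models built on the latent space, Bayes-factor model
comparison, and a quantitative framework for latent-space **multimodality**
and **smoothness**.

It is aimed at cheminformatics researchers who want to study *how* a
latent prior shapes a molecular embedding, not just to generate molecules.
Everything runs on synthetic small-molecule fixtures at desk scale — no
dataset downloads, no GPU.

## The model

A permutation-invariant graph VAE encodes a molecular graph G (dense node
features V and symmetric edge features E over all atom pairs) into a single
Gaussian latent, q_φ(z₀|G) = N(μ, diag σ²).  Instead of a standard-normal
prior, the prior p_w(z₀) is the marginal of a **denoising diffusion
probabilistic model** (DDPM) over the latent space: a forward chain
q(z_t|z_{t−1}) = N(√(1−β_t) z_{t−1}, β_t I) with β linearly increasing
from 0.001 to 0.2, and a learned reverse chain parameterized through a
noise-prediction MLP ε_w(z_t, t).  The training objective is the ELBO

    E_q[ log p_θ(G|z₀) − log q_φ(z₀|G) − E_t‖ε − ε_w(z_t, t)‖² ],

i.e. reconstruction + posterior entropy − latent denoising error (the
one-step latent-reconstruction term is a constant and is reported, not
optimized).  Training is multi-stage: (1) autoencoder pretraining on
reconstruction, (2) DDPM fitting on frozen encoder means, (3) joint
fine-tuning at a reduced learning rate.  Graph AE and Graph VAE baselines
are configuration variants of the same backbone.

Generalization of a frozen encoder is measured by regressing properties y
on the latent means with a small Bayesian neural network sampled by
unadjusted Langevin Monte Carlo, and reporting

* **WAIC** (per datum): −1/N Σ log E_w[p(yᵢ|w)] + 1/N Σ Var_w[log p(yᵢ|w)],
* **WBIC** (total): E_w^β[Σ −log p(yᵢ|w)] under the β = 1/log N tempered
  posterior — an estimate of the Bayesian free energy,
* **2 log_e Bayes factors** between encoders, 2(F₁ − F₀), interpreted on
  the Kass–Raftery scale.

Latent-space quality is quantified by (a) the number of X-means clusters
(full-covariance Gaussian BIC) found after a UMAP projection whose target
dimension is chosen at the knee of the k-nearest-neighbor preservation
curve, and (b) directional-derivative norms |f(uᵢ) − f(a)|/ε and Tanimoto
(ECFP4) neighbor profiles around latent anchors.

## Worked example

Train the multi-stage and joint variants on 200 synthetic molecules
(≤ 9 heavy atoms, C/N/O/F) and compare their converged objectives:

```python
from graphlda import BackboneConfig, TrainConfig, train
from graphlda.fixtures import FixtureSpec, gen_molecules
from graphlda.molgraph import build_schema
from graphlda.training import prepare_dataset, reconstruction_rate, smoothed

smiles = gen_molecules(FixtureSpec(n_molecules=200, seed=1))
schema = build_schema("zinc")
cfg = BackboneConfig.desk()

stable = train(smiles, schema, cfg, TrainConfig.desk(variant="graph_lda_stable", seed=0))
joint  = train(smiles, schema, cfg, TrainConfig.desk(variant="graph_lda_joint", seed=0))

graphs = prepare_dataset(smiles, schema, cfg.n_max)
print("reconstruction:", reconstruction_rate(stable, graphs))
print("neg-ELBO  stable:", smoothed(stable.history["stage3_neg_elbo"]))
print("neg-ELBO  joint :", smoothed(joint.history["joint_neg_elbo"]))
```

Output (a few minutes on one CPU core):

```
reconstruction: 0.91
neg-ELBO  stable: 17.93
neg-ELBO  joint : 26.52
```

91% of the training molecules decode back to their exact canonical SMILES
from the posterior mean, and the multi-stage run converges to a lower
negative ELBO than joint training from scratch at equal total epochs — the
joint run drifts into a high-entropy latent that never learns to
reconstruct.

The same workflow is available from the shell:

```bash
graphlda fixtures --n 200 --seed 1 --out-smi mols.smi --out-csv props.csv
graphlda train --data mols.smi --variant graph_lda_stable --out enc.npz
graphlda eval --encoder enc.npz --data props.csv --seed 1
graphlda analyze --encoder enc.npz --data mols.smi --what multimodality
```

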