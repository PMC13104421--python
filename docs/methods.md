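# Methods

This note documents the models, estimators and design choices behind
`graphlda`, the defaults that matter, and what the synthetic test
conditions do and do not establish.

## Molecular graphs

Molecules are heavy-atom graphs with dense feature tensors padded to a
fixed `n_max`.  Two layouts are provided:

* **zinc** (43 atom / 13 bond features): atom identity over 12 categories
  (C, N, O, F, Br, Si, P, S, Cl, I, B, other), degree 0–10, implicit
  valence 0–6, formal charge and radical-electron count as raw values,
  hybridization (sp…sp³d²), aromaticity flag, implicit-hydrogen count
  0–4; bonds carry type (single/double/triple/aromatic/none), conjugation
  and ring flags, and a one-hot shortest-path distance capped at 5 bonds.
* **qm9** (36 atom / 8 bond features): identity over C, N, O, F, H and the
  same remaining blocks; the pairwise distance is a single Euclidean value
  (requires 3D coordinates, e.g. from an SDF).  A topological variant
  replaces it with the clipped shortest-path one-hot for ablations.

Graphs are over heavy atoms only; the H identity slot of the qm9 layout is
retained for schema fidelity but unused by default (hydrogen counts live
in the implicit-hydrogen block).  Shortest-path distances beyond 5 are
clipped into the top category.  The edge tensor is defined over *all*
ordered pairs; non-bonded pairs and the diagonal carry the bond-type
"none" category, and it is symmetric by construction.  Value-kind columns
(formal charge, radicals, Euclidean distance) are z-scored across the
dataset before model input; columns with zero spread are left untouched.
Decoding argmaxes each one-hot block, assembles bonds from non-"none"
pairs, and sanitizes with RDKit; disconnected or chemically invalid
assemblies return a sentinel (`None`) rather than raising, so
reconstruction rates can be computed over arbitrary decoder outputs.
Rare hybridizations outside the five listed categories are mapped to sp³.

## Backbone autoencoder

The encoder is an edge-conditioned message-passing network: per-layer,
node i aggregates tanh(W_h h_j + W_e e_ij) by summation over all masked
partners j, and updates through a gated MLP; a masked mean-pool produces
one graph vector from which linear heads emit μ and σ (softplus with a
1e-4 floor, keeping the posterior entropy finite).  Summation and mean
pooling make the posterior exactly permutation-invariant — the property
the architecture must guarantee — without requiring attention internals.
The decoder expands z₀ through learned positional encodings to per-slot
node states, refines them with globally-conditioned residual MLP layers,
and emits atom logits from a node head and bond logits from a symmetric
pair head built from (sᵢ + sⱼ, sᵢ ⊙ sⱼ), so edge logits are symmetric by
construction.  The decoder is conditioned on the true atom count; the
package targets representation learning, not de-novo generation.

Reconstruction log-likelihood sums categorical terms over one-hot blocks,
Bernoulli terms over flags and unit-variance Gaussian terms over value
blocks, across valid nodes and all valid ordered pairs (masked rows
contribute zero).

Full-scale defaults follow the reference configuration (latent 90 for the
zinc layout / 50 for qm9, 16 layers, 256-dim messages, 64-dim positional
encodings, batch 20, Adam at 5e-5 with exponential decay γ = 0.9).  The
test suite runs a desk configuration — latent 16, 2 layers, 64-dim
messages, n_max 9 — chosen so that the full multi-stage pipeline and its
baselines train in minutes on one core.  All neural components run on a
small reverse-mode autodiff engine over NumPy float64 included in the
package; training is exactly reproducible under a seed on a single
worker.

## Latent diffusion

The variance schedule is linear from β₁ = 0.001 to β_T = 0.2.  The number
of steps T is a free parameter (default 1000; the desk configuration uses
200); at T = 1000 the terminal KL between q(z_T|z₀) and N(0, I) is below
1e-3 per dimension for unit-scale latents, which is the diagnostic the
`terminal_kl` helper reports.  The forward marginal uses the standard
√ᾱ_t z₀ mean; the reverse chain uses μ_w = (z_t − β_t/√β̄_t ε_w)/√α_t with
σ_t² = β_t and a noiseless final step.  The denoiser is an MLP with
residual blocks and a sinusoidal time embedding, zero-initialized at the
output so an untrained model predicts ε = 0.  The one-step latent
reconstruction term d·[C₁ − 1/(2α₁)] is constant during training and
exposed for ELBO reporting only; both parenthesizations of C₁ are
implemented, with the Gaussian-normalizer reading log(1/√(2πβ₁)) as the
default (it is the value the Monte-Carlo evaluation of the one-step
kernel actually produces).

## Training scheme

`graph_lda_stable` runs three stages: (1) autoencoder pretraining,
(2) denoiser training on frozen encoder means, (3) end-to-end fine-tuning
of all components on the full objective at a reduced learning rate.
Stage 1 is a plain graph AE (entropy weight 0, configurable): with no
denoising term in the objective, an entropy bonus is unopposed — σ grows
without bound and reconstruction collapses — so the pretraining stage
must not include it.  `graph_lda_joint` optimizes the full objective from
random initialization for the same total number of epochs.  `graph_ae`
and `graph_vae` reuse the backbone with reconstruction-only and
closed-form-KL objectives respectively.  Gradients are clipped at norm 5;
an epoch loss exceeding ten times its initial value aborts with a
diagnostic.

Desk-scale stages are 200/60/60 epochs at lr 2e-3 (γ = 0.995) with
stage-3 lr 2e-4.  At this scale the multi-stage run converges to a
reconstruction-faithful optimum with moderate σ, while the joint run
finds the degenerate high-entropy region early and never develops
reconstruction — reproducing the qualitative convergence ordering the
multi-stage scheme exists to fix.  Stage 3 must run long enough for the
trailing-window mean of the negative ELBO to reflect its converged value;
60 epochs suffice at desk scale.

## WAIC, WBIC, and Langevin sampling

A Bayesian regressor (default: one tanh hidden layer of width 64; a
linear architecture is provided for conjugate oracles) with prior
N(0, τ²I), τ = 1, and a fixed Gaussian likelihood noise s estimated from
a preliminary ridge fit (floor 0.1) is sampled by unadjusted Langevin
Monte Carlo, w ← w − (η²/2)∇U + ηξ, with U(w) = −log q(w) − β Σ log p(yᵢ|w).
Gradients come from the autodiff engine.  Targets y are standardized so
that s and η defaults transfer across tasks.  Defaults are η = 1e-4 with
50k iterations, 10k burn-in and thinning 10 — deliberately conservative;
the test suite uses larger steps with fewer iterations, which the
conjugate oracles show is sufficient (LMC WAIC within 2% of the
exact-posterior WAIC).  A norm guard (‖w‖ > 1e6) aborts with a
step-size suggestion.

WAIC is reported per datum with a log-mean-exp lppd and the population
variance of pointwise log-likelihoods; WBIC is the tempered-posterior
(β = 1/log N) mean of the total negative log-likelihood.  Encoder
comparison uses 2 log_e BF₀₁ = 2(F₁ − F₀) from the two WBIC values,
labeled on the Kass–Raftery scale.  The package ships the published WBIC
benchmark table for eight pretrained encoders across ten property tasks
(`graphlda.benchmarks`) so the comparison arithmetic can be reproduced
without the trained models.

## Latent-space analysis

*Multimodality.*  Step 1 projects latent means with UMAP and selects the
target dimension at the knee (normalized max-distance-to-chord) of the
kNN-preservation curve, k = ⌈0.005 N⌉, with a fallback to the smallest
dimension within 95% of the best rate when the curve has no knee.  Step 2
counts clusters by recursive 2-means splitting, accepting a split when
the two-component BIC — full-covariance Gaussian log-likelihood with
hard-assignment mixing weights, penalized by p/2·log n with
p = l + l(l+1)/2 free parameters per component plus one mixing weight —
exceeds the parent's single-Gaussian BIC.  Unbiased covariances are used;
singular covariances get a 1e-6 diagonal ridge (flagged), and a split
producing a child too small to estimate a full covariance is rejected.
Clusters smaller than k are dissolved after splitting and excluded from
the count.  UMAP defaults to 250 neighbors (the visualization setting;
whether the selection step used the same value is not documented
upstream, so it is exposed in the config) and min_dist 0.1.  Neighbor
ties are broken by index for determinism.

*Smoothness.*  For each anchor, the mean of |f(uᵢ) − f(a)|/ε over its M
nearest latent neighbors (Euclidean, self excluded), averaged over
anchors; ε = 1 and M ∈ {5, 10} by convention, with 1000 random
seed-controlled anchors by default.  The Tanimoto profile computes the
mean ECFP4 (radius-2, 2048-bit) similarity between anchors and their
rank-1…50 latent neighbors; empty fingerprints are scored 0 and flagged.

## Synthetic fixtures

The molecule generator grows random valence-respecting trees over a
carbon-weighted C/N/O/F alphabet (≤ 9 heavy atoms by default, a
zinc-like preset with a wider alphabet and n_max 38 exists), optionally
closing 5/6-membered rings, then sanitizes, canonicalizes and
deduplicates.  Properties are deterministic molecular scores — heavy-atom
count, ring count, or an exactly atom-additive logP-like sum of
per-element contributions — plus optional seeded Gaussian noise clipped
at 6σ.  Latent clouds with known modality come from balanced Gaussian
mixtures with means at a guaranteed mutual separation; WAIC/WBIC oracles
come from a linear-Gaussian generator that returns the exact (optionally
tempered) posterior and the closed-form log evidence.

These fixtures emulate the *statistical* shape of curated small-molecule
datasets — valid, low-weight, outlier-free molecules with smooth scalar
properties — not their chemical diversity: no stereochemistry, charged
species, fused ring systems or aromatic heterocycles are generated, and
property noise is homoscedastic.  Passing tests therefore demonstrate the
correctness and qualitative behavior of the machinery at desk scale, not
performance claims about real ZINC/QM9-scale corpora, whose headline
benchmark numbers require full-scale training.

## Known limitations

* The encoder/decoder is a contract-faithful re-specification
  (permutation invariance, single Gaussian latent, symmetric edge
  logits), not a replica of the reference architecture's attention and
  permutation-matrix internals.
* Decoding conditions on the true atom count; sampling novel molecules
  from the prior is out of scope.
* Unadjusted Langevin has O(η²) stationary bias and no Metropolis
  correction; the conjugate oracles bound its practical error at the
  step sizes used.
* Problem sizes in the test suite (200 training molecules, N ≤ 1500
  clustering clouds, 10-seed majorities) are desk-scale choices; the
  full-scale defaults are documented but not exercised by the suite.
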