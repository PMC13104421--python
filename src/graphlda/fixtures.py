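"""Deterministic synthetic inputs: molecules, properties, latent clouds,
and conjugate regression data with closed-form posteriors.

The molecule generator emulates QM9-style inputs by default: chemically
valid low-molecular-weight organics (≤ 9 heavy atoms, alphabet C/N/O/F)
with optional 5/6-membered rings, paired with smooth scalar properties
(additive logP-like scores, atom counts, ring counts) plus optional
Gaussian noise.  All randomness flows through one seeded generator per
call; regeneration under the same seed is bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "FixtureSpec", "gen_molecules", "gen_property", "gen_properties",
    "gen_gaussian_mixture", "gen_conjugate_regression", "ConjugateRegression",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}

# Per-element additive contributions for the logP-like score
# (Crippen-style in spirit: carbon lipophilic, heteroatoms hydrophilic).
_LOGP_CONTRIB = {"C": 0.36, "N": -0.60, "O": -0.63, "F": 0.22}


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 200
    n_max: int = 9
    alphabet: tuple[str, ...] = ("C", "N", "O", "F")
    # carbon-dominated element frequencies, as in small organic datasets
    weights: tuple[float, ...] | None = (0.6, 0.15, 0.15, 0.1)
    ring_prob: float = 0.3
    seed: int = 0

    def element_weights(self) -> np.ndarray:
        if self.weights is not None and len(self.weights) == len(self.alphabet):
            w = np.asarray(self.weights, dtype=np.float64)
        else:
            w = np.ones(len(self.alphabet))
        return w / w.sum()


ZINC_LIKE = FixtureSpec(n_max=38, alphabet=("C", "N", "O", "F", "S", "Cl"),
                        weights=(0.6, 0.12, 0.12, 0.05, 0.06, 0.05))
# extend valences for the zinc-like preset
_VALENCE.update({"S": 2, "Cl": 1})
_LOGP_CONTRIB.update({"S": 0.25, "Cl": 0.65})


def _random_molecule(rng: np.random.Generator, spec: FixtureSpec) -> str | None:
    """Grow a random valence-respecting tree, optionally close a 5/6-ring."""
    n = int(rng.integers(2, spec.n_max + 1))
    w = spec.element_weights()
    symbols = [str(rng.choice(spec.alphabet, p=w)) for _ in range(n)]
    # first atom must support growth
    if _VALENCE[symbols[0]] < 2:
        symbols[0] = "C"
    mol = Chem.RWMol()
    free = []  # remaining valence per atom
    mol.AddAtom(Chem.Atom(symbols[0]))
    free.append(_VALENCE[symbols[0]])
    for sym in symbols[1:]:
        hosts = [i for i, f in enumerate(free) if f >= 1]
        if not hosts:
            break
        host = int(rng.choice(hosts))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(host, idx, Chem.BondType.SINGLE)
        free[host] -= 1
        free.append(_VALENCE[sym] - 1)
    if mol.GetNumAtoms() >= 5 and rng.random() < spec.ring_prob:
        _try_close_ring(mol, free, rng)
    m = mol.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return Chem.MolToSmiles(m)


def _try_close_ring(mol: Chem.RWMol, free: list[int],
                    rng: np.random.Generator) -> None:
    m = mol.GetMol()
    dist = Chem.GetDistanceMatrix(m)
    cands = [(i, j) for i in range(mol.GetNumAtoms())
             for j in range(i + 1, mol.GetNumAtoms())
             if dist[i, j] in (4, 5) and free[i] >= 1 and free[j] >= 1]
    if cands:
        i, j = cands[int(rng.integers(len(cands)))]
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        free[i] -= 1
        free[j] -= 1


def gen_molecules(spec: FixtureSpec) -> list[str]:
    """Generate ``spec.n_molecules`` distinct canonical SMILES."""
    if spec.n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 2000 * spec.n_molecules
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("fixture spec too restrictive to fill; "
                               "increase n_max or the alphabet")
        smi = _random_molecule(rng, spec)
        if smi is not None and smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


def gen_property(smiles: str, kind: str = "additive_logp", seed: int = 0,
                 noise: float = 0.0) -> float:
    """Deterministic scalar property of a molecule, plus optional noise.

    ``atom_count``: heavy-atom count.  ``additive_logp``: sum of per-element
    contributions (exactly additive over fragments).  ``ring_count``: number
    of smallest rings.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if kind == "atom_count":
        base = float(mol.GetNumAtoms())
    elif kind == "additive_logp":
        base = float(sum(_LOGP_CONTRIB.get(a.GetSymbol(), 0.0)
                         for a in mol.GetAtoms()))
    elif kind == "ring_count":
        base = float(mol.GetRingInfo().NumRings())
    else:
        raise ValueError(f"unknown property kind {kind!r}")
    if noise > 0:
        rng = np.random.default_rng(seed)
        eps = float(rng.normal(0.0, noise))
        eps = float(np.clip(eps, -6 * noise, 6 * noise))  # outlier guard
        base += eps
    return base


def gen_properties(smiles_list: list[str], kind: str = "additive_logp",
                   seed: int = 0, noise: float = 0.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    base = np.array([gen_property(s, kind) for s in smiles_list])
    if noise > 0:
        eps = rng.normal(0.0, noise, size=len(base))
        base = base + np.clip(eps, -6 * noise, 6 * noise)
    return base


def gen_gaussian_mixture(k: int, dims: int, separation: float, n: int,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balanced unit-covariance Gaussian mixture with component means at
    mutual distance >= separation (in units of the within-component sigma)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.zeros((k, dims))
    for i in range(1, k):
        for _ in range(10_000):
            cand = rng.normal(0.0, separation, size=dims)
            cand *= (separation * (1 + i)) / (np.linalg.norm(cand) + 1e-12)
            if np.all(np.linalg.norm(means[:i] - cand, axis=1) >= separation):
                means[i] = cand
                break
        else:  # pragma: no cover - ample room in practice
            raise RuntimeError("could not place mixture components")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    points, labels = [], []
    for c in range(k):
        points.append(means[c] + rng.normal(size=(sizes[c], dims)))
        labels.append(np.full(sizes[c], c))
    return np.vstack(points), np.concatenate(labels)


@dataclass
class ConjugateRegression:
    """Linear-Gaussian data with its exact posterior and evidence.

    Model: y = X w + noise·eps, prior w ~ N(0, tau^2 I).  The posterior is
    N(post_mean, post_cov) and log_evidence is the closed-form log marginal
    likelihood; both are exact, for use as oracles against sampled estimates.
    """

    X: np.ndarray
    y: np.ndarray
    w_true: np.ndarray
    noise: float
    tau: float
    post_mean: np.ndarray = field(init=False)
    post_cov: np.ndarray = field(init=False)
    log_evidence: float = field(init=False)

    def __post_init__(self):
        self.post_mean, self.post_cov = self.tempered_posterior(1.0)
        n = len(self.y)
        K = self.noise ** 2 * np.eye(n) + self.tau ** 2 * (self.X @ self.X.T)
        sign, logdet = np.linalg.slogdet(2 * np.pi * K)
        self.log_evidence = float(
            -0.5 * (logdet + self.y @ np.linalg.solve(K, self.y)))

    def tempered_posterior(self, beta: float) -> tuple[np.ndarray, np.ndarray]:
        """Exact Gaussian posterior with the likelihood raised to beta."""
        p = self.X.shape[1]
        prec = beta * (self.X.T @ self.X) / self.noise ** 2 + np.eye(p) / self.tau ** 2
        cov = np.linalg.inv(prec)
        mean = beta * cov @ self.X.T @ self.y / self.noise ** 2
        return mean, cov

    def sample_posterior(self, n_samples: int, seed: int,
                         beta: float = 1.0) -> np.ndarray:
        mean, cov = self.tempered_posterior(beta)
        rng = np.random.default_rng(seed)
        return rng.multivariate_normal(mean, cov, size=n_samples)

    def loglik_matrix(self, W: np.ndarray) -> np.ndarray:
        """Pointwise Gaussian log-likelihoods, shape (S, N)."""
        preds = W @ self.X.T
        resid = self.y[None, :] - preds
        return (-0.5 * resid ** 2 / self.noise ** 2
                - 0.5 * np.log(2 * np.pi * self.noise ** 2))


def gen_conjugate_regression(n: int, p: int, noise: float, seed: int = 0,
                             tau: float = 1.0) -> ConjugateRegression:
    if n <= p:
        raise ValueError("need n > p")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w_true = rng.normal(size=p)
    y = X @ w_true + noise * rng.normal(size=n)
    return ConjugateRegression(X, y, w_true, noise, tau)
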