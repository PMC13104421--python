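"""Generalization evaluation of a frozen encoder with WAIC and WBIC.

A small Bayesian neural network regresses molecular properties on the
encoder's posterior means.  Posterior samples come from unadjusted Langevin
Monte Carlo on the potential U(w) = -log q(w) - beta * sum_i log p(y_i | w),
with beta = 1 for the WAIC posterior and beta = 1/log N for the WBIC
(tempered) posterior.  WAIC is reported per datum; WBIC as a total negative
log-likelihood, matching the conventional scales.  Model comparison uses
2 log_e Bayes factors computed from WBIC free-energy estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "RegressionTask", "BayesianRegressor", "LMCConfig", "potential",
    "lmc_sample", "waic", "wbic", "bayes_factor_2log", "kass_raftery_label",
    "evaluate_encoder", "evaluate_representation",
]

LOG_2PI = float(np.log(2 * np.pi))


@dataclass
class RegressionTask:
    """Supervised data: encoder means X (N, d), standardized targets y (N,),
    and the fixed Gaussian likelihood noise scale s."""

    X: np.ndarray
    y: np.ndarray
    noise: float

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.y) < 2:
            raise ValueError("need at least two observations")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite features")
        if self.noise <= 0:
            raise ValueError("noise scale must be positive")

    @property
    def n(self) -> int:
        return len(self.y)


class BayesianRegressor:
    """Feed-forward regressor with a flattened parameter vector.

    ``architecture='linear'`` gives Bayesian linear regression (the
    conjugate-oracle configuration); ``'mlp'`` one tanh hidden layer.
    The prior is N(0, tau^2 I) over all parameters.
    """

    def __init__(self, in_dim: int, architecture: str = "mlp",
                 hidden: int = 64, tau: float = 1.0, bias: bool = True):
        if architecture not in ("linear", "mlp"):
            raise ValueError(f"unknown architecture {architecture!r}")
        self.in_dim = in_dim
        self.architecture = architecture
        self.hidden = hidden
        self.tau = tau
        self.bias = bias
        if architecture == "linear":
            self.n_params = in_dim + (1 if bias else 0)
        else:
            self.n_params = in_dim * hidden + hidden + hidden + 1

    # autodiff path (used inside the LMC potential)
    def predict_t(self, w: Tensor, X: np.ndarray) -> Tensor:
        Xt = Tensor(X)
        d, h = self.in_dim, self.hidden
        if self.architecture == "linear":
            pred = Xt @ w[:d].reshape(d, 1)
            if self.bias:
                pred = pred + w[d]
            return pred.reshape(-1)
        W1 = w[: d * h].reshape(d, h)
        b1 = w[d * h: d * h + h].reshape(1, h)
        W2 = w[d * h + h: d * h + 2 * h].reshape(h, 1)
        b2 = w[-1]
        return ((Xt @ W1 + b1).tanh() @ W2 + b2).reshape(-1)

    def predict(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        d, h = self.in_dim, self.hidden
        if self.architecture == "linear":
            pred = X @ w[:d]
            return pred + (w[d] if self.bias else 0.0)
        W1 = w[: d * h].reshape(d, h)
        b1 = w[d * h: d * h + h]
        W2 = w[d * h + h: d * h + 2 * h]
        b2 = w[-1]
        return np.tanh(X @ W1 + b1) @ W2 + b2

    def loglik_matrix(self, W: np.ndarray, task: RegressionTask) -> np.ndarray:
        """Pointwise log-likelihoods over samples, shape (S, N)."""
        ll = np.empty((len(W), task.n))
        for s, w in enumerate(W):
            resid = task.y - self.predict(w, task.X)
            ll[s] = (-0.5 * resid ** 2 / task.noise ** 2
                     - 0.5 * np.log(2 * np.pi * task.noise ** 2))
        return ll


@dataclass(frozen=True)
class LMCConfig:
    """Unadjusted Langevin settings.  ``temper`` is the likelihood inverse
    temperature: 1 for the WAIC posterior, 1/log N for WBIC."""

    step: float = 1e-4
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0
    temper: float = 1.0
    init_scale: float = 0.1

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if not 0 < self.temper <= 1:
            raise ValueError("temper must lie in (0, 1]")


def potential(w: np.ndarray, task: RegressionTask,
              regressor: BayesianRegressor,
              beta: float = 1.0) -> tuple[float, np.ndarray]:
    """U(w) = -log q(w) - beta * sum_i log p(y_i | w); value and exact
    gradient (reverse-mode automatic differentiation)."""
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    wt = Tensor(np.asarray(w, dtype=np.float64), requires_grad=True)
    pred = regressor.predict_t(wt, task.X)
    resid = Tensor(task.y) - pred
    nll = ((resid * resid).sum() * (0.5 / task.noise ** 2)
           + task.n * 0.5 * np.log(2 * np.pi * task.noise ** 2))
    prior = ((wt * wt).sum() * (0.5 / regressor.tau ** 2)
             + regressor.n_params * 0.5 * np.log(2 * np.pi * regressor.tau ** 2))
    U = prior + nll * beta
    U.backward()
    value = float(U.data)
    if not np.isfinite(value):
        raise FloatingPointError("non-finite potential")
    return value, wt.grad.copy()


def lmc_sample(potential_fn, n_params: int, config: LMCConfig) -> np.ndarray:
    """Iterate w <- w - (eta^2/2) grad U(w) + eta xi and return the
    post-burn-in, thinned samples; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    w = config.init_scale * rng.standard_normal(n_params)
    eta = config.step
    samples = []
    for k in range(config.n_iterations):
        _, grad = potential_fn(w)
        w = w - 0.5 * eta ** 2 * grad + eta * rng.standard_normal(n_params)
        if np.linalg.norm(w) > 1e6:
            raise FloatingPointError(
                f"LMC diverged at iteration {k}; decrease step {eta:g}")
        if k >= config.burn_in and (k - config.burn_in) % config.thinning == 0:
            samples.append(w.copy())
    return np.array(samples)


def waic(ll: np.ndarray) -> float:
    """Widely applicable information criterion from an (S, N) matrix of
    pointwise posterior log-likelihoods, on the per-datum scale:

        -1/N sum_i log E_w[p(y_i|w)]  +  1/N sum_i Var_w[log p(y_i|w)]

    The first term uses a numerically stable log-mean-exp; the variance is
    the population variance over samples.
    """
    ll = np.asarray(ll, dtype=np.float64)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need an (S, N) matrix with S >= 2")
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite log-likelihoods")
    S = ll.shape[0]
    m = ll.max(axis=0)
    lppd = m + np.log(np.exp(ll - m).sum(axis=0)) - np.log(S)
    penalty = ll.var(axis=0)
    return float(np.mean(-lppd + penalty))


def wbic(ll_tempered: np.ndarray) -> float:
    """WBIC from an (S, N) log-likelihood matrix computed under the
    beta = 1/log N tempered posterior: the posterior mean of the total
    negative log-likelihood (total scale)."""
    ll = np.asarray(ll_tempered, dtype=np.float64)
    if ll.ndim != 2:
        raise ValueError("need an (S, N) matrix")
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite log-likelihoods")
    return float(np.mean(-ll.sum(axis=1)))


def bayes_factor_2log(F0: float, F1: float) -> float:
    """2 log_e BF_01 from two free-energy (WBIC) values: 2 (F1 - F0).

    Positive values favor model 0 (the reference); interpret with
    ``kass_raftery_label``.
    """
    if not (np.isfinite(F0) and np.isfinite(F1)):
        raise ValueError("free energies must be finite")
    return float(2.0 * (F1 - F0))


def kass_raftery_label(two_log_bf: float) -> str:
    """Evidence-strength band for a 2 log_e Bayes factor."""
    if two_log_bf < 0:
        return "negative (supports the alternative model)"
    if two_log_bf <= 2:
        return "not worth more than a bare mention"
    if two_log_bf <= 6:
        return "substantial"
    if two_log_bf <= 10:
        return "strong"
    return "decisive"


# ------------------------------------------------------------ full pipeline

def _estimate_noise(X: np.ndarray, y: np.ndarray, alpha: float = 1.0,
                    floor: float = 0.1) -> float:
    """Residual scale of a preliminary ridge fit (fixes the likelihood s)."""
    from sklearn.linear_model import Ridge

    model = Ridge(alpha=alpha)
    model.fit(X, y)
    resid = y - model.predict(X)
    return max(float(resid.std()), floor)


def evaluate_representation(X: np.ndarray, y: np.ndarray,
                            lmc: LMCConfig = LMCConfig(),
                            architecture: str = "mlp",
                            hidden: int = 64, tau: float = 1.0,
                            noise: float | None = None) -> dict:
    """WAIC and WBIC of a Bayesian NN regression of y on the latent means X.

    Standardizes y, fixes the likelihood noise from a ridge pre-fit, runs
    two LMC chains (beta = 1 and beta = 1/log N) and returns both criteria
    with chain diagnostics.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    y_std = y.std()
    if y_std < 1e-12:
        raise ValueError("property values are constant")
    y = (y - y.mean()) / y_std
    if noise is None:
        noise = _estimate_noise(X, y)
    task = RegressionTask(X, y, noise)
    reg = BayesianRegressor(X.shape[1], architecture=architecture,
                            hidden=hidden, tau=tau)
    N = task.n
    beta_wbic = 1.0 / np.log(N)

    def run(beta: float, cfg: LMCConfig) -> np.ndarray:
        fn = lambda w: potential(w, task, reg, beta=beta)  # noqa: E731
        return lmc_sample(fn, reg.n_params, cfg)

    W1 = run(1.0, replace(lmc, temper=1.0))
    W2 = run(beta_wbic, replace(lmc, temper=beta_wbic, seed=lmc.seed + 1))
    ll1 = reg.loglik_matrix(W1, task)
    ll2 = reg.loglik_matrix(W2, task)
    return {
        "waic": waic(ll1),
        "wbic": wbic(ll2),
        "n": N,
        "noise": noise,
        "beta_wbic": beta_wbic,
        "n_samples": (len(W1), len(W2)),
        "diagnostics": {
            "w_norm_mean": (float(np.linalg.norm(W1, axis=1).mean()),
                            float(np.linalg.norm(W2, axis=1).mean())),
            "finite_fraction": (float(np.isfinite(ll1).mean()),
                                float(np.isfinite(ll2).mean())),
        },
    }


def evaluate_encoder(autoencoder, smiles: list[str], y: np.ndarray,
                     lmc: LMCConfig = LMCConfig(), **kw) -> dict:
    """Encode molecules with a frozen autoencoder and evaluate the latent
    means with ``evaluate_representation``."""
    from .training import prepare_dataset

    graphs = prepare_dataset(smiles, autoencoder.schema,
                             autoencoder.config.n_max)
    X = autoencoder.encode_means(graphs)
    return evaluate_representation(X, np.asarray(y, dtype=np.float64),
                                   lmc=lmc, **kw)
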