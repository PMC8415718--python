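"""Flat-prior Bayesian logistic regression sampled by Hamiltonian Monte Carlo.

The posterior is p(beta | y, X) ∝ prod_i Bernoulli(y_i | F(beta0 + x_i.beta))
with an improper uniform prior on every coefficient (implemented as a zero
log-prior term), so the log-posterior equals the log-likelihood and the
posterior mode coincides with the maximum-likelihood estimate.

Sampling uses HMC with a diagonal mass matrix preconditioned on the observed
information at the MLE (falling back to warmup-estimated scales when the MLE
does not exist, e.g. under separation), leapfrog step size adapted by dual
averaging during warmup, and jittered trajectory lengths.  Chains are
vectorized: one leapfrog step advances all chains with a single matrix
product.  Convergence is gated on the split potential-scale-reduction factor
R-hat < 1.1 for every parameter.

A deterministic Newton (IRLS) maximum-likelihood mode is provided for fast
repeated fits inside wrapper feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BayesianLogit",
    "HMCResults",
    "MLEResults",
    "ConvergenceError",
    "log_likelihood",
    "split_rhat",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, rhat: np.ndarray | None = None):
        super().__init__(message)
        self.rhat = rhat


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood sum_i [y_i log p_i + (1-y_i) log(1-p_i)].

    ``X`` must already include the intercept column.  Computed as
    y*eta - log(1+exp(eta)) via logaddexp, stable for |eta| up to ~700.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    eta = _as_matrix(X) @ np.asarray(beta, dtype=float)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def split_rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    doubling the chain count, which also detects within-chain trends.
    Identical constant chains give exactly 1 (zero-variance guard).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([chains[:, :n], chains[:, chains.shape[1] - n :]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class MLEResults:
    params: np.ndarray
    converged: bool
    iterations: int
    loglike: float
    cov: np.ndarray | None
    names: list[str]

    def predict_prob(self, X) -> np.ndarray:
        X = _with_intercept(_as_matrix(X), len(self.params))
        return _sigmoid(X @ self.params)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov)) if self.cov is not None else np.full_like(self.params, np.nan)
        return pd.DataFrame({"coef": self.params, "se": se}, index=self.names)


@dataclass
class HMCResults:
    """Posterior sample matrix with chain layout and diagnostics.

    ``draws`` is (chains*draws_per_chain) x K_total with the intercept first;
    row order is chain-major (all of chain 0, then chain 1, ...).
    """

    draws: np.ndarray
    chains: int
    draws_per_chain: int
    rhat: np.ndarray
    names: list[str]
    accept_rate: float
    step_size: float

    @property
    def sample_matrix(self) -> np.ndarray:
        return self.draws

    @property
    def params(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def predict_prob(self, X) -> np.ndarray:
        """Posterior mean of the per-draw response probabilities."""
        X = _with_intercept(_as_matrix(X), self.draws.shape[1])
        eta = X @ self.draws.T
        return _sigmoid(eta).mean(axis=1)

    def summary(self) -> pd.DataFrame:
        from .recon import hdi

        q = self.draws
        lo50 = np.empty(q.shape[1])
        hi50 = np.empty(q.shape[1])
        lo99 = np.empty(q.shape[1])
        hi99 = np.empty(q.shape[1])
        for j in range(q.shape[1]):
            lo50[j], hi50[j] = hdi(q[:, j], 0.50)
            lo99[j], hi99[j] = hdi(q[:, j], 0.99)
        return pd.DataFrame(
            {
                "mean": q.mean(axis=0),
                "sd": q.std(axis=0, ddof=1),
                "median": np.median(q, axis=0),
                "hdi50_lower": lo50,
                "hdi50_upper": hi50,
                "hdi99_lower": lo99,
                "hdi99_upper": hi99,
                "rhat": self.rhat,
            },
            index=self.names,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.draws, columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(self.chains), self.draws_per_chain))
        df.to_csv(path, index=False)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _with_intercept(X: np.ndarray, k_total: int) -> np.ndarray:
    if X.shape[1] == k_total:
        return X
    if X.shape[1] == k_total - 1:
        return np.column_stack([np.ones(len(X)), X])
    raise ValueError(f"X has {X.shape[1]} columns; model expects {k_total - 1} (+intercept)")


class BayesianLogit:
    """Flat-prior Bayesian logistic regression model.

    Parameters
    ----------
    endog : binary 0/1 outcome vector.
    exog : predictor matrix or DataFrame (no intercept column; one is added).
    exog_names : optional predictor names (taken from the DataFrame if given).
    """

    def __init__(self, endog, exog, exog_names: list[str] | None = None):
        y = np.asarray(endog, dtype=float).ravel()
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if exog_names is None and isinstance(exog, pd.DataFrame):
            exog_names = [str(c) for c in exog.columns]
        X = _as_matrix(exog)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("exog must be 2-d with one row per outcome")
        self.y = y
        self.X = np.column_stack([np.ones(len(y)), X])
        self.names = ["intercept"] + (
            exog_names if exog_names is not None else [f"x{j + 1}" for j in range(X.shape[1])]
        )

    # -- log posterior (= log likelihood under the flat prior) --------------
    def loglike(self, beta: np.ndarray) -> float:
        eta = self.X @ beta
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    def score(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta
        return self.X.T @ (self.y - _sigmoid(eta))

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        p = _sigmoid(self.X @ beta)
        w = p * (1.0 - p)
        return -(self.X * w[:, None]).T @ self.X

    # -- deterministic MLE (Newton / IRLS) ----------------------------------
    def fit_mle(self, maxiter: int = 60, tol: float = 1e-10) -> MLEResults:
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            p = _sigmoid(X @ beta)
            w = np.clip(p * (1.0 - p), 1e-12, None)
            grad = X.T @ (y - p)
            H = (X * w[:, None]).T @ X
            # minimum-norm step keeps rank-deficient designs (duplicated or
            # collinear columns) usable: predictions stay well defined
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
            # dampen huge steps (separation sends coefficients to infinity)
            norm = np.linalg.norm(step)
            if norm > 20.0:
                step *= 20.0 / norm
            beta = beta + step
            if np.max(np.abs(grad)) < 1e-6 and norm < tol * (1.0 + np.linalg.norm(beta)):
                converged = True
                break
            if np.max(np.abs(beta)) > 40.0:  # drifting to infinity: separation
                break
        cov = None
        if converged:
            p = _sigmoid(X @ beta)
            w = np.clip(p * (1.0 - p), 1e-12, None)
            cov = np.linalg.pinv((X * w[:, None]).T @ X)
        return MLEResults(
            params=beta,
            converged=converged,
            iterations=it,
            loglike=self.loglike(beta),
            cov=cov,
            names=self.names,
        )

    # -- HMC -----------------------------------------------------------------
    def fit(
        self,
        chains: int = 8,
        draws: int = 400,
        warmup: int = 1000,
        seed: int | None = None,
        rhat_threshold: float = 1.1,
        target_accept: float = 0.8,
        max_leapfrog: int = 24,
        jitter: float = 1e-2,
    ) -> HMCResults:
        """Sample the posterior; raises :class:`ConvergenceError` if any
        parameter's split R-hat reaches ``rhat_threshold``."""
        if chains < 2:
            raise ValueError("need >= 2 chains for the R-hat gate")
        rng = np.random.default_rng(seed)
        K = self.X.shape[1]

        mle = self.fit_mle()
        if mle.converged:
            start = np.tile(mle.params, (chains, 1))
            p = _sigmoid(self.X @ mle.params)
            w = np.clip(p * (1.0 - p), 1e-12, None)
            mass = np.clip(np.einsum("ij,i,ij->j", self.X, w, self.X), 1e-8, None)
        else:
            start = np.zeros((chains, K))
            # crude scale: diagonal Fisher information at beta = 0
            mass = np.clip(0.25 * np.einsum("ij,ij->j", self.X, self.X), 1e-8, None)
        start = start + jitter * rng.standard_normal((chains, K)) / np.sqrt(mass)

        draws_out, accept_rate, step_size = self._hmc_run(
            start, mass, chains, draws, warmup, target_accept, max_leapfrog, rng
        )

        rhat = np.array([split_rhat(draws_out[:, :, j]) for j in range(K)])
        if np.any(rhat >= rhat_threshold):
            bad = {self.names[j]: float(rhat[j]) for j in np.flatnonzero(rhat >= rhat_threshold)}
            raise ConvergenceError(
                f"chains failed the R-hat < {rhat_threshold} gate: {bad}", rhat=rhat
            )
        flat = draws_out.reshape(chains * draws, K)
        return HMCResults(
            draws=flat,
            chains=chains,
            draws_per_chain=draws,
            rhat=rhat,
            names=self.names,
            accept_rate=accept_rate,
            step_size=step_size,
        )

    def _hmc_run(self, theta, mass, chains, draws, warmup, target_accept, max_leapfrog, rng):
        X, y = self.X, self.y
        inv_mass = 1.0 / mass
        sqrt_mass = np.sqrt(mass)

        def logp_grad(Th):
            eta = Th @ X.T  # chains x n
            p = _sigmoid(eta)
            lp = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
            grad = (y - p) @ X  # chains x K
            return lp, grad

        lp, grad = logp_grad(theta)
        eps = 0.25  # in preconditioned coordinates; adapted below
        # dual averaging state
        mu = np.log(10 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75

        total = warmup + draws
        out = np.empty((chains, draws, theta.shape[1]))
        acc_sum, acc_n = 0.0, 0

        for it in range(total):
            r = rng.standard_normal(theta.shape) * sqrt_mass
            L = int(rng.integers(max(1, max_leapfrog // 3), max_leapfrog + 1))
            th, g = theta.copy(), grad.copy()
            p_mom = r + 0.5 * eps * g
            for step in range(L):
                th = th + eps * (p_mom * inv_mass)
                lp_new, g = logp_grad(th)
                if step < L - 1:
                    p_mom = p_mom + eps * g
            p_mom = p_mom + 0.5 * eps * g

            ke0 = 0.5 * np.sum(r * r * inv_mass, axis=1)
            ke1 = 0.5 * np.sum(p_mom * p_mom * inv_mass, axis=1)
            log_accept = np.minimum(0.0, (lp_new - ke1) - (lp - ke0))
            log_accept = np.where(np.isfinite(log_accept), log_accept, -np.inf)
            accept = np.log(rng.random(theta.shape[0])) < log_accept

            theta[accept] = th[accept]
            lp = np.where(accept, lp_new, lp)
            grad[accept] = g[accept]
            a_mean = float(np.exp(log_accept).mean())

            if it < warmup:
                # dual averaging on a single shared step size
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - a_mean) / (m + t0)
                log_eps = mu - np.sqrt(m) / gamma * h_bar
                w = m**-kappa
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if it == warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                out[:, it - warmup, :] = theta
                acc_sum += a_mean
                acc_n += 1

        return out, acc_sum / max(acc_n, 1), eps
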