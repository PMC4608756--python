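"""Signal-dependent-noise constrained Gaussian mixtures fitted by EM.

A muscle observed under a mixture of commanded inputs produces tensions
distributed as a Gaussian mixture in which every component obeys the SDN
law: component ``k`` has mean ``mu_k`` and standard deviation
``alpha * mu_k``.  The variance is therefore tied to the mean, leaving only
two free parameters per component (``mu_k`` and the mixing weight
``pi_k``).  The EM M-step for ``mu_k`` has a closed form: maximizing the
expected complete-data log-likelihood reduces to the positive root of

    alpha^2 * N_k * mu^2 + S1 * mu - S2 = 0,

with ``S1 = sum_n gamma_nk x_n`` and ``S2 = sum_n gamma_nk x_n^2``.

The number of components is chosen by BIC with ``2K - 1`` free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["SDNMixtureFit", "fit_sdn_mixture", "select_mixture"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SDNMixtureFit:
    """Converged SDN-constrained mixture for one muscle."""

    K: int
    means: np.ndarray
    mixing: np.ndarray
    responsibilities: np.ndarray  # (N, K)
    effective_counts: np.ndarray  # N_k = sum_n gamma_nk
    log_likelihood: float
    bic: float
    converged: bool
    n_iterations: int
    alpha: float
    muscle_label: str = ""

    def __post_init__(self) -> None:
        for name in ("means", "mixing", "effective_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        object.__setattr__(
            self, "responsibilities", np.atleast_2d(np.asarray(self.responsibilities, float))
        )

    @property
    def component_sds(self) -> np.ndarray:
        """SDN standard deviations ``alpha * mu_k`` of each component."""
        return self.alpha * self.means


def _log_component_densities(x: np.ndarray, means: np.ndarray, alpha: float) -> np.ndarray:
    """(N, K) log N(x_n; mu_k, (alpha mu_k)^2)."""
    sd = alpha * means  # (K,)
    z = (x[:, None] - means[None, :]) / sd[None, :]
    return -0.5 * _LOG_2PI - np.log(sd)[None, :] - 0.5 * z**2


def _m_step_mean(weights: np.ndarray, x: np.ndarray, alpha: float) -> float:
    """Closed-form SDN M-step: positive root of a^2 N_k mu^2 + S1 mu - S2 = 0."""
    nk = weights.sum()
    s1 = weights @ x
    s2 = weights @ x**2
    return float((-s1 + np.sqrt(s1**2 + 4.0 * alpha**2 * nk * s2)) / (2.0 * alpha**2 * nk))


def _m_step_means(gamma: np.ndarray, nk: np.ndarray, x: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized closed-form M-step over all components at once."""
    s1 = gamma.T @ x
    s2 = gamma.T @ x**2
    return (-s1 + np.sqrt(s1**2 + 4.0 * alpha**2 * nk * s2)) / (2.0 * alpha**2 * nk)


def _init_means(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Quantile-spread initial means with mild seeded jitter."""
    q = (np.arange(K) + 0.5) / K
    mu0 = np.quantile(x, q)
    jitter = rng.uniform(0.95, 1.05, K)
    return np.maximum(mu0 * jitter, np.min(x) * 1e-3)


def fit_sdn_mixture(
    values: np.ndarray,
    alpha: float,
    K: int,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
    muscle_label: str = "",
) -> SDNMixtureFit:
    """Fit a K-component SDN-constrained Gaussian mixture by EM.

    Parameters
    ----------
    values
        Strictly positive observations (the SDN density is undefined at
        non-positive means, and component means stay positive only for
        positive data).
    alpha
        The muscle's coefficient of variation (> 0), held fixed.
    K
        Number of mixture components.
    init
        Optional explicit initial means; otherwise data quantiles with
        seeded jitter.
    tol, max_iter
        EM stops when the log-likelihood improves by less than ``tol`` or
        after ``max_iter`` iterations.

    Returns the converged fit including final responsibilities and BIC.
    Components whose effective count falls below ``1e-6 * N`` are dropped
    (with a warning) and the fit continues with fewer components.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < K:
        raise ValueError(f"need at least K={K} observations, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("SDN mixture requires strictly positive values")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")

    rng = np.random.default_rng(seed)
    N = x.size
    means = (
        np.sort(np.asarray(init, dtype=float).ravel())
        if init is not None
        else _init_means(x, K, rng)
    )
    if means.size != K:
        raise ValueError("init must supply K means")
    mixing = np.full(K, 1.0 / K)

    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step (inline log-sum-exp over components)
        log_joint = np.log(mixing)[None, :] + _log_component_densities(x, means, alpha)
        top = log_joint.max(axis=1)
        norm = np.exp(log_joint - top[:, None]).sum(axis=1)
        log_norm = top + np.log(norm)
        gamma = np.exp(log_joint - log_norm[:, None])
        ll = float(log_norm.sum())
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll_prev} -> {ll}); "
                "this indicates a numerical fault"
            )
        # M-step
        nk = gamma.sum(axis=0)
        alive = nk >= 1e-6 * N
        if not np.all(alive):
            warnings.warn(
                f"dropping {np.count_nonzero(~alive)} empty mixture component(s)",
                RuntimeWarning,
                stacklevel=2,
            )
            means = means[alive]
            gamma = gamma[:, alive]
            gamma /= gamma.sum(axis=1, keepdims=True)
            nk = gamma.sum(axis=0)
        mixing = nk / N
        means = _m_step_means(gamma, nk, x, alpha)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

    # final E-step so responsibilities match the returned parameters
    log_joint = np.log(mixing)[None, :] + _log_component_densities(x, means, alpha)
    log_norm = logsumexp(log_joint, axis=1)
    gamma = np.exp(log_joint - log_norm[:, None])
    ll = float(log_norm.sum())
    K_eff = means.size
    p = 2 * K_eff - 1
    bic = -2.0 * ll + p * np.log(N)

    order = np.argsort(means)
    return SDNMixtureFit(
        K=K_eff,
        means=means[order],
        mixing=mixing[order],
        responsibilities=gamma[:, order],
        effective_counts=gamma[:, order].sum(axis=0),
        log_likelihood=ll,
        bic=float(bic),
        converged=converged,
        n_iterations=n_iter,
        alpha=float(alpha),
        muscle_label=muscle_label,
    )


def select_mixture(
    values: np.ndarray,
    alpha: float,
    K_max: int = 5,
    restarts: int = 5,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    muscle_label: str = "",
) -> SDNMixtureFit:
    """Fit mixtures with K = 1..K_max and return the one minimizing BIC.

    Each K is fitted from ``restarts`` seeded initializations and the best
    log-likelihood kept; candidates then compete on
    ``BIC = -2 log L + (2K - 1) ln N``.  Ties favour the smaller model.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    x = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    best: SDNMixtureFit | None = None
    for K in range(1, min(K_max, x.size) + 1):
        best_k: SDNMixtureFit | None = None
        for _ in range(max(restarts, 1)):
            fit = fit_sdn_mixture(
                x,
                alpha,
                K,
                tol=tol,
                max_iter=max_iter,
                seed=rng.integers(2**31),
                muscle_label=muscle_label,
            )
            if best_k is None or fit.log_likelihood > best_k.log_likelihood:
                best_k = fit
        assert best_k is not None
        if best is None or best_k.bic < best.bic:
            best = best_k
    assert best is not None
    return best
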