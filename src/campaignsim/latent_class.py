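"""Latent class analysis for categorical survey indicators.

Classical finite-mixture model for J categorical items: class k has mixing
proportion pi_k and item-response probabilities rho[k, j, m] = P(item j takes
category m | class k), with items conditionally independent given class.
Fitted by EM from multiple random starts; model selection by BIC with AIC and
relative entropy reported alongside.

Data are integer-coded matrices (N x J) with categories 1..M_j per item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RHO_FLOOR = 1e-6  # item-response probabilities floored and renormalized each M-step


class DegenerateModelError(ValueError):
    """Requested class count exceeds the number of distinct response patterns."""


@dataclass
class LCAModel:
    """A fitted latent class solution.

    Attributes
    ----------
    K : number of latent classes.
    mixing_proportions : (K,) class proportions pi, summing to 1.
    item_response : list of K x M_j arrays, one per item; rows sum to 1.
    log_likelihood : maximized observed-data log-likelihood.
    n_params : (K-1) + K * sum_j (M_j - 1).
    aic, bic : information criteria (-2*ll + 2p, -2*ll + p*ln N).
    entropy_R2 : relative-entropy classification quality in [0, 1].
    n_obs : sample size the model was fitted to.
    """

    K: int
    mixing_proportions: np.ndarray
    item_response: list[np.ndarray]
    log_likelihood: float
    n_params: int
    aic: float
    bic: float
    entropy_R2: float
    n_obs: int
    converged: bool = True
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_items(self) -> int:
        return len(self.item_response)

    def summary(self) -> dict:
        return {
            "K": self.K,
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "entropy_R2": self.entropy_R2,
            "mixing_proportions": self.mixing_proportions.tolist(),
        }


@dataclass
class ClassAssignment:
    """Posterior membership probabilities and modal class labels (1-based)."""

    posterior: np.ndarray  # (N, K), rows sum to 1
    modal_class: np.ndarray  # (N,), values in 1..K

    @property
    def K(self) -> int:
        return self.posterior.shape[1]


# ---------------------------------------------------------------------------
# fitting


def _validate_data(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data)
    if data.ndim != 2 or data.size == 0:
        raise ValueError("indicator data must be a non-empty N x J matrix")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.asarray(data, float) == np.asarray(data, float).astype(int)):
            raise ValueError("indicator codes must be integers")
        data = data.astype(int)
    if data.min() < 1:
        raise ValueError("indicator codes must start at 1")
    n_cats = data.max(axis=0)
    return data, n_cats


def _log_component_densities(data: np.ndarray, log_pi: np.ndarray,
                             log_rho: list[np.ndarray]) -> np.ndarray:
    """(N, K) array of log pi_k + sum_j log rho[k, j, x_ij]."""
    N = data.shape[0]
    K = log_pi.shape[0]
    ll = np.broadcast_to(log_pi, (N, K)).copy()
    for j, lr in enumerate(log_rho):
        ll += lr[:, data[:, j] - 1].T  # lr is (K, M_j)
    return ll


def _em_single_start(data: np.ndarray, n_cats: np.ndarray, K: int,
                     rng: np.random.Generator, tol: float, max_iter: int):
    N, J = data.shape
    pi = rng.dirichlet(np.ones(K))
    rho = [rng.dirichlet(np.ones(m), size=K) for m in n_cats]

    trace = []
    prev = -np.inf
    converged = False
    post = None
    for it in range(max_iter):
        log_rho = [np.log(r) for r in rho]
        logd = _log_component_densities(data, np.log(pi), log_rho)
        m = logd.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logd - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        post = np.exp(logd - lse[:, None])

        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll

        # M-step
        nk = post.sum(axis=0)
        pi = nk / N
        rho = []
        for j, m_j in enumerate(n_cats):
            onehot = np.zeros((N, m_j))
            onehot[np.arange(N), data[:, j] - 1] = 1.0
            r = post.T @ onehot  # (K, M_j)
            r = np.maximum(r / nk[:, None], RHO_FLOOR)
            rho.append(r / r.sum(axis=1, keepdims=True))
    return pi, rho, trace[-1], np.array(trace), post, converged, len(trace)


def entropy_R2(posterior: np.ndarray) -> float:
    """Relative entropy of a posterior matrix: 1 - sum(-p ln p) / (N ln K).

    Equals 1 for perfectly separated (one-hot) rows, 0 for uniform rows.
    Returns 1.0 by convention for K=1, where classification is trivial.
    """
    posterior = np.asarray(posterior, float)
    N, K = posterior.shape
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(posterior > 0, posterior * np.log(posterior), 0.0)
    return float(1.0 + plogp.sum() / (N * np.log(K)))


def fit_lca(data, K: int, n_starts: int = 10, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500) -> LCAModel:
    """Fit a K-class model by EM from ``n_starts`` random initializations.

    Initial parameters are flat-Dirichlet draws; the start achieving the
    highest converged log-likelihood is returned. Within each start the
    log-likelihood is non-decreasing (guaranteed by EM; asserted in tests).
    """
    data, n_cats = _validate_data(data)
    N, J = data.shape
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if not 1 <= K <= N:
        raise ValueError(f"K={K} out of range for N={N}")
    n_patterns = len({tuple(row) for row in data})
    if K > n_patterns:
        raise DegenerateModelError(
            f"K={K} exceeds the {n_patterns} distinct response patterns")

    if K == 1:
        # closed form: single-class MLE is the empirical item distribution
        pi = np.ones(1)
        rho = []
        ll = 0.0
        for j, m_j in enumerate(n_cats):
            counts = np.bincount(data[:, j] - 1, minlength=m_j).astype(float)
            p = counts / N
            pos = counts > 0
            ll += float((counts[pos] * np.log(p[pos])).sum())
            rho.append(np.maximum(p, RHO_FLOOR)[None, :])
            rho[-1] /= rho[-1].sum()
        best = (pi, rho, ll, np.array([ll]), np.ones((N, 1)), True, 1)
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            res = _em_single_start(data, n_cats, K, rng, tol, max_iter)
            if best is None or res[2] > best[2]:
                best = res

    pi, rho, ll, trace, post, converged, n_iter = best
    n_params = (K - 1) + K * int((n_cats - 1).sum())
    return LCAModel(
        K=K, mixing_proportions=pi, item_response=rho, log_likelihood=ll,
        n_params=n_params, aic=-2 * ll + 2 * n_params,
        bic=-2 * ll + n_params * np.log(N),
        entropy_R2=entropy_R2(post), n_obs=N, converged=converged,
        n_iter=n_iter, loglik_trace=trace,
    )


def select_model(models: list[LCAModel]) -> LCAModel:
    """Pick the minimum-BIC model; ties go to the smaller K."""
    if not models:
        raise ValueError("no models to select from")
    return min(models, key=lambda m: (m.bic, m.K))


def comparison_table(models: list[LCAModel]) -> pd.DataFrame:
    """K-vs-criteria table reported alongside selection."""
    return pd.DataFrame(
        [{"K": m.K, "log_likelihood": m.log_likelihood, "n_params": m.n_params,
          "aic": m.aic, "bic": m.bic, "entropy_R2": m.entropy_R2}
         for m in sorted(models, key=lambda m: m.K)]
    )


def posterior_and_modal(model: LCAModel, data) -> ClassAssignment:
    """Posterior membership (rows proportional to pi_k * prod_j rho) and
    modal labels; posterior ties resolve to the lowest class index."""
    data, n_cats = _validate_data(data)
    if len(n_cats) != model.n_items:
        raise ValueError("data items do not match the fitted model")
    for j, r in enumerate(model.item_response):
        if n_cats[j] > r.shape[1]:
            raise ValueError(f"item {j} has unseen category codes")
    logd = _log_component_densities(
        data, np.log(model.mixing_proportions),
        [np.log(r) for r in model.item_response])
    m = logd.max(axis=1, keepdims=True)
    w = np.exp(logd - m)
    tot = w.sum(axis=1, keepdims=True)
    if np.any(tot <= 0) or not np.all(np.isfinite(tot)):
        raise FloatingPointError("zero total posterior density for some row")
    post = w / tot
    return ClassAssignment(posterior=post, modal_class=post.argmax(axis=1) + 1)


# ---------------------------------------------------------------------------
# label alignment (estimated classes are identified only up to permutation)


def align_labels(model: LCAModel, reference: list[np.ndarray]) -> np.ndarray:
    """Greedy permutation matching estimated to reference item-response
    profiles by total-variation distance; returns perm with
    ``perm[estimated_k] = reference_k``."""
    K = model.K
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = sum(
                0.5 * np.abs(model.item_response[j][a] - reference[j][b]).sum()
                for j in range(model.n_items))
    perm = np.full(K, -1)
    used = set()
    for a, b in sorted(((a, b) for a in range(K) for b in range(K)),
                       key=lambda ab: cost[ab]):
        if perm[a] < 0 and b not in used:
            perm[a] = b
            used.add(b)
    return perm


def simulate_lca(pi: np.ndarray, rho: list[np.ndarray], N: int,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw N observations from a latent class model; returns (data, labels).

    Used by the recovery tests and as a generic categorical-mixture sampler.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, float)
    labels = rng.choice(len(pi), size=N, p=pi)
    data = np.empty((N, len(rho)), int)
    for j, r in enumerate(rho):
        cum = np.cumsum(r, axis=1)
        u = rng.random(N)
        data[:, j] = (u[:, None] > cum[labels]).sum(axis=1) + 1
    return data, labels + 1
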