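"""Binomial latent class analysis of genotype matrices.

Each SNP genotype is modelled as a Binomial(2, theta_kj) count given latent
class k, with class weights pi.  Missing genotypes are handled
available-case under a missing-at-random assumption: a sample contributes
only its observed markers to the likelihood.  Estimation is EM with random
restarts; the number of classes is chosen either by a parametric-bootstrap
likelihood-ratio test of K vs K+1 classes or by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, logsumexp

from .genotypes import GenotypeMatrix

__all__ = [
    "LCAModel",
    "LCAPosterior",
    "BootstrapLRResult",
    "ZScoreTable",
    "lca_loglik",
    "lca_fit",
    "lca_assign",
    "bootstrap_lr_test",
    "select_k",
    "lca_zscores",
    "simulate_from_model",
]

_EPS = 1e-6  # clamp for theta, keeps the likelihood finite near the boundary


@dataclass
class LCAModel:
    K: int
    weights: np.ndarray          # pi_k, sums to 1
    theta: np.ndarray            # K x m class-specific allele frequencies
    loglik: float
    n_iter: int = 0
    converged: bool = True
    restart_index: int = 0
    loglik_trace: np.ndarray | None = None  # per-iteration loglik of the kept restart

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K * self.theta.shape[1]

    def bic(self, n: int) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(n)


@dataclass
class LCAPosterior:
    responsibilities: np.ndarray  # n x K, rows sum to 1
    modal_label: np.ndarray       # 1..K, ties -> lowest class index
    max_prob: np.ndarray


@dataclass
class BootstrapLRResult:
    observed_lr: float
    B: int
    count_geq: int
    p_value: float
    replicate_lrs: np.ndarray
    seed: int | None


@dataclass
class ZScoreTable:
    z: np.ndarray                # K x m
    significant: np.ndarray      # |z| > 1.96 (0.05 level)
    se: np.ndarray
    gamma: np.ndarray


def _prepare(G: GenotypeMatrix):
    vals = np.nan_to_num(G.values)
    obs = (~G.missing_mask).astype(float)
    empty = obs.sum(axis=1) == 0
    if empty.any():
        bad = [G.sample_ids[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"samples with zero observed markers: {bad}")
    # class-independent log C(2, g): log 2 for heterozygotes, 0 otherwise
    const = (np.log(2.0) * ((vals == 1.0) & (obs == 1.0))).sum(axis=1)
    return vals, obs, const


def _log_class_lik(vals, obs, const, theta):
    """n x K matrix of per-class log-likelihood contributions (no weights)."""
    th = np.clip(theta, _EPS, 1 - _EPS)
    return vals @ np.log(th).T + (2.0 * obs - vals) @ np.log1p(-th).T + const[:, None]


def lca_loglik(G: GenotypeMatrix, model: LCAModel) -> float:
    """Observed-data log-likelihood, summing each sample over classes in log space."""
    if model.theta.shape[1] != G.m:
        raise ValueError("model and genotype matrix have different marker counts")
    vals, obs, const = _prepare(G)
    comp = _log_class_lik(vals, obs, const, model.theta)
    return float(logsumexp(np.log(model.weights) + comp, axis=1).sum())


def _posterior(vals, obs, const, weights, theta):
    logp = np.log(weights) + _log_class_lik(vals, obs, const, theta)
    norm = logsumexp(logp, axis=1)
    r = np.exp(logp - norm[:, None])
    return r, float(norm.sum())


def lca_fit(G: GenotypeMatrix, K: int, n_restarts: int = 10, tol: float = 1e-8,
            max_iter: int = 1000, seed: int | None = None
            ) -> tuple[LCAModel, LCAPosterior]:
    """Fit a K-class binomial mixture by EM with random restarts.

    Each restart initialises random responsibilities, applies an M-step and
    iterates EM until the relative log-likelihood change falls below ``tol``.
    The best restart by log-likelihood is returned; classes are canonicalised
    by descending weight.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n:
        raise ValueError(f"K={K} exceeds the sample count n={G.n}")
    vals, obs, const = _prepare(G)
    n = G.n
    rng = np.random.default_rng(seed)

    best: tuple | None = None
    for restart in range(max(1, n_restarts) if K > 1 else 1):
        r = rng.random((n, K)) + 1e-3
        r /= r.sum(axis=1, keepdims=True)
        ll_old = -np.inf
        converged = False
        trace: list[float] = []
        for it in range(1, max_iter + 1):
            # M-step
            weights = r.mean(axis=0)
            weights = np.clip(weights, 1e-12, None)
            weights /= weights.sum()
            num = r.T @ vals
            den = 2.0 * (r.T @ obs)
            theta = np.clip(num / np.clip(den, 1e-300, None), _EPS, 1 - _EPS)
            # E-step
            r, ll = _posterior(vals, obs, const, weights, theta)
            trace.append(ll)
            if ll - ll_old <= tol * (abs(ll_old) + 1.0) and it > 1:
                converged = True
                break
            ll_old = ll
        if best is None or ll > best[0]:
            best = (ll, weights, theta, it, converged, restart, trace)

    ll, weights, theta, n_iter, converged, restart, trace = best
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")
    order = np.argsort(-weights, kind="stable")
    weights, theta = weights[order], theta[order]
    r, ll = _posterior(vals, obs, const, weights, theta)
    model = LCAModel(K=K, weights=weights, theta=theta, loglik=ll,
                     n_iter=n_iter, converged=converged, restart_index=restart,
                     loglik_trace=np.asarray(trace))
    return model, _make_posterior(r)


def _make_posterior(r: np.ndarray) -> LCAPosterior:
    modal = np.argmax(r, axis=1) + 1  # argmax takes the lowest index on ties
    return LCAPosterior(responsibilities=r, modal_label=modal,
                        max_prob=r.max(axis=1))


def lca_assign(posterior: LCAPosterior) -> dict:
    """Modal class labels plus the reliability bands of the assignment.

    Reports the fractions of samples whose maximum membership probability is
    above 0.9 (reliable) and below 0.6 (unreliable).
    """
    return {
        "labels": posterior.modal_label,
        "frac_above_0.9": float((posterior.max_prob > 0.9).mean()),
        "frac_below_0.6": float((posterior.max_prob < 0.6).mean()),
    }


def simulate_from_model(model: LCAModel, n: int, missing_mask: np.ndarray | None,
                        rng: np.random.Generator) -> GenotypeMatrix:
    """Draw a genotype matrix from a fitted model, imposing a missing mask."""
    classes = rng.choice(model.K, size=n, p=model.weights)
    probs = model.theta[classes]  # n x m
    vals = rng.binomial(2, probs).astype(float)
    if missing_mask is not None:
        vals[missing_mask] = np.nan
    m = model.theta.shape[1]
    return GenotypeMatrix([f"s{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)], vals)


def bootstrap_lr_test(G: GenotypeMatrix, N: int, B: int = 500,
                      seed: int | None = None, inner_restarts: int = 3,
                      n_restarts: int = 10, tol: float = 1e-8,
                      max_iter: int = 1000) -> BootstrapLRResult:
    """Parametric-bootstrap LR test of N classes against N + 1.

    The observed statistic is LR = 2 (loglik_{N+1} - loglik_N) on the data.
    Each replicate simulates a dataset from the fitted N-class model (with
    the observed missing mask preserved exactly), refits both models and
    records its LR.  p = (1 + #{LR_b >= LR_obs}) / (B + 1), never zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    null_model, _ = lca_fit(G, N, n_restarts=n_restarts, tol=tol,
                            max_iter=max_iter, seed=int(rng.integers(2**31)))
    alt_model, _ = lca_fit(G, N + 1, n_restarts=n_restarts, tol=tol,
                           max_iter=max_iter, seed=int(rng.integers(2**31)))
    lr_obs = 2.0 * (alt_model.loglik - null_model.loglik)
    if lr_obs < 0:
        if lr_obs < -1e-6 * (abs(null_model.loglik) + 1):
            warnings.warn(f"negative observed LR {lr_obs:.3g} clamped to 0")
        lr_obs = 0.0

    mask = G.missing_mask
    lrs = np.empty(B)
    for b in range(B):
        try:
            Gb = simulate_from_model(null_model, G.n, mask, rng)
            m0, _ = lca_fit(Gb, N, n_restarts=inner_restarts, tol=tol,
                            max_iter=max_iter, seed=int(rng.integers(2**31)))
            m1, _ = lca_fit(Gb, N + 1, n_restarts=inner_restarts, tol=tol,
                            max_iter=max_iter, seed=int(rng.integers(2**31)))
        except Exception as err:  # propagate with replicate context
            raise RuntimeError(f"bootstrap replicate {b} failed: {err}") from err
        lrs[b] = max(0.0, 2.0 * (m1.loglik - m0.loglik))
    count_geq = int((lrs >= lr_obs).sum())
    return BootstrapLRResult(observed_lr=lr_obs, B=B, count_geq=count_geq,
                             p_value=(count_geq + 1) / (B + 1),
                             replicate_lrs=lrs, seed=seed)


def select_k(G: GenotypeMatrix, mode: str = "bootstrap_lr", alpha: float = 0.05,
             K_max: int = 10, B: int = 500, seed: int | None = None,
             **fit_kwargs) -> tuple[int, list]:
    """Choose the number of latent classes.

    ``bootstrap_lr``: starting at N=1, test N vs N+1 and increment while the
    bootstrap p-value is below ``alpha``; stop at the first non-rejection (or
    at ``K_max``).  ``bic``: fit K = 1..K_max and return the BIC minimiser.
    Returns the chosen K with the full selection trace.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    rng = np.random.default_rng(seed)
    trace: list = []
    if mode == "bootstrap_lr":
        K = 1
        while K < K_max:
            res = bootstrap_lr_test(G, K, B=B, seed=int(rng.integers(2**31)),
                                    **fit_kwargs)
            trace.append({"N": K, "p_value": res.p_value, "lr": res.observed_lr})
            if res.p_value >= alpha:
                return K, trace
            K += 1
        return K, trace
    if mode == "bic":
        best_k, best_bic = 1, np.inf
        for K in range(1, K_max + 1):
            model, _ = lca_fit(G, K, seed=int(rng.integers(2**31)), **fit_kwargs)
            bic = model.bic(G.n)
            trace.append({"K": K, "bic": bic, "loglik": model.loglik})
            if bic < best_bic:
                best_k, best_bic = K, bic
        return best_k, trace
    raise ValueError(f"unknown mode {mode!r}")


def _pack(weights, theta):
    """Effect-coded parameter vector: pi log-odds, per-marker intercepts beta_j
    and class effects gamma_kj (k = 1..K-1; gamma_K = -sum of the others)."""
    K, m = theta.shape
    lt = logit(np.clip(theta, _EPS, 1 - _EPS))
    beta = lt.mean(axis=0)
    gamma = lt - beta  # K x m, columns sum to 0
    alpha = np.log(weights[:-1] / weights[-1]) if K > 1 else np.empty(0)
    return np.concatenate([alpha, beta, gamma[:-1].ravel()])


def _unpack(x, K, m):
    alpha, beta, gfree = x[:K - 1], x[K - 1:K - 1 + m], x[K - 1 + m:]
    expa = np.exp(np.concatenate([alpha, [0.0]]))
    weights = expa / expa.sum()
    gamma = np.empty((K, m))
    if K > 1:
        gamma[:-1] = gfree.reshape(K - 1, m)
        gamma[-1] = -gamma[:-1].sum(axis=0)
    else:
        gamma[:] = 0.0
    theta = expit(beta + gamma)
    return weights, theta, gamma


def lca_zscores(G: GenotypeMatrix, model: LCAModel) -> ZScoreTable:
    """Wald Z-scores for class-specific SNP effects.

    theta is reparameterised as logit(theta_kj) = beta_j + gamma_kj with the
    gamma summing to zero over classes; standard errors come from the inverse
    observed information of the full log-likelihood, computed by central
    finite differences at the MLE.  |z| > 1.96 flags a SNP as influential for
    a class at the 0.05 level.
    """
    K, m = model.theta.shape
    if K == 1:
        zeros = np.zeros((1, m))
        return ZScoreTable(z=zeros, significant=zeros.astype(bool),
                           se=np.full((1, m), np.nan), gamma=zeros)
    vals, obs, const = _prepare(G)
    x0 = _pack(model.weights, model.theta)

    def negll(x):
        weights, theta, _ = _unpack(x, K, m)
        comp = _log_class_lik(vals, obs, const, theta)
        return -float(logsumexp(np.log(weights) + comp, axis=1).sum())

    P = x0.size
    h = 1e-4 * np.maximum(1.0, np.abs(x0))
    H = np.empty((P, P))
    f0 = negll(x0)
    # diagonal
    for i in range(P):
        e = np.zeros(P); e[i] = h[i]
        H[i, i] = (negll(x0 + e) - 2 * f0 + negll(x0 - e)) / h[i] ** 2
    for i in range(P):
        for j in range(i + 1, P):
            ei = np.zeros(P); ei[i] = h[i]
            ej = np.zeros(P); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                negll(x0 + ei + ej) - negll(x0 + ei - ej)
                - negll(x0 - ei + ej) + negll(x0 - ei - ej)
            ) / (4 * h[i] * h[j])

    try:
        cov = np.linalg.inv(H)
        singular = not np.all(np.isfinite(cov))
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        warnings.warn("observed information is singular; using pseudo-inverse, "
                      "non-identified entries reported as missing")
        cov = np.linalg.pinv(H)

    _, _, gamma = _unpack(x0, K, m)
    off = K - 1 + m  # start of the free gamma block
    var = np.empty((K, m))
    for j in range(m):
        idx = [off + k * m + j for k in range(K - 1)]
        block = cov[np.ix_(idx, idx)]
        for k in range(K - 1):
            var[k, j] = block[k, k]
        var[K - 1, j] = block.sum()  # Var(-sum of free gammas)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(var)
        bad = ~np.isfinite(se) | (se <= 0)
        z = np.where(bad, np.nan, gamma / np.where(bad, 1.0, se))
    if np.any(bad):
        warnings.warn("some Z-scores are undefined (non-positive variance)")
    sig = np.abs(z) > 1.96
    sig = np.where(np.isnan(z), False, sig)
    return ZScoreTable(z=z, significant=sig.astype(bool), se=se, gamma=gamma)
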