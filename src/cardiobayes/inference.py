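"""MCMC fitting of the parameter graph and convergence diagnostics.

The posterior targets the Bernoulli likelihood of the pathogenic/benign
labels under the class-specific linear predictors, with N(0, v) priors on
coefficients and the hierarchical zero-mean normal / inverse-gamma prior
on domain effects.  The sampler is an adaptive random-walk
Metropolis-within-Gibbs: each scalar parameter is updated by a univariate
Metropolis step whose proposal scale adapts toward a 44% acceptance rate
during burn-in (and is frozen afterwards, preserving detailed balance in
the kept draws); the domain-effect variance is conjugate and drawn
exactly from its inverse-gamma full conditional.

Convergence is assessed per parameter by the potential scale reduction

    R = sqrt(Var(phi|y) / W),   Var(phi|y) = W (n-1)/n + B / n

with W the within-chain variance, B the variance of the per-chain means
and n the number of kept draws per chain; R < 1.1 is taken as converged.
Posterior medians over the pooled kept draws are the plug-in fitted
values used for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardiobayes.model_network import ParameterGraph
from cardiobayes.annotations import VariantRecord

_TARGET_ACCEPT = 0.44


class InferenceError(RuntimeError):
    pass


@dataclass
class ChainSet:
    """Kept posterior draws: one (n_chains, n_kept) array per parameter."""

    draws: dict[str, np.ndarray]
    seed: int
    n_iter: int
    burn_fraction: float

    @property
    def param_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, parameter: str) -> np.ndarray:
        return self.draws[parameter].ravel()


@dataclass
class ConvergenceStats:
    parameter: str
    W: float
    B: float
    var_hat: float
    R: float


@dataclass
class PosteriorSummary:
    """Per-parameter posterior medians (the plug-in values) and quantiles."""

    median: dict[str, float]
    q05: dict[str, float]
    q95: dict[str, float]

    def values(self) -> dict[str, float]:
        return dict(self.median)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # Bernoulli-logistic log likelihood; logaddexp for numerical stability
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    if not np.isfinite(ll):
        raise InferenceError("non-finite log likelihood")
    return ll


def _run_chain(
    X: np.ndarray,
    y: np.ndarray,
    prior_var: np.ndarray,
    delta_idx: np.ndarray,
    sigma_shape: float,
    sigma_rate: float,
    n_iter: int,
    n_burn: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One chain; returns kept draws (n_kept, k) and sigma2 draws (n_kept,)."""
    n, k = X.shape
    has_sigma = delta_idx.size > 0
    is_delta = np.zeros(k, dtype=bool)
    is_delta[delta_idx] = True

    theta = rng.normal(0.0, 0.1, size=k)
    sigma2 = 1.0
    eta = X @ theta
    ll = _log_likelihood(eta, y)
    log_scale = np.full(k, np.log(0.5))
    cols = [X[:, j] for j in range(k)]
    informative = np.array([np.any(c != 0.0) for c in cols])

    kept = np.empty((n_iter - n_burn, k))
    kept_sigma = np.empty(n_iter - n_burn)

    for t in range(n_iter):
        adapt = t < n_burn
        gamma = min(0.1, 2.0 / np.sqrt(t + 1.0)) if adapt else 0.0
        steps = np.exp(log_scale) * rng.standard_normal(k)
        unif = np.log(rng.random(k))
        for j in range(k):
            d = steps[j]
            new = theta[j] + d
            pv = sigma2 if is_delta[j] else prior_var[j]
            log_prior_diff = (theta[j] ** 2 - new**2) / (2.0 * pv)
            if informative[j]:
                eta_new = eta + cols[j] * d
                ll_new = float(y @ eta_new - np.logaddexp(0.0, eta_new).sum())
                log_ratio = ll_new - ll + log_prior_diff
            else:
                log_ratio = log_prior_diff
            accepted = unif[j] < log_ratio
            if accepted:
                theta[j] = new
                if informative[j]:
                    eta = eta_new
                    ll = ll_new
            if adapt:
                log_scale[j] += gamma * ((1.0 if accepted else 0.0) - _TARGET_ACCEPT)
        if has_sigma:
            deltas = theta[delta_idx]
            shape = sigma_shape + 0.5 * deltas.size
            rate = sigma_rate + 0.5 * float(deltas @ deltas)
            sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)
        if t >= n_burn:
            kept[t - n_burn] = theta
            kept_sigma[t - n_burn] = sigma2
    return kept, kept_sigma


def fit(
    graph: ParameterGraph,
    training: list[VariantRecord],
    n_chains: int = 10,
    n_iter: int = 40_000,
    burn_fraction: float = 0.2,
    seed: int = 0,
    until_converged: bool = False,
    rhat_threshold: float = 1.1,
    max_rounds: int = 3,
) -> ChainSet:
    """Sample the posterior of the graph's parameters on labelled variants.

    Chains are independently seeded from the master seed.  The first
    ``burn_fraction`` of each chain is discarded.  With
    ``until_converged``, the run is repeated with doubled iteration counts
    (up to ``max_rounds`` times) until every parameter satisfies
    R < ``rhat_threshold``.
    """
    if not training:
        raise InferenceError("training set is empty")
    labels = {v.label for v in training}
    if labels != {"pathogenic", "benign"}:
        raise InferenceError(
            f"training set must contain both labels; found {sorted(l or '?' for l in labels)}"
        )
    X, y = graph.encode(training)
    prior_var = np.array([graph.prior_var.get(name, np.nan) for name in graph.param_names])
    delta_names = graph.sigma_groups.get("sigma2_dom", [])
    delta_idx = np.array([graph.index(n) for n in delta_names], dtype=int)
    shape = graph.config.hyper.domain_variance_shape
    rate = graph.config.hyper.domain_variance_rate

    current_iter = n_iter
    for round_no in range(max_rounds):
        n_burn = int(round(current_iter * burn_fraction))
        seeds = np.random.SeedSequence(seed).spawn(n_chains)
        chains, sigmas = [], []
        for ss in seeds:
            kept, kept_sigma = _run_chain(
                X, y, prior_var, delta_idx, shape, rate,
                current_iter, n_burn, np.random.default_rng(ss),
            )
            chains.append(kept)
            sigmas.append(kept_sigma)
        draws = {
            name: np.stack([c[:, j] for c in chains])
            for j, name in enumerate(graph.param_names)
        }
        if delta_idx.size:
            draws["sigma2_dom"] = np.stack(sigmas)
        chain_set = ChainSet(
            draws=draws, seed=seed, n_iter=current_iter, burn_fraction=burn_fraction
        )
        if not until_converged or max_rhat(chain_set) < rhat_threshold:
            return chain_set
        current_iter *= 2
    return chain_set


def potential_scale_reduction(chains: ChainSet, parameter: str) -> float:
    """R = sqrt(Var(phi|y) / W) for one parameter.

    W is the mean within-chain variance, B the variance of the per-chain
    means, and Var(phi|y) = W (n-1)/n + B/n with n kept draws per chain.
    When all chains agree exactly (W = 0), R is defined as 1.
    """
    draws = chains.draws[parameter]
    n_chains, n = draws.shape
    if n_chains < 2:
        raise InferenceError("potential scale reduction requires at least two chains")
    if n < 2:
        raise InferenceError("potential scale reduction requires at least two draws")
    W = float(draws.var(axis=1, ddof=1).mean())
    B = float(draws.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0
    var_hat = W * (n - 1) / n + B / n
    return float(np.sqrt(var_hat / W))


def convergence_stats(chains: ChainSet) -> dict[str, ConvergenceStats]:
    out = {}
    for name, draws in chains.draws.items():
        n = draws.shape[1]
        W = float(draws.var(axis=1, ddof=1).mean())
        B = float(draws.mean(axis=1).var(ddof=1))
        R = 1.0 if W == 0.0 else float(np.sqrt((W * (n - 1) / n + B / n) / W))
        out[name] = ConvergenceStats(parameter=name, W=W, B=B,
                                     var_hat=W * (n - 1) / n + B / n, R=R)
    return out


def max_rhat(chains: ChainSet) -> float:
    return max(s.R for s in convergence_stats(chains).values())


def summarise(chains: ChainSet) -> PosteriorSummary:
    """Pooled posterior medians and 5%/95% quantiles per parameter."""
    if not chains.draws:
        raise InferenceError("empty chain set")
    median, q05, q95 = {}, {}, {}
    for name in chains.draws:
        pooled = chains.pooled(name)
        median[name] = float(np.median(pooled))
        q05[name] = float(np.quantile(pooled, 0.05))
        q95[name] = float(np.quantile(pooled, 0.95))
    return PosteriorSummary(median=median, q05=q05, q95=q95)
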