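"""Empirical-Bayes adaptive shrinkage of effect estimates.

Likelihood: beta_hat_j ~ N(b_j, se_j^2) with b_j drawn from a zero-centred
scale mixture, either normal components N(0, scale_m^2) or uniform
components U(-scale_m, scale_m). Mixture weights are fitted by (penalized)
EM on the marginal likelihood. Outputs are posterior means / sds, local
false sign rates, s-values, and the marginal log-likelihood-ratio against
the all-null (b = 0) model.

The default scale grid is geometric with ratio sqrt(2) from min(se)/10 up
to 2 * max|beta|; it is recorded on the fitted prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ShrinkPrior",
    "ShrinkResult",
    "default_scale_grid",
    "fit_mixture_prior",
    "shrink_estimates",
    "compute_svalues",
    "log_lr",
]

_TINY = 1e-300


@dataclass
class ShrinkPrior:
    family: str  # "normal" or "uniform"
    scales: np.ndarray  # strictly increasing component scales
    weights: np.ndarray  # simplex over components
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unknown component family {self.family!r}")
        if self.scales.size != self.weights.size:
            raise ValueError("scales and weights must have equal length")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if self.scales.size > 1 and np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(self.scales < 0):
            raise ValueError("scales must be non-negative")

    @property
    def has_pointmass(self) -> bool:
        """A zero first scale acts as a point mass at zero."""
        return bool(self.scales.size and self.scales[0] == 0.0)


@dataclass
class ShrinkResult:
    postmean: np.ndarray
    postsd: np.ndarray
    lfsr: np.ndarray
    svalue: np.ndarray
    zscore: np.ndarray


def default_scale_grid(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Geometric grid, ratio sqrt(2), spanning min(se)/10 to 2 max|beta|."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    lo = float(np.min(se)) / 10.0
    hi = 2.0 * float(np.max(np.abs(beta)))
    if hi <= lo or not np.isfinite(hi) or hi == 0:
        return np.array([max(lo, 1e-8)])
    n = int(math.ceil(math.log(hi / lo) / math.log(math.sqrt(2.0)))) + 1
    grid = lo * (math.sqrt(2.0) ** np.arange(n))
    return grid


def _marginal_lik_matrix(beta, se, scales, family) -> np.ndarray:
    """L[j, m] = density of beta_j under component m convolved with N(0, se_j^2)."""
    beta = beta[:, None]
    se = se[:, None]
    a = scales[None, :]
    if family == "normal":
        sd = np.sqrt(se**2 + a**2)
        return norm.pdf(beta, loc=0.0, scale=sd)
    # uniform: (Phi((a - b)/s) - Phi((-a - b)/s)) / (2a); a -> 0 limit is N(b; 0, s^2)
    out = np.empty((beta.shape[0], scales.size))
    small = a < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        num = norm.cdf((a - beta) / se) - norm.cdf((-a - beta) / se)
        out = num / (2.0 * a)
    if small.any():
        out[:, small.ravel()] = norm.pdf(beta, loc=0.0, scale=se)
    return out


def fit_mixture_prior(
    beta,
    se,
    family: str = "normal",
    weights_prior: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    pointmass: bool = False,
    tol: float = 1e-7,
    maxiter: int = 5000,
) -> ShrinkPrior:
    """Fit mixture weights by penalized EM on the marginal likelihood.

    ``weights_prior`` is a Dirichlet parameter vector (default all ones, i.e.
    no penalty). A custom ``scales`` grid may be supplied, e.g. to share one
    grid across refits. ``pointmass=True`` prepends a point mass at zero
    (scale 0) to the default grid; the no-point-mass default mirrors the
    shrink-only configuration used in the DE pipeline.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    se = np.asarray(se, dtype=float).ravel()
    if beta.size != se.size or beta.size < 1:
        raise ValueError("beta and se must have equal, positive length")
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    if scales is None:
        scales = default_scale_grid(beta, se)
        if pointmass:
            scales = np.concatenate([[0.0], scales])
    scales = np.asarray(scales, dtype=float).ravel()
    M = scales.size
    alpha = np.ones(M) if weights_prior is None else np.asarray(weights_prior, float)
    if alpha.size != M:
        raise ValueError("weights_prior length must match the scale grid")
    lik = np.maximum(_marginal_lik_matrix(beta, se, scales, family), _TINY)
    w = np.full(M, 1.0 / M)
    prev_obj = -np.inf
    for _ in range(maxiter):
        post = lik * w[None, :]
        rowsum = post.sum(axis=1, keepdims=True)
        resp = post / rowsum
        counts = resp.sum(axis=0) + alpha - 1.0
        counts = np.maximum(counts, 0.0)
        if counts.sum() == 0:
            counts = np.ones(M)
        w = counts / counts.sum()
        obj = float(np.sum(np.log(rowsum))) + float(
            np.sum((alpha - 1.0) * np.log(np.maximum(w, _TINY)))
        )
        if np.isfinite(prev_obj) and abs(obj - prev_obj) <= tol * (
            abs(prev_obj) + 1.0
        ):
            prev_obj = obj
            break
        prev_obj = obj
    loglik = float(np.sum(np.log(np.maximum(lik @ w, _TINY))))
    return ShrinkPrior(family=family, scales=scales, weights=w, loglik=loglik)


def _component_posteriors(beta, se, prior):
    """Responsibilities and per-component posterior moments/sign masses.

    Returns (resp, mean, var, negprob) each of shape (n, M).
    """
    beta = beta[:, None]
    se = se[:, None]
    a = prior.scales[None, :]
    lik = np.maximum(
        _marginal_lik_matrix(beta.ravel(), se.ravel(), prior.scales, prior.family),
        _TINY,
    )
    post = lik * prior.weights[None, :]
    resp = post / post.sum(axis=1, keepdims=True)
    if prior.family == "normal":
        shrinkf = a**2 / (a**2 + se**2)
        mean = beta * shrinkf
        var = shrinkf * se**2
        sd = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            negprob = np.where(sd > 0, norm.cdf(-mean / np.maximum(sd, _TINY)),
                               (mean < 0).astype(float))
        return resp, mean, var, negprob
    # uniform components: posterior of b is N(beta, se^2) truncated to [-a, a]
    from scipy.stats import truncnorm

    lo = (-a - beta) / se
    hi = (a - beta) / se
    small = (a < 1e-12) | (hi - lo < 1e-12)
    lo_c = np.where(small, -1.0, lo)
    hi_c = np.where(small, 1.0, hi)
    mean = beta + se * truncnorm.mean(lo_c, hi_c)
    var = se**2 * truncnorm.var(lo_c, hi_c)
    mean = np.where(small, 0.0, mean)
    var = np.where(small, 0.0, var)
    denom = np.maximum(norm.cdf(hi) - norm.cdf(lo), _TINY)
    negprob = (norm.cdf(np.clip(-beta / se, lo, hi)) - norm.cdf(lo)) / denom
    # tiny half-widths act as a point mass at zero: no strictly-negative mass
    negprob = np.where(small, 0.0, negprob)
    return resp, mean, var, negprob


def shrink_estimates(beta, se, prior: ShrinkPrior) -> ShrinkResult:
    """Posterior summaries of each effect under the fitted mixture prior.

    lfsr = min{P(b >= 0 | data), P(b <= 0 | data)}; with continuous priors
    there is no mass at zero so the two probabilities sum to one.
    Entries with se = 0 are passed through unshrunk.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    se = np.asarray(se, dtype=float).ravel()
    ok = se > 0
    postmean = beta.copy()
    postsd = np.zeros_like(beta)
    lfsr = np.where(beta == 0, 0.5, 0.0)
    if ok.any():
        resp, mean, var, negprob = _component_posteriors(beta[ok], se[ok], prior)
        pm = np.sum(resp * mean, axis=1)
        second = np.sum(resp * (var + mean**2), axis=1)
        psd = np.sqrt(np.maximum(second - pm**2, 0.0))
        neg = np.clip(np.sum(resp * negprob, axis=1), 0.0, 1.0)
        # posterior mass exactly at zero (point-mass components; tiny
        # uniform half-widths degenerate to a point mass)
        if prior.family == "uniform":
            zero_cols = prior.scales < 1e-12
        else:
            zero_cols = prior.scales == 0.0
        p0 = resp[:, zero_cols].sum(axis=1) if zero_cols.any() else 0.0
        pos = np.clip(1.0 - neg - p0, 0.0, 1.0)
        postmean[ok] = pm
        postsd[ok] = psd
        lfsr[ok] = np.clip(np.minimum(neg, pos) + p0, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(postsd > 0, postmean / postsd, 0.0)
    return ShrinkResult(
        postmean=postmean,
        postsd=postsd,
        lfsr=lfsr,
        svalue=compute_svalues(lfsr),
        zscore=z,
    )


def compute_svalues(lfsr) -> np.ndarray:
    """s_j = mean lfsr over all tests with lfsr <= lfsr_j (ties share a value)."""
    lfsr = np.asarray(lfsr, dtype=float).ravel()
    if lfsr.size == 0:
        return lfsr.copy()
    if np.any((lfsr < 0) | (lfsr > 1)):
        raise ValueError("lfsr values must lie in [0, 1]")
    order = np.argsort(lfsr, kind="stable")
    srt = lfsr[order]
    cummean = np.cumsum(srt) / np.arange(1, lfsr.size + 1)
    # ties share the cumulative mean at the last element of the tie group
    out_sorted = np.empty_like(cummean)
    i = 0
    while i < srt.size:
        j = i
        while j + 1 < srt.size and srt[j + 1] == srt[i]:
            j += 1
        out_sorted[i:j + 1] = cummean[j]
        i = j + 1
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


def log_lr(beta, se, prior: ShrinkPrior) -> float:
    """Marginal log-likelihood of the fitted prior vs. the all-null model.

    sum_j [log f(beta_j | prior) - log N(beta_j; 0, se_j^2)].
    """
    beta = np.asarray(beta, dtype=float).ravel()
    se = np.asarray(se, dtype=float).ravel()
    lik = np.maximum(_marginal_lik_matrix(beta, se, prior.scales, prior.family),
                     _TINY)
    f = np.maximum(lik @ prior.weights, _TINY)
    f0 = np.maximum(norm.pdf(beta, loc=0.0, scale=se), _TINY)
    return float(np.sum(np.log(f) - np.log(f0)))
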