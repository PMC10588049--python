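"""Poisson non-negative matrix factorization and the equivalent topic model.

The count matrix X (n cells x m features) is modeled as
x_ij ~ Poisson(lambda_ij) with Lambda = H W^T, H n x K, W m x K, all
entries non-negative. The equivalent multinomial topic model (L, F) is
recovered by rescaling columns of W to sum to one and renormalizing rows
of H.

Two update rules are provided: "em" multiplicative (Lee-Seung for the
KL/Poisson objective; monotone in the log-likelihood) and "cd", cyclic
per-topic Newton updates on one factor at a time. Entries are clamped at a
small positive floor so zeros are never absorbing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_model import CountsMatrix, SizeFactors

__all__ = [
    "PoissonNMFFit",
    "TopicModelFit",
    "poisson_nmf_loglik",
    "update_factors",
    "fit_poisson_nmf",
    "poisson2multinom",
    "compare_fits",
    "save_fit",
    "load_fit",
    "FACTOR_FLOOR",
]

FACTOR_FLOOR = 1e-15


@dataclass
class PoissonNMFFit:
    """Factors of the Poisson NMF model Lambda = H W^T."""

    W: np.ndarray  # m x K
    H: np.ndarray  # n x K
    K: int
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if self.W.shape[1] != self.K or self.H.shape[1] != self.K:
            raise ValueError("W and H must both have K columns")
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("factor entries must be non-negative")


@dataclass
class TopicModelFit:
    """Membership proportions L (rows sum to 1), topic frequencies F
    (columns sum to 1), and size factors s."""

    L: np.ndarray  # n x K
    F: np.ndarray  # m x K
    s: SizeFactors

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if np.any(self.L < 0) or np.any(self.F < 0):
            raise ValueError("L and F must be non-negative")

    @property
    def K(self) -> int:
        return self.L.shape[1]


def _nonzero_lambda(x: sp.spmatrix, W: np.ndarray, H: np.ndarray):
    """lambda_ij at the nonzero entries of x; returns (rows, cols, vals, lam)."""
    coo = x.tocoo()
    lam = np.einsum("ik,ik->i", H[coo.row], W[coo.col])
    return coo.row, coo.col, coo.data.astype(float), lam


def poisson_nmf_loglik(x: CountsMatrix, fit: PoissonNMFFit) -> float:
    """Sum_ij [x_ij log lambda_ij - lambda_ij], log x! constants omitted.

    Entries with x_ij = 0 and lambda_ij = 0 contribute 0; lambda_ij = 0 at a
    nonzero count yields -inf (returned, not raised).
    """
    n, m = x.shape
    if fit.H.shape[0] != n or fit.W.shape[0] != m:
        raise ValueError("fit dimensions do not match counts matrix")
    _, _, xv, lam = _nonzero_lambda(x.values, fit.W, fit.H)
    if np.any(lam == 0):
        return float("-inf")
    total_lam = float(fit.H.sum(axis=0) @ fit.W.sum(axis=0))
    return float(np.dot(xv, np.log(lam)) - total_lam)


def _em_update_W(x: sp.spmatrix, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    rows, cols, xv, lam = _nonzero_lambda(x, W, H)
    ratio = sp.coo_matrix((xv / np.maximum(lam, FACTOR_FLOOR), (rows, cols)),
                          shape=x.shape).tocsr()
    num = ratio.T @ H  # m x K
    den = H.sum(axis=0)  # K
    return np.maximum(W * num / np.maximum(den, FACTOR_FLOOR), FACTOR_FLOOR)


def _cd_update_W(x: sp.spmatrix, W: np.ndarray, H: np.ndarray,
                 inner: int = 1) -> np.ndarray:
    """Cyclic per-topic Newton updates of W with H fixed.

    The 1-D objective in w_jk is concave; the Newton step is clamped at the
    floor. lambda at the nonzero entries is maintained incrementally.
    """
    W = W.copy()
    csc = x.tocsc()
    rows, cols, xv, lam = _nonzero_lambda(csc, W, H)
    hsum = H.sum(axis=0)
    K = W.shape[1]
    for _ in range(inner):
        for k in range(K):
            hk = H[rows, k]
            # grad_j = sum_i x_ij h_ik / lam_ij - hsum_k
            r = xv * hk / np.maximum(lam, FACTOR_FLOOR)
            grad = np.bincount(cols, weights=r, minlength=W.shape[0]) - hsum[k]
            curv = np.bincount(cols, weights=r * hk / np.maximum(lam, FACTOR_FLOOR),
                               minlength=W.shape[0])
            step = grad / np.maximum(curv, FACTOR_FLOOR)
            w_new = np.maximum(W[:, k] + step, FACTOR_FLOOR)
            lam += (w_new - W[:, k])[cols] * hk
            W[:, k] = w_new
        if not np.all(np.isfinite(W)):
            raise FloatingPointError("non-finite values in CD factor update")
    return W


def update_factors(
    x: CountsMatrix,
    fit: PoissonNMFFit,
    which: str = "W",
    method: str = "em",
    numiter: int = 1,
) -> PoissonNMFFit:
    """Run ``numiter`` updates of one factor (the other held fixed).

    EM updates never decrease the Poisson NMF log-likelihood.
    """
    if numiter < 1:
        raise ValueError("numiter must be >= 1")
    W, H = fit.W.copy(), fit.H.copy()
    xs = x.values
    for it in range(numiter):
        if which == "W":
            if method == "em":
                W = _em_update_W(xs, W, H)
            elif method == "cd":
                W = _cd_update_W(xs, W, H)
            else:
                raise ValueError(f"unknown method {method!r}")
        elif which == "H":
            if method == "em":
                H = _em_update_W(xs.T, H, W)
            elif method == "cd":
                H = _cd_update_W(xs.T, H, W)
            else:
                raise ValueError(f"unknown method {method!r}")
        else:
            raise ValueError(f"unknown factor {which!r}")
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
            raise FloatingPointError(f"non-finite factor values at iteration {it}")
    return PoissonNMFFit(W=W, H=H, K=fit.K, loglik_trace=list(fit.loglik_trace))


def fit_poisson_nmf(
    x: CountsMatrix,
    K: int,
    prefit_iters: int = 1000,
    refine_iters: int = 1000,
    seed: int = 0,
    init_h_iters: int = 10,
    loglik_tol: float | None = None,
) -> PoissonNMFFit:
    """Fit a Poisson NMF by seeded random init -> 10 CD updates of H with W
    fixed -> EM prefitting phase -> CD refinement phase.

    Deterministic given the seed. ``loglik_tol`` optionally stops either
    phase early once the per-iteration log-likelihood change drops below it.
    """
    n, m = x.shape
    if K < 1 or K > min(n, m):
        raise ValueError(f"K={K} must be in [1, min(n, m)={min(n, m)}]")
    rng = np.random.default_rng(seed)
    W = rng.uniform(size=(m, K))
    H = rng.uniform(size=(n, K))
    # scale so total(lambda) = total(x)
    total = float(x.values.sum())
    cur = float(H.sum(axis=0) @ W.sum(axis=0))
    c = np.sqrt(total / cur) if cur > 0 and total > 0 else 1.0
    W *= c
    H *= c
    fit = PoissonNMFFit(W=W, H=H, K=K)
    fit.loglik_trace.append(poisson_nmf_loglik(x, fit))
    for _ in range(init_h_iters):
        fit = update_factors(x, fit, which="H", method="cd")
        fit.loglik_trace.append(poisson_nmf_loglik(x, fit))

    def run_phase(fit: PoissonNMFFit, method: str, iters: int) -> PoissonNMFFit:
        for _ in range(iters):
            fit = update_factors(x, fit, which="W", method=method)
            fit = update_factors(x, fit, which="H", method=method)
            ll = poisson_nmf_loglik(x, fit)
            prev = fit.loglik_trace[-1]
            fit.loglik_trace.append(ll)
            if loglik_tol is not None and abs(ll - prev) < loglik_tol:
                break
        return fit

    fit = run_phase(fit, "em", prefit_iters)
    fit = run_phase(fit, "cd", refine_iters)
    return fit


def poisson2multinom(fit: PoissonNMFFit) -> TopicModelFit:
    """Recover (L, F, s) from (W, H).

    c_k = sum_j w_jk; f_jk = w_jk / c_k; l_ik proportional to h_ik c_k;
    s_i = sum_k h_ik c_k. Satisfies H W^T = diag(s) L F^T.
    """
    c = fit.W.sum(axis=0)
    bad = np.flatnonzero(c <= 0)
    if bad.size:
        raise ValueError(f"degenerate (all-zero) topics: {bad.tolist()}")
    F = fit.W / c
    Hw = fit.H * c
    s = Hw.sum(axis=1)
    if np.any(s <= 0):
        raise ValueError("cells with all-zero loadings; cannot normalize")
    L = Hw / s[:, None]
    return TopicModelFit(L=L, F=F, s=SizeFactors(s))


def compare_fits(x: CountsMatrix, fits: list[PoissonNMFFit]):
    """Table of (K, loglik) rows sorted by K."""
    import pandas as pd

    if not fits:
        raise ValueError("need at least one fit")
    rows = [(f.K, poisson_nmf_loglik(x, f)) for f in fits]
    return (
        pd.DataFrame(rows, columns=["K", "loglik"])
        .sort_values("K", kind="stable")
        .reset_index(drop=True)
    )


def save_fit(fit: PoissonNMFFit, outdir: str, seed: int | None = None) -> None:
    """Serialize a fit bundle: W.tsv, H.tsv, L.tsv, F.tsv + metadata.json."""
    os.makedirs(outdir, exist_ok=True)
    np.savetxt(os.path.join(outdir, "W.tsv"), fit.W, delimiter="\t")
    np.savetxt(os.path.join(outdir, "H.tsv"), fit.H, delimiter="\t")
    tm = poisson2multinom(fit)
    np.savetxt(os.path.join(outdir, "L.tsv"), tm.L, delimiter="\t")
    np.savetxt(os.path.join(outdir, "F.tsv"), tm.F, delimiter="\t")
    meta = {
        "K": fit.K,
        "seed": seed,
        "n_loglik_evals": len(fit.loglik_trace),
        "final_loglik": fit.loglik_trace[-1] if fit.loglik_trace else None,
    }
    with open(os.path.join(outdir, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_fit(outdir: str) -> PoissonNMFFit:
    W = np.atleast_2d(np.loadtxt(os.path.join(outdir, "W.tsv"), delimiter="\t"))
    H = np.atleast_2d(np.loadtxt(os.path.join(outdir, "H.tsv"), delimiter="\t"))
    if W.ndim == 1:
        W = W[:, None]
    if H.ndim == 1:
        H = H[:, None]
    with open(os.path.join(outdir, "metadata.json")) as fh:
        meta = json.load(fh)
    K = int(meta["K"])
    if W.shape[1] != K:
        W = W.reshape(-1, K)
    if H.shape[1] != K:
        H = H.reshape(-1, K)
    return PoissonNMFFit(W=W, H=H, K=K)
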