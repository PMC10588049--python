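"""Per-feature Poisson differential expression allowing partial memberships.

Model for feature j: x_ij ~ Poisson(s_i * theta_ij), theta_ij =
sum_k l_ik p_jk, with the membership matrix L treated as known. Topic rates
p_jk get a Gamma(1 + eps, 1) prior implemented by augmenting the data with
K pseudocount rows of value eps whose membership block is the K x K
identity and whose size factors are 1 (no augmentation when eps = 0, which
leaves the plain MLE). Posterior uncertainty comes from a random-walk
Metropolis sampler on g = log p.

Topics are indexed 0-based throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from ._mcmc import rw_chain
from .data_model import CountsMatrix, SizeFactors

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRates",
    "McmcOptions",
    "DeTable",
    "fit_null_rate",
    "fit_gene_rates_map",
    "fit_rates_map_all",
    "pairwise_lfc",
    "le_lfc",
    "null_lfc",
    "mcmc_sample_rates",
    "summarize_posterior",
    "de_analysis",
]

RATE_FLOOR = 1e-15
LOG2 = math.log(2.0)


@dataclass
class GeneRates:
    """Topic rates p_k for one feature plus the shared null rate p0."""

    p: np.ndarray
    p0: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        if np.any(self.p < 0):
            raise ValueError("rates must be non-negative")

    @property
    def K(self) -> int:
        return self.p.size

    @property
    def g(self) -> np.ndarray:
        """log p_k; -inf where p_k = 0."""
        with np.errstate(divide="ignore"):
            return np.log(self.p)


@dataclass
class McmcOptions:
    """Tuning parameters of the posterior sampler."""

    ns: int = 10000
    sigma: float = 0.3
    eps: float = 0.1
    seed: int = 0
    hpd_level: float = 0.68

    def __post_init__(self) -> None:
        if self.ns < 1:
            raise ValueError("ns must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")
        if not 0 < self.hpd_level < 1:
            raise ValueError("hpd_level must be in (0, 1)")


@dataclass
class DeTable:
    """Long-format per (feature, topic) posterior summaries.

    ``table`` columns: feature_id, topic, map, postmean, hpd_lo, hpd_hi, se,
    z, pvalue, lfsr, svalue, p0. Pre-shrinkage hpd_lo <= postmean <= hpd_hi.
    """

    table: "object"  # pandas.DataFrame
    lfc_mode: str
    shrink: bool
    failed_features: list[str] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# point estimation


def fit_null_rate(x_j: np.ndarray, s: SizeFactors | np.ndarray) -> float:
    """MLE of the single shared rate: sum(x) / sum(s)."""
    sv = s.s if isinstance(s, SizeFactors) else np.asarray(s, dtype=float)
    tot = float(np.sum(sv))
    if tot <= 0:
        raise ValueError("sum of size factors must be positive")
    return float(np.sum(x_j)) / tot


def _augment(L: np.ndarray, s: np.ndarray, eps: float):
    """Stack the eps pseudocount block below (L, s); identity memberships,
    unit size factors. Returns (L_aug, s_aug, n_pseudo)."""
    K = L.shape[1]
    if eps == 0:
        return L, s, 0
    L_aug = np.vstack([L, np.eye(K)])
    s_aug = np.concatenate([s, np.ones(K)])
    return L_aug, s_aug, K


def fit_rates_map_all(
    x: sp.spmatrix,
    L: np.ndarray,
    s: np.ndarray,
    eps: float = 0.1,
    numiter: int = 40,
) -> np.ndarray:
    """MAP topic rates for every feature at once; returns m x K.

    Cyclic 1-D multiplicative updates on the augmented likelihood, each a
    minorize-maximize step in one coordinate, hence monotone. Only nonzero
    counts enter the numerator; the eps block is handled in closed form.
    """
    n, m = x.shape
    K = L.shape[1]
    B = L * np.asarray(s, dtype=float)[:, None]  # n x K, b_ik = s_i l_ik
    bsum = B.sum(axis=0) + (1.0 if eps > 0 else 0.0) * np.ones(K)
    if eps == 0:
        bsum = B.sum(axis=0)
    coo = x.tocoo()
    rows, cols, xv = coo.row, coo.col, coo.data.astype(float)
    # init at the augmented null rate (strictly positive)
    colsum = np.asarray(x.sum(axis=0)).ravel().astype(float)
    p = np.tile(
        ((colsum + eps) / (float(np.sum(s)) + (1.0 if eps > 0 else 0.0)))[:, None],
        (1, K),
    )
    p = np.maximum(p, RATE_FLOOR)
    lam = np.einsum("qk,qk->q", B[rows], p[cols])  # s_i * theta at nonzeros
    for _ in range(numiter):
        for k in range(K):
            bk = B[rows, k]
            r = xv * bk / np.maximum(lam, RATE_FLOOR)
            num = np.bincount(cols, weights=r, minlength=m)
            if eps > 0:
                num = num + eps / np.maximum(p[:, k], RATE_FLOOR)
            p_new = np.maximum(p[:, k] * num / max(bsum[k], RATE_FLOOR), RATE_FLOOR)
            lam += bk * (p_new - p[:, k])[cols]
            p[:, k] = p_new
        if not np.all(np.isfinite(p)):
            bad = int(np.flatnonzero(~np.isfinite(p).all(axis=0))[0])
            raise FloatingPointError(f"non-finite rate estimate for topic {bad}")
    return p


def fit_gene_rates_map(
    x_j: np.ndarray,
    L: np.ndarray,
    s: SizeFactors | np.ndarray,
    eps: float = 0.1,
    numiter: int = 40,
) -> GeneRates:
    """MAP estimate of the topic rates for a single feature."""
    sv = s.s if isinstance(s, SizeFactors) else np.asarray(s, dtype=float)
    x_j = np.asarray(x_j, dtype=float).ravel()
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if not np.allclose(L.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of L must sum to 1")
    xs = sp.csc_matrix(x_j[:, None])
    p = fit_rates_map_all(xs, L, sv, eps=eps, numiter=numiter)[0]
    return GeneRates(p=p, p0=fit_null_rate(x_j, sv))


# ---------------------------------------------------------------------------
# LFC statistics


def pairwise_lfc(p: GeneRates, k: int, l: int) -> float:
    """log2(p_k / p_l); signed infinity if exactly one rate is zero, 0 if both."""
    pk, pl = p.p[k], p.p[l]
    if pk == 0 and pl == 0:
        logger.warning("pairwise_lfc: both rates zero for topics %d, %d", k, l)
        return 0.0
    if pl == 0:
        logger.warning("pairwise_lfc: zero denominator rate for topic %d", l)
        return math.inf
    if pk == 0:
        logger.warning("pairwise_lfc: zero numerator rate for topic %d", k)
        return -math.inf
    return math.log2(pk / pl)


def le_lfc(p: GeneRates, k: int) -> float:
    """Least extreme LFC: the pairwise LFC against the topic minimizing its
    absolute value (ties broken by smallest topic index)."""
    if p.K < 2:
        raise ValueError("least extreme LFC is undefined for K = 1")
    best = None
    best_abs = math.inf
    for l in range(p.K):
        if l == k:
            continue
        v = pairwise_lfc(p, k, l)
        if abs(v) < best_abs:
            best_abs = abs(v)
            best = v
    return best


def null_lfc(p: GeneRates, k: int) -> float:
    """log2(p_k / p0) against the shared null rate."""
    if p.p0 <= 0:
        raise ValueError("null rate is zero; null-comparison LFC undefined")
    if p.p[k] == 0:
        return -math.inf
    return math.log2(p.p[k] / p.p0)


def _stat_samples(
    G: np.ndarray,
    mode: str,
    p0: float | None = None,
    ref: int | None = None,
) -> np.ndarray:
    """Per-sample LFC statistic matrix (ns x K) from log-rate samples G."""
    ns, K = G.shape
    if mode == "le":
        if K < 2:
            raise ValueError("least extreme LFC is undefined for K = 1")
        diffs = G[:, :, None] - G[:, None, :]  # ns x K x K, [s,k,l] = g_k - g_l
        absd = np.abs(diffs)
        idx = np.arange(K)
        absd[:, idx, idx] = np.inf
        lstar = np.argmin(absd, axis=2)  # first (lowest) index wins ties
        return np.take_along_axis(diffs, lstar[:, :, None], axis=2)[:, :, 0] / LOG2
    if mode == "null":
        if p0 is None or p0 <= 0:
            raise ValueError("null mode requires a positive p0")
        return (G - math.log(p0)) / LOG2
    if mode == "reference":
        if ref is None:
            raise ValueError("reference mode requires a topic index")
        return (G - G[:, ref][:, None]) / LOG2
    raise ValueError(f"unknown lfc mode {mode!r}")


# ---------------------------------------------------------------------------
# MCMC


def mcmc_sample_rates(
    x_j: np.ndarray,
    L: np.ndarray,
    s: SizeFactors | np.ndarray,
    init: GeneRates,
    opts: McmcOptions,
) -> np.ndarray:
    """Random-walk Metropolis on g = log p; returns ns x K sampled g vectors.

    Inputs are taken as-is (callers append pseudocount rows beforehand). Per
    step one topic is picked uniformly, its coordinate perturbed by
    N(0, sigma^2), and the move accepted with probability
    min{1, likelihood ratio x p*_k/p_k} (Jacobian of the log transform under
    a flat prior on p). Deterministic given ``opts.seed``.
    """
    x_j = np.asarray(x_j, dtype=float).ravel()
    L = np.atleast_2d(np.asarray(L, dtype=float))
    sv = s.s if isinstance(s, SizeFactors) else np.asarray(s, dtype=float).ravel()
    K = L.shape[1]
    if np.any(init.p <= 0):
        raise ValueError("MCMC initialization requires strictly positive rates")
    nz = np.flatnonzero(x_j > 0)
    xnz = x_j[nz]
    Lnz = np.ascontiguousarray(L[nz])
    sl = L.T @ sv  # sum_i s_i l_ik, all rows
    rng = np.random.default_rng(opts.seed)
    topics = rng.integers(0, K, size=opts.ns)
    deltas = rng.normal(0.0, opts.sigma, size=opts.ns)
    with np.errstate(divide="ignore"):
        logu = np.log(rng.random(size=opts.ns))
    out = np.empty((opts.ns, K))
    rw_chain(np.log(init.p), xnz, Lnz, sl, topics, deltas, logu, out)
    return out


def summarize_posterior(
    samples: np.ndarray,
    stat: str = "le",
    hpd_level: float = 0.68,
    p0: float | None = None,
    ref: int | None = None,
):
    """Posterior mean, HPD bounds, and asymmetric SE of a per-sample LFC.

    The statistic is evaluated on every sample and then summarized (for the
    least extreme LFC the comparison topic may differ across samples). The
    HPD interval is the shortest window of sorted per-sample values holding
    ceil(level * ns) samples. se = hpd_hi - mean when mean < 0 else
    mean - hpd_lo (floored at 0).
    Returns (postmean, hpd_lo, hpd_hi, se), each a length-K array.
    """
    samples = np.atleast_2d(samples)
    ns, K = samples.shape
    vals = _stat_samples(samples, stat, p0=p0, ref=ref)
    postmean = vals.mean(axis=0)
    w = int(math.ceil(hpd_level * ns))
    hpd_lo = np.empty(K)
    hpd_hi = np.empty(K)
    for k in range(K):
        srt = np.sort(vals[:, k])
        if w >= ns:
            hpd_lo[k], hpd_hi[k] = srt[0], srt[-1]
        else:
            widths = srt[w - 1:] - srt[: ns - w + 1]
            i = int(np.argmin(widths))
            hpd_lo[k], hpd_hi[k] = srt[i], srt[i + w - 1]
    se = np.where(postmean < 0, hpd_hi - postmean, postmean - hpd_lo)
    se = np.maximum(se, 0.0)
    return postmean, hpd_lo, hpd_hi, se


# ---------------------------------------------------------------------------
# orchestration


def de_analysis(
    x: CountsMatrix,
    L: np.ndarray,
    opts: McmcOptions | None = None,
    lfc_mode: str = "le",
    shrink: bool = True,
    s: SizeFactors | np.ndarray | None = None,
    reference: int | None = None,
    map_numiter: int = 40,
) -> DeTable:
    """Full per-feature analysis: MAP fit, MCMC, posterior summaries, and
    (optionally) adaptive shrinkage with lfsr / s-value statistics.

    Features are processed independently with RNG streams derived from
    (seed, feature index), so results do not depend on processing order.
    ``lfc_mode`` is one of "le", "null", "reference" (the latter requires
    ``reference``). Per-feature failures are logged and flagged, not fatal.
    """
    import pandas as pd

    from . import shrinkage as shr

    opts = opts or McmcOptions()
    L = np.atleast_2d(np.asarray(L, dtype=float))
    n, m = x.shape
    K = L.shape[1]
    if L.shape[0] != n:
        raise ValueError("L must have one row per cell")
    if not np.allclose(L.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of L must sum to 1")
    if lfc_mode == "reference" and reference is None:
        raise ValueError("reference mode requires a topic index")
    if s is None:
        sv = np.asarray(x.values.sum(axis=1)).ravel().astype(float)
    else:
        sv = s.s if isinstance(s, SizeFactors) else np.asarray(s, dtype=float)

    colsum = np.asarray(x.values.sum(axis=0)).ravel().astype(float)
    p0 = colsum / float(np.sum(sv))

    P = fit_rates_map_all(x.values, L, sv, eps=opts.eps, numiter=map_numiter)
    n_floored = int(np.sum(P <= RATE_FLOOR))
    if n_floored:
        logger.info("de_analysis: %d MAP rates at the positivity floor", n_floored)

    L_aug, s_aug, n_pseudo = _augment(L, sv, opts.eps)
    csc = x.values.tocsc()
    eps_x = np.full(n_pseudo, opts.eps)

    cols = {
        c: np.full(m * K, np.nan)
        for c in ("map", "postmean", "hpd_lo", "hpd_hi", "se")
    }
    failed: list[str] = []
    for j in range(m):
        lo, hi = csc.indptr[j], csc.indptr[j + 1]
        rows_j = csc.indices[lo:hi]
        x_nz = csc.data[lo:hi].astype(float)
        x_aug = np.concatenate([x_nz, eps_x])
        La = np.vstack([L[rows_j], np.eye(K)]) if n_pseudo else L[rows_j]
        # the zero-count cells are absent above but their s_i l_ik totals
        # enter through sl inside the sampler via the full (L_aug, s_aug)
        try:
            rates = GeneRates(p=np.maximum(P[j], RATE_FLOOR), p0=p0[j])
            feat_opts = McmcOptions(
                ns=opts.ns, sigma=opts.sigma, eps=opts.eps,
                seed=np.random.SeedSequence([opts.seed, j]).entropy,
                hpd_level=opts.hpd_level,
            )
            samples = _mcmc_feature(
                x_aug, La, rows_j, L_aug, s_aug, rates, feat_opts
            )
            pm, lo_, hi_, se = summarize_posterior(
                samples, stat=lfc_mode, hpd_level=opts.hpd_level,
                p0=p0[j] if p0[j] > 0 else None, ref=reference,
            )
            map_stat = _map_statistic(rates, lfc_mode, reference)
            sl_ = slice(j * K, (j + 1) * K)
            cols["map"][sl_] = map_stat
            cols["postmean"][sl_] = pm
            cols["hpd_lo"][sl_] = lo_
            cols["hpd_hi"][sl_] = hi_
            cols["se"][sl_] = se
        except Exception as exc:  # per-feature failures are non-fatal
            failed.append(x.feature_ids[j])
            logger.warning("de_analysis: feature %s failed: %s", x.feature_ids[j], exc)

    table = pd.DataFrame(
        {
            "feature_id": np.repeat(x.feature_ids, K),
            "topic": np.tile(np.arange(K), m),
            "map": cols["map"],
            "postmean": cols["postmean"],
            "hpd_lo": cols["hpd_lo"],
            "hpd_hi": cols["hpd_hi"],
            "se": cols["se"],
            "p0": np.repeat(p0, K),
        }
    )
    # unmoderated z and two-sided normal p-value
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        raw_z = np.where(table["se"] > 0, table["postmean"] / table["se"], 0.0)
    table["pvalue"] = 2.0 * norm.sf(np.abs(raw_z))

    if shrink:
        ok = table["se"].to_numpy() > 0
        beta = table["postmean"].to_numpy()
        se_arr = table["se"].to_numpy()
        post_mean = beta.copy()
        post_sd = se_arr.copy()
        lfsr = np.full(len(table), np.nan)
        if ok.any():
            prior = shr.fit_mixture_prior(beta[ok], se_arr[ok], family="normal")
            res = shr.shrink_estimates(beta[ok], se_arr[ok], prior)
            post_mean[ok] = res.postmean
            post_sd[ok] = res.postsd
            lfsr[ok] = res.lfsr
        # se = 0: passed through unshrunk; sign is certain unless beta = 0
        lfsr[~ok] = np.where(beta[~ok] == 0, 0.5, 0.0)
        table["postmean"] = post_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            table["z"] = np.where(post_sd > 0, post_mean / post_sd, 0.0)
        table["lfsr"] = lfsr
        table["svalue"] = shr.compute_svalues(np.nan_to_num(lfsr, nan=1.0))
    else:
        table["z"] = raw_z
        table["lfsr"] = np.nan
        table["svalue"] = np.nan

    return DeTable(table=table, lfc_mode=lfc_mode, shrink=shrink,
                   failed_features=failed)


def _map_statistic(rates: GeneRates, mode: str, reference: int | None) -> np.ndarray:
    K = rates.K
    if mode == "le":
        return np.array([le_lfc(rates, k) for k in range(K)])
    if mode == "null":
        if rates.p0 <= 0:
            return np.zeros(K)
        return np.array([null_lfc(rates, k) for k in range(K)])
    if mode == "reference":
        return np.array([pairwise_lfc(rates, k, reference) for k in range(K)])
    raise ValueError(f"unknown lfc mode {mode!r}")


def _mcmc_feature(x_aug, L_nz_aug, rows_j, L_aug, s_aug, rates, opts):
    """Run the sampler for one feature given its nonzero slice.

    x_aug / L_nz_aug cover the cells with nonzero counts plus the
    pseudocount block; the linear term uses the full augmented (L, s).
    """
    K = L_aug.shape[1]
    sl = L_aug.T @ s_aug
    rng = np.random.default_rng(opts.seed)
    topics = rng.integers(0, K, size=opts.ns)
    deltas = rng.normal(0.0, opts.sigma, size=opts.ns)
    with np.errstate(divide="ignore"):
        logu = np.log(rng.random(size=opts.ns))
    keep = x_aug > 0
    out = np.empty((opts.ns, K))
    rw_chain(
        np.log(rates.p),
        np.ascontiguousarray(x_aug[keep]),
        np.ascontiguousarray(L_nz_aug[keep]),
        sl, topics, deltas, logu, out,
    )
    return out
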