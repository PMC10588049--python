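"""Synthetic UMI counts with known topic structure.

Generative procedure, per data set (draw order: size factors -> memberships
-> rates -> counts, each stage on its own child RNG stream so presets are
bit-reproducible):

* size factors  s_i = 10^u_i, u_i ~ N(0, sd = 1/5)
* memberships   K' nonzero topics with P(K' = k') proportional to 2^{-k'}
  (normalized over 1..K), topics chosen uniformly without replacement,
  proportions 1 when K' = 1 else Dirichlet(alpha restricted to the chosen
  topics)
* rates         with probability 0.5 all topics share 2^{v_j},
  v_j ~ N(-4, sd 2); otherwise one uniformly chosen topic k' gets
  2^{v_j + e_j}, e_j ~ N(0, 1)
* counts        x_ij ~ Poisson(lambda_ij), lambda = H W^T with
  h_ik = s_i l_ik and w_jk = f_jk
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_model import CountsMatrix, SizeFactors

__all__ = [
    "SimScenario",
    "SimTruth",
    "PRESETS",
    "simulate_size_factors",
    "simulate_memberships",
    "simulate_gene_rates",
    "simulate_counts",
    "simulate_dataset",
]


@dataclass
class SimScenario:
    n: int
    K: int
    alpha: np.ndarray
    m: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.n < 1 or self.m < 1 or self.K < 1:
            raise ValueError("n, m, K must all be >= 1")
        if self.alpha.size != self.K:
            raise ValueError("alpha must have K entries")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive")


PRESETS = {
    "discrete2": dict(n=200, K=2, alpha=(0.01, 0.01)),
    "mixed2": dict(n=200, K=2, alpha=(1.0, 1.0)),
    "mixed6": dict(n=1000, K=6, alpha=(1.0,) * 6),
}


@dataclass
class SimTruth:
    """Ground truth of one simulated data set.

    diff_topic is -1 for features with equal rates across topics; effects
    holds the planted log2 difference e_j (0 where diff_topic = -1).
    """

    L: np.ndarray
    s: np.ndarray
    F: np.ndarray
    diff_topic: np.ndarray
    effects: np.ndarray
    u: np.ndarray = field(default=None)
    v: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not np.allclose(self.L.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if np.any(self.F <= 0):
            raise ValueError("rates must be strictly positive")

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        np.savetxt(os.path.join(outdir, "L.tsv"), self.L, delimiter="\t")
        np.savetxt(os.path.join(outdir, "F.tsv"), self.F, delimiter="\t")
        np.savetxt(os.path.join(outdir, "s.tsv"), self.s, delimiter="\t")
        import pandas as pd

        pd.DataFrame(
            {"diff_topic": self.diff_topic, "effect": self.effects}
        ).to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, outdir: str) -> "SimTruth":
        import pandas as pd

        L = np.atleast_2d(np.loadtxt(os.path.join(outdir, "L.tsv"), delimiter="\t"))
        F = np.atleast_2d(np.loadtxt(os.path.join(outdir, "F.tsv"), delimiter="\t"))
        s = np.loadtxt(os.path.join(outdir, "s.tsv"), delimiter="\t")
        tr = pd.read_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
        return cls(
            L=L, s=np.atleast_1d(s), F=F,
            diff_topic=tr["diff_topic"].to_numpy(),
            effects=tr["effect"].to_numpy(),
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_size_factors(n: int, seed=0) -> SizeFactors:
    """s_i = 10^u_i with u_i ~ N(0, sd 1/5)."""
    rng = _rng(seed)
    u = rng.normal(0.0, 0.2, size=n)
    return SizeFactors(10.0 ** u)


def simulate_memberships(n: int, K: int, alpha, seed=0) -> np.ndarray:
    """Sparse Dirichlet membership rows; see module docstring."""
    rng = _rng(seed)
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != K:
        raise ValueError("alpha must have K entries")
    probs = 2.0 ** -np.arange(1, K + 1)
    probs /= probs.sum()
    L = np.zeros((n, K))
    for i in range(n):
        kprime = int(rng.choice(K, p=probs)) + 1
        chosen = rng.choice(K, size=kprime, replace=False)
        if kprime == 1:
            L[i, chosen[0]] = 1.0
        else:
            L[i, chosen] = rng.dirichlet(alpha[chosen])
    return L


def simulate_gene_rates(m: int, K: int, seed=0):
    """Per-feature topic rates with planted single-topic differences.

    Returns (F, diff_topic, effects, v): F is m x K, diff_topic is -1 for
    features whose rates are equal across topics, effects is the log2
    perturbation e_j applied to the differing topic.
    """
    rng = _rng(seed)
    v = rng.normal(-4.0, 2.0, size=m)
    F = np.tile((2.0 ** v)[:, None], (1, K))
    diff_topic = np.full(m, -1, dtype=int)
    effects = np.zeros(m)
    is_diff = rng.random(m) < 0.5
    for j in np.flatnonzero(is_diff):
        kp = int(rng.integers(K))
        e = rng.normal(0.0, 1.0)
        F[j, kp] = 2.0 ** (v[j] + e)
        diff_topic[j] = kp
        effects[j] = e
    return F, diff_topic, effects, v


def simulate_counts(truth: SimTruth, seed=0) -> CountsMatrix:
    """x_ij ~ Poisson(lambda_ij), lambda = (s * L) F^T."""
    rng = _rng(seed)
    H = truth.L * truth.s[:, None]
    lam = H @ truth.F.T
    x = rng.poisson(lam)
    n, m = x.shape
    return CountsMatrix(
        sp.csr_matrix(x),
        [f"cell{i+1}" for i in range(n)],
        [f"gene{j+1}" for j in range(m)],
    )


def simulate_dataset(scenario: SimScenario):
    """Compose the generators; returns (CountsMatrix, SimTruth)."""
    streams = np.random.SeedSequence(scenario.seed).spawn(4)
    s = simulate_size_factors(scenario.n, np.random.default_rng(streams[0]))
    L = simulate_memberships(
        scenario.n, scenario.K, scenario.alpha, np.random.default_rng(streams[1])
    )
    F, diff_topic, effects, v = simulate_gene_rates(
        scenario.m, scenario.K, np.random.default_rng(streams[2])
    )
    truth = SimTruth(L=L, s=s.s, F=F, diff_topic=diff_topic, effects=effects, v=v)
    x = simulate_counts(truth, np.random.default_rng(streams[3]))
    return x, truth


def preset_scenario(name: str, seed: int = 0, m: int | None = None) -> SimScenario:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    if m is not None:
        cfg["m"] = m
    return SimScenario(seed=seed, **cfg)
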