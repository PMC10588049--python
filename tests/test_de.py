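import math

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import gamma, poisson

from topicde._mcmc import _rw_chain
from topicde.data_model import CountsMatrix
from topicde.de import (
    GeneRates,
    McmcOptions,
    de_analysis,
    fit_gene_rates_map,
    fit_null_rate,
    le_lfc,
    mcmc_sample_rates,
    null_lfc,
    pairwise_lfc,
    summarize_posterior,
)


class TestNullRate:
    def test_forced_example(self):
        assert fit_null_rate(np.array([1, 2, 3]), np.array([10, 20, 30])) == (
            pytest.approx(0.1)
        )

    def test_all_zero(self):
        assert fit_null_rate(np.zeros(4), np.ones(4)) == 0.0

    def test_ratio_of_sums_oracle(self, rng):
        x = rng.poisson(3, 20)
        s = rng.uniform(0.5, 2, 20)
        assert fit_null_rate(x, s) == pytest.approx(x.sum() / s.sum())


class TestMapEstimation:
    def test_hard_memberships_mle(self, rng):
        n = 40
        L = np.zeros((n, 2))
        L[np.arange(n), rng.integers(0, 2, n)] = 1
        x = rng.poisson(4, n).astype(float)
        s = rng.uniform(0.5, 2, n)
        r = fit_gene_rates_map(x, L, s, eps=0.0, numiter=200)
        for k in range(2):
            grp = L[:, k] == 1
            assert r.p[k] == pytest.approx(x[grp].sum() / s[grp].sum(), rel=1e-6)

    def test_hard_memberships_augmented(self, rng):
        n = 30
        L = np.zeros((n, 2))
        L[np.arange(n), rng.integers(0, 2, n)] = 1
        x = rng.poisson(2, n).astype(float)
        s = rng.uniform(0.5, 2, n)
        r = fit_gene_rates_map(x, L, s, eps=0.1, numiter=300)
        for k in range(2):
            grp = L[:, k] == 1
            expect = (x[grp].sum() + 0.1) / (s[grp].sum() + 1.0)
            assert r.p[k] == pytest.approx(expect, rel=1e-6)

    def test_mixed_membership_grid_oracle(self):
        # 5 cells, printed memberships; compare to a dense 2-D grid search
        # over the augmented likelihood
        L = np.array([[1.0, 0.0], [0.8, 0.2], [0.5, 0.5], [0.2, 0.8], [0.0, 1.0]])
        x = np.array([6.0, 4.0, 3.0, 1.0, 0.0])
        s = np.array([1.0, 2.0, 1.0, 1.0, 2.0])
        eps = 0.1

        def aug_loglik(p1, p2):
            p = np.array([p1, p2])
            theta = L @ p
            ll = float(np.sum(x * np.log(s * theta) - s * theta))
            ll += float(np.sum(eps * np.log(p) - p))  # pseudocount rows
            return ll

        grid = np.linspace(0.01, 6.0, 240)
        best = max(
            ((aug_loglik(a, b), a, b) for a in grid for b in grid),
            key=lambda t: t[0],
        )
        r = fit_gene_rates_map(x, L, s, eps=eps, numiter=400)
        step = grid[1] - grid[0]
        assert abs(r.p[0] - best[1]) <= step
        assert abs(r.p[1] - best[2]) <= step


class TestLfcStatistics:
    def test_distinctive_gene_worked_example(self):
        # rate 0.01 in topic 1, 0.0001 in topics 2..10 -> l.e. LFC log2(100)
        p = GeneRates(p=[0.01] + [0.0001] * 9)
        assert pairwise_lfc(p, 0, 1) == pytest.approx(math.log2(100))
        assert le_lfc(p, 0) == pytest.approx(math.log2(100))
        assert round(le_lfc(p, 0), 1) == 6.6

    def test_shared_gene_worked_example(self):
        # rates 0.01 in topics 1 and 2, 0.0001 elsewhere -> l.e. LFC 0
        p = GeneRates(p=[0.01, 0.01] + [0.0001] * 8)
        assert le_lfc(p, 0) == 0.0

    def test_pairwise_identity(self):
        p = GeneRates(p=[0.3, 0.3])
        assert pairwise_lfc(p, 0, 1) == 0.0

    def test_pairwise_antisymmetry(self, rng):
        p = GeneRates(p=rng.uniform(0.01, 2, 6))
        for k in range(6):
            for l in range(6):
                assert pairwise_lfc(p, k, l) == pytest.approx(
                    -pairwise_lfc(p, l, k)
                )

    def test_pairwise_zero_handling(self):
        p = GeneRates(p=[0.5, 0.0])
        assert pairwise_lfc(p, 0, 1) == math.inf
        assert pairwise_lfc(p, 1, 0) == -math.inf
        assert pairwise_lfc(GeneRates(p=[0.0, 0.0]), 0, 1) == 0.0

    def test_le_reduces_to_pairwise_at_k2(self, rng):
        p = GeneRates(p=rng.uniform(0.01, 1, 2))
        assert le_lfc(p, 0) == pytest.approx(pairwise_lfc(p, 0, 1))

    def test_le_k1_error(self):
        with pytest.raises(ValueError):
            le_lfc(GeneRates(p=[0.5]), 0)

    def test_le_tie_break_smallest_index(self):
        p = GeneRates(p=[0.4, 0.2, 0.8])  # |log2(2)| ties with |log2(0.5)|
        assert le_lfc(p, 0) == pytest.approx(1.0)  # vs topic 1, not topic 2

    def test_le_scale_invariance(self, rng):
        p = rng.uniform(0.01, 1, 5)
        for k in range(5):
            assert le_lfc(GeneRates(p=p), k) == pytest.approx(
                le_lfc(GeneRates(p=7.3 * p), k)
            )

    def test_null_lfc(self):
        p = GeneRates(p=[0.2, 0.8], p0=0.2)
        assert null_lfc(p, 0) == 0.0
        assert null_lfc(p, 1) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            null_lfc(GeneRates(p=[0.1], p0=0.0), 0)

    def test_null_lfc_direct_formula(self, rng):
        x = rng.poisson(3, 15)
        s = rng.uniform(0.5, 2, 15)
        p0 = fit_null_rate(x, s)
        p = GeneRates(p=rng.uniform(0.01, 1, 3), p0=p0)
        for k in range(3):
            assert null_lfc(p, k) == pytest.approx(math.log2(p.p[k] / p0))


def dense_metropolis_oracle(g0, x, L, s, topics, deltas, logu):
    """Reference chain computing full dense Poisson log-likelihoods."""
    g = g0.copy()
    out = np.empty((len(topics), len(g0)))
    for t in range(len(topics)):
        k = topics[t]
        gstar = g.copy()
        gstar[k] += deltas[t]
        lam_cur = s * (L @ np.exp(g))
        lam_new = s * (L @ np.exp(gstar))
        ll_cur = float(np.sum(poisson.logpmf(x, lam_cur)))
        ll_new = float(np.sum(poisson.logpmf(x, lam_new)))
        loga = ll_new - ll_cur + deltas[t]  # Jacobian log(p*/p)
        if logu[t] <= min(0.0, loga):
            g = gstar
        out[t] = g
    return out


class TestMcmc:
    def test_kernel_matches_dense_oracle(self, rng):
        n, K = 8, 3
        L = rng.dirichlet(np.ones(K), size=n)
        s = rng.uniform(0.5, 2, n)
        x = rng.poisson(2.0, n).astype(float)
        g0 = np.log(rng.uniform(0.2, 1.5, K))
        ns = 300
        topics = rng.integers(0, K, ns)
        deltas = rng.normal(0, 0.5, ns)
        logu = np.log(rng.random(ns))
        nz = x > 0
        out = np.empty((ns, K))
        _rw_chain(g0, x[nz], np.ascontiguousarray((L * s[:, None])[nz]),
                  L.T @ s, topics, deltas, logu, out)
        # counts enter the kernel against s_i * theta via pre-scaled rows
        expect = dense_metropolis_oracle(g0, x, L, s, topics, deltas, logu)
        assert np.allclose(out, expect)

    def test_zero_delta_always_accepted(self):
        g0 = np.array([0.0])
        out = np.empty((5, 1))
        _rw_chain(g0, np.array([3.0]), np.array([[1.0]]), np.array([1.0]),
                  np.zeros(5, dtype=np.int64), np.zeros(5),
                  np.log(np.random.default_rng(0).random(5)), out)
        assert np.all(out == 0.0)

    def test_conjugate_gamma_oracle(self):
        # 1 cell, 1 topic, x = 3, s = 1, flat prior -> posterior Gamma(4, 1)
        opts = McmcOptions(ns=100000, sigma=0.3, seed=11)
        init = GeneRates(p=[3.0])
        G = mcmc_sample_rates(np.array([3.0]), np.array([[1.0]]),
                              np.array([1.0]), init, opts)
        p = np.exp(G[:, 0])
        nb = 100
        batches = p.reshape(nb, -1).mean(axis=1)
        mc_se = batches.std(ddof=1) / math.sqrt(nb)
        assert abs(p.mean() - 4.0) <= 3 * mc_se
        tail = (p < 2.0).astype(float)
        tb = tail.reshape(nb, -1).mean(axis=1)
        tail_se = tb.std(ddof=1) / math.sqrt(nb)
        assert abs(tail.mean() - gamma.cdf(2.0, 4)) <= 3 * max(tail_se, 1e-3)

    def test_deterministic(self, rng):
        L = rng.dirichlet(np.ones(2), size=6)
        s = rng.uniform(0.5, 2, 6)
        x = rng.poisson(2.0, 6).astype(float)
        init = GeneRates(p=[0.5, 0.5])
        opts = McmcOptions(ns=500, seed=42)
        a = mcmc_sample_rates(x, L, s, init, opts)
        b = mcmc_sample_rates(x, L, s, init, opts)
        assert np.array_equal(a, b)

    def test_requires_positive_init(self):
        with pytest.raises(ValueError):
            mcmc_sample_rates(np.array([1.0]), np.array([[1.0]]),
                              np.array([1.0]), GeneRates(p=[0.0]),
                              McmcOptions(ns=10))


class TestSummarizePosterior:
    def test_constant_samples(self):
        G = np.full((200, 2), math.log(0.5))
        pm, lo, hi, se = summarize_posterior(G, stat="le")
        assert np.allclose(pm, 0.0) and np.allclose(lo, 0.0)
        assert np.allclose(hi, 0.0) and np.allclose(se, 0.0)

    def test_exhaustive_window_oracle(self, rng):
        # stat "reference" with ref=1 on a 2-column sample matrix isolates
        # column 0 as (g0 - g1)/log2
        raw = rng.normal(size=100)
        G = np.zeros((100, 2))
        G[:, 0] = raw * math.log(2)
        pm, lo, hi, se = summarize_posterior(G, stat="reference",
                                             hpd_level=0.68, ref=1)
        vals = np.sort(G[:, 0] / math.log(2))
        w = math.ceil(0.68 * 100)
        widths = vals[w - 1:] - vals[: 100 - w + 1]
        i = int(np.argmin(widths))
        assert lo[0] == vals[i] and hi[0] == vals[i + w - 1]

    @pytest.mark.parametrize("shift", [-2.0, 2.0])
    def test_asymmetric_se_rule(self, rng, shift):
        raw = rng.normal(loc=shift, size=200)
        G = np.zeros((200, 2))
        G[:, 0] = raw * math.log(2)
        pm, lo, hi, se = summarize_posterior(G, stat="reference", ref=1,
                                             hpd_level=0.68)
        expect = hi[0] - pm[0] if pm[0] < 0 else pm[0] - lo[0]
        assert se[0] == pytest.approx(expect)

    def test_le_per_sample_statistic(self, rng):
        G = rng.normal(size=(50, 4))
        pm, *_ = summarize_posterior(G, stat="le")
        oracle = np.empty((50, 4))
        for s_ in range(50):
            rates = GeneRates(p=np.exp(G[s_]))
            for k in range(4):
                oracle[s_, k] = le_lfc(rates, k)
        assert np.allclose(pm, oracle.mean(axis=0))


def two_group_data(rng, n=60, m=25):
    L = np.zeros((n, 2))
    L[: n // 2, 0] = 1
    L[n // 2:, 1] = 1
    lam = rng.uniform(0.5, 8, size=(2, m))
    s = rng.uniform(0.5, 2, n)
    xd = rng.poisson(s[:, None] * lam[np.argmax(L, axis=1)])
    x = CountsMatrix(sp.csr_matrix(xd), [f"c{i}" for i in range(n)],
                     [f"g{j}" for j in range(m)])
    return x, L, s


class TestDeAnalysis:
    def test_two_group_closed_form_oracle(self, rng):
        x, L, s = two_group_data(rng)
        eps = 0.1
        res = de_analysis(x, L, opts=McmcOptions(ns=4000, eps=eps, seed=1),
                          shrink=False, s=s)
        xd = x.toarray()
        g0 = L[:, 0] == 1
        cf = np.log2(
            ((xd[g0].sum(0) + eps) / (s[g0].sum() + 1))
            / ((xd[~g0].sum(0) + eps) / (s[~g0].sum() + 1))
        )
        tab = res.table[res.table.topic == 0].set_index("feature_id")
        got_map = tab.loc[[f"g{j}" for j in range(25)], "map"].to_numpy()
        got_pm = tab.loc[[f"g{j}" for j in range(25)], "postmean"].to_numpy()
        assert np.allclose(got_map, cf, atol=1e-6)
        # posterior means agree up to MC error at these counts
        assert np.corrcoef(got_pm, cf)[0, 1] > 0.98

    def test_reference_mode_k2_matches_le_magnitude(self, rng):
        x, L, s = two_group_data(rng, n=30, m=10)
        opts = McmcOptions(ns=1500, eps=0.1, seed=5)
        le = de_analysis(x, L, opts=opts, shrink=False, s=s)
        ref = de_analysis(x, L, opts=opts, shrink=False, s=s,
                          lfc_mode="reference", reference=0)
        le1 = le.table[le.table.topic == 1]["map"].to_numpy()
        ref1 = ref.table[ref.table.topic == 1]["map"].to_numpy()
        assert np.allclose(np.abs(ref1), np.abs(le1))
        le_pm = le.table[le.table.topic == 1]["postmean"].to_numpy()
        ref_pm = ref.table[ref.table.topic == 1]["postmean"].to_numpy()
        assert np.allclose(np.abs(ref_pm), np.abs(le_pm))

    def test_topic_permutation(self, rng):
        x, L, s = two_group_data(rng, n=30, m=8)
        opts = McmcOptions(ns=1500, eps=0.1, seed=5)
        a = de_analysis(x, L, opts=opts, shrink=False, s=s)
        b = de_analysis(x, L[:, ::-1], opts=opts, shrink=False, s=s)
        am = a.table.pivot(index="feature_id", columns="topic", values="map")
        bm = b.table.pivot(index="feature_id", columns="topic", values="map")
        # deterministic MAP statistics permute exactly
        assert np.allclose(am.to_numpy(), bm.to_numpy()[:, ::-1])
        # posterior means permute within MC error
        ap = a.table.pivot(index="feature_id", columns="topic", values="postmean")
        bp = b.table.pivot(index="feature_id", columns="topic", values="postmean")
        ase = a.table.pivot(index="feature_id", columns="topic", values="se")
        tol = 4 * np.maximum(ase.to_numpy(), 0.05)
        assert np.all(np.abs(ap.to_numpy() - bp.to_numpy()[:, ::-1]) < tol)

    def test_null_mode(self, rng):
        x, L, s = two_group_data(rng, n=30, m=8)
        res = de_analysis(x, L, opts=McmcOptions(ns=800, eps=0.1, seed=2),
                          shrink=False, s=s, lfc_mode="null")
        xd = x.toarray()
        p0 = xd.sum(0) / s.sum()
        tab = res.table
        assert np.allclose(tab["p0"].to_numpy().reshape(-1, 2)[:, 0], p0)

    def test_shrink_adds_lfsr_and_svalue(self, rng):
        x, L, s = two_group_data(rng, n=30, m=8)
        res = de_analysis(x, L, opts=McmcOptions(ns=800, eps=0.1, seed=2),
                          shrink=True, s=s)
        assert res.table["lfsr"].between(0, 1).all()
        assert res.table["svalue"].notna().all()
        # z = postmean / postsd relation: zero postmean gives zero z
        zero = res.table["postmean"] == 0
        assert (res.table.loc[zero, "z"] == 0).all()

    def test_invalid_memberships(self, rng):
        x, L, s = two_group_data(rng, n=10, m=4)
        with pytest.raises(ValueError, match="sum to 1"):
            de_analysis(x, L * 2.0, opts=McmcOptions(ns=100))
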