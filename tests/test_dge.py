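"""Thinning normalization, NBP fit, exact conditional test, q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqtally import dge, synth
from seqtally.counts import CountMatrix
from seqtally.dge import (
    NBPFit,
    exact_test,
    fit_nbp,
    nbp_test,
    qvalues,
    thin_counts,
    thinning_stability,
)


def matrix_from(counts, na=3, nb=3, prefix=("a", "b")):
    reps = [f"{prefix[0]}{i}" for i in range(na)] + [
        f"{prefix[1]}{i}" for i in range(nb)
    ]
    trt = {r: r[0] for r in reps}
    genes = [f"g{i}" for i in range(len(counts))]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=reps),
        treatments=trt,
    )


class TestThinning:
    def test_equal_libraries_identity(self):
        m = matrix_from([[10, 10, 10, 10, 10, 10], [5, 5, 5, 5, 5, 5]])
        t = thin_counts(m, seed=1)
        pd.testing.assert_frame_equal(t.counts, m.counts)

    def test_expectation_preserved(self):
        # count 10 in a library of 200 thinned to 100: E = 5
        rng_draws = []
        counts = [[10, 0], [190, 100]]  # libraries 200 and 100
        for seed in range(10_000):
            m = matrix_from(counts, na=1, nb=1)
            t = thin_counts(m, seed=seed)
            rng_draws.append(t.counts.iloc[0, 0])
        mean = np.mean(rng_draws)
        se = np.std(rng_draws) / np.sqrt(len(rng_draws))
        assert abs(mean - 5.0) < 3 * se

    def test_seed_determinism(self):
        m = matrix_from([[40, 10, 25, 5, 0, 9], [160, 90, 75, 95, 100, 91]])
        t1 = thin_counts(m, seed=42)
        t2 = thin_counts(m, seed=42)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        t3 = thin_counts(m, seed=43)
        assert not t3.counts.equals(t1.counts)

    def test_non_integral_matrix_rejected(self):
        m = matrix_from([[1.5, 2, 2, 2, 2, 2]])
        with pytest.raises(ValueError, match="integral"):
            thin_counts(m, seed=0)


class TestExactTest:
    fit = NBPFit(phi=0.1, alpha=2.0, mu_hat=None, target_library=1.0)

    def test_balanced_split_gives_p_one(self):
        assert exact_test([10, 10], [10, 10], self.fit) == 1.0

    def test_zero_total_gives_p_one(self):
        assert exact_test([0, 0], [0, 0], self.fit) == 1.0

    def test_group_swap_symmetry(self):
        ya, yb = [3, 9, 1], [20, 14, 30]
        p1 = exact_test(ya, yb, self.fit)
        p2 = exact_test(yb, ya, self.fit)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        # independent oracle: scipy nbinom pmf products, normalized
        def oracle(ya, yb, r):
            a1, a2 = len(ya) * r, len(yb) * r
            S = sum(ya) + sum(yb)
            s = np.arange(S + 1)
            w = stats.nbinom.pmf(s, a1, 0.5) * stats.nbinom.pmf(S - s, a2, 0.5)
            w = w / w.sum()
            obs = w[sum(ya)]
            return w[w <= obs * (1 + dge.TIE_RTOL)].sum()

        rng = np.random.default_rng(0)
        for _ in range(150):
            na, nb = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            ya = rng.integers(0, 30, na)
            yb = rng.integers(0, 30, nb)
            S = ya.sum() + yb.sum()
            if S == 0 or S > 200:
                continue
            mu = np.concatenate([ya, yb]).mean()
            r = float(self.fit.size(mu))
            assert exact_test(ya, yb, self.fit, mu=mu) == pytest.approx(
                oracle(list(ya), list(yb), r), abs=1e-12
            )

    def test_poisson_limit_matches_binomial_test(self):
        tiny = NBPFit(phi=1e-10, alpha=2.0, mu_hat=None, target_library=1.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            ya = rng.integers(0, 40, 3)
            yb = rng.integers(0, 40, 2)
            S = int(ya.sum() + yb.sum())
            if S == 0:
                continue
            p = exact_test(ya, yb, tiny,
                           mu=float(np.concatenate([ya, yb]).mean()))
            ref = stats.binomtest(int(ya.sum()), S, 3 / 5).pvalue
            assert p == pytest.approx(ref, abs=1e-9)


class TestFit:
    def test_parameter_recovery(self):
        m, _ = synth.make_counts(
            n_genes=2000, n_per_group=(3, 3), phi=0.1, alpha=2.0,
            seed=7, lib_factors=[1.0] * 6,
        )
        f = fit_nbp(m)
        assert abs(f.alpha - 2.0) <= 0.15
        assert abs(f.phi - 0.1) / 0.1 <= 0.20

    def test_poisson_data_gives_small_phi(self):
        m, _ = synth.make_counts(
            n_genes=1500, n_per_group=(3, 3), phi=0.0, alpha=2.0,
            seed=8, lib_factors=[1.0] * 6,
        )
        f = fit_nbp(m)
        mu = m.counts.values.mean(axis=1)
        mu = mu[mu > 0]
        # fitted variance inflation over Poisson stays small
        assert np.median(f.variance(mu) / mu) < 1.1

    def test_duplicating_replicates_keeps_likelihood_shape(self):
        # The group means, and hence the profiled likelihood surface, are
        # unchanged when every replicate is duplicated; the Cox-Reid
        # penalty is sample-size aware, so the optimum may shift modestly
        # (duplicated replicates are not independent data), but alpha is
        # stable and phi stays the same order.
        m, _ = synth.make_counts(
            n_genes=800, n_per_group=(3, 3), phi=0.1, alpha=2.0,
            seed=9, lib_factors=[1.0] * 6,
        )
        dup = CountMatrix(
            counts=pd.concat(
                [m.counts, m.counts.add_suffix("_dup", axis=1)], axis=1
            ),
            treatments={
                **m.treatments,
                **{f"{r}_dup": t for r, t in m.treatments.items()},
            },
        )
        f1 = fit_nbp(m)
        f2 = fit_nbp(dup)
        assert f2.alpha == pytest.approx(f1.alpha, abs=0.1)
        assert 0.5 * f1.phi <= f2.phi <= 1.5 * f1.phi


class TestQValues:
    def test_all_ones(self):
        assert (qvalues([1.0, 1.0, 1.0], pi0=1.0) == 1.0).all()

    def test_bh_stepup_example(self):
        np.testing.assert_allclose(
            qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0), [0.04] * 4
        )

    def test_bh_oracle_random(self):
        # independent step-up oracle
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1, 300)
        m = len(p)
        expect = np.empty(m)
        order = np.argsort(p)
        prev = 1.0
        for rank_from_last in range(m, 0, -1):
            i = order[rank_from_last - 1]
            prev = min(prev, p[i] * m / rank_from_last)
            expect[i] = prev
        np.testing.assert_allclose(qvalues(p, pi0=1.0), expect, atol=1e-12)

    def test_pi0_on_uniform_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 5000)
        q = qvalues(p)
        bh = qvalues(p, pi0=1.0)
        ratio = np.median(q / bh)
        assert 0.9 <= ratio <= 1.1  # pi0-hat near 1 for null data

    def test_few_pvalues_warns_and_uses_bh(self):
        with pytest.warns(UserWarning, match="pi0"):
            q = qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.0, 0.5])


class TestDriver:
    def test_direction_and_symmetry(self):
        m, de = synth.make_counts(
            n_genes=400, n_per_group=(3, 3), mu_low=50, mu_high=500,
            phi=0.05, alpha=2.0, fold=4.0, de_fraction=0.1, seed=10,
        )
        res = nbp_test(m, seed=2)
        up = [g for g, f in de.items() if f > 1]
        down = [g for g, f in de.items() if f < 1]
        sig = res.significant(0.05)
        called_up = set(sig[sig["direction"] == "induced"].index)
        called_down = set(sig[sig["direction"] == "repressed"].index)
        assert len(called_up & set(up)) > len(up) * 0.5
        assert len(called_down & set(down)) > len(down) * 0.5

    def test_determinism(self):
        m, _ = synth.make_counts(n_genes=200, n_per_group=(3, 3), seed=11)
        r1 = nbp_test(m, seed=5)
        r2 = nbp_test(m, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestStability:
    def test_equal_libraries_detection_is_total(self):
        rng = np.random.default_rng(12)
        base = synth.nb_counts(
            np.full(300, 200.0), 0.05, 2.0, rng, size=(6, 300)
        ).T
        base[:15, 3:] *= 5  # strong planted effects
        # equalize library sizes exactly so thinning is the identity
        diff = base.sum(axis=0).max() - base.sum(axis=0)
        base[-1, :] += diff
        m = matrix_from(base.tolist())
        assert len(set(m.library_sizes.values())) == 1
        tab = thinning_stability(m, n_iter=20, fdr=0.05, seed=3)
        sig = tab[tab["reference_q"] <= 0.05]
        assert len(sig) > 0
        assert (sig["detection_pct"] == 100.0).all()

    def test_detection_declines_with_reference_q(self):
        m, _ = synth.make_counts(
            n_genes=400, n_per_group=(3, 3), mu_low=50, mu_high=800,
            phi=0.1, alpha=2.0, fold=3.0, de_fraction=0.15, seed=13,
        )
        tab = thinning_stability(m, n_iter=30, fdr=0.05, seed=4)
        rho = stats.spearmanr(
            tab["reference_q"], tab["detection_pct"]
        ).statistic
        assert rho < -0.3
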