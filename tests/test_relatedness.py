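import numpy as np
import pytest

import hybridgp as hg
from hybridgp.relatedness import RelatednessError

from conftest import random_dosages


def matrix_of(D):
    D = np.asarray(D, dtype=float)
    return hg.GenotypeMatrix([f"L{i}" for i in range(D.shape[0])],
                             [f"M{j}" for j in range(D.shape[1])], D,
                             strict_classes=False)


def grm_bruteforce(D):
    """Independent double-loop oracle for the VanRaden GRM."""
    n, m = D.shape
    p = D.mean(axis=0) / 2.0
    W = np.empty_like(D)
    for j in range(m):
        W[:, j] = (D[:, j] - 2 * p[j]) / np.sqrt(2 * p[j] * (1 - p[j]))
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(W[i, j] * W[k, j] for j in range(m)) / m
    return G


def simulate_h2_data(n_hyb, m, h2, seed):
    cfg = hg.SimulationConfig(
        n_lines_per_group={"g1": 35, "g2": 35}, n_markers=m,
        divergence_f=0.1, n_qtl=max(1, m // 10),
        h2_target=max(h2, 0.01), missing_rate=0.0, seed=seed)
    founders, truth = hg.simulate_founders(cfg)
    founders, _ = hg.filter_hybrid_markers(founders, min_rare_allele=0.05)
    qtl = hg.simulate_qtl_effects(founders, min(cfg.n_qtl, founders.n_markers),
                                  seed=seed + 1)
    qtl.group_of_line = truth.group_of_line
    crosses = hg.sample_crosses(founders.line_ids, n_hyb, seed=seed + 2)
    hyb = hg.make_hybrid_genotypes(founders, crosses)
    if h2 == 0:
        rng = np.random.default_rng(seed + 3)
        y = rng.standard_normal(n_hyb)
    else:
        ph = hg.simulate_hybrid_phenotypes(hyb, qtl, h2, seed=seed + 3)
        y = ph.data["trait"].to_numpy()
    return hyb, y


class TestGrm:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            D = random_dosages(rng, rng.integers(4, 9), rng.integers(10, 31))
            D[0], D[1] = 0.0, 2.0  # guarantee every marker is polymorphic
            G = hg.compute_grm(matrix_of(D)).values
            np.testing.assert_allclose(G, grm_bruteforce(D), atol=1e-10)

    def test_identical_inbred_lines(self):
        D = np.array([[0, 2, 2, 0], [0, 2, 2, 0], [2, 0, 0, 2]], dtype=float)
        G = hg.compute_grm(matrix_of(D)).values
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)
        assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-12)

    def test_diagonal_mean_near_one_outbred(self, rng):
        D = random_dosages(rng, 200, 5000, maf_low=0.1)
        G = hg.compute_grm(matrix_of(D)).values
        assert abs(np.diag(G).mean() - 1.0) < 0.05

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(RelatednessError, match="filter"):
            hg.compute_grm(matrix_of([[0, 0], [2, 0]]))

    def test_psd(self, rng):
        D = random_dosages(rng, 20, 100)
        G = hg.compute_grm(matrix_of(D)).values
        assert np.linalg.eigvalsh(G).min() > -1e-10


class TestIbs:
    def test_identical_and_opposite(self):
        D = np.array([[0, 2, 2], [0, 2, 2], [2, 0, 0]], dtype=float)
        ibs = hg.compute_ibs(matrix_of(D)).values
        assert ibs[0, 1] == 1.0
        assert ibs[0, 2] == 0.0
        assert np.all(np.diag(ibs) == 1.0)

    def test_hand_value(self):
        # (0,2,2) vs (0,0,2): mean |di-dj|/2 = (0+1+0)/3 -> IBS = 2/3
        D = np.array([[0, 2, 2], [0, 0, 2]], dtype=float)
        ibs = hg.compute_ibs(matrix_of(D)).values
        assert ibs[0, 1] == pytest.approx(2 / 3, abs=1e-12)

    def test_missingness_uses_shared_markers(self):
        D = np.array([[0, 2, np.nan], [0, np.nan, 2]])
        ibs = hg.compute_ibs(matrix_of(D)).values
        assert ibs[0, 1] == 1.0  # only marker 0 is shared, and it matches

    def test_disjoint_missingness_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 2]])
        with pytest.raises(RelatednessError, match="shares no"):
            hg.compute_ibs(matrix_of(D))


class TestHeRegression:
    def test_null_trait_centered_at_zero(self):
        ests = []
        for rep in range(20):
            hyb, y = simulate_h2_data(300, 500, 0.0, seed=200 + 10 * rep)
            ibs = hg.compute_ibs(hyb)
            est = hg.he_regression(ibs, y, clamp=(-10, 10))
            ests.append(est.sigma_g2)
        assert -0.05 <= np.mean(ests) <= 0.05

    def test_recovers_h2_half(self):
        ests = []
        for rep in range(10):
            hyb, y = simulate_h2_data(500, 1000, 0.5, seed=500 + 10 * rep)
            ests.append(hg.he_regression(hg.compute_ibs(hyb), y).h2)
        assert 0.4 <= np.mean(ests) <= 0.6

    def test_slope_matches_polyfit_oracle(self, rng):
        """The HE slope equals an independently computed OLS fit of the
        standardized cross-products on the relatedness entries."""
        n = 40
        A = rng.standard_normal((n, n)) * 0.1
        rel = (A + A.T) / 2
        np.fill_diagonal(rel, 1.0)
        y = rng.standard_normal(n)
        R = hg.RelatednessMatrix([f"i{i}" for i in range(n)], rel, "grm")
        est = hg.he_regression(R, y, clamp=(-100, 100))
        ys = (y - y.mean()) / y.std(ddof=1)
        iu, ju = np.triu_indices(n, k=1)
        slope = np.polyfit(rel[iu, ju], ys[iu] * ys[ju], 1)[0]
        assert est.sigma_g2 == pytest.approx(slope, abs=1e-10)

    def test_affine_invariance(self, small_population):
        hyb = small_population["hybrids"]
        y = small_population["pheno"].data["trait"].to_numpy()
        ibs = hg.compute_ibs(hyb)
        a = hg.he_regression(ibs, y).h2
        b = hg.he_regression(ibs, 3.7 * y - 12.0).h2
        assert a == pytest.approx(b, abs=1e-12)

    def test_clamping_flag(self, rng):
        n = 30
        A = rng.standard_normal((n, n)) * 0.05
        rel = (A + A.T) / 2
        np.fill_diagonal(rel, 1.0)
        y = rng.standard_normal(n)
        R = hg.RelatednessMatrix([f"i{i}" for i in range(n)], rel, "grm")
        raw = hg.he_regression(R, y, clamp=(-100, 100)).sigma_g2
        est = hg.he_regression(R, y)  # default clamp [0, 1]
        assert est.clamped == (not 0.0 <= raw <= 1.0)
        assert 0.0 <= est.sigma_g2 <= 1.0


class TestReml:
    def test_null_trait_small_h2(self):
        small = 0
        for rep in range(10):
            hyb, y = simulate_h2_data(300, 500, 0.0, seed=900 + 10 * rep)
            grm = hg.compute_grm(hg.impute_missing(hyb))
            grm = hg.RelatednessMatrix(grm.ids, grm.values, "grm")
            est = hg.reml_heritability(grm, y)
            small += est.h2 < 0.1
        assert small >= 9

    def test_agreement_with_he(self):
        diffs = []
        for rep in range(10):
            hyb, y = simulate_h2_data(500, 1000, 0.5, seed=1500 + 10 * rep)
            he = hg.he_regression(hg.compute_ibs(hyb), y).h2
            reml = hg.reml_heritability(hg.compute_grm(hyb), y).h2
            diffs.append(reml - he)
        assert abs(np.mean(diffs)) < 0.1

    def test_local_optimality(self, small_population):
        hyb = hg.impute_missing(small_population["hybrids"])
        y = small_population["pheno"].data["trait"].to_numpy()
        grm = hg.compute_grm(hyb)
        est = hg.reml_heritability(grm, y)

        d, U = np.linalg.eigh(grm.values)
        d = np.maximum(d, 0)
        yr, xr = U.T @ y, U.T @ np.ones(len(y))

        def rll(h2):
            lam = h2 * d + 1 - h2
            w = 1 / lam
            xtx = (xr * w * xr).sum()
            beta = (xr * w * yr).sum() / xtx
            r = yr - beta * xr
            s2 = (r * w * r).sum() / (len(y) - 1)
            return -0.5 * ((len(y) - 1) * np.log(s2) + np.log(lam).sum()
                           + np.log(xtx) + (len(y) - 1))

        at = rll(est.h2)
        for h2 in (est.h2 - 0.05, est.h2 + 0.05):
            if 1e-6 < h2 < 1 - 1e-6:
                assert at >= rll(h2) - 1e-9

    def test_h2_identity(self, small_population):
        hyb = hg.impute_missing(small_population["hybrids"])
        y = small_population["pheno"].data["trait"].to_numpy()
        est = hg.reml_heritability(hg.compute_grm(hyb), y)
        assert est.h2 == pytest.approx(
            est.sigma_g2 / (est.sigma_g2 + est.sigma_e2), abs=1e-12)

    def test_requires_grm_kind(self, small_population):
        ibs = hg.compute_ibs(small_population["hybrids"])
        y = small_population["pheno"].data["trait"].to_numpy()
        with pytest.raises(RelatednessError, match="GRM"):
            hg.reml_heritability(ibs, y)


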