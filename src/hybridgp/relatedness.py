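"""Genomic relationship / IBS matrices and SNP heritability estimation.

Two moment/likelihood routes to h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2):

* Haseman-Elston (HE) regression — OLS of phenotype cross-products y_i*y_j on
  pairwise relatedness over all i<j pairs, with y standardized, so the slope is
  the genetic variance on the unit-variance scale and equals h2 directly.
* Single-component REML — eigendecomposition of the GRM and a bounded 1-D
  search of the restricted log-likelihood over h2, reporting variance
  components on the observed phenotype scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .genotypes import GenotypeMatrix, HybridGenotypeMatrix


class RelatednessError(ValueError):
    pass


@dataclass
class RelatednessMatrix:
    """Symmetric n x n relatedness among lines/hybrids; kind 'grm' or 'ibs'.

    For IBS matrices, ``calibration`` holds the affine map (a, b) from IBS to
    the relationship (GRM) scale fitted on the same marker panel; HE
    regression uses it so the variance explained is on the heritability scale.
    """

    ids: list[str]
    values: np.ndarray
    kind: str  # {"grm", "ibs"}
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise RelatednessError("relatedness matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise RelatednessError("relatedness matrix not symmetric")
        if self.kind not in ("grm", "ibs"):
            raise RelatednessError(f"unknown kind {self.kind!r}")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id")


@dataclass
class HeritabilityEstimate:
    """Variance components and h2 with the estimation route recorded."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    method: str  # {"he", "reml"}
    n: int
    m: int
    clamped: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _dosage_ids(g) -> tuple[np.ndarray, list[str]]:
    if isinstance(g, HybridGenotypeMatrix):
        return g.dosages, list(g.hybrid_ids)
    if isinstance(g, GenotypeMatrix):
        return g.dosages, list(g.line_ids)
    raise TypeError(type(g))


def compute_grm(g) -> RelatednessMatrix:
    """VanRaden-style GRM: G = W W^T / m with columns centered by 2p and
    scaled by sqrt(2p(1-p)), p the observed alt-allele frequency.

    Requires complete (imputed) dosages and polymorphic markers.
    """
    D, ids = _dosage_ids(g)
    if np.isnan(D).any():
        raise RelatednessError("missing dosages: impute before compute_grm")
    if D.shape[0] < 2:
        raise RelatednessError("need at least 2 lines")
    p = D.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        j = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        raise RelatednessError(
            f"monomorphic marker at column {j}; filter before compute_grm")
    W = (D - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = W @ W.T / D.shape[1]
    G = (G + G.T) / 2.0
    return RelatednessMatrix(ids, G, "grm")


def compute_ibs(g) -> RelatednessMatrix:
    """Identity-by-state similarity: 1 - mean |d_i - d_j| / 2 over markers
    observed in both lines. Diagonal is 1; missing calls handled pairwise."""
    D, ids = _dosage_ids(g)
    obs = ~np.isnan(D)
    D0 = np.where(obs, D, 0.0)
    O = obs.astype(float)
    n_shared = O @ O.T
    if (n_shared == 0).any():
        raise RelatednessError("a pair of lines shares no non-missing marker")
    # sum over shared markers of |d_i - d_j| without forming n x n x m
    if obs.all():
        n = D.shape[0]
        S = np.empty((n, n))
        for i in range(n):
            S[i] = np.abs(D - D[i]).sum(axis=1)
    else:
        n = D.shape[0]
        S = np.empty((n, n))
        for i in range(n):
            both = obs & obs[i]
            S[i] = np.abs(np.where(both, D0 - D0[i], 0.0)).sum(axis=1)
    ibs = 1.0 - (S / n_shared) / 2.0
    ibs = (ibs + ibs.T) / 2.0
    np.fill_diagonal(ibs, 1.0)

    # calibrate the IBS -> relationship map on this panel: IBS compresses the
    # genomic relationship by roughly the mean marker heterozygosity, so the
    # raw slope is several times too small for variance estimation
    calibration = None
    if D.shape[0] >= 10:
        col_means = np.nansum(D0, axis=0) / np.maximum(O.sum(axis=0), 1)
        Dimp = np.where(obs, D0, col_means[None, :])
        p = Dimp.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if poly.sum() >= 2:
            pp = p[poly]
            Wp = (Dimp[:, poly] - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
            G = Wp @ Wp.T / poly.sum()
            iu, ju = np.triu_indices(D.shape[0], k=1)
            x, gv = ibs[iu, ju], G[iu, ju]
            if x.var() > 0:
                b = np.cov(x, gv, ddof=1)[0, 1] / x.var(ddof=1)
                a = gv.mean() - b * x.mean()
                calibration = (float(a), float(b))
    return RelatednessMatrix(ids, ibs, "ibs", calibration=calibration)


def he_regression(rel: RelatednessMatrix, y: np.ndarray,
                  clamp: tuple[float, float] = (0.0, 1.0)) -> HeritabilityEstimate:
    """Haseman-Elston regression of y_i*y_j on relatedness over i<j pairs.

    y is standardized to zero mean and unit variance first, which makes the
    OLS slope the genetic variance on that scale (= h2) and the estimate
    invariant to affine transformations of the phenotype.

    An IBS matrix is first mapped onto the relationship scale via its stored
    panel calibration (or, failing that, A = (IBS - c)/(1 - c) with c the
    mean off-diagonal IBS): raw IBS is an affine compression of the genomic
    relationship, so regressing on it directly would inflate the variance
    estimate several-fold. GRM input is used as-is.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(rel.ids):
        raise RelatednessError("phenotype / relatedness length mismatch")
    if n < 10:
        raise RelatednessError("need n >= 10 for HE regression")
    sd = y.std(ddof=1)
    if sd == 0:
        raise RelatednessError("phenotype has zero variance")
    ys = (y - y.mean()) / sd

    iu, ju = np.triu_indices(n, k=1)
    x = rel.values[iu, ju]
    if rel.kind == "ibs":
        if rel.calibration is not None:
            a, b = rel.calibration
            x = a + b * x
        else:
            c = x.mean()
            if c >= 1.0:
                raise RelatednessError("IBS matrix is constant 1 across pairs")
            x = (x - c) / (1.0 - c)
    prod = ys[iu] * ys[ju]
    vx = x.var()
    if vx == 0:
        raise RelatednessError("relatedness has zero variance across pairs")
    slope = np.cov(x, prod, ddof=1)[0, 1] / x.var(ddof=1)

    lo, hi = clamp
    clamped = not (lo <= slope <= hi)
    sg2 = float(min(max(slope, lo), hi))
    return HeritabilityEstimate(
        sigma_g2=sg2, sigma_e2=float(1.0 - sg2), h2=sg2,
        method="he", n=n, m=0, clamped=clamped)


def reml_heritability(rel: RelatednessMatrix, y: np.ndarray,
                      tol: float = 1e-6) -> HeritabilityEstimate:
    """Single-component REML with an intercept as the only fixed effect.

    The GRM eigendecomposition G = U diag(d) U^T reduces the model to
    independent coordinates with variances sigma_p^2 * (h2*d_i + 1-h2);
    sigma_p^2 is profiled out and h2 maximized by bounded scalar search.
    """
    if rel.kind != "grm":
        raise RelatednessError("reml_heritability requires a GRM")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(rel.ids):
        raise RelatednessError("phenotype / relatedness length mismatch")
    if y.std(ddof=1) == 0:
        raise RelatednessError("phenotype has zero variance")
    d, U = np.linalg.eigh(rel.values)
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise RelatednessError("GRM not PSD beyond tolerance")
    d = np.maximum(d, 0.0)
    yr = U.T @ y
    xr = U.T @ np.ones(n)

    def neg_restricted_ll(h2: float) -> float:
        lam = h2 * d + (1.0 - h2)
        w = 1.0 / lam
        xtx = (xr * w * xr).sum()
        beta = (xr * w * yr).sum() / xtx
        r = yr - beta * xr
        rss = (r * w * r).sum()
        s2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(s2) + np.log(lam).sum()
                     + np.log(xtx) + (n - 1))
        return -ll

    res = minimize_scalar(neg_restricted_ll, bounds=(1e-6, 1 - 1e-6),
                          method="bounded", options={"xatol": tol})
    h2 = float(res.x)
    lam = h2 * d + (1.0 - h2)
    w = 1.0 / lam
    xtx = (xr * w * xr).sum()
    beta = (xr * w * yr).sum() / xtx
    r = yr - beta * xr
    s2 = float((r * w * r).sum() / (n - 1))  # sigma_p^2 on observed scale
    return HeritabilityEstimate(
        sigma_g2=h2 * s2, sigma_e2=(1.0 - h2) * s2, h2=h2,
        method="reml", n=n, m=0, clamped=False)


def lambda_from_h2(h2: float, clamp: tuple[float, float] = (0.01, 0.99)) -> float:
    """Shrinkage ratio (1 - sigma_u^2)/sigma_u^2 on the unit-variance scale,
    with h2 clamped away from {0, 1} to keep lambda finite and positive."""
    h2c = min(max(h2, clamp[0]), clamp[1])
    return (1.0 - h2c) / h2c
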