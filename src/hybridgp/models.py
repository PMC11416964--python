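"""Genomic prediction models: ridge-regression BLUP, HE-based BLUP, ensembles.

The parametric methods share one linear model, y = mu + Z u + e with
u ~ N(0, I sigma_u^2), whose BLUP solution is computed through the n x n dual
(kinship) system:

    u_hat = Zc^T (Zc Zc^T + lambda I)^{-1} (y - mu_hat),

with Zc the column-centered training genotypes. They differ only in how the
ridge parameter lambda = sigma_e^2 / sigma_u^2 is chosen: ``RidgeBLUP`` uses
REML on the training kinship (or a 10-fold cross-validated grid), while
``HEBLUPAdditive`` takes sigma_u^2 from IBS-based Haseman-Elston regression and
sets lambda = (1 - sigma_u^2) / sigma_u^2 on the unit-variance scale, mapped
onto the centered-dosage system by the mean kinship diagonal. ``EnsembleGP``
delegates to random-forest / gradient-boosted-tree regressors with their
default hyperparameters, behind the same predict contract.

All models follow the Model/Results convention: construct from (y, Z), call
``fit()``, and use the returned results object for prediction and summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GenotypeMatrix, HybridGenotypeMatrix
from .relatedness import (
    RelatednessMatrix,
    compute_grm,
    compute_ibs,
    he_regression,
    lambda_from_h2,
    reml_heritability,
)

H2_CLAMP = (0.01, 0.99)


class ModelError(ValueError):
    pass


def _as_matrix(Z, marker_ids=None):
    """Accept a plain array or a (hybrid) genotype container."""
    if isinstance(Z, HybridGenotypeMatrix):
        return np.asarray(Z.dosages, float), list(Z.marker_ids)
    if isinstance(Z, GenotypeMatrix):
        return np.asarray(Z.dosages, float), list(Z.marker_ids)
    Z = np.asarray(Z, dtype=float)
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(Z.shape[1])]
    return Z, list(marker_ids)


def _solve_kinship(K: np.ndarray, lam: float, rhs: np.ndarray) -> np.ndarray:
    A = K + lam * np.eye(K.shape[0])
    try:
        return cho_solve(cho_factor(A), rhs)
    except np.linalg.LinAlgError:
        return cho_solve(cho_factor(A + 1e-8 * np.eye(K.shape[0])), rhs)


@dataclass
class GenomicPredictionResults:
    """Fitted predictor: intercept, marker effects (parametric), or a
    delegated learner (ensemble), plus everything needed to score new
    genotypes on the training scale."""

    method: str  # {"rrblup", "heblp_a", "rf", "gbm"}
    mu_hat: float
    marker_ids: list[str]
    train_marker_means: np.ndarray
    marker_effects: np.ndarray | None = None
    lam: float | None = None
    lambda_strategy: str | None = None
    h2_used: float | None = None
    delegated_model: object | None = None
    seed: int | None = None
    n_train: int = 0
    warnings_: list[str] = field(default_factory=list)

    @property
    def is_parametric(self) -> bool:
        return self.marker_effects is not None

    def predict(self, genotypes, marker_ids: Sequence[str] | None = None) -> np.ndarray:
        """GEBVs (trait units) for rows of ``genotypes``.

        Marker ids, when supplied or carried by the container, must match the
        training markers in order; missing entries are rejected.
        """
        Z, ids = _as_matrix(genotypes, marker_ids)
        if ids != self.marker_ids:
            for k, (a, b) in enumerate(zip(ids, self.marker_ids)):
                if a != b:
                    raise ModelError(
                        f"marker mismatch at position {k}: {a!r} != {b!r}")
            raise ModelError(
                f"marker count mismatch: {len(ids)} != {len(self.marker_ids)}")
        if np.isnan(Z).any():
            raise ModelError("missing genotypes: impute before predicting")
        if self.is_parametric:
            return self.mu_hat + (Z - self.train_marker_means) @ self.marker_effects
        return np.asarray(self.delegated_model.predict(Z), dtype=float)

    def summary(self) -> str:
        lines = [
            "Genomic prediction results",
            "=" * 42,
            f"method            {self.method}",
            f"n training        {self.n_train}",
            f"n markers         {len(self.marker_ids)}",
            f"mu_hat            {self.mu_hat:.6g}",
        ]
        if self.is_parametric:
            lines += [
                f"lambda            {self.lam:.6g} ({self.lambda_strategy})",
                f"h2 used           {'-' if self.h2_used is None else f'{self.h2_used:.4f}'}",
                f"||u||             {np.linalg.norm(self.marker_effects):.6g}",
            ]
        if self.warnings_:
            lines += ["warnings:"] + [f"  - {w}" for w in self.warnings_]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        if not self.is_parametric:
            raise ModelError("only parametric models serialize to JSON")
        payload = {
            "method": self.method,
            "mu_hat": self.mu_hat,
            "marker_ids": self.marker_ids,
            "train_marker_means": self.train_marker_means.tolist(),
            "marker_effects": self.marker_effects.tolist(),
            "lambda": self.lam,
            "lambda_strategy": self.lambda_strategy,
            "h2_used": self.h2_used,
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GenomicPredictionResults":
        d = json.loads(Path(path).read_text())
        return cls(
            method=d["method"], mu_hat=d["mu_hat"], marker_ids=d["marker_ids"],
            train_marker_means=np.asarray(d["train_marker_means"]),
            marker_effects=np.asarray(d["marker_effects"]), lam=d["lambda"],
            lambda_strategy=d.get("lambda_strategy"), h2_used=d.get("h2_used"),
            n_train=d.get("n_train", 0),
        )


class _ParametricBase:
    def __init__(self, y, Z, marker_ids=None):
        self.Z, self.marker_ids = _as_matrix(Z, marker_ids)
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != self.Z.shape[0]:
            raise ModelError("y and Z row count mismatch")
        if np.isnan(self.Z).any():
            raise ModelError("missing genotypes: impute before fitting")
        if len(self.y) < 10:
            raise ModelError("need at least 10 training hybrids")
        if self.y.std(ddof=1) == 0:
            raise ModelError("phenotype has zero variance")
        self.marker_means = self.Z.mean(axis=0)
        self.Zc = self.Z - self.marker_means
        self.K = self.Zc @ self.Zc.T
        # mean kinship diagonal: maps unit-variance lambda onto this system
        self.kin_scale = float(np.trace(self.K) / self.K.shape[0])

    def _solve(self, lam: float, method: str, strategy: str,
               h2_used: float | None, warns: list[str]) -> GenomicPredictionResults:
        if lam <= 0:
            raise ModelError(f"lambda must be positive, got {lam}")
        mu = float(self.y.mean())
        alpha = _solve_kinship(self.K, lam, self.y - mu)
        u = self.Zc.T @ alpha
        return GenomicPredictionResults(
            method=method, mu_hat=mu, marker_ids=self.marker_ids,
            train_marker_means=self.marker_means, marker_effects=u, lam=lam,
            lambda_strategy=strategy, h2_used=h2_used, n_train=len(self.y),
            warnings_=warns,
        )


class RidgeBLUP(_ParametricBase):
    """Ridge-regression BLUP of marker effects.

    Parameters
    ----------
    y : training phenotypes (trait units).
    Z : training genotypes (hybrids x markers), complete.
    lambda_strategy : "reml" (default; REML on the training kinship),
        "cv_grid" (10-fold cross-validated grid, 25 log-spaced points,
        ties broken toward heavier shrinkage), or "fixed" with ``lam``.
    """

    def __init__(self, y, Z, marker_ids=None, lambda_strategy="reml",
                 lam=None, n_folds=10, seed=0):
        super().__init__(y, Z, marker_ids)
        if lam is not None:
            lambda_strategy = "fixed"
        if lambda_strategy not in ("reml", "cv_grid", "fixed"):
            raise ModelError(f"unknown lambda strategy {lambda_strategy!r}")
        if lambda_strategy == "fixed" and lam is None:
            raise ModelError("fixed strategy requires lam")
        self.lambda_strategy = lambda_strategy
        self.lam = lam
        self.n_folds = n_folds
        self.seed = seed

    def fit(self) -> GenomicPredictionResults:
        warns: list[str] = []
        h2_used = None
        if self.lambda_strategy == "fixed":
            lam = float(self.lam)
        elif self.lambda_strategy == "reml":
            G = RelatednessMatrix(
                [str(i) for i in range(len(self.y))],
                self.K / self.kin_scale, "grm")
            est = reml_heritability(G, self.y)
            h2c = min(max(est.h2, H2_CLAMP[0]), H2_CLAMP[1])
            if h2c != est.h2:
                warns.append(f"REML h2 {est.h2:.4f} clamped to {h2c}")
            h2_used = h2c
            lam = self.kin_scale * (1.0 - h2c) / h2c
        else:
            lam = self._cv_lambda()
        return self._solve(lam, "rrblup", self.lambda_strategy, h2_used, warns)

    def _cv_lambda(self) -> float:
        grid = np.logspace(-3, 3, 25) * self.kin_scale
        rng = np.random.default_rng(self.seed)
        n = len(self.y)
        order = rng.permutation(n)
        folds = np.array_split(order, self.n_folds)
        sse = np.zeros(len(grid))
        for hold in folds:
            tr = np.setdiff1d(np.arange(n), hold)
            Ktr = self.K[np.ix_(tr, tr)]
            Kht = self.K[np.ix_(hold, tr)]
            mu = self.y[tr].mean()
            d, U = np.linalg.eigh(Ktr)
            v = U.T @ (self.y[tr] - mu)
            for g, lam in enumerate(grid):
                alpha = U @ (v / (d + lam))
                pred = mu + Kht @ alpha
                sse[g] += ((self.y[hold] - pred) ** 2).sum()
        best = sse.min()
        # ties (within tiny numerical slack) resolved toward larger lambda
        return float(grid[np.flatnonzero(sse <= best * (1 + 1e-12))[-1]])


class HEBLUPAdditive(_ParametricBase):
    """BLUP with lambda from IBS-based Haseman-Elston regression.

    sigma_u^2 is the HE slope on the standardized-phenotype scale, so
    lambda = (1 - sigma_u^2)/sigma_u^2 there; it is rescaled to the
    centered-dosage solver by the mean kinship diagonal. The solution is
    otherwise identical to ``RidgeBLUP`` at the same lambda.
    """

    def __init__(self, y, Z, ibs: RelatednessMatrix | None = None, marker_ids=None):
        super().__init__(y, Z, marker_ids)
        if ibs is not None and len(ibs.ids) != len(self.y):
            raise ModelError("IBS matrix does not align with training data")
        self.ibs = ibs

    def fit(self) -> GenomicPredictionResults:
        warns: list[str] = []
        ibs = self.ibs
        if ibs is None:
            ibs = compute_ibs(GenotypeMatrix(
                [f"h{i}" for i in range(len(self.y))],
                self.marker_ids, self.Z, strict_classes=False))
        est = he_regression(ibs, self.y)
        h2c = min(max(est.h2, H2_CLAMP[0]), H2_CLAMP[1])
        if h2c != est.h2 or est.clamped:
            warns.append(
                f"HE sigma_u^2 {est.sigma_g2:.4f} at clamp boundary {h2c}")
        lam_std = lambda_from_h2(h2c)
        lam = self.kin_scale * lam_std
        res = self._solve(lam, "heblp_a", "he", h2c, warns)
        return res


class EnsembleGP:
    """Random-forest or gradient-boosted-trees baseline behind the same
    predict contract; markers enter as plain features, hyperparameters stay
    at the delegated library's defaults, and the seed fixes the fit."""

    def __init__(self, y, Z, method="rf", marker_ids=None, seed=0):
        self.Z, self.marker_ids = _as_matrix(Z, marker_ids)
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != self.Z.shape[0]:
            raise ModelError("y and Z row count mismatch")
        if np.isnan(self.Z).any():
            raise ModelError("missing genotypes: impute before fitting")
        if method not in ("rf", "gbm"):
            raise ModelError(f"unknown ensemble method {method!r}")
        self.method = method
        self.seed = seed

    def fit(self) -> GenomicPredictionResults:
        if self.method == "rf":
            try:
                from sklearn.ensemble import RandomForestRegressor
            except ImportError as exc:  # pragma: no cover
                raise ModelError("random forest backend unavailable") from exc
            reg = RandomForestRegressor(random_state=self.seed)
        else:
            try:
                from lightgbm import LGBMRegressor
            except ImportError as exc:  # pragma: no cover
                raise ModelError("gradient boosting backend unavailable") from exc
            reg = LGBMRegressor(random_state=self.seed, verbosity=-1,
                                deterministic=True, force_row_wise=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg.fit(self.Z, self.y)
        return GenomicPredictionResults(
            method=self.method, mu_hat=float(self.y.mean()),
            marker_ids=self.marker_ids,
            train_marker_means=self.Z.mean(axis=0),
            delegated_model=reg, seed=self.seed, n_train=len(self.y),
        )


# ---------------------------------------------------------------------------
# Functional facade

def fit_rrblup(Z, y, lambda_strategy="reml", marker_ids=None, lam=None,
               seed=0) -> GenomicPredictionResults:
    return RidgeBLUP(y, Z, marker_ids=marker_ids,
                     lambda_strategy=lambda_strategy, lam=lam, seed=seed).fit()


def fit_heblp_a(Z, y, ibs=None, marker_ids=None) -> GenomicPredictionResults:
    return HEBLUPAdditive(y, Z, ibs=ibs, marker_ids=marker_ids).fit()


def fit_ensemble(method, Z, y, marker_ids=None, seed=0) -> GenomicPredictionResults:
    return EnsembleGP(y, Z, method=method, marker_ids=marker_ids, seed=seed).fit()


def predict_gebv(model: GenomicPredictionResults, genotypes,
                 marker_ids=None) -> np.ndarray:
    return model.predict(genotypes, marker_ids)


FIT_BY_METHOD = {
    "rrblup": lambda Z, y, seed=0, **kw: fit_rrblup(Z, y, seed=seed, **kw),
    "heblp_a": lambda Z, y, seed=0, **kw: fit_heblp_a(Z, y, **kw),
    "rf": lambda Z, y, seed=0, **kw: fit_ensemble("rf", Z, y, seed=seed, **kw),
    "gbm": lambda Z, y, seed=0, **kw: fit_ensemble("gbm", Z, y, seed=seed, **kw),
}
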