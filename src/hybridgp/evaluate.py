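"""Accuracy protocol: repeated random train/candidate splits, Pearson
accuracy per trait and method, and the heritability-accuracy correlation.

Within a replicate, every method is fitted on the same training set and
scored on the same candidates (a paired design); candidates are simply all
non-training hybrids with an observed trait value, which is why candidate
sizes vary across traits with missingness. The "accuracy" is the Pearson
correlation between observed phenotypes and predicted genomic values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import FIT_BY_METHOD

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class SplitPlan:
    replicate: int
    training_ids: list[str]
    candidate_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.candidate_ids):
            raise EvaluationError("training and candidate sets overlap")


@dataclass
class AccuracyReport:
    """Tidy per-replicate accuracies plus mean +/- standard error."""

    records: pd.DataFrame  # trait, method, replicate, r, n_train, n_candidate
    n_replicates: int
    flags: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        def se(x):
            return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

        out = (self.records.groupby(["trait", "method"])["r"]
               .agg(mean_r="mean", se_r=se, n_replicates="count")
               .reset_index())
        return out

    def mean_accuracy_by_trait(self) -> pd.Series:
        """Per-trait accuracy averaged over methods and replicates."""
        return self.records.groupby("trait")["r"].mean()


def make_splits(ids_with_phenotype: list[str], n_train: int,
                n_replicates: int, seed: int) -> list[SplitPlan]:
    """Uniform training samples without replacement; candidates are the rest.

    Replicate r uses seed + r so the plan is reproducible yet varies across
    replicates.
    """
    ids = list(ids_with_phenotype)
    if n_train >= len(ids):
        raise EvaluationError(
            f"n_train={n_train} >= available phenotyped ids ({len(ids)})")
    plans = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        train_idx = rng.choice(len(ids), size=n_train, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[train_idx] = True
        plans.append(SplitPlan(
            replicate=r,
            training_ids=[ids[i] for i in np.flatnonzero(mask)],
            candidate_ids=[ids[i] for i in np.flatnonzero(~mask)],
            seed=seed + r,
        ))
    return plans


def accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed phenotypes and predictions."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if len(observed) != len(predicted) or len(observed) < 3:
        raise EvaluationError("need equal-length vectors with n >= 3")
    if observed.std() == 0 or predicted.std() == 0:
        raise EvaluationError("zero variance in observed or predicted values")
    return float(np.corrcoef(observed, predicted)[0, 1])


def evaluate_methods(
    hybrid_dosages: np.ndarray,
    hybrid_ids: list[str],
    phenotypes: pd.DataFrame,
    traits: list[str],
    methods: list[str],
    n_train: int,
    n_replicates: int = 10,
    seed: int = 0,
) -> AccuracyReport:
    """Fit every method on shared splits and aggregate Pearson accuracies.

    ``phenotypes`` must carry a ``hybrid_id`` column plus one column per
    trait; records missing a trait are dropped for that trait only.
    """
    for mth in methods:
        if mth not in FIT_BY_METHOD:
            raise EvaluationError(f"unknown method {mth!r}")
    pheno = phenotypes.set_index("hybrid_id")
    row_of = {h: i for i, h in enumerate(hybrid_ids)}
    rows = []
    flags: list[str] = []
    for trait in traits:
        vals = pheno[trait].dropna()
        ids = [h for h in vals.index if h in row_of]
        plans = make_splits(ids, n_train, n_replicates, seed)
        for plan in plans:
            tr_rows = [row_of[h] for h in plan.training_ids]
            ca_rows = [row_of[h] for h in plan.candidate_ids]
            Ztr = hybrid_dosages[tr_rows]
            Zca = hybrid_dosages[ca_rows]
            ytr = vals.loc[plan.training_ids].to_numpy()
            yca = vals.loc[plan.candidate_ids].to_numpy()
            for mth in methods:
                try:
                    model = FIT_BY_METHOD[mth](Ztr, ytr, seed=plan.seed)
                    pred = model.predict(Zca, marker_ids=model.marker_ids)
                    r = accuracy(yca, pred)
                except Exception as exc:  # degrade, don't abort the trait
                    msg = (f"trait={trait} method={mth} replicate="
                           f"{plan.replicate}: {exc}")
                    logger.warning("replicate excluded: %s", msg)
                    flags.append(msg)
                    continue
                rows.append({
                    "trait": trait, "method": mth,
                    "replicate": plan.replicate, "r": r,
                    "n_train": len(tr_rows), "n_candidate": len(ca_rows),
                })
    if n_replicates == 1:
        flags.append("single replicate: standard errors reported as 0")
    return AccuracyReport(pd.DataFrame(rows), n_replicates, flags)


def correlate_h2_accuracy(report: AccuracyReport,
                          h2_by_trait: dict[str, float]) -> tuple[float, float]:
    """Pearson R (and two-sided p) between per-trait heritability and
    per-trait accuracy averaged over methods."""
    acc = report.mean_accuracy_by_trait()
    traits = [t for t in acc.index if t in h2_by_trait]
    if len(traits) < 3:
        raise EvaluationError("need at least 3 traits")
    x = np.array([h2_by_trait[t] for t in traits])
    y = acc.loc[traits].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise EvaluationError("zero variance across traits")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return float(r), float(p)
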