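"""Exhaustive half-diallel prediction, ranking, genetic gain, GCA and
heterotic-pattern summaries.

For N inbred parents the half-diallel holds N(N-1)/2 unordered crosses
without selfs. Hybrid genotypes are built and scored in batches so the full
cross set is never materialized at once. "GCA" here is the operational
breeder's definition — a line's mean predicted GEBV over its N-1 crosses —
not the classical least-squares diallel decomposition. "Genetic gain" for a
selected fraction is the mean GEBV of that top fraction minus the mean over
all crosses.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, make_hybrid_genotypes
from .models import GenomicPredictionResults


class DiallelError(ValueError):
    pass


@dataclass
class CrossTable:
    """Predicted GEBVs for unordered parent pairs (canonical order)."""

    data: pd.DataFrame  # parent1, parent2, gebv
    trait: str = "trait"
    method: str = ""

    def __post_init__(self) -> None:
        d = self.data
        if (d["parent1"] == d["parent2"]).any():
            raise DiallelError("self-cross in cross table")
        if (d["parent1"] > d["parent2"]).any():
            raise DiallelError("non-canonical parent order in cross table")
        if d.duplicated(["parent1", "parent2"]).any():
            raise DiallelError("duplicate cross in table")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def parents(self) -> list[str]:
        return sorted(set(self.data["parent1"]) | set(self.data["parent2"]))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class HeteroticSummary:
    """Per group-pair category statistics and top-fraction composition."""

    categories: pd.DataFrame  # category, count, mean_gebv, sd_gebv
    overall_mean: float
    top_composition: dict[float, pd.DataFrame]  # fraction -> category, count, share
    group_involvement: dict[float, dict[str, float]]  # fraction -> group -> share
    n_crosses: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "overall_mean": self.overall_mean,
            "n_crosses": self.n_crosses,
            "categories": self.categories.to_dict(orient="records"),
            "top_composition": {
                str(f): df.to_dict(orient="records")
                for f, df in self.top_composition.items()},
            "group_involvement": {
                str(f): d for f, d in self.group_involvement.items()},
        }, indent=2))


def enumerate_crosses(line_ids: list[str]) -> list[tuple[str, str]]:
    """All N(N-1)/2 unordered pairs in lexicographic order, no selfs."""
    ids = sorted(line_ids)
    if len(ids) != len(set(ids)):
        raise DiallelError("duplicate line ids")
    if len(ids) < 2:
        raise DiallelError("need at least 2 lines")
    return list(itertools.combinations(ids, 2))


def predict_all_crosses(
    model: GenomicPredictionResults,
    parents: GenotypeMatrix,
    batch_size: int = 5000,
    trait: str = "trait",
) -> CrossTable:
    """Predict every half-diallel cross, batched for memory."""
    if np.isnan(parents.dosages).any():
        raise DiallelError("parents carry missing dosages: impute first")
    crosses = enumerate_crosses(parents.line_ids)
    gebvs = np.empty(len(crosses))
    for start in range(0, len(crosses), batch_size):
        chunk = crosses[start:start + batch_size]
        hyb = make_hybrid_genotypes(parents, chunk)
        gebvs[start:start + len(chunk)] = model.predict(hyb)
    df = pd.DataFrame({
        "parent1": [c[0] for c in crosses],
        "parent2": [c[1] for c in crosses],
        "gebv": gebvs,
    })
    return CrossTable(df, trait=trait, method=model.method)


def top_fraction(table: CrossTable, fraction: float) -> CrossTable:
    """Top floor(fraction * N) crosses by GEBV, ties broken by canonical
    pair order so the selection is deterministic."""
    if not (0 < fraction <= 1):
        raise DiallelError("fraction must lie in (0, 1]")
    if len(table) == 0:
        raise DiallelError("empty cross table")
    k = int(np.floor(fraction * len(table)))
    d = table.data.sort_values(
        ["gebv", "parent1", "parent2"], ascending=[False, True, True],
        kind="mergesort").head(k).reset_index(drop=True)
    return CrossTable(d, trait=table.trait, method=table.method)


def genetic_gain(table: CrossTable, fraction: float) -> float:
    """Mean GEBV of the selected top fraction minus the overall mean.

    An empty selection (floor(fraction * N) = 0) yields zero gain.
    """
    top = top_fraction(table, fraction)
    if len(top) == 0:
        return 0.0
    return float(top.data["gebv"].mean() - table.data["gebv"].mean())


def gca(table: CrossTable) -> pd.Series:
    """Per-line mean GEBV over its crosses in a complete half-diallel,
    sorted descending. Errors if any pair of lines is missing."""
    lines = table.parents
    n = len(lines)
    expected = n * (n - 1) // 2
    if len(table) != expected:
        have = {(a, b) for a, b in zip(table.data["parent1"], table.data["parent2"])}
        for pair in itertools.combinations(lines, 2):
            if pair not in have:
                raise DiallelError(f"incomplete diallel: missing cross {pair}")
        raise DiallelError("incomplete diallel")
    sums: dict[str, float] = {l: 0.0 for l in lines}
    for p1, p2, g in zip(table.data["parent1"], table.data["parent2"],
                         table.data["gebv"]):
        sums[p1] += g
        sums[p2] += g
    out = pd.Series({l: s / (n - 1) for l, s in sums.items()}, name="gca")
    return out.sort_values(ascending=False)


def heterotic_summary(
    table: CrossTable,
    groups: dict[str, str],
    top_fractions: tuple[float, ...] = (0.05, 0.10),
) -> HeteroticSummary:
    """Group-pair category means and top-fraction composition.

    With k germplasm groups there are k(k+1)/2 unordered pair categories
    (within-group pairs included). For each requested top fraction the
    summary reports each category's share of the top set and, per single
    group, the share of top crosses with at least one parent in it.
    """
    missing = [p for p in table.parents if p not in groups]
    if missing:
        raise DiallelError(f"unlabeled parents: {missing[:5]}")

    def category(p1: str, p2: str) -> str:
        a, b = sorted((groups[p1], groups[p2]))
        return f"{a} x {b}"

    d = table.data.copy()
    d["category"] = [category(a, b) for a, b in zip(d["parent1"], d["parent2"])]
    cats = (d.groupby("category")["gebv"]
            .agg(count="count", mean_gebv="mean", sd_gebv=lambda x: x.std(ddof=1))
            .reset_index()
            .sort_values("mean_gebv", ascending=False)
            .reset_index(drop=True))
    if int(cats["count"].sum()) != len(d):
        raise DiallelError("category counts do not conserve the total")

    group_labels = sorted(set(groups[p] for p in table.parents))
    top_comp: dict[float, pd.DataFrame] = {}
    involvement: dict[float, dict[str, float]] = {}
    for f in top_fractions:
        top = top_fraction(table, f).data
        topcat = [category(a, b) for a, b in zip(top["parent1"], top["parent2"])]
        counts = pd.Series(topcat).value_counts()
        comp = pd.DataFrame({
            "category": counts.index,
            "count": counts.to_numpy(),
            "share": counts.to_numpy() / len(top),
        })
        top_comp[f] = comp.reset_index(drop=True)
        inv = {}
        for glab in group_labels:
            has = [(groups[a] == glab or groups[b] == glab)
                   for a, b in zip(top["parent1"], top["parent2"])]
            inv[glab] = float(np.mean(has))
        involvement[f] = inv
    return HeteroticSummary(
        categories=cats,
        overall_mean=float(d["gebv"].mean()),
        top_composition=top_comp,
        group_involvement=involvement,
        n_crosses=len(d),
    )
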