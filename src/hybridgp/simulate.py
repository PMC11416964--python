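"""Synthetic breeding population with ground truth.

Emulates the study design the package targets: a panel of fully inbred
founder lines structured into germplasm groups, an additive QTL architecture,
in-silico F1 hybrids, and hybrid phenotypes at a controlled heritability with
optional group-pair ("heterotic") mean shifts.

Group structure follows the Balding-Nichols model: each marker has an
ancestral allele frequency p ~ U(0.1, 0.9), and each group draws its own
frequency from Beta with mean p and variance F * p * (1 - p), F being the
differentiation parameter. Inbred lines are homozygous, so dosages are 0 or 2
before missingness. True QTL effects are scaled so the genetic-value variance
across founder lines is 1, which makes the target heritability control the
noise variance exactly and keeps downstream tolerances scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    HybridGenotypeMatrix,
    PhenotypeTable,
    canonical_cross,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 3 germplasm groups of 50 inbred lines, 2000
    markers at moderate differentiation (F = 0.2, enough for 3 separable
    clusters), 200 additive QTL, heritability 0.8, 2% missing calls."""

    n_lines_per_group: dict[str, int] = field(
        default_factory=lambda: {"temperate": 50, "temp_tropic": 50, "tropic": 50})
    n_markers: int = 2000
    divergence_f: float = 0.2
    n_qtl: int = 200
    h2_target: float = 0.8
    group_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_lines_per_group:
            raise SimulationError("need at least one group")
        for g, n in self.n_lines_per_group.items():
            if n <= 0:
                raise SimulationError(f"group {g!r} has {n} lines")
        if self.n_markers <= 0:
            raise SimulationError("n_markers must be positive")
        if not (0 < self.n_qtl <= self.n_markers):
            raise SimulationError("need 0 < n_qtl <= n_markers")
        if not (0.0 <= self.h2_target <= 1.0):
            raise SimulationError("h2_target must lie in [0, 1]")
        if not (0.0 < self.divergence_f < 1.0):
            raise SimulationError("divergence_f must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must lie in [0, 1)")
        labels = sorted(self.n_lines_per_group)
        valid = {tuple(sorted(p)) for p in
                 [(a, b) for i, a in enumerate(labels) for b in labels[i:]]}
        self.group_shift = {tuple(sorted(k)): v for k, v in self.group_shift.items()}
        for pair in self.group_shift:
            if pair not in valid:
                raise SimulationError(f"group_shift names unknown pair {pair}")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    group_of_line: dict[str, str]
    true_genetic_values: dict[str, float] = field(default_factory=dict)
    realized_h2: float | None = None
    degenerate_scaling: bool = False

    def __post_init__(self) -> None:
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise SimulationError("qtl index/effect length mismatch")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "qtl_indices": np.asarray(self.qtl_indices).tolist(),
            "qtl_effects": np.asarray(self.qtl_effects).tolist(),
            "group_of_line": self.group_of_line,
            "true_genetic_values": self.true_genetic_values,
            "realized_h2": self.realized_h2,
            "degenerate_scaling": self.degenerate_scaling,
        }, indent=2))


def simulate_founders(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw the inbred founder panel under the Balding-Nichols model."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    F = config.divergence_f
    p_anc = rng.uniform(0.1, 0.9, size=m)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F

    line_ids: list[str] = []
    group_of_line: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for group in sorted(config.n_lines_per_group):
        n_g = config.n_lines_per_group[group]
        p_g = rng.beta(a, b)
        # fully inbred: one allele draw per line per marker, dosage 0 or 2
        dos = 2.0 * (rng.random((n_g, m)) < p_g[None, :])
        rows.append(dos)
        for i in range(n_g):
            lid = f"{group}_{i:03d}"
            line_ids.append(lid)
            group_of_line[lid] = group
    D = np.vstack(rows)
    if config.missing_rate > 0:
        D[rng.random(D.shape) < config.missing_rate] = np.nan

    g = GenotypeMatrix(
        line_ids=line_ids,
        marker_ids=[f"snp{j:05d}" for j in range(m)],
        dosages=D,
        chrom=["1"] * m,
        pos=np.arange(1, m + 1) * 100,
        ref=["A"] * m,
        alt=["T"] * m,
    )
    truth = TruthRecord(qtl_indices=np.array([], dtype=int),
                        qtl_effects=np.array([]),
                        group_of_line=group_of_line)
    return g, truth


def simulate_qtl_effects(genotypes: GenotypeMatrix, n_qtl: int,
                         seed: int) -> TruthRecord:
    """Sample QTL positions and effects; scale to unit genetic variance.

    Missing dosages are imputed by the marker mean for the genetic value, so
    every line gets a defined true value. If the founder panel carries no
    genetic variation the scaling is degenerate and flagged as such.
    """
    if not (0 < n_qtl <= genotypes.n_markers):
        raise SimulationError("need 0 < n_qtl <= n_markers")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(genotypes.n_markers, size=n_qtl, replace=False))
    eff = rng.standard_normal(n_qtl)

    D = genotypes.dosages[:, idx]
    obs = ~np.isnan(D)
    col_means = np.nansum(D, axis=0) / np.maximum(obs.sum(axis=0), 1)
    Dimp = np.where(obs, D, col_means[None, :])
    g_vals = Dimp @ eff
    sd = g_vals.std(ddof=1)
    degenerate = sd == 0
    if not degenerate:
        eff = eff / sd
        g_vals = g_vals / sd
    truth = TruthRecord(
        qtl_indices=idx, qtl_effects=eff,
        group_of_line={}, degenerate_scaling=bool(degenerate))
    truth.true_genetic_values = dict(zip(genotypes.line_ids, g_vals))
    return truth


def genetic_values_of_hybrids(hybrids: HybridGenotypeMatrix,
                              truth: TruthRecord) -> np.ndarray:
    D = hybrids.dosages[:, truth.qtl_indices]
    obs = ~np.isnan(D)
    col_means = np.nansum(D, axis=0) / np.maximum(obs.sum(axis=0), 1)
    Dimp = np.where(obs, D, col_means[None, :])
    return Dimp @ truth.qtl_effects


def simulate_hybrid_phenotypes(
    hybrids: HybridGenotypeMatrix,
    truth: TruthRecord,
    h2_target: float,
    group_shift: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Phenotype = hybrid genetic value + group-pair shift + Gaussian noise.

    Noise variance is var(genetic values) * (1 - h2) / h2 so the expected
    heritability among these hybrids equals ``h2_target``; at h2 = 1 the
    phenotype is the genetic value exactly (plus any shift).
    """
    if hybrids.n_hybrids == 0:
        raise SimulationError("empty hybrid set")
    if h2_target <= 0 or h2_target > 1:
        raise SimulationError("h2_target must lie in (0, 1]")
    group_shift = {tuple(sorted(k)): v for k, v in (group_shift or {}).items()}
    g_vals = genetic_values_of_hybrids(hybrids, truth)

    shifts = np.zeros(hybrids.n_hybrids)
    if group_shift:
        for k, (p1, p2) in enumerate(hybrids.parents):
            try:
                pair = tuple(sorted((truth.group_of_line[p1],
                                     truth.group_of_line[p2])))
            except KeyError as exc:
                raise SimulationError(f"no group label for parent {exc}") from exc
            shifts[k] = group_shift.get(pair, 0.0)

    rng = np.random.default_rng(seed)
    var_g = g_vals.var(ddof=1)
    sigma_e = np.sqrt(var_g * (1.0 - h2_target) / h2_target)
    noise = rng.standard_normal(hybrids.n_hybrids) * sigma_e
    pheno = g_vals + shifts + noise

    truth.true_genetic_values.update(dict(zip(hybrids.hybrid_ids, g_vals)))
    if pheno.std(ddof=1) > 0 and g_vals.std(ddof=1) > 0:
        truth.realized_h2 = float(np.corrcoef(pheno, g_vals)[0, 1] ** 2)

    df = pd.DataFrame({
        "hybrid_id": hybrids.hybrid_ids,
        "parent1": [p[0] for p in hybrids.parents],
        "parent2": [p[1] for p in hybrids.parents],
        trait_name: pheno,
    })
    return PhenotypeTable(df)


def sample_crosses(line_ids: list[str], n_crosses: int,
                   seed: int) -> list[tuple[str, str]]:
    """Random distinct unordered crosses, mirroring a sparse sample of the
    half-diallel (the study phenotypes only a fraction of possible crosses)."""
    rng = np.random.default_rng(seed)
    n = len(line_ids)
    total = n * (n - 1) // 2
    if n_crosses > total:
        raise SimulationError(f"requested {n_crosses} crosses from {total} possible")
    flat = rng.choice(total, size=n_crosses, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    return [canonical_cross(line_ids[iu[f]], line_ids[ju[f]]) for f in np.sort(flat)]
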