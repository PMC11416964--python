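"""End-to-end demo pipeline on synthetic data.

Mirrors the full breeding-analysis workflow: simulate a structured founder
panel, filter markers, construct and phenotype a sample of hybrids, estimate
SNP heritability (HE and REML), evaluate the prediction methods on repeated
train/candidate splits, fit the HE-based BLUP on all phenotyped hybrids,
predict the complete half-diallel, and derive GCA rankings, heterotic-pattern
summaries, and the germplasm tree/grouping. Every artifact lands in an output
directory with a manifest recording seeds and content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diallel, evaluate, phylo, relatedness, simulate
from .genotypes import (
    filter_hybrid_markers,
    impute_missing,
    make_hybrid_genotypes,
    write_genotypes,
)
from .models import HEBLUPAdditive

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Demo-scale defaults that keep the protocol shape of the target study:
    10 replications, top 5%/10% selections, HE-based BLUP for the exhaustive
    cross prediction, and the 0.3 / 0.1 marker-retention thresholds."""

    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    n_phenotyped_hybrids: int = 1000
    max_missing: float = 0.3
    min_rare_allele: float = 0.1
    n_train: int = 800
    n_replicates: int = 10
    methods: tuple[str, ...] = ("rrblup", "heblp_a", "rf", "gbm")
    top_fractions: tuple[float, ...] = (0.05, 0.10)
    k_groups: int = 3
    seed: int = 0


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the whole pipeline; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}

    def emit(name: str, writer) -> None:
        path = out / name
        _atomic_write(path, writer)
        manifest["outputs"][name] = _sha256(path)

    # 1. simulate founders + QTL + hybrids + phenotypes
    logger.info("stage: simulate")
    founders, truth = simulate.simulate_founders(config.sim)
    crosses = simulate.sample_crosses(founders.line_ids,
                                      config.n_phenotyped_hybrids,
                                      seed=config.seed + 2)

    # 2. filter markers on the parental matrix, then build hybrids
    logger.info("stage: filter")
    filtered, report = filter_hybrid_markers(
        founders, max_missing=config.max_missing,
        min_rare_allele=config.min_rare_allele)
    qtl_kept = simulate.simulate_qtl_effects(filtered, min(config.sim.n_qtl,
                                             filtered.n_markers),
                                             seed=config.seed + 1)
    qtl_kept.group_of_line = truth.group_of_line
    hybrids = make_hybrid_genotypes(filtered, crosses)
    phenos = simulate.simulate_hybrid_phenotypes(
        hybrids, qtl_kept, config.sim.h2_target,
        group_shift=config.sim.group_shift, seed=config.seed + 3)
    emit("founders.vcf", lambda p: write_genotypes(filtered, p, format="vcf"))
    emit("founders.dosages.tsv", lambda p: write_genotypes(filtered, p, format="tsv"))
    emit("phenotypes.csv", phenos.to_csv)
    emit("filter_report.json", report.to_json)
    emit("truth.json", qtl_kept.to_json)

    hyb_imp = impute_missing(hybrids)
    parents_imp = impute_missing(filtered)
    trait = phenos.traits[0]
    y = phenos.data[trait].to_numpy()

    # 3. heritability, both routes
    logger.info("stage: heritability")
    grm = relatedness.compute_grm(hyb_imp)
    ibs = relatedness.compute_ibs(hybrids)
    he = relatedness.he_regression(ibs, y)
    reml = relatedness.reml_heritability(grm, y)
    emit("heritability_he.json", he.to_json)
    emit("heritability_reml.json", reml.to_json)

    # 4. method evaluation on shared splits
    logger.info("stage: evaluate")
    acc = evaluate.evaluate_methods(
        hyb_imp.dosages, hyb_imp.hybrid_ids, phenos.data, [trait],
        list(config.methods), n_train=config.n_train,
        n_replicates=config.n_replicates, seed=config.seed + 4)
    emit("accuracy_replicates.csv",
         lambda p: acc.records.to_csv(p, index=False))
    emit("accuracy_summary.csv",
         lambda p: acc.summary().to_csv(p, index=False))

    # 5. fit on all phenotyped hybrids, predict the whole half-diallel
    logger.info("stage: cross prediction")
    model = HEBLUPAdditive(y, hyb_imp, ibs=ibs).fit()
    table = diallel.predict_all_crosses(model, parents_imp, trait=trait)
    emit("crosses.csv", table.to_csv)
    gains = {f: diallel.genetic_gain(table, f) for f in config.top_fractions}
    gca_series = diallel.gca(table)
    emit("gca.csv", lambda p: gca_series.to_csv(p, index_label="line_id"))

    summary = diallel.heterotic_summary(table, truth.group_of_line,
                                        top_fractions=config.top_fractions)
    emit("heterotic_summary.json", summary.to_json)

    # 6. tree and groups from the parental p-distances
    logger.info("stage: tree/groups")
    dmat = phylo.p_distance_matrix(filtered)
    emit("distances.tsv", dmat.to_tsv)
    tree = phylo.nj_tree(dmat)
    emit("tree.nwk", lambda p: phylo.write_newick(tree, p))
    groups = phylo.assign_groups(dmat, config.k_groups)
    emit("groups.tsv", groups.to_tsv)

    manifest["stages"] = ["simulate", "filter", "heritability", "evaluate",
                          "cross_prediction", "tree_groups"]
    manifest["config"] = {
        "sim": {**asdict(config.sim),
                "group_shift": {" x ".join(k): v
                                for k, v in config.sim.group_shift.items()}},
        "n_phenotyped_hybrids": config.n_phenotyped_hybrids,
        "n_train": config.n_train,
        "n_replicates": config.n_replicates,
        "methods": list(config.methods),
        "top_fractions": list(config.top_fractions),
        "k_groups": config.k_groups,
        "seed": config.seed,
    }
    manifest["results"] = {
        "h2_he": he.h2,
        "h2_reml": reml.h2,
        "n_markers_kept": report.n_kept,
        "n_crosses": len(table),
        "overall_mean_gebv": summary.overall_mean,
        "genetic_gain": {str(f): g for f, g in gains.items()},
        "accuracy": {
            f"{row.trait}:{row.method}": row.mean_r
            for row in acc.summary().itertuples()},
    }
    _atomic_write(out / "manifest.json",
                  lambda p: p.write_text(json.dumps(manifest, indent=2)))
    manifest["outputs"]["manifest.json"] = None
    return manifest
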