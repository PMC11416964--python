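# hybridgp

Genomic prediction and heterotic-pattern analysis for hybrid breeding
programs that cross a panel of inbred parent lines — the setting of maize
single-cross breeding, where a few thousand phenotyped F1 hybrids must stand
in for tens of thousands of possible crosses.

`hybridgp` covers the whole desk-side workflow:

* read inbred genotypes (VCF or dosage TSV), apply locus-retention filters,
  and build in-silico F1 genotypes as parental dosage means;
* estimate SNP heritability, h² = σ²g / (σ²g + σ²e), by Haseman–Elston (HE)
  regression on IBS similarity and by single-component REML on the VanRaden
  genomic relationship matrix (GRM);
* fit genomic prediction models and score any genotype:
  ridge-regression BLUP (rrBLUP), the HE-based BLUP variant (HEBLP|A), and
  random-forest / gradient-boosted-tree baselines;
* evaluate accuracy with repeated random train/candidate splits (Pearson r
  between observed phenotypes and predictions, mean ± s.e.);
* enumerate the complete half-diallel — N(N−1)/2 crosses for N parents —
  predict every cross's GEBV, rank them, and derive genetic gain of top
  fractions, per-line GCA (mean GEBV over a line's N−1 crosses), and
  heterotic-pattern summaries over germplasm-group pairs;
* build a neighbor-joining tree from SNP p-distances and assign lines to
  germplasm groups;
* simulate a full synthetic breeding population (Balding–Nichols group
  structure, additive QTL, controlled h², planted group-pair shifts) with
  complete ground truth.

## The model

All parametric predictions come from one linear mixed model,

    y = μ + Z u + e,    u ~ N(0, I σ²u),    e ~ N(0, I σ²e),

with y the training-hybrid phenotypes and Z their marker dosages. The BLUP
of the marker effects is computed through the n×n dual system

    û = Zᵀ (Z Zᵀ + λ I)⁻¹ (y − μ̂),    λ = σ²e / σ²u,

and a candidate's GEBV is μ̂ + (z − z̄)·û. rrBLUP obtains λ from REML on the
training kinship (or a 10-fold cross-validated grid); HEBLP|A takes σ²u from
IBS-based HE regression and sets λ = (1 − σ²u) / σ²u on the unit-variance
scale. The two share the solver, so they differ only through λ.

## Worked example

```python
import hybridgp as hg

# a synthetic breeding program: 3 germplasm groups x 50 inbreds, 2000 SNPs,
# 1000 phenotyped hybrids at h2 = 0.8, tropic germplasm boosted
cfg = hg.PipelineConfig(
    sim=hg.SimulationConfig(
        group_shift={("tropic", "tropic"): 1.0,
                     ("temp_tropic", "tropic"): 0.5,
                     ("temperate", "tropic"): 0.5},
        seed=11),
    n_replicates=2, methods=("rrblup", "heblp_a"), seed=11)
manifest = hg.run_demo(cfg, "demo_out")
print(manifest["results"])
```

prints (numbers from this exact run):

```
{'h2_he': 1.0, 'h2_reml': 0.8083, 'n_markers_kept': 1787,
 'n_crosses': 11175, 'overall_mean_gebv': 0.8911,
 'genetic_gain': {'0.05': 1.9327, '0.1': 1.6340},
 'accuracy': {'trait:heblp_a': 0.8478, 'trait:rrblup': 0.8723}}
```

Reading: REML recovers the simulated heritability (0.81 vs the 0.8 target;
the HE estimate hits its upper clamp because the planted group bonus adds
marker-associated variance), the filters keep 1787/2000 loci, all
150·149/2 = 11,175 crosses are scored, selecting the top 10% of crosses
would raise mean GEBV by ≈1.6 genetic standard deviations, and both
parametric methods predict held-out hybrids at r ≈ 0.85–0.87, near the
√h² ≈ 0.89 ceiling. The output
directory additionally holds the cross table, GCA ranking, heterotic
summary, NJ tree and group assignment, each with a manifest hash.

The same stages are available as a CLI:
`hybridgp simulate | filter | heritability | evaluate | fit |
predict-crosses | gca | summarize | tree | groups | demo`.

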