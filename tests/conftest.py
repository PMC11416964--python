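import numpy as np
import pytest

import hybridgp as hg


@pytest.fixture(scope="session")
def small_population():
    """3-group founder panel with 500 phenotyped hybrids at h2=0.5."""
    cfg = hg.SimulationConfig(
        n_lines_per_group={"a": 40, "b": 40, "c": 40},
        n_markers=1000, divergence_f=0.2, n_qtl=100,
        h2_target=0.5, missing_rate=0.02, seed=101)
    founders, truth = hg.simulate_founders(cfg)
    filtered, report = hg.filter_hybrid_markers(founders)
    qtl = hg.simulate_qtl_effects(filtered, 100, seed=102)
    qtl.group_of_line = truth.group_of_line
    crosses = hg.sample_crosses(filtered.line_ids, 500, seed=103)
    hybrids = hg.make_hybrid_genotypes(filtered, crosses)
    pheno = hg.simulate_hybrid_phenotypes(hybrids, qtl, 0.5, seed=104)
    return {
        "config": cfg, "founders": founders, "filtered": filtered,
        "report": report, "truth": qtl, "hybrids": hybrids, "pheno": pheno,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dosages(rng, n, m, maf_low=0.1):
    p = rng.uniform(maf_low, 1 - maf_low, size=m)
    return rng.binomial(2, p, size=(n, m)).astype(float)
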