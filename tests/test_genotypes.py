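import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import hybridgp as hg
from hybridgp.genotypes import GenotypeError, canonical_cross

from conftest import random_dosages


def make_matrix(dosages, **kw):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return hg.GenotypeMatrix([f"L{i}" for i in range(n)],
                             [f"M{j}" for j in range(m)], dosages, **kw)


class TestVcfIO:
    def test_gt_coding_convention(self, tmp_path):
        """0/0, 0/1, 1/1 and ./. map to dosages 0, 1, 2 and missing."""
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\n"
            "1\t100\tsnp1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.\n")
        g = hg.read_genotypes(vcf)
        np.testing.assert_array_equal(
            g.dosages[:, 0], [0.0, 1.0, 2.0, np.nan])

    def test_hand_written_vcf_transcription(self, tmp_path):
        """3 samples x 2 sites transcribed by hand."""
        vcf = tmp_path / "hand.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "2\t10\ts1\tG\tC\t.\t.\t.\tGT\t1/1\t0/0\t0/1\n"
            "2\t20\ts2\tG\tA\t.\t.\t.\tGT\t0/0\t./.\t1/1\n")
        g = hg.read_genotypes(vcf)
        assert g.line_ids == ["A", "B", "C"]
        assert g.marker_ids == ["s1", "s2"]
        expected = np.array([[2.0, 0.0], [0.0, np.nan], [1.0, 2.0]])
        np.testing.assert_array_equal(g.dosages, expected)
        assert g.chrom == ["2", "2"]
        np.testing.assert_array_equal(g.pos, [10, 20])

    @pytest.mark.parametrize("format", ["vcf", "tsv"])
    def test_round_trip_identity(self, tmp_path, rng, format):
        D = random_dosages(rng, 10, 50)
        D[rng.random(D.shape) < 0.1] = np.nan
        g = make_matrix(D)
        path = tmp_path / f"rt.{format}"
        hg.write_genotypes(g, path, format=format)
        back = hg.read_genotypes(path, format=format)
        assert back.line_ids == g.line_ids
        assert back.marker_ids == g.marker_ids
        np.testing.assert_array_equal(back.dosages, g.dosages)

    def test_multiallelic_records_skipped(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t1\tbi\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\n"
            "1\t2\ttri\tA\tT,C\t.\t.\t.\tGT\t0/0\t1/2\n")
        g = hg.read_genotypes(vcf)
        assert g.marker_ids == ["bi"]
        assert g.n_multiallelic_skipped == 1

    def test_duplicate_line_id_rejected(self):
        with pytest.raises(GenotypeError, match="duplicate"):
            hg.GenotypeMatrix(["A", "A"], ["m"], np.zeros((2, 1)))


class TestFilter:
    def test_three_criteria_toy(self):
        """Manual application of the retention rules on 10 lines."""
        col_mono = [0.0] * 10                      # dropped by (a)
        col_missing = [0, 2, 2, 0, 2, 0] + [np.nan] * 4   # 0.4 missing -> (b)
        col_rare = [1.0] + [0.0] * 9               # MAF 0.05 -> (c)
        col_keep = [0.0] * 5 + [2.0] * 5           # kept
        g = make_matrix(np.column_stack([col_mono, col_missing, col_rare, col_keep]))
        kept, rep = hg.filter_hybrid_markers(g)
        assert rep.n_kept == 1
        assert kept.marker_ids == ["M3"]
        assert rep.dropped_monomorphic == 1
        assert rep.dropped_missing == 1
        assert rep.dropped_rare_allele == 1
        assert rep.n_input_markers == rep.n_kept + 3

    def test_monomorphic_but_for_missing(self):
        g = make_matrix(np.array([[2.0], [2.0], [np.nan], [2.0]] * 3))
        _, rep = hg.filter_hybrid_markers(g)
        assert rep.dropped_monomorphic == 1 and rep.n_kept == 0

    def test_idempotence(self, small_population):
        filtered = small_population["filtered"]
        again, rep = hg.filter_hybrid_markers(filtered)
        assert rep.n_kept == filtered.n_markers
        np.testing.assert_array_equal(again.dosages, filtered.dosages)

    def test_accounting_identity_random_pathologies(self, rng):
        D = random_dosages(rng, 30, 200)
        D[:, :20] = 0.0                       # monomorphic
        D[rng.random(D.shape) < 0.15] = np.nan
        _, rep = hg.filter_hybrid_markers(make_matrix(D))
        assert rep.n_input_markers == (rep.n_kept + rep.dropped_monomorphic
                                       + rep.dropped_missing + rep.dropped_rare_allele)
        assert len(rep.kept_marker_ids) == rep.n_kept


class TestHybrids:
    def test_mendelian_rules(self):
        """0x2 -> 1; 2x2 -> 2; 0 x missing -> missing."""
        g = make_matrix([[0.0, 2.0, 0.0], [2.0, 2.0, np.nan]])
        hyb = hg.make_hybrid_genotypes(g, [("L0", "L1")])
        np.testing.assert_array_equal(hyb.dosages[0], [1.0, 2.0, np.nan])

    def test_symmetry_and_canonical_id(self):
        g = make_matrix([[0.0, 2.0], [2.0, 0.0]])
        ab = hg.make_hybrid_genotypes(g, [("L0", "L1")])
        ba = hg.make_hybrid_genotypes(g, [("L1", "L0")])
        assert ab.hybrid_ids == ba.hybrid_ids == ["L0xL1"]
        np.testing.assert_array_equal(ab.dosages, ba.dosages)

    def test_self_cross_and_unknown_parent_rejected(self):
        g = make_matrix([[0.0], [2.0]])
        with pytest.raises(GenotypeError, match="self-cross"):
            hg.make_hybrid_genotypes(g, [("L0", "L0")])
        with pytest.raises(GenotypeError, match="unknown parent"):
            hg.make_hybrid_genotypes(g, [("L0", "Lx")])

    def test_filter_commutes_with_crossing(self, rng):
        """Filter-then-cross equals cross-then-subset on kept markers."""
        D = random_dosages(rng, 12, 80)
        D[rng.random(D.shape) < 0.2] = np.nan
        D[:, :5] = 2.0
        g = make_matrix(D)
        kept, rep = hg.filter_hybrid_markers(g)
        crosses = [("L0", "L1"), ("L2", "L7"), ("L3", "L11")]
        h1 = hg.make_hybrid_genotypes(kept, crosses)
        h_full = hg.make_hybrid_genotypes(g, crosses)
        keep_idx = [g.marker_ids.index(m) for m in rep.kept_marker_ids]
        np.testing.assert_array_equal(h1.dosages, h_full.dosages[:, keep_idx])


class TestImpute:
    def test_marker_mean_fill(self):
        g = make_matrix([[0.0], [2.0], [np.nan]])
        out = hg.impute_missing(g)
        np.testing.assert_array_equal(out.dosages[:, 0], [0.0, 2.0, 1.0])

    def test_no_missing_is_identity(self, rng):
        g = make_matrix(random_dosages(rng, 8, 20))
        np.testing.assert_array_equal(hg.impute_missing(g).dosages, g.dosages)

    def test_column_means_preserved(self, rng):
        D = random_dosages(rng, 20, 30)
        D[rng.random(D.shape) < 0.25] = np.nan
        D[0] = 1.0  # guarantee one observed call per marker
        g = make_matrix(D)
        out = hg.impute_missing(g)
        np.testing.assert_allclose(out.dosages.mean(axis=0),
                                   np.nanmean(D, axis=0), atol=1e-12)

    def test_fully_missing_marker_errors(self):
        g = make_matrix([[np.nan], [np.nan]])
        with pytest.raises(GenotypeError, match="filter"):
            hg.impute_missing(g)


def test_canonical_cross_ordering():
    assert canonical_cross("B", "A") == ("A", "B") == canonical_cross("A", "B")


@settings(derandomize=True, max_examples=30, deadline=None)
@given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                               min_side=3, max_side=12),
                  elements=st.sampled_from([0.0, 1.0, 2.0, np.nan])))
def test_filter_accounting_identity_holds_for_any_matrix(D):
    """n_input = n_kept + sum of per-criterion drops, for arbitrary
    dosage/missingness patterns."""
    g = make_matrix(D)
    kept, rep = hg.filter_hybrid_markers(g)
    assert rep.n_input_markers == (rep.n_kept + rep.dropped_monomorphic
                                   + rep.dropped_missing
                                   + rep.dropped_rare_allele)
    assert kept.n_markers == rep.n_kept
    # filtering is idempotent whenever anything survives
    if rep.n_kept:
        again, rep2 = hg.filter_hybrid_markers(kept)
        assert rep2.n_kept == rep.n_kept
        np.testing.assert_array_equal(again.dosages, kept.dosages)
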