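import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    bruteforce_allele_snps,
    bruteforce_diversity,
    bruteforce_genotype,
)
from polyweave import snpcall
from polyweave.snpcall import (
    call_allele_snps,
    call_homoeo_snps,
    consensus_allele,
    diversity,
    genotype_from_counts,
)


def _counts(*cols):
    """(4, L) count matrix from per-site [A, C, G, T] lists."""
    return np.array(cols, dtype=np.int32).T


class TestPileupGenotype:
    def test_unanimous_call(self):
        calls = genotype_from_counts(_counts([0, 6, 0, 0]))
        assert calls[0] == "C"

    def test_four_reads_fail_min_allele_cov(self):
        calls = genotype_from_counts(_counts([0, 4, 0, 0]))
        assert calls[0] == "."

    def test_het_when_both_thresholds_met(self):
        # 10xC + 5xT: 5 >= 5 reads and 5/15 = 33% >= 30%
        calls = genotype_from_counts(_counts([0, 10, 0, 5]))
        assert calls[0] == "C/T"

    def test_minor_allele_below_frequency_dropped(self):
        # 20xC + 5xT: 5/25 = 20% < 30% -> homozygous C
        calls = genotype_from_counts(_counts([0, 20, 0, 5]))
        assert calls[0] == "C"

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_caller(self, trial):
        rng = np.random.default_rng(200 + trial)
        counts = rng.integers(0, 12, size=(4, 50)).astype(np.int32)
        got = genotype_from_counts(counts, 5, 0.30)
        for i in range(50):
            assert got[i] == bruteforce_genotype(counts[:, i], 5, 0.30), i

    def test_raising_min_cov_never_adds_calls(self):
        rng = np.random.default_rng(33)
        counts = rng.integers(0, 12, size=(4, 200)).astype(np.int32)
        loose = genotype_from_counts(counts, 5, 0.30)
        strict = genotype_from_counts(counts, 8, 0.30)
        assert ((strict != ".") <= (loose != ".")).all()


def _matrix(values, accessions=None, sub="A"):
    values = np.asarray(values, dtype=object)
    n = values.shape[1]
    accessions = accessions or [f"acc{i}" for i in range(n)]
    cols = pd.MultiIndex.from_tuples([(a, sub) for a in accessions],
                                     names=["accession", "subgenome"])
    index = pd.MultiIndex.from_tuples(
        [("chr1", i) for i in range(values.shape[0])],
        names=["chrom", "pos"])
    return pd.DataFrame(values, index=index, columns=cols)


class TestAlleleSNPs:
    def test_boundary_maf_kept(self):
        m = _matrix([["C"] * 9 + ["T"]])
        recs = call_allele_snps(m, list(m.columns), maf_filter=0.10)
        assert len(recs) == 1 and recs[0].maf == pytest.approx(0.10)

    def test_below_maf_dropped(self):
        m = _matrix([["C"] * 19 + ["T"]])
        assert call_allele_snps(m, list(m.columns), 0.10) == []

    def test_monomorphic_not_a_snp(self):
        m = _matrix([["C"] * 5])
        assert call_allele_snps(m, list(m.columns), 0.10) == []

    def test_single_accession_group_is_an_error(self):
        m = _matrix([["C"]])
        with pytest.raises(ValueError):
            call_allele_snps(m, list(m.columns))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_filter(self, trial):
        rng = np.random.default_rng(300 + trial)
        values = rng.choice(["A", "C", "G", "T", ".", "C/T"],
                            size=(40, 8),
                            p=[0.2, 0.3, 0.2, 0.1, 0.15, 0.05])
        m = _matrix(values)
        got = call_allele_snps(m, list(m.columns), 0.10)
        want = bruteforce_allele_snps(values, 0.10)
        assert [(r.pos, round(r.maf, 9)) for r in got] == \
            [(i, round(maf, 9)) for i, maf in want]


class TestHomoeoSNPs:
    def test_majority_thresholds_met(self):
        a_calls = ["C"] * 10 + ["T"] * 3
        d_calls = ["T"] * 11 + ["C"] * 2
        m = pd.concat([
            _matrix([a_calls], [f"x{i}" for i in range(13)], "A"),
            _matrix([d_calls], [f"x{i}" for i in range(13)], "D"),
        ], axis=1)
        recs = call_homoeo_snps(m, [f"x{i}" for i in range(13)], 0.75)
        assert len(recs) == 1 and recs[0].alleles == ("C", "T")

    def test_concordant_subgenomes_not_called(self):
        m = pd.concat([
            _matrix([["C", "C"]], ["x0", "x1"], "A"),
            _matrix([["C", "C"]], ["x0", "x1"], "D"),
        ], axis=1)
        assert call_homoeo_snps(m, ["x0", "x1"]) == []

    def test_consensus_allele_single_observation_is_total(self):
        assert consensus_allele(np.array(["C"])) == "C"
        assert consensus_allele(np.array(["."])) is None

    def test_consensus_below_threshold_is_none(self):
        calls = np.array(["C"] * 7 + ["T"] * 3)
        assert consensus_allele(calls, 0.75) is None


class TestDiversity:
    def test_direct_ratio(self):
        # two accessions differing at 2 of 4 co-covered polymorphic sites
        m = _matrix([["C", "T"], ["C", "G"], ["A", "A"], ["T", "T"],
                     ["C", "C"]])
        # rows 0,1 differ; rows 2,3,4 equal; polymorphic rows: 0,1 only
        assert diversity(m, list(m.columns)) == pytest.approx(1.0)

    def test_identical_accessions_zero(self):
        m = _matrix([["C", "C"], ["T", "T"]])
        assert diversity(m, list(m.columns)) == 0.0

    def test_uniform_group_with_missing_data_is_zero(self):
        # no within-group polymorphism at all -> diversity 0 by definition
        # (a polymorphic site always carries its own co-covered pair, so
        # the undefined case reduces to the uniform group)
        m = _matrix([["C", "."], [".", "T"]])
        assert diversity(m, list(m.columns)) == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_recount(self, trial):
        rng = np.random.default_rng(400 + trial)
        values = rng.choice(["A", "C", "G", "T", "."], size=(30, 5),
                            p=[0.25, 0.25, 0.2, 0.15, 0.15])
        m = _matrix(values)
        got = diversity(m, list(m.columns))
        want = bruteforce_diversity(values)
        assert got == pytest.approx(want)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_in_unit_interval_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.choice(["A", "C", "G", "T", "."], size=(20, 4))
        m = _matrix(values)
        cols = list(m.columns)
        try:
            d1 = diversity(m, cols)
        except ValueError:
            return
        if np.isnan(d1):
            return
        assert 0.0 <= d1 <= 1.0
        d2 = diversity(m, cols[::-1])
        assert d1 == pytest.approx(d2)
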