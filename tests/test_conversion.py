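import numpy as np
import pandas as pd
import pytest

from polyweave.cnv import CNVSegment
from polyweave.conversion import (
    ANCIENT,
    LIKELY,
    OUTGROUP_MISSING,
    ConversionSite,
    classify_conversion_site,
    cnv_overlap_scan,
    find_conversion_runs,
    outgroup_filter,
    scan_conversion_sites,
    species_consensus,
)
from polyweave.simgenome import (
    ConversionSpec,
    SimConfig,
    simulate_polyploid_panel,
    simulate_progenitors,
    truth_genotype_matrix,
)


def _matrix(rows_by_sub, accessions):
    """rows_by_sub: {"A": [row, ...], "D": [...]}, each row a call list."""
    frames = []
    for sub, rows in rows_by_sub.items():
        values = np.asarray(rows, dtype=object)
        cols = pd.MultiIndex.from_tuples([(a, sub) for a in accessions])
        idx = pd.MultiIndex.from_tuples(
            [("chr1", i) for i in range(values.shape[0])],
            names=["chrom", "pos"])
        frames.append(pd.DataFrame(values, index=idx, columns=cols))
    return pd.concat(frames, axis=1)


class TestSpeciesConsensus:
    def test_ten_of_thirteen_covered_and_agreeing(self):
        row = ["C"] * 10 + ["."] * 3
        m = _matrix({"A": [row]}, [f"x{i}" for i in range(13)])
        cons = species_consensus(m, [f"x{i}" for i in range(13)])
        assert cons["A"].iloc[0] == "C"

    def test_nine_of_thirteen_covered_is_missing(self):
        row = ["C"] * 9 + ["."] * 4
        m = _matrix({"A": [row]}, [f"x{i}" for i in range(13)])
        cons = species_consensus(m, [f"x{i}" for i in range(13)])
        assert cons["A"].iloc[0] == "."

    def test_seventy_percent_agreement_is_missing(self):
        row = ["C"] * 7 + ["T"] * 3
        m = _matrix({"A": [row]}, [f"x{i}" for i in range(10)])
        cons = species_consensus(m, [f"x{i}" for i in range(10)])
        assert cons["A"].iloc[0] == "."


class TestClassify:
    @pytest.mark.parametrize("a2,d5,at,dt,want", [
        ("C", "T", "C", "C", "A-dominant"),
        ("C", "T", "T", "T", "D-dominant"),
        ("C", "C", "C", "C", None),      # no divergence
        ("C", "T", "C", "T", None),      # normal homoeo-SNP
        ("C", "T", "G", "G", None),      # third allele
        (".", "T", "C", "C", None),      # missing input
    ])
    def test_pattern_table(self, a2, d5, at, dt, want):
        assert classify_conversion_site(a2, d5, at, dt) == want


def _dip(rows):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i) for i in range(len(rows))], names=["chrom", "pos"])
    return pd.DataFrame(rows, index=idx, columns=["A", "D"])


class TestOutgroupFilter:
    def _site(self, pos=0, direction="A-dominant"):
        return ConversionSite("chr1", pos, "AD1", direction)

    def test_same_pattern_in_outgroup_is_ancient(self):
        dip = _dip([["C", "T"]])
        out = _dip([["C", "C"]])  # outgroup also converted / autapomorphy
        got = outgroup_filter([self._site()], dip, out)
        assert got[0].outgroup_status == ANCIENT

    def test_outgroup_with_parental_alleles_is_likely(self):
        dip = _dip([["C", "T"]])
        out = _dip([["C", "T"]])  # AT=A2, DT=D5
        got = outgroup_filter([self._site()], dip, out)
        assert got[0].outgroup_status == LIKELY

    def test_missing_outgroup_is_flagged(self):
        dip = _dip([["C", "T"]])
        out = _dip([["C", "."]])
        got = outgroup_filter([self._site()], dip, out)
        assert got[0].outgroup_status == OUTGROUP_MISSING


class TestRuns:
    def _sites(self, specs):
        return [ConversionSite("chr1", p, "AD1", d, s) for p, d, s in specs]

    def test_minimal_run_of_two_adjacent_informative_sites(self):
        info = {"chr1": np.array([10, 20, 30, 40, 50, 60])}
        sites = self._sites([(50, "A-dominant", LIKELY),
                             (60, "A-dominant", LIKELY)])
        regions = find_conversion_runs(sites, info, min_run=2)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_sites) == (50, 61, 2)

    def test_intervening_informative_site_breaks_the_run(self):
        info = {"chr1": np.array([10, 20, 30])}
        sites = self._sites([(10, "A-dominant", LIKELY),
                             (30, "A-dominant", LIKELY)])
        assert find_conversion_runs(sites, info) == []

    def test_direction_switch_terminates(self):
        info = {"chr1": np.array([10, 20, 30, 40])}
        sites = self._sites([(10, "A-dominant", LIKELY),
                             (20, "D-dominant", LIKELY),
                             (30, "A-dominant", LIKELY)])
        assert find_conversion_runs(sites, info) == []

    def test_outgroup_missing_sites_never_join(self):
        info = {"chr1": np.array([10, 20])}
        sites = self._sites([(10, "A-dominant", LIKELY),
                             (20, "A-dominant", OUTGROUP_MISSING)])
        assert find_conversion_runs(sites, info) == []

    def test_long_run_with_gene_annotation(self):
        info = {"chr1": np.arange(10, 80, 10)}
        sites = self._sites([(p, "D-dominant", LIKELY)
                             for p in range(10, 80, 10)])
        ann = [("chr1", 0, 15, "geneA"), ("chr1", 200, 300, "geneB")]
        regions = find_conversion_runs(sites, info, annotation=ann)
        assert len(regions) == 1
        assert regions[0].n_sites == 7
        assert regions[0].genes == ["geneA"]


class TestCnvOverlap:
    def _seg(self, kind, start, end, genome, acc="x"):
        sign = 1.0 if kind == "duplication" else -4.0
        return CNVSegment("chr1", start, end, kind, sign, acc, genome)

    def test_reciprocal_dup_del_pair_is_a_candidate(self):
        segs_a = [self._seg("duplication", 1000, 6000, "A")]
        segs_d = [self._seg("deletion", 1200, 6100, "D")]
        cands = cnv_overlap_scan(segs_a, segs_d)
        assert len(cands) == 1
        assert cands[0].dup_genome == "A"

    def test_duplication_without_deletion_is_nothing(self):
        segs_a = [self._seg("duplication", 1000, 6000, "A")]
        assert cnv_overlap_scan(segs_a, []) == []

    def test_deletion_alone_is_nothing(self):
        segs_d = [self._seg("deletion", 1000, 6000, "D")]
        assert cnv_overlap_scan([], segs_d) == []

    def test_different_accessions_do_not_pair(self):
        segs_a = [self._seg("duplication", 1000, 6000, "A", acc="x")]
        segs_d = [self._seg("deletion", 1000, 6000, "D", acc="y")]
        assert cnv_overlap_scan(segs_a, segs_d) == []

    def test_homoeolog_map_shifts_coordinates(self):
        segs_a = [self._seg("duplication", 1000, 2000, "A")]
        segs_d = [self._seg("deletion", 11_000, 12_000, "D")]
        shift = lambda iv: (iv[0], iv[1] + 10_000, iv[2] + 10_000)
        assert cnv_overlap_scan(segs_a, segs_d) == []
        assert len(cnv_overlap_scan(segs_a, segs_d,
                                    homoeolog_map=shift)) == 1


class TestDirectionSymmetry:
    def test_swapping_progenitor_labels_swaps_directions(self):
        cfg = SimConfig(seed=55, genome_length=30_000,
                        branch_sub_prob=0.001,
                        conversion_tracts=(
                            ConversionSpec("AD1", "D", 1500, 2),
                            ConversionSpec("AD1", "A", 1500, 1),
                        ),
                        accessions=(("AD1", 2), ("AD4", 1)))
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        sites = {c: np.flatnonzero(truth.diploid_a[c] != truth.diploid_d[c])
                 for c in truth.diploid_a}
        m = truth_genotype_matrix(truth, sites)
        dip = _dip_from(m, ("A2", "A"), ("D5", "D"))
        ad1 = [a for a in truth.accessions if a.startswith("AD1")]
        focal = species_consensus(m, ad1)
        cand = scan_conversion_sites(dip, focal, "AD1")
        # swap: feed the diploids and the focal consensus mirrored
        dip_sw = dip.rename(columns={"A": "D", "D": "A"})[["A", "D"]]
        focal_sw = focal.rename(columns={"A": "D", "D": "A"})[["A", "D"]]
        cand_sw = scan_conversion_sites(dip_sw, focal_sw, "AD1")
        n = lambda cs, d: sum(1 for s in cs if s.direction == d)
        assert n(cand, "A-dominant") == n(cand_sw, "D-dominant")
        assert n(cand, "D-dominant") == n(cand_sw, "A-dominant")


def _dip_from(matrix, a_col, d_col):
    return pd.DataFrame({
        "A": matrix[a_col].to_numpy(),
        "D": matrix[d_col].to_numpy(),
    }, index=matrix.index)
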