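import numpy as np
import pytest
from scipy import stats

from polyweave import _seq
from polyweave.simgenome import (
    CNVSpec,
    ConversionSpec,
    IntrogressionSpec,
    SimConfig,
    SimulationError,
    simulate_polyploid_panel,
    simulate_progenitors,
    simulate_reads,
)


class TestProgenitors:
    def test_zero_divergence_yields_identical_genomes(self):
        cfg = SimConfig(seed=1, genome_length=5000,
                        progenitor_divergence=0.0)
        prog = simulate_progenitors(cfg)
        assert prog.n_divergence_sites() == 0
        np.testing.assert_array_equal(prog.genome_a["chr1"],
                                      prog.genome_d["chr1"])

    def test_divergence_count_matches_binomial_expectation(self):
        # closed form: with per-branch probability p on each of two
        # branches, a site differs with q = 2p(1-p) + (2/3)p^2
        L, p = 100_000, 0.005
        cfg = SimConfig(seed=7, genome_length=L,
                        progenitor_divergence=2 * p)
        prog = simulate_progenitors(cfg)
        q = 2 * p * (1 - p) + (2 / 3) * p * p
        mean, sd = L * q, np.sqrt(L * q * (1 - q))
        assert abs(prog.n_divergence_sites() - mean) < 3 * sd

    def test_same_seed_reproduces_byte_identical_genomes(self):
        cfg = SimConfig(seed=5, genome_length=3000)
        a = simulate_progenitors(cfg)
        b = simulate_progenitors(cfg)
        for chrom in a.ancestor:
            np.testing.assert_array_equal(a.genome_a[chrom],
                                          b.genome_a[chrom])
            np.testing.assert_array_equal(a.divergence_sites[chrom],
                                          b.divergence_sites[chrom])

    def test_divergence_sites_are_exact(self):
        cfg = SimConfig(seed=3, genome_length=5000)
        prog = simulate_progenitors(cfg)
        diff = np.flatnonzero(prog.genome_a["chr1"] != prog.genome_d["chr1"])
        np.testing.assert_array_equal(diff, prog.divergence_sites["chr1"])

    def test_too_short_genome_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(genome_length=10)


class TestPanel:
    def test_conversion_tract_copies_homoeolog_exactly(self):
        cfg = SimConfig(seed=11, genome_length=20_000,
                        conversion_tracts=(ConversionSpec("AD1", "D", 500),),
                        accessions=(("AD1", 1),))
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        ev = truth.events_of("conversion").iloc[0]
        acc = truth.accessions["AD1_1"]
        np.testing.assert_array_equal(
            acc.genome_d[ev.chrom][ev.start:ev.end],
            acc.genome_a[ev.chrom][ev.start:ev.end])

    def test_autapomorphy_gives_three_vs_one_pattern_everywhere(self):
        cfg = SimConfig(seed=13, genome_length=20_000, branch_sub_prob=0.0,
                        autapomorphy_count=5)
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        d5 = truth.events[(truth.events.kind == "autapomorphy")
                          & (truth.events.genome == "D5")]
        assert len(d5) == 5
        for row in d5.itertuples():
            a2 = truth.diploid_a[row.chrom][row.start]
            d5b = truth.diploid_d[row.chrom][row.start]
            assert a2 != d5b
            for acc in truth.accessions.values():  # includes AD4
                assert acc.genome_a[row.chrom][row.start] == a2
                assert acc.genome_d[row.chrom][row.start] == a2

    def test_null_config_reproduces_progenitors(self):
        cfg = SimConfig(seed=17, genome_length=5000, branch_sub_prob=0.0)
        prog = simulate_progenitors(cfg)
        truth = simulate_polyploid_panel(prog, cfg)
        for acc in truth.accessions.values():
            np.testing.assert_array_equal(acc.genome_a["chr1"],
                                          prog.genome_a["chr1"])
            np.testing.assert_array_equal(acc.genome_d["chr1"],
                                          prog.genome_d["chr1"])

    def test_introgression_block_equals_donor_consensus(self):
        cfg = SimConfig(seed=19, genome_length=20_000,
                        introgression_blocks=(
                            IntrogressionSpec("AD1_1", "AD2", 2000, 1, "A"),),
                        accessions=(("AD1", 2), ("AD2", 1)))
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        ev = truth.events_of("introgression").iloc[0]
        donor = truth.species_seqs["AD2"][0]
        acc = truth.accessions["AD1_1"]
        np.testing.assert_array_equal(
            acc.genome_a[ev.chrom][ev.start:ev.end],
            donor[ev.chrom][ev.start:ev.end])

    def test_every_changed_base_is_ledgered(self):
        # ledger completeness: accession bases differing from the species
        # node are explained by a mutation/conversion/introgression event
        cfg = SimConfig(seed=23, genome_length=10_000,
                        conversion_tracts=(ConversionSpec("AD1", "D", 300),),
                        accessions=(("AD1", 1),))
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        acc = truth.accessions["AD1_1"]
        node_a, node_d = truth.species_seqs["AD1"]
        ev = truth.events
        explained = {
            (g, c): set()
            for g in ("AD1_1:A", "AD1_1:D") for c in ("chr1",)
        }
        for row in ev[ev.genome.isin(["AD1_1:A", "AD1_1:D"])].itertuples():
            explained[(row.genome, row.chrom)].update(
                range(row.start, row.end))
        for sub, got, node in (("A", acc.genome_a, node_a),
                               ("D", acc.genome_d, node_d)):
            diff = set(np.flatnonzero(got["chr1"] != node["chr1"]).tolist())
            assert diff <= explained[(f"AD1_1:{sub}", "chr1")]

    def test_conversion_never_overlaps_deletion(self):
        cfg = SimConfig(seed=29, genome_length=50_000,
                        conversion_tracts=(ConversionSpec("AD1", "D", 1000, 3),),
                        cnv_events=(CNVSpec("D", "deletion", 1000, 3,
                                            "AD1_1"),),
                        accessions=(("AD1", 1),))
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        conv = truth.events_of("conversion")
        dele = truth.events_of("deletion")
        for c in conv.itertuples():
            for d in dele.itertuples():
                assert c.end <= d.start or d.end <= c.start


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self):
        cfg = SimConfig(seed=31, genome_length=5000)
        prog = simulate_progenitors(cfg)
        reads, origin = simulate_reads({"A": prog.genome_a}, 5.0, 50, 0.0,
                                       seed=1)
        for i, row in enumerate(origin.itertuples()):
            src = prog.genome_a[row.chrom][row.start:row.start + 50]
            np.testing.assert_array_equal(reads.codes[i], src)

    def test_read_count_matches_coverage_arithmetic(self):
        cfg = SimConfig(seed=31, genome_length=10_000)
        prog = simulate_progenitors(cfg)
        reads, _ = simulate_reads({"A": prog.genome_a}, 30.0, 100, 0.0,
                                  seed=2)
        assert len(reads) == round(30 * 10_000 / 100)

    def test_duplication_doubles_depth_within_poisson_bounds(self):
        cfg = SimConfig(seed=37, genome_length=50_000)
        prog = simulate_progenitors(cfg)
        dup = ("chr1", 20_000, 30_000)
        reads, origin = simulate_reads(
            {"A": prog.genome_a}, 20.0, 100, 0.0, seed=3,
            duplications={"A": [dup]})
        starts = origin["start"].to_numpy()
        inside = ((starts >= dup[1]) & (starts < dup[2] - 100)).sum()
        outside = ((starts < dup[1] - 100)).sum()
        # reads-per-base ratio should be ~2x; compare rates with 3 sigma
        rate_in = inside / (dup[2] - dup[1] - 100)
        rate_out = outside / (dup[1] - 100)
        lam = 20.0 / 100
        sd_in = np.sqrt(2 * lam / (dup[2] - dup[1] - 100))
        assert abs(rate_in - 2 * lam) < 3 * sd_in
        assert abs(rate_out - lam) < 3 * np.sqrt(lam / (dup[1] - 100))

    def test_deleted_interval_yields_no_reads(self):
        cfg = SimConfig(seed=41, genome_length=10_000)
        prog = simulate_progenitors(cfg)
        dele = ("chr1", 4000, 6000)
        reads, origin = simulate_reads(
            {"A": prog.genome_a}, 10.0, 100, 0.0, seed=4,
            deletions={"A": [dele]})
        starts = origin["start"].to_numpy()
        assert not ((starts + 100 > 4000) & (starts < 6000)).any()

    def test_nonpositive_depth_rejected(self):
        cfg = SimConfig(seed=43, genome_length=2000)
        prog = simulate_progenitors(cfg)
        with pytest.raises(SimulationError):
            simulate_reads({"A": prog.genome_a}, 0.0, 50, 0.0, seed=1)

    def test_same_seed_gives_identical_reads(self):
        cfg = SimConfig(seed=47, genome_length=3000)
        prog = simulate_progenitors(cfg)
        r1, o1 = simulate_reads({"A": prog.genome_a}, 5.0, 50, 0.01, seed=9)
        r2, o2 = simulate_reads({"A": prog.genome_a}, 5.0, 50, 0.01, seed=9)
        np.testing.assert_array_equal(r1.codes, r2.codes)
        assert o1.equals(o2)
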