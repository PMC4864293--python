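"""End-to-end evaluation scenarios on simulated panels with ledgered truth.

Each scenario builds a small synthetic study, runs the relevant slice of the
pipeline, and scores the calls against the simulator's event ledger. The
problem sizes (100 kb genomes, 20-30x coverage, desk-scale panels) are the
package's standard benchmark conditions; every scenario is driven by a
single integer seed and is deterministic given that seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import categorize, cnv, conversion, introgression, phylo
from .homoeoindex import build_diploid_index
from .simgenome import (
    CNVSpec,
    ConversionSpec,
    IntrogressionSpec,
    SimConfig,
    simulate_polyploid_panel,
    simulate_progenitors,
    simulate_reads,
    truth_genotype_matrix,
)
from .toymap import map_reads


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# homoeo-SNP index recovery
# ---------------------------------------------------------------------------

def index_recovery(seed: int) -> dict:
    """Build the diploid homoeo-SNP index at 1% divergence, 30x, 0.5% error
    and score it against the truth divergence sites covered >= 5x by each
    diploid's final mapped reads."""
    cfg = SimConfig(seed=_sub_seed(seed, 1), genome_length=100_000,
                    progenitor_divergence=0.01, depth=30.0,
                    error_rate=0.005)
    prog = simulate_progenitors(cfg)
    reads_a, _ = simulate_reads({"A": prog.genome_a}, cfg.depth,
                                cfg.read_length, cfg.error_rate,
                                _sub_seed(seed, 2), name_prefix="a")
    reads_d, _ = simulate_reads({"D": prog.genome_d}, cfg.depth,
                                cfg.read_length, cfg.error_rate,
                                _sub_seed(seed, 3), name_prefix="d")
    index = build_diploid_index(reads_a, reads_d, prog.genome_d, "D")
    chrom_lengths = {c: int(s.shape[0]) for c, s in prog.genome_d.items()}
    depth_other = cnv.per_base_depth(index.other_alignments, chrom_lengths)
    depth_own = cnv.per_base_depth(index.own_alignments, chrom_lengths)
    truth_scored = set()
    for chrom, pos in prog.divergence_sites.items():
        ok = (depth_other[chrom][pos] >= 5) & (depth_own[chrom][pos] >= 5)
        truth_scored.update((chrom, int(p)) for p in pos[ok])
    found = {(c, p) for c, p, _ in index.items()}
    tp = len(truth_scored & found)
    return {
        "sensitivity_pct": 100.0 * tp / max(len(truth_scored), 1),
        "false_entry_pct": 100.0 * (len(found) - len(
            found & {(c, int(p)) for c, pos in
                     prog.divergence_sites.items() for p in pos}
        )) / max(len(found), 1),
        "iterations": index.build_iterations,
        "index_size": len(found),
        "n_truth_sites": len(truth_scored),
    }


# ---------------------------------------------------------------------------
# categorization error
# ---------------------------------------------------------------------------

def vote_corruption_bound(k_sites: np.ndarray, error_rate: float) -> float:
    """Per-read binomial bound on wrong-majority votes.

    A read overlapping k indexed sites can only flip to the wrong genome if
    more than k/2 of those sites carry a sequencing error, so
    P(wrong) <= P(Bin(k, e) > k/2); the bound reported is the mean over the
    categorized reads' k values.
    """
    from scipy.stats import binom

    ks = np.asarray(k_sites)
    probs = [float(binom.sf(k / 2.0, k, error_rate)) for k in ks]
    return float(np.mean(probs)) if probs else math.nan


def categorization_error(seed: int) -> dict:
    """Measure subgenome-assignment error on reads of known diploid origin.

    Reads simulated from the A-genome diploid at 1% divergence and 1%
    sequencing error are categorized by homoeo-SNP voting (on the masked
    D-reference mapping) and by best-of-two-mappings; both are scored
    against the known origin, with the binomial vote-corruption bound as
    the reference ceiling for the voting method.
    """
    error_rate = 0.01
    cfg = SimConfig(seed=_sub_seed(seed, 10), genome_length=50_000,
                    progenitor_divergence=0.01, depth=20.0,
                    error_rate=error_rate)
    prog = simulate_progenitors(cfg)
    reads_a, _ = simulate_reads({"A": prog.genome_a}, cfg.depth,
                                cfg.read_length, error_rate,
                                _sub_seed(seed, 11), name_prefix="a")
    reads_d, _ = simulate_reads({"D": prog.genome_d}, cfg.depth,
                                cfg.read_length, error_rate,
                                _sub_seed(seed, 12), name_prefix="d")
    index = build_diploid_index(reads_a, reads_d, prog.genome_d, "D")
    truth = {n: "A" for n in reads_a.names}

    aln_masked = map_reads(reads_a, prog.genome_d, snp_mask=index)
    cats = categorize.polycat_categorize(aln_masked, index)
    labels = {c.record.read_id: c.label for c in cats}
    polycat = categorize.measure_categorization_error(labels, truth)

    k_sites = []
    for c in cats:
        if c.label is None:
            continue
        rec = c.record
        positions = index.positions(rec.ref_id)
        k = int(np.searchsorted(positions, rec.end)
                - np.searchsorted(positions, rec.start))
        k_sites.append(k)
    bound = vote_corruption_bound(np.array(k_sites), error_rate)

    aln_to_a = map_reads(reads_a, prog.genome_a)
    aln_to_d = map_reads(reads_a, prog.genome_d)
    dog = categorize.polydog_categorize_all(aln_to_a, aln_to_d)
    polydog = categorize.measure_categorization_error(dog, truth)
    return {
        "polycat_error": polycat.error_rate,
        "polycat_rate": polycat.categorization_rate,
        "oracle_bound": bound,
        "polydog_error": polydog.error_rate,
        "polydog_rate": polydog.categorization_rate,
    }


# ---------------------------------------------------------------------------
# conversion detection (SNP-pattern method)
# ---------------------------------------------------------------------------

def _conversion_config(seed: int, with_tracts: bool) -> SimConfig:
    tracts = ()
    if with_tracts:
        tracts = (
            ConversionSpec("AD1", "D", 2000, 5),  # A-dominant
            ConversionSpec("AD1", "A", 2000, 5),  # D-dominant
        )
    return SimConfig(
        seed=_sub_seed(seed, 20), genome_length=100_000,
        progenitor_divergence=0.01, branch_sub_prob=0.001,
        conversion_tracts=tracts, autapomorphy_count=25,
        accessions=(("AD1", 3), ("AD2", 2), ("AD4", 1)),
    )


def _conversion_scan(truth):
    """Genotype-level SNP-pattern scan of a simulated panel."""
    sites = {
        chrom: np.flatnonzero(truth.diploid_a[chrom] !=
                              truth.diploid_d[chrom])
        for chrom in truth.diploid_a
    }
    matrix = truth_genotype_matrix(truth, sites)
    dip = pd.DataFrame({
        "A": matrix[("A2", "A")].to_numpy(),
        "D": matrix[("D5", "D")].to_numpy(),
    }, index=matrix.index)
    ad1 = [a for a in truth.accessions if a.startswith("AD1")]
    ad4 = [a for a in truth.accessions if a.startswith("AD4")]
    focal = conversion.species_consensus(matrix, ad1)
    outgrp = conversion.species_consensus(matrix, ad4)
    cand = conversion.scan_conversion_sites(dip, focal, "AD1")
    cand = conversion.outgroup_filter(cand, dip, outgrp)
    informative = {}
    for chrom in truth.diploid_a:
        at_ok = focal["A"].xs(chrom, level="chrom").to_numpy() != "."
        dt_ok = focal["D"].xs(chrom, level="chrom").to_numpy() != "."
        informative[chrom] = sites[chrom][at_ok & dt_ok]
    regions = conversion.find_conversion_runs(cand, informative, min_run=2)
    return sites, cand, regions


def conversion_recovery(seed: int) -> dict:
    """Plant 10 conversion tracts plus 50 diploid autapomorphies; score
    tract recovery as same-direction runs, the outgroup filter on the
    autapomorphies, and the false-call count of a no-conversion replicate."""
    cfg = _conversion_config(seed, with_tracts=True)
    truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
    _, cand, regions = _conversion_scan(truth)

    tracts = truth.events_of("conversion")
    tract_iv = {
        (row.chrom, row.start, row.end,
         "A-dominant" if row.genome.endswith(":D") else "D-dominant")
        for row in tracts.itertuples()
    }
    recovered = 0
    for chrom, start, end, direction in tract_iv:
        hit = any(
            r.chrom == chrom and r.direction == direction
            and r.start < end and start < r.end
            for r in regions
        )
        recovered += hit

    auta = truth.events_of("autapomorphy")
    auta_sites = {(row.chrom, row.start) for row in auta.itertuples()}
    cand_by_site = {(s.chrom, s.pos): s for s in cand}
    flagged = [cand_by_site[k] for k in auta_sites if k in cand_by_site]
    n_ancient = sum(
        s.outgroup_status == conversion.ANCIENT for s in flagged)

    cfg0 = _conversion_config(seed, with_tracts=False)
    truth0 = simulate_polyploid_panel(simulate_progenitors(cfg0), cfg0)
    _, _, regions0 = _conversion_scan(truth0)
    return {
        "n_tracts": len(tract_iv),
        "tracts_recovered": int(recovered),
        "autapomorphy_candidates": len(flagged),
        "autapomorphy_ancient_pct":
            100.0 * n_ancient / max(len(flagged), 1),
        "null_likely_runs": len(regions0),
    }


# ---------------------------------------------------------------------------
# conversion detection (CNV-overlap method)
# ---------------------------------------------------------------------------

def cnv_conversion(seed: int, window_size: int = 1000) -> dict:
    """One 5 kb planted conversion tract detected as an overlapping
    duplication/deletion pair through read categorization coverage."""
    cfg = SimConfig(
        seed=_sub_seed(seed, 30), genome_length=50_000,
        progenitor_divergence=0.01, depth=30.0, error_rate=0.005,
        conversion_tracts=(ConversionSpec("AD1", "D", 5000, 1),),
        accessions=(("AD1", 1),),
    )
    prog = simulate_progenitors(cfg)
    truth = simulate_polyploid_panel(prog, cfg)
    chrom_lengths = cfg.chrom_lengths()
    reads_a, _ = simulate_reads({"A": prog.genome_a}, cfg.depth,
                                cfg.read_length, cfg.error_rate,
                                _sub_seed(seed, 31), name_prefix="a")
    reads_d, _ = simulate_reads({"D": prog.genome_d}, cfg.depth,
                                cfg.read_length, cfg.error_rate,
                                _sub_seed(seed, 32), name_prefix="d")
    index = build_diploid_index(reads_a, reads_d, prog.genome_d, "D")

    acc = truth.accessions["AD1_1"]
    reads_t, _ = simulate_reads(
        {"A": acc.genome_a, "D": acc.genome_d}, cfg.depth,
        cfg.read_length, cfg.error_rate, _sub_seed(seed, 33),
        name_prefix="t")
    aln = map_reads(reads_t, prog.genome_d, snp_mask=index)
    cats = categorize.polycat_categorize(aln, index)
    by_label = categorize.split_by_label(cats)

    prof_at = cnv.coverage_profile(by_label.get("A", []), chrom_lengths,
                                   window_size)
    prof_dt = cnv.coverage_profile(by_label.get("D", []), chrom_lengths,
                                   window_size)
    # pooled diploid reference profiles, categorized the same way
    dip_a = categorize.split_by_label(categorize.polycat_categorize(
        index.other_alignments, index)).get("A", [])
    dip_d = categorize.split_by_label(categorize.polycat_categorize(
        index.own_alignments, index)).get("D", [])
    ref_a = cnv.coverage_profile(dip_a, chrom_lengths, window_size)
    ref_d = cnv.coverage_profile(dip_d, chrom_lengths, window_size)

    # margin ~= 2-3 window-level SEs: a converted tract is exactly 2-fold,
    # so the expected log2 ratio sits on the call boundary itself
    segs_a = cnv.log2_ratio_segments(prof_at, ref_a, margin=0.4,
                                     accession="AD1_1", genome="A")
    segs_d = cnv.log2_ratio_segments(prof_dt, ref_d, margin=0.4,
                                     accession="AD1_1", genome="D")
    candidates = conversion.cnv_overlap_scan(segs_a, segs_d)

    tract = truth.events_of("conversion").iloc[0]
    max_offset = math.nan
    if candidates:
        c = candidates[0]
        offs = [abs(c.dup_start - tract.start), abs(c.dup_end - tract.end),
                abs(c.del_start - tract.start), abs(c.del_end - tract.end)]
        max_offset = max(offs) / window_size
    return {
        "n_candidates": len(candidates),
        "max_breakpoint_offset_windows": max_offset,
        "n_dup_segments": sum(s.kind == "duplication" for s in segs_a),
        "n_del_segments": sum(s.kind == "deletion" for s in segs_d),
    }


# ---------------------------------------------------------------------------
# D-statistic calibration and introgression
# ---------------------------------------------------------------------------

def _dstat_tracks(truth):
    """(P1, P2, P3, O) A-subgenome code tracks for the standard test:
    wild conspecific, test cultivar, donor species, diploid outgroup."""
    def codes(g):
        return {c: s.astype(np.int8) for c, s in g.items()}

    return (
        codes(truth.accessions["AD1_1"].genome_a),
        codes(truth.accessions["AD1_2"].genome_a),
        codes(truth.accessions["AD2_1"].genome_a),
        codes(truth.diploid_a),
    )


def dstat_calibration(seed: int, n_reps: int = 20) -> dict:
    """No-introgression replicates should give |D| < 3 SE; a planted donor
    block covering ~20% of the genome should give genome-wide D > 0 at
    |Z| > 3 and a region-restricted D above the genome-wide value."""
    within = 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=_sub_seed(seed, 40 + rep),
                        genome_length=200_000, branch_sub_prob=0.02,
                        progenitor_divergence=0.01,
                        accessions=(("AD1", 2), ("AD2", 1)))
        truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
        res = introgression.patterson_d(*_dstat_tracks(truth))
        if res.undefined or abs(res.d) < 3 * res.se:
            within += 1

    cfg = SimConfig(seed=_sub_seed(seed, 70), genome_length=200_000,
                    branch_sub_prob=0.02, progenitor_divergence=0.01,
                    introgression_blocks=(
                        IntrogressionSpec("AD1_2", "AD2", 10_000, 4, "A"),),
                    accessions=(("AD1", 2), ("AD2", 1)))
    truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
    p1, p2, p3, out = _dstat_tracks(truth)
    genome_wide = introgression.patterson_d(p1, p2, p3, out)
    mask = {c: np.zeros(s.shape[0], dtype=bool)
            for c, s in truth.diploid_a.items()}
    for row in truth.events_of("introgression").itertuples():
        mask[row.chrom][row.start:row.end] = True
    region = introgression.patterson_d(p1, p2, p3, out, region_mask=mask)
    return {
        "calibration_within_3se_pct": 100.0 * within / n_reps,
        "genomewide_d": genome_wide.d,
        "genomewide_z": genome_wide.z,
        "region_d": region.d,
    }


def introgression_recovery(seed: int) -> dict:
    """Recover planted donor blocks from cultivar reads at 20x under the
    >= 10x donor-like coverage rule, scored at base level."""
    cfg = SimConfig(
        seed=_sub_seed(seed, 80), genome_length=100_000,
        branch_sub_prob=0.01, progenitor_divergence=0.01,
        depth=20.0, error_rate=0.005,
        introgression_blocks=(
            IntrogressionSpec("AD1_4", "AD2", 8000, 3, "A"),),
        accessions=(("AD1", 4), ("AD2", 2)),
    )
    truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
    chrom_lengths = cfg.chrom_lengths()
    # genotype-level wild/donor panels at segregating sites
    stack = np.stack(
        [truth.accessions[a].genome_a["chr1"] for a in truth.accessions
         if not a.startswith("AD1_4")])
    sites = {"chr1": np.flatnonzero((stack != stack[0]).any(axis=0))}
    matrix = truth_genotype_matrix(truth, sites)
    wild = ["AD1_1", "AD1_2", "AD1_3"]
    donors = ["AD2_1", "AD2_2"]
    diag = introgression.find_diagnostic_snps(
        matrix, wild, donors, cultivar_accessions=["AD1_4"], subgenome="A")

    # species-adjusted reference: the AD1 species-node A genome
    reference = truth.species_seqs["AD1"][0]
    reads, _ = simulate_reads(
        {"A": truth.accessions["AD1_4"].genome_a}, cfg.depth,
        cfg.read_length, cfg.error_rate, _sub_seed(seed, 81),
        name_prefix="c")
    aln = map_reads(reads, reference, snp_mask=diag)
    cats = introgression.categorize_read_origin(aln, diag)
    donor_reads = [c.record for c in cats if c.label == "donor"]
    depth = cnv.per_base_depth(donor_reads, chrom_lengths)
    regions = introgression.call_introgressed_regions(
        depth, min_depth=10.0, min_length=2 * cfg.read_length,
        accession="AD1_4", genome="A")

    truth_mask = np.zeros(chrom_lengths["chr1"], dtype=bool)
    for row in truth.events_of("introgression").itertuples():
        truth_mask[row.start:row.end] = True
    call_mask = np.zeros_like(truth_mask)
    for r in regions:
        call_mask[r.start:r.end] = True
    tp = int((truth_mask & call_mask).sum())
    return {
        "n_diagnostic_snps": len(diag),
        "n_regions": len(regions),
        "sensitivity_pct": 100.0 * tp / max(int(truth_mask.sum()), 1),
        "precision_pct": 100.0 * tp / max(int(call_mask.sum()), 1),
    }


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

AD1_CLADE = {"AD1", "AD3", "AD6", "AD7"}
AD2_CLADE = {"AD2", "AD5"}


def phylo_recovery(seed: int, n_reps: int = 1000) -> dict:
    """Bootstrap-consensus NJ on an 8-accession panel over the species
    tree; reports support for the AD1-clade/AD2-clade split and whether
    the species topology is recovered."""
    cfg = SimConfig(seed=_sub_seed(seed, 90), genome_length=50_000,
                    branch_sub_prob=0.01, progenitor_divergence=0.01,
                    accessions=(("AD1", 2), ("AD2", 1), ("AD3", 1),
                                ("AD4", 1), ("AD5", 1), ("AD6", 1),
                                ("AD7", 1)))
    truth = simulate_polyploid_panel(simulate_progenitors(cfg), cfg)
    names = list(truth.accessions)
    stack = np.stack([truth.accessions[a].genome_a["chr1"] for a in names],
                     axis=1).astype(np.int8)
    poly = (stack != stack[:, [0]]).any(axis=1)
    codes = stack[poly]
    tree = phylo.bootstrap_consensus(codes, taxa=names, n_reps=n_reps,
                                     frac=0.05, seed=_sub_seed(seed, 91))
    supports = tree.split_supports()
    # the AD1-clade/AD2-clade split, canonicalized away from the first taxon
    all_taxa = frozenset(names)
    ref = min(all_taxa)
    clade2 = frozenset(
        n for n in names
        if n.rsplit("_", 1)[0] in AD2_CLADE | {"AD4"})
    side = clade2 if ref not in clade2 else all_taxa - clade2
    support = supports.get(side, 0.0)

    # species-tree splits all recovered?
    want = []
    for group in (AD1_CLADE, AD2_CLADE, {"AD2", "AD5", "AD4"}):
        s = frozenset(n for n in names if n.rsplit("_", 1)[0] in group)
        want.append(s if ref not in s else all_taxa - s)
    found = tree.splits()
    return {
        "n_sites": int(poly.sum()),
        "main_split_support_pct": float(support),
        "topology_recovered": int(all(
            s in found for s in want if 1 < len(s) < len(all_taxa) - 1)),
    }


def nj_additivity(seed: int) -> dict:
    """NJ on an additive matrix must reproduce the input path lengths."""
    rng = np.random.default_rng(seed)
    # random additive matrix from a random tree on 8 taxa
    taxa = [f"t{i}" for i in range(8)]
    # build a random bifurcating tree by sequential attachment
    from .phylo import TreeNode, PhyloTree

    nodes = [TreeNode(t) for t in taxa[:3]]
    root = TreeNode(children=[(n, float(rng.uniform(0.1, 1.0)))
                              for n in nodes])
    tree = PhyloTree(root)
    for t in taxa[3:]:
        # pick a random edge: descend to a random internal node
        parents = []

        def collect(node):
            for i, (child, L) in enumerate(node.children):
                parents.append((node, i))
                collect(child)

        collect(root)
        node, i = parents[rng.integers(len(parents))]
        child, L = node.children[i]
        split = TreeNode(children=[
            (child, float(L) / 2),
            (TreeNode(t), float(rng.uniform(0.1, 1.0))),
        ])
        node.children[i] = (split, float(L) / 2)
    dm = tree.leaf_distances()
    nj = phylo.neighbor_joining(dm, join_order_seed=seed)
    back = nj.leaf_distances()
    order = [back.taxa.index(t) for t in dm.taxa]
    err = float(np.max(np.abs(back.matrix[np.ix_(order, order)] -
                              dm.matrix)))
    return {"max_path_error": err,
            "topology_match": int(nj.splits() == tree.splits())}
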