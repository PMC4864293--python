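"""End-to-end orchestration: simulate -> map -> index -> categorize ->
SNPs -> CNV -> conversion -> introgression -> phylogeny.

All stages are deterministic under the configured seed (per-stage seeds are
derived from it by fixed offsets), every intermediate is serialized in a
standard flat format, and the final report scores calls against the
simulator's truth ledger whenever planted events exist. Internally all
intervals are 0-based half-open; 1-based coordinates appear only inside SAM
and VCF files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorize as cat
from . import cnv as cnvmod
from . import conversion as conv
from . import fileio, introgression, phylo, snpcall
from .homoeoindex import HomoeoSNPIndex, IndexThresholds, build_diploid_index
from .simgenome import (
    CNVSpec,
    ConversionSpec,
    IntrogressionSpec,
    SimConfig,
    simulate_polyploid_panel,
    simulate_progenitors,
    simulate_reads,
)
from .toymap import map_reads, write_sam

log = logging.getLogger("polyweave")

STAGES = ["sim", "index", "categorize", "snps", "cnv", "conversion",
          "introgression", "phylo"]


@dataclass
class ThresholdConfig:
    """Every numeric threshold of the analysis, at its standard default."""

    min_allele_cov: int = 5
    min_allele_freq: float = 0.30
    maf_filter: float = 0.10
    consensus_frac: float = 0.75
    single_accession_consensus: float = 1.0
    log2_dup: float = 1.0
    log2_del: float = -1.0
    cnv_margin: float = 0.4
    window_size: int = 1000
    min_windows: int = 3
    introgression_min_depth: float = 10.0
    bootstrap_reps: int = 1000
    bootstrap_frac: float = 0.05
    min_run: int = 2
    phred_floor: int = 20
    max_mismatch: int = 3
    dstat_block: int = 5000


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh,
                      indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"polyweave run (seed {self.seed})\n")
            for stage in STAGES:
                info = self.stages.get(stage)
                fh.write(f"\n[{stage}]\n")
                if info is None:
                    fh.write("  skipped\n")
                    continue
                for k, v in sorted(info.items()):
                    fh.write(f"  {k}: {v}\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(type(x))


def load_config(path) -> tuple[SimConfig, ThresholdConfig]:
    """Read the single YAML run configuration."""
    raw = yaml.safe_load(open(path)) or {}
    sim = dict(raw.get("sim", {}))
    for key, cls in (("conversion_tracts", ConversionSpec),
                     ("cnv_events", CNVSpec),
                     ("introgression_blocks", IntrogressionSpec)):
        if key in sim:
            sim[key] = tuple(cls(**d) for d in sim[key])
    if "accessions" in sim:
        sim["accessions"] = tuple(
            (sp, int(n)) for sp, n in sim["accessions"])
    thr = ThresholdConfig(**raw.get("thresholds", {}))
    return SimConfig(**sim), thr


def run_pipeline(
    sim_config: SimConfig,
    thresholds: ThresholdConfig | None = None,
    outdir: str | Path = "polyweave_out",
    until: str = "phylo",
) -> RunReport:
    """Run all stages through ``until`` (inclusive), writing outputs under
    ``outdir`` and returning the summary report."""
    thr = thresholds or ThresholdConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    report = RunReport(seed=sim_config.seed)
    state: dict = {}
    for stage in STAGES[: last + 1]:
        t0 = time.time()
        log.info("stage %s start", stage)
        try:
            info = _STAGE_FUNCS[stage](sim_config, thr, outdir, state)
        except Exception:
            log.exception("stage %s failed", stage)
            report.to_json(outdir / "report.json")
            raise
        # wall time goes to the log only, keeping reports byte-reproducible
        report.stages[stage] = info
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    report.to_json(outdir / "report.json")
    report.to_text(outdir / "report.txt")
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_sim(cfg: SimConfig, thr: ThresholdConfig, outdir: Path, state):
    prog = simulate_progenitors(cfg)
    truth = simulate_polyploid_panel(prog, cfg)
    state["prog"] = prog
    state["truth"] = truth
    state["chrom_lengths"] = cfg.chrom_lengths()
    fileio.write_fasta(outdir / "ancestor.fa", prog.ancestor)
    fileio.write_fasta(outdir / "diploid_A2.fa", truth.diploid_a)
    fileio.write_fasta(outdir / "diploid_D5.fa", truth.diploid_d)
    truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    fileio.write_bed(outdir / "truth_events.bed", [
        (r.chrom, r.start, r.end, f"{r.kind}:{r.branch}")
        for r in truth.events.itertuples()
    ])
    seed_base = cfg.seed + 10_000
    reads_a, _ = simulate_reads({"A2": truth.diploid_a}, cfg.depth,
                                cfg.read_length, cfg.error_rate,
                                seed_base + 1, name_prefix="dipA")
    reads_d, _ = simulate_reads({"D5": truth.diploid_d}, cfg.depth,
                                cfg.read_length, cfg.error_rate,
                                seed_base + 2, name_prefix="dipD")
    state["diploid_reads"] = {"A": reads_a, "D": reads_d}
    fileio.write_fastq(outdir / "diploid_A2.fastq", reads_a)
    fileio.write_fastq(outdir / "diploid_D5.fastq", reads_d)
    state["acc_reads"] = {}
    for i, (name, acc) in enumerate(truth.accessions.items()):
        dels = {s: truth.cnv_intervals(name, s, "deletion")
                for s in ("A", "D")}
        dups = {s: truth.cnv_intervals(name, s, "duplication")
                for s in ("A", "D")}
        reads, origin = simulate_reads(
            {"A": acc.genome_a, "D": acc.genome_d}, cfg.depth,
            cfg.read_length, cfg.error_rate, seed_base + 10 + i,
            deletions=dels, duplications=dups, name_prefix=name)
        state["acc_reads"][name] = (reads, origin)
        fileio.write_fastq(outdir / f"{name}.fastq", reads)
    return {
        "n_accessions": len(truth.accessions),
        "n_divergence_sites": prog.n_divergence_sites(),
        "n_events": int(len(truth.events)),
    }


def _stage_index(cfg, thr, outdir, state):
    ithr = IndexThresholds(min_allele_cov=thr.min_allele_cov,
                           max_mismatch=thr.max_mismatch)
    index = build_diploid_index(
        state["diploid_reads"]["A"], state["diploid_reads"]["D"],
        state["truth"].diploid_d, "D", ithr)
    state["index"] = index
    index.to_tsv(outdir / "homoeo_index.tsv")
    return {
        "index_size": len(index),
        "iterations": index.build_iterations,
        "history": index.build_history,
    }


def _stage_categorize(cfg, thr, outdir, state):
    from .homoeoindex import augment_index_with_tetraploid

    index: HomoeoSNPIndex = state["index"]
    reference = state["truth"].diploid_d
    state["acc_aln"] = {}
    state["acc_cats"] = {}
    counts = {}
    for name, (reads, _origin) in state["acc_reads"].items():
        state["acc_aln"][name] = map_reads(reads, reference,
                                           thr.max_mismatch, snp_mask=index)
    # tetraploid-specific homoeo-SNPs, one augmentation pass per species
    by_species: dict[str, dict] = {}
    for name, acc in state["truth"].accessions.items():
        by_species.setdefault(acc.species, {})[name] = \
            state["acc_aln"][name]
    n_before = len(index)
    for species in sorted(by_species):
        augment_index_with_tetraploid(
            index, by_species[species], species,
            state["chrom_lengths"], consensus=thr.consensus_frac,
            phred_floor=thr.phred_floor)
    index.to_tsv(outdir / "homoeo_index.tsv")  # now with tetraploid sites
    for name, (reads, _origin) in state["acc_reads"].items():
        aln = state["acc_aln"][name]
        cats = cat.polycat_categorize(aln, index,
                                      phred_floor=thr.phred_floor)
        state["acc_cats"][name] = cats
        by = cat.split_by_label(cats)
        for sub in ("A", "D"):
            write_sam(outdir / f"{name}.{sub}.sam", by.get(sub, []),
                      reference)
        cat.write_label_table(outdir / f"{name}.labels.tsv", cats)
        n_mapped = sum(1 for a in aln if a.mapped)
        counts[name] = {
            "mapped": n_mapped,
            "A": len(by.get("A", [])),
            "D": len(by.get("D", [])),
            "uncategorized": n_mapped - len(by.get("A", []))
            - len(by.get("D", [])),
        }
    return {"per_accession": counts,
            "tetraploid_snps_added": len(index) - n_before}


def _stage_snps(cfg, thr, outdir, state):
    chrom_lengths = state["chrom_lengths"]
    tracks = {}
    for name, cats in state["acc_cats"].items():
        by = cat.split_by_label(cats)
        for sub in ("A", "D"):
            tracks[(name, sub)] = snpcall.pileup_genotype(
                by.get(sub, []), chrom_lengths, thr.min_allele_cov,
                thr.min_allele_freq)
    state["tracks"] = tracks
    # variable or divergent sites across all tracks
    sites = {}
    for chrom, L in chrom_lengths.items():
        stack = np.stack([t[chrom] for t in tracks.values()])
        codes = snpcall.calls_to_codes(stack)
        anycall = (codes >= 0).any(axis=0)
        first = np.where(codes >= 0, codes, -1).max(axis=0)
        differs = ((codes >= 0) & (codes != first[None, :])).any(axis=0)
        var = anycall & differs
        sites[chrom] = np.flatnonzero(var)
    matrix = snpcall.genotype_matrix(tracks, sites)
    state["matrix"] = matrix
    state["sites"] = sites
    snpcall.write_genotype_matrix(outdir / "genotypes.tsv", matrix)
    species = sorted({a.species for a in
                      state["truth"].accessions.values()})
    info = {"n_sites": int(matrix.shape[0])}
    all_records = []
    for sub in ("A", "D"):
        group = [(a, sub) for a in state["truth"].accessions]
        if len(group) >= 2:
            recs = snpcall.call_allele_snps(matrix, group, thr.maf_filter)
            all_records.extend(recs)
            info[f"allele_snps_{sub}"] = len(recs)
            if len(group) >= 2:
                info[f"diversity_{sub}"] = snpcall.diversity(matrix, group)
    for sp in species:
        accs = [a for a, v in state["truth"].accessions.items()
                if v.species == sp]
        recs = snpcall.call_homoeo_snps(matrix, accs, thr.consensus_frac)
        all_records.extend(recs)
        info[f"homoeo_snps_{sp}"] = len(recs)
    snpcall.write_vcf(outdir / "snps.vcf", all_records)
    return info


def _stage_cnv(cfg, thr, outdir, state):
    chrom_lengths = state["chrom_lengths"]
    # depth comparisons use the diploid-provenance index only: diploid
    # reads cannot be voted at tetraploid-specific sites, and sample and
    # reference profiles must share one categorization rule to cancel
    index = state["index"].subset_by_provenance("diploid")
    index.other_alignments = state["index"].other_alignments
    index.own_alignments = state["index"].own_alignments
    dip_a = cat.split_by_label(cat.polycat_categorize(
        index.other_alignments, index)).get("A", [])
    dip_d = cat.split_by_label(cat.polycat_categorize(
        index.own_alignments, index)).get("D", [])
    ref_profiles = {
        "A": cnvmod.coverage_profile(dip_a, chrom_lengths, thr.window_size),
        "D": cnvmod.coverage_profile(dip_d, chrom_lengths, thr.window_size),
    }
    fileio.write_bedgraph(outdir / "diploid_A.bedgraph", ref_profiles["A"])
    fileio.write_bedgraph(outdir / "diploid_D.bedgraph", ref_profiles["D"])
    segments = []
    state["segments"] = {}
    for name in state["acc_cats"]:
        cats = cat.polycat_categorize(state["acc_aln"][name], index,
                                      phred_floor=thr.phred_floor)
        by = cat.split_by_label(cats)
        for sub in ("A", "D"):
            prof = cnvmod.coverage_profile(by.get(sub, []), chrom_lengths,
                                           thr.window_size)
            segs = cnvmod.log2_ratio_segments(
                prof, ref_profiles[sub], thr.log2_dup, thr.log2_del,
                thr.min_windows, margin=thr.cnv_margin,
                accession=name, genome=sub)
            state["segments"][(name, sub)] = segs
            segments.extend(segs)
    cnvmod.write_segments_bed(outdir / "cnv_segments.bed", segments)
    blocks = []
    if len(state["acc_cats"]) >= 2 and segments:
        blocks = cnvmod.cnv_conservation(segments)
    return {"n_segments": len(segments), "n_conserved_blocks": len(blocks)}


def _stage_conversion(cfg, thr, outdir, state):
    truth = state["truth"]
    matrix = state["matrix"]
    dip_tracks = {}
    chrom_lengths = state["chrom_lengths"]
    # diploid proxy consensus from the index-building alignments
    from .snpcall import base_counts, genotype_from_counts

    index = state["index"]
    dip_calls = {}
    for label, aln in (("A", index.other_alignments),
                       ("D", index.own_alignments)):
        counts = base_counts(aln, chrom_lengths)
        dip_calls[label] = {
            c: genotype_from_counts(cts, thr.min_allele_cov,
                                    thr.min_allele_freq)
            for c, cts in counts.items()
        }
    sites = state["sites"]
    idx = matrix.index
    dip = pd.DataFrame({
        sub: np.concatenate([dip_calls[sub][c][p]
                             for c, p in sites.items()])
        for sub in ("A", "D")
    }, index=idx)
    species_accs = {}
    for name, acc in truth.accessions.items():
        species_accs.setdefault(acc.species, []).append(name)
    out_cons = None
    if "AD4" in species_accs:
        out_cons = conv.species_consensus(matrix, species_accs["AD4"],
                                          thr.consensus_frac,
                                          thr.consensus_frac)
    info = {}
    all_sites = []
    all_regions = []
    for sp in ("AD1", "AD2"):
        if sp not in species_accs:
            continue
        focal = conv.species_consensus(matrix, species_accs[sp],
                                       thr.consensus_frac,
                                       thr.consensus_frac)
        cand = conv.scan_conversion_sites(dip, focal, sp)
        if out_cons is not None:
            cand = conv.outgroup_filter(cand, dip, out_cons)
        informative = {}
        for chrom in chrom_lengths:
            chrom_idx = [i for i, (c, _p) in enumerate(idx) if c == chrom]
            sub = np.array(chrom_idx, dtype=int)
            at_ok = focal["A"].to_numpy()[sub] != "."
            dt_ok = focal["D"].to_numpy()[sub] != "."
            da = dip["A"].to_numpy()[sub]
            dd = dip["D"].to_numpy()[sub]
            div = (da != ".") & (dd != ".") & (da != dd)
            informative[chrom] = np.array(
                [idx[i][1] for i in sub[at_ok & dt_ok & div]])
        regions = conv.find_conversion_runs(cand, informative, thr.min_run)
        all_sites.extend(cand)
        all_regions.extend(regions)
        info[f"{sp}_candidate_sites"] = len(cand)
        info[f"{sp}_likely_runs"] = len(regions)
    conv.write_sites_tsv(outdir / "conversion_sites.tsv", all_sites)
    conv.write_regions_bed(outdir / "conversion_regions.bed", all_regions)
    # CNV-overlap scan per accession (colinear homoeolog map)
    candidates = []
    for name in truth.accessions:
        segs_a = state["segments"].get((name, "A"), [])
        segs_d = state["segments"].get((name, "D"), [])
        candidates.extend(conv.cnv_overlap_scan(segs_a, segs_d))
    info["cnv_overlap_candidates"] = len(candidates)
    # truth recovery: a tract counts if either method finds it — the SNP
    # method sees read-length-scale patterns, the CNV method large blocks
    tracts = truth.events_of("conversion")
    tract_iv = {(r.chrom, r.start, r.end) for r in tracts.itertuples()}
    recovered = sum(
        any(r.chrom == c and r.start < e and s < r.end
            for r in all_regions)
        or any(cd.chrom == c and cd.dup_start < e and s < cd.dup_end
               for cd in candidates)
        for c, s, e in tract_iv)
    info["true_tracts"] = len(tract_iv)
    info["true_tracts_recovered"] = int(recovered)
    return info


def _stage_introgression(cfg, thr, outdir, state):
    truth = state["truth"]
    recipients = sorted({b.recipient for b in cfg.introgression_blocks})
    if not recipients:
        return {"skipped": "no introgression blocks configured",
                "true_blocks": 0, "true_blocks_recovered": 0}
    matrix = state["matrix"]
    info = {}
    regions_all = []
    dstats = {}
    for block in cfg.introgression_blocks:
        recip = block.recipient
        sp = truth.accessions[recip].species
        donor_sp = block.donor_species
        wild = [a for a, v in truth.accessions.items()
                if v.species == sp and a not in recipients]
        donors = [a for a, v in truth.accessions.items()
                  if v.species == donor_sp]
        if not wild or not donors:
            info[f"{recip}_skipped"] = "no wild or donor panel"
            continue
        diag = introgression.find_diagnostic_snps(
            matrix, wild, donors, cultivar_accessions=recipients,
            subgenome=block.genome, consensus=thr.consensus_frac,
            min_covered=thr.consensus_frac)
        cats = introgression.categorize_read_origin(
            state["acc_aln"][recip], diag, phred_floor=thr.phred_floor)
        donor_reads = [c.record for c in cats if c.label == "donor"]
        depth = cnvmod.per_base_depth(donor_reads, state["chrom_lengths"])
        regions = introgression.call_introgressed_regions(
            depth, thr.introgression_min_depth, 2 * cfg.read_length,
            accession=recip, genome=block.genome)
        regions_all.extend(regions)
        info[f"{recip}_diagnostic_snps"] = len(diag)
        info[f"{recip}_regions"] = len(regions)
        # D-statistic from the genotype call tracks
        tracks = state["tracks"]

        def codes_of(key):
            return {c: snpcall.calls_to_codes(v)
                    for c, v in tracks[key].items()}

        if wild and donors:
            p1 = codes_of((wild[0], block.genome))
            p2 = codes_of((recip, block.genome))
            p3 = codes_of((donors[0], block.genome))
            out_genome = (truth.diploid_a if block.genome == "A"
                          else truth.diploid_d)
            out_codes = {c: s.astype(np.int8)
                         for c, s in out_genome.items()}
            res = introgression.patterson_d(p1, p2, p3, out_codes,
                                            block_size=thr.dstat_block)
            dstats[recip] = res
            info[f"{recip}_D"] = res.d
            info[f"{recip}_Z"] = res.z
    introgression.write_regions_bed(outdir / "introgression_regions.bed",
                                    regions_all)
    if dstats:
        introgression.write_dstat_tsv(outdir / "dstat.tsv", dstats)
    # truth recovery at base level
    ev = truth.events_of("introgression")
    truth_bases = 0
    hit_bases = 0
    for row in ev.itertuples():
        truth_bases += row.end - row.start
        for r in regions_all:
            lo = max(row.start, r.start)
            hi = min(row.end, r.end)
            if hi > lo:
                hit_bases += hi - lo
    info["true_blocks"] = int(len(ev))
    info["base_sensitivity"] = (hit_bases / truth_bases
                                if truth_bases else float("nan"))
    return info


def _stage_phylo(cfg, thr, outdir, state):
    matrix = state["matrix"]
    accs = list(state["truth"].accessions)
    info = {}
    for sub in ("A", "D"):
        group = [(a, sub) for a in accs if (a, sub) in matrix.columns]
        if len(group) < 3:
            info[f"{sub}_skipped"] = "fewer than 3 taxa"
            continue
        try:
            dm = phylo.distance_matrix(matrix, group)
        except ValueError as exc:
            info[f"{sub}_skipped"] = str(exc)
            continue
        fileio.write_phylip(outdir / f"tree_{sub}.dist", dm.taxa, dm.matrix)
        tree = phylo.neighbor_joining(dm, join_order_seed=cfg.seed)
        (outdir / f"tree_{sub}.nwk").write_text(tree.to_newick() + "\n")
        n_sites = matrix.shape[0]
        if thr.bootstrap_frac * n_sites >= 10:
            cons = phylo.bootstrap_consensus(
                matrix, group, n_reps=thr.bootstrap_reps,
                frac=thr.bootstrap_frac, seed=cfg.seed)
            (outdir / f"tree_{sub}.consensus.nwk").write_text(
                cons.to_newick() + "\n")
            info[f"{sub}_consensus_splits"] = len(cons.splits())
        else:
            info[f"{sub}_bootstrap_skipped"] = "too few sites"
        info[f"{sub}_taxa"] = len(group)
    return info


_STAGE_FUNCS = {
    "sim": _stage_sim,
    "index": _stage_index,
    "categorize": _stage_categorize,
    "snps": _stage_snps,
    "cnv": _stage_cnv,
    "conversion": _stage_conversion,
    "introgression": _stage_introgression,
    "phylo": _stage_phylo,
}
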