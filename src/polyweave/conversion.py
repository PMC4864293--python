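"""Homoeologous-conversion detection.

Two complementary detectors. The SNP-pattern method finds sites where both
subgenomes of a focal species carry the same parental allele while the two
diploid proxies differ (A-dominant: A2 = AT = DT != D5; D-dominant the
mirror). Because a mutation private to one diploid lineage produces the
identical pattern in every tetraploid, candidates are screened against the
basal outgroup species (AD4): a candidate that shows the same pattern in
AD4 is indistinguishable from a diploid autapomorphy or a conversion
coincident with polyploidization, and only candidates where AD4 retains
both parental alleles remain likely lineage-specific conversions. Regions
are then called as runs of >= 2 consecutive same-direction likely-conversion
sites, where "consecutive" is over informative loci (sites with diploid
divergence and tetraploid consensus), not genomic adjacency.

The CNV-overlap method targets recent, read-length-scale or larger tracts:
mis-categorized reads from a converted tract double coverage on one genome
and zero it on the homoeologous locus, so a duplication segment reciprocally
overlapping a deletion segment at the homoeologous position (through a
homoeolog coordinate map) in the same accession is a large-conversion
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import CNVSegment, reciprocal_overlap
from .snpcall import consensus_allele

A_DOMINANT = "A-dominant"
D_DOMINANT = "D-dominant"

LIKELY = "likely-conversion"
ANCIENT = "autapomorphy-or-ancient"
OUTGROUP_MISSING = "outgroup-missing"


def species_consensus(
    matrix: pd.DataFrame,
    accessions: list[str],
    cov_frac: float = 0.75,
    agree_frac: float = 0.75,
) -> pd.DataFrame:
    """Per-site per-subgenome species consensus genotypes.

    A consensus is emitted only when at least ``cov_frac`` of the species'
    accessions have a call at the site and at least ``agree_frac`` of the
    observed calls agree. Returns a DataFrame with columns "A" and "D"
    (missing = ".") aligned to the matrix index.
    """
    out = {}
    for sub in ("A", "D"):
        cols = [(a, sub) for a in accessions if (a, sub) in matrix.columns]
        if not cols:
            out[sub] = np.full(matrix.shape[0], ".", dtype="<U3")
            continue
        values = matrix[cols].to_numpy()
        n_total = len(cols)
        col = np.full(matrix.shape[0], ".", dtype="<U3")
        for i in range(matrix.shape[0]):
            row = values[i]
            observed = row[(row != ".")]
            observed = observed[np.char.find(observed.astype(str), "/") < 0]
            observed = observed[observed != "amb"]
            if observed.size / n_total < cov_frac - 1e-12:
                continue
            allele = consensus_allele(observed, agree_frac)
            if allele is not None:
                col[i] = allele
        out[sub] = col
    return pd.DataFrame(out, index=matrix.index)


@dataclass
class ConversionSite:
    chrom: str
    pos: int
    species: str
    direction: str  # A_DOMINANT or D_DOMINANT
    outgroup_status: str = OUTGROUP_MISSING


def classify_conversion_site(
    a2: str, d5: str, a_t: str, d_t: str
) -> str | None:
    """Four-way genotype pattern test at one site.

    A-dominant iff A2 = AT = DT != D5; D-dominant iff D5 = AT = DT != A2;
    anything else (including any missing input) is no candidate.
    """
    calls = (a2, d5, a_t, d_t)
    if any(c is None or c == "." or "/" in c or c == "amb" for c in calls):
        return None
    if a2 == d5 or a_t != d_t:
        return None
    if a_t == a2:
        return A_DOMINANT
    if a_t == d5:
        return D_DOMINANT
    return None


def scan_conversion_sites(
    diploid_consensus: pd.DataFrame,
    focal_consensus: pd.DataFrame,
    species: str,
) -> list[ConversionSite]:
    """Apply the pattern test across all sites of a consensus table.

    ``diploid_consensus`` columns "A"/"D" hold the A2/D5 proxy genotypes;
    ``focal_consensus`` holds the focal species' AT/DT consensus.
    """
    sites = []
    a2 = diploid_consensus["A"].to_numpy()
    d5 = diploid_consensus["D"].to_numpy()
    at = focal_consensus["A"].to_numpy()
    dt = focal_consensus["D"].to_numpy()
    for i, (chrom, pos) in enumerate(diploid_consensus.index):
        direction = classify_conversion_site(a2[i], d5[i], at[i], dt[i])
        if direction is not None:
            sites.append(ConversionSite(chrom, int(pos), species, direction))
    return sites


def outgroup_filter(
    sites: list[ConversionSite],
    diploid_consensus: pd.DataFrame,
    outgroup_consensus: pd.DataFrame,
) -> list[ConversionSite]:
    """Set outgroup_status on each candidate using the basal species.

    Same pattern in the outgroup -> autapomorphy-or-ancient; outgroup
    retaining both parental alleles (AT = A2 and DT = D5) -> likely
    conversion; outgroup missing or in any other state -> outgroup-missing
    (conservatively excluded from region calling).
    """
    dip = diploid_consensus
    out = outgroup_consensus
    lut_dip = {idx: i for i, idx in enumerate(dip.index)}
    a2 = dip["A"].to_numpy()
    d5 = dip["D"].to_numpy()
    oa = out["A"].to_numpy()
    od = out["D"].to_numpy()
    result = []
    for s in sites:
        i = lut_dip[(s.chrom, s.pos)]
        og_dir = classify_conversion_site(a2[i], d5[i], oa[i], od[i])
        if og_dir == s.direction:
            status = ANCIENT
        elif oa[i] == a2[i] and od[i] == d5[i] and oa[i] != "." \
                and od[i] != ".":
            status = LIKELY
        else:
            status = OUTGROUP_MISSING
        result.append(ConversionSite(s.chrom, s.pos, s.species, s.direction,
                                     status))
    return result


@dataclass
class ConversionRegion:
    chrom: str
    start: int
    end: int  # half-open: last site position + 1
    n_sites: int
    direction: str
    species: str
    genes: list[str]


def find_conversion_runs(
    sites: list[ConversionSite],
    informative_positions: dict[str, np.ndarray],
    min_run: int = 2,
    annotation: list[tuple[str, int, int, str]] | None = None,
) -> list[ConversionRegion]:
    """Maximal runs of consecutive same-direction likely-conversion sites.

    Consecutive means adjacent ranks among the informative loci of the
    chromosome (no intervening informative site that is not part of the
    run). Sites not marked likely-conversion never join a run and a
    direction switch terminates one.
    """
    regions: list[ConversionRegion] = []
    by_chrom: dict[str, list[ConversionSite]] = {}
    for s in sites:
        if s.outgroup_status == LIKELY:
            by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_sites in by_chrom.items():
        info = informative_positions.get(chrom, np.empty(0, dtype=np.int64))
        chrom_sites.sort(key=lambda s: s.pos)
        ranks = np.searchsorted(info, [s.pos for s in chrom_sites])
        run: list[ConversionSite] = []

        def flush(run):
            if len(run) >= min_run:
                regions.append(ConversionRegion(
                    chrom, run[0].pos, run[-1].pos + 1, len(run),
                    run[0].direction, run[0].species,
                    _genes_in(annotation, chrom, run[0].pos,
                              run[-1].pos + 1)))

        prev_rank = None
        for s, rank in zip(chrom_sites, ranks):
            if run and rank == prev_rank + 1 and \
                    s.direction == run[-1].direction:
                run.append(s)
            else:
                flush(run)
                run = [s]
            prev_rank = rank
        flush(run)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _genes_in(annotation, chrom, start, end) -> list[str]:
    if not annotation:
        return []
    return [name for c, s, e, name in annotation
            if c == chrom and s < end and start < e]


@dataclass
class LargeConversionCandidate:
    accession: str
    dup_genome: str
    chrom: str
    dup_start: int
    dup_end: int
    del_start: int
    del_end: int
    genes: list[str]


def cnv_overlap_scan(
    segments_a: list[CNVSegment],
    segments_d: list[CNVSegment],
    homoeolog_map=None,
    min_overlap_fraction: float = 0.5,
    annotation: list[tuple[str, int, int, str]] | None = None,
) -> list[LargeConversionCandidate]:
    """Duplication in one genome reciprocally overlapping a deletion at the
    homoeologous locus of the other genome, in the same accession.

    ``homoeolog_map`` maps (chrom, start, end) intervals from A-reference
    to D-reference coordinates (and is applied to A-genome intervals before
    intersection); ``None`` means colinear references with shared
    coordinates.
    """
    def mapped(iv):
        if homoeolog_map is None:
            return iv
        return homoeolog_map(iv)

    candidates = []
    for dup_genome, dups, dels in (
        ("A", segments_a, segments_d),
        ("D", segments_d, segments_a),
    ):
        for dup in (s for s in dups if s.kind == "duplication"):
            dup_iv = (dup.chrom, dup.start, dup.end)
            if dup_genome == "A":
                m = mapped(dup_iv)
            else:
                m = dup_iv  # map is A->D; D-side intervals stay put
            if m is None:
                continue
            mc, ms, me = m
            for dele in (s for s in dels if s.kind == "deletion"):
                if dele.accession != dup.accession:
                    continue
                d_iv = (dele.chrom, dele.start, dele.end)
                if dup_genome == "D":
                    d_iv = mapped(d_iv)
                    if d_iv is None:
                        continue
                dc, ds, de = d_iv
                if dc != mc:
                    continue
                if reciprocal_overlap((ms, me), (ds, de)) >= \
                        min_overlap_fraction:
                    candidates.append(LargeConversionCandidate(
                        dup.accession, dup_genome, dup.chrom,
                        dup.start, dup.end, dele.start, dele.end,
                        _genes_in(annotation, dup.chrom, dup.start,
                                  dup.end)))
    return candidates


def write_sites_tsv(path, sites: list[ConversionSite]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tspecies\tdirection\toutgroup_status\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.species}\t{s.direction}\t"
                     f"{s.outgroup_status}\n")


def write_regions_bed(path, regions: list[ConversionRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.direction}:{r.species}:n={r.n_sites}\n")
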