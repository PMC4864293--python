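"""Interspecies introgression detection and D-statistic validation.

Diagnostic SNPs are fixed differences between a wild conspecific panel and
a donor-species panel; wild accessions define the native allele so that
introgression already present in cultivars cannot contaminate the index
(the circularity guard). Cultivar reads are then categorized native-like or
donor-like by the same voting rule used for subgenome assignment, and
introgressed regions are maximal intervals where donor-like read depth
stays at or above a threshold (default 10x).

The Patterson D-statistic provides the formal test: over biallelic sites
with a fixed ancestral outgroup allele, D = (nABBA - nBABA) / (nABBA +
nBABA) for the arrangement (((P1, P2), P3), O) with P1 a wild conspecific,
P2 the test cultivar and P3 the donor species. A positive D indicates
excess allele sharing between P2 and P3. The standard error comes from a
delete-one block jackknife over non-overlapping genomic blocks; restricting
the counted sites to predicted introgression regions should drive D toward
1 when the regions are real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homoeoindex import HomoeoSNPIndex
from .snpcall import calls_to_codes
from .conversion import species_consensus


@dataclass
class IntrogressionRegion:
    accession: str
    genome: str
    chrom: str
    start: int
    end: int
    mean_donor_depth: float
    genes: list[str]


def find_diagnostic_snps(
    matrix: pd.DataFrame,
    wild_accessions: list[str],
    donor_accessions: list[str],
    cultivar_accessions: list[str] | None = None,
    subgenome: str = "A",
    consensus: float = 0.75,
    min_covered: float = 0.75,
) -> HomoeoSNPIndex:
    """Fixed wild-vs-donor differences as a (native, donor) index.

    Raises if a known cultivar appears in the wild panel — the wild-only
    rule that keeps the index independent of the accessions being tested.
    """
    if not wild_accessions or not donor_accessions:
        raise ValueError("empty wild or donor panel")
    if cultivar_accessions:
        leaked = set(wild_accessions) & set(cultivar_accessions)
        if leaked:
            raise ValueError(
                f"cultivar accessions in the wild panel: {sorted(leaked)}")
    wild = species_consensus(matrix, wild_accessions, min_covered, consensus)
    donor = species_consensus(matrix, donor_accessions, min_covered,
                              consensus)
    index = HomoeoSNPIndex(labels=("native", "donor"))
    w = calls_to_codes(wild[subgenome].to_numpy())
    d = calls_to_codes(donor[subgenome].to_numpy())
    for i, (chrom, pos) in enumerate(wild.index):
        if w[i] >= 0 and d[i] >= 0 and w[i] != d[i]:
            index.add(chrom, int(pos), int(w[i]), int(d[i]),
                      "diagnostic")
    return index


def categorize_read_origin(alignments, index: HomoeoSNPIndex,
                           phred_floor: int = 20):
    """Label cultivar reads native-like / donor-like by diagnostic voting."""
    from .categorize import polycat_categorize

    if index.labels != ("native", "donor"):
        raise ValueError("expected a (native, donor) diagnostic index")
    return polycat_categorize(alignments, index, phred_floor=phred_floor)


def call_introgressed_regions(
    donor_depth: dict[str, np.ndarray],
    min_depth: float = 10.0,
    min_length: int = 200,
    accession: str = "",
    genome: str = "",
    annotation: list[tuple[str, int, int, str]] | None = None,
) -> list[IntrogressionRegion]:
    """Maximal intervals of donor-like per-base depth >= ``min_depth``.

    ``min_length`` (default two read lengths) suppresses single-read
    islands of spurious donor-like coverage.
    """
    from .conversion import _genes_in

    regions = []
    for chrom, depth in donor_depth.items():
        above = depth >= min_depth
        boundaries = np.flatnonzero(np.diff(
            np.concatenate([[0], above.view(np.int8), [0]])))
        for s, e in boundaries.reshape(-1, 2):
            if e - s >= min_length:
                regions.append(IntrogressionRegion(
                    accession, genome, chrom, int(s), int(e),
                    float(depth[s:e].mean()),
                    _genes_in(annotation, chrom, int(s), int(e))))
    return regions


@dataclass
class DStatResult:
    n_abba: int
    n_baba: int
    d: float
    se: float
    z: float
    block_size: int
    n_blocks: int
    restricted: bool
    undefined: bool = False


def patterson_d(
    p1: dict[str, np.ndarray],
    p2: dict[str, np.ndarray],
    p3: dict[str, np.ndarray],
    outgroup: dict[str, np.ndarray],
    region_mask: dict[str, np.ndarray] | None = None,
    block_size: int = 5000,
) -> DStatResult:
    """ABBA-BABA counts, D, and a delete-one block jackknife SE.

    Inputs are per-chromosome haploid genotype code arrays (-1 = missing).
    A site is counted when all four taxa are called, the outgroup allele is
    taken as ancestral, and the site pattern is ABBA (P2 = P3 != P1, P1
    ancestral) or BABA (P1 = P3 != P2, P2 ancestral). ``region_mask``
    restricts counting to True positions.
    """
    abba_blocks: list[int] = []
    baba_blocks: list[int] = []
    for chrom in p1:
        g1, g2, g3, go = p1[chrom], p2[chrom], p3[chrom], outgroup[chrom]
        ok = (g1 >= 0) & (g2 >= 0) & (g3 >= 0) & (go >= 0)
        if region_mask is not None:
            ok = ok & region_mask[chrom]
        abba = ok & (g2 == g3) & (g2 != g1) & (g1 == go)
        baba = ok & (g1 == g3) & (g1 != g2) & (g2 == go)
        L = g1.shape[0]
        edges = np.arange(0, L, block_size)
        abba_blocks.extend(np.add.reduceat(abba.astype(np.int64), edges))
        baba_blocks.extend(np.add.reduceat(baba.astype(np.int64), edges))
    a = np.asarray(abba_blocks, dtype=np.float64)
    b = np.asarray(baba_blocks, dtype=np.float64)
    n_abba, n_baba = int(a.sum()), int(b.sum())
    total = n_abba + n_baba
    if total == 0:
        warnings.warn("D undefined: no ABBA or BABA sites")
        return DStatResult(0, 0, float("nan"), float("nan"), float("nan"),
                           block_size, len(a), region_mask is not None,
                           undefined=True)
    d = (n_abba - n_baba) / total
    # delete-one jackknife over blocks that carry any informative site
    informative = (a + b) > 0
    ai, bi = a[informative], b[informative]
    nb = ai.shape[0]
    if nb > 1:
        loo = (n_abba - ai - (n_baba - bi)) / (total - ai - bi)
        se = float(np.sqrt((nb - 1) / nb * np.sum((loo - loo.mean()) ** 2)))
    else:
        se = float("nan")
    z = d / se if se and se > 0 else float("nan")
    return DStatResult(n_abba, n_baba, float(d), se, float(z),
                       block_size, nb, region_mask is not None)


def write_regions_bed(path, regions: list[IntrogressionRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.accession}:{r.genome}\t"
                     f"{int(round(r.mean_donor_depth))}\n")


def write_dstat_tsv(path, results: dict[str, DStatResult]) -> None:
    with open(path, "w") as fh:
        fh.write("#test\tnABBA\tnBABA\tD\tSE\tZ\tblocks\trestricted\n")
        for name, r in results.items():
            fh.write(f"{name}\t{r.n_abba}\t{r.n_baba}\t{r.d:.4f}\t"
                     f"{r.se:.4f}\t{r.z:.2f}\t{r.n_blocks}\t"
                     f"{int(r.restricted)}\n")
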