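"""Pileup genotyping, SNP calling, and the pairwise diversity statistic.

Genotype calls are per accession per subgenome. An allele is reported only
with at least ``min_allele_cov`` supporting reads (default 5) and at least
``min_freq`` of the site's total depth (default 30%); sites with no
qualifying allele are missing, one qualifying allele is a homozygous call,
two is heterozygous, and more than two is flagged ambiguous. Because each
subgenome of a highly inbred accession is genotyped as a single haplotype,
heterozygous/ambiguous calls are carried but excluded from consensus and
distance computations.

Genotype matrices are pandas DataFrames indexed by (chrom, pos) with a
(accession, subgenome) column MultiIndex; missing calls are ``"."``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .toymap import AlignmentRecord

MISSING = "."
AMBIGUOUS = "amb"


def base_counts(
    alignments: list[AlignmentRecord],
    chrom_lengths: dict[str, int],
    phred_floor: int = 0,
) -> dict[str, np.ndarray]:
    """Per-base allele counts: a (4, L) matrix per chromosome."""
    counts = {
        chrom: np.zeros((4, L), dtype=np.int32)
        for chrom, L in chrom_lengths.items()
    }
    for rec in alignments:
        if not rec.mapped or rec.ref_id not in counts:
            continue
        codes = rec.query_codes
        pos = np.arange(rec.start, rec.start + codes.shape[0])
        ok = codes < 4
        if phred_floor > 0 and rec.quals is not None:
            ok = ok & (rec.quals >= phred_floor)
        np.add.at(counts[rec.ref_id], (codes[ok], pos[ok]), 1)
    return counts


def genotype_from_counts(
    counts: np.ndarray, min_allele_cov: int = 5, min_freq: float = 0.30
) -> np.ndarray:
    """Vectorized genotype calls from a (4, L) allele-count matrix.

    Returns an array of strings: a base, "X/Y" for heterozygous, "." for
    missing, "amb" for more than two qualifying alleles.
    """
    depth = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, counts / np.maximum(depth, 1), 0.0)
    qual = (counts >= min_allele_cov) & (freq >= min_freq)
    n_alleles = qual.sum(axis=0)
    calls = np.full(counts.shape[1], MISSING, dtype="<U3")
    # homozygous
    hom = n_alleles == 1
    if hom.any():
        allele = qual[:, hom].argmax(axis=0)
        calls[hom] = np.array(list(_seq.BASES))[allele]
    het = n_alleles == 2
    for i in np.flatnonzero(het):
        a, b = np.flatnonzero(qual[:, i])
        calls[i] = f"{_seq.BASES[a]}/{_seq.BASES[b]}"
    calls[n_alleles > 2] = AMBIGUOUS
    return calls


def pileup_genotype(
    alignments: list[AlignmentRecord],
    chrom_lengths: dict[str, int],
    min_allele_cov: int = 5,
    min_freq: float = 0.30,
    phred_floor: int = 0,
) -> dict[str, np.ndarray]:
    """Genotype every position of every chromosome from raw alignments."""
    counts = base_counts(alignments, chrom_lengths, phred_floor)
    return {
        chrom: genotype_from_counts(c, min_allele_cov, min_freq)
        for chrom, c in counts.items()
    }


def genotype_matrix(
    tracks: dict[tuple[str, str], dict[str, np.ndarray]],
    sites: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Assemble per-(accession, subgenome) call tracks into one matrix."""
    index = pd.MultiIndex.from_tuples(
        [(chrom, int(p)) for chrom, pos in sites.items() for p in pos],
        names=["chrom", "pos"],
    )
    data = {}
    for key, track in tracks.items():
        col = []
        for chrom, pos in sites.items():
            col.extend(track[chrom][pos])
        data[key] = col
    df = pd.DataFrame(data, index=index)
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["accession", "subgenome"])
    return df


def calls_to_codes(values: np.ndarray) -> np.ndarray:
    """Map call strings to int codes; missing/het/ambiguous become -1."""
    values = np.asarray(values, dtype="<U3")
    codes = np.full(values.shape, -1, dtype=np.int8)
    for i, b in enumerate(_seq.BASES):
        codes[values == b] = i
    return codes


@dataclass
class SNPRecord:
    chrom: str
    pos: int
    kind: str  # "allele" or "homoeo"
    alleles: tuple[str, ...]
    maf: float


def call_allele_snps(
    matrix: pd.DataFrame,
    group: list[tuple[str, str]],
    maf_filter: float = 0.10,
) -> list[SNPRecord]:
    """Sites polymorphic within one subgenome across accessions.

    The minor allele frequency is computed over non-missing haploid calls
    only; sites below ``maf_filter`` are dropped (the boundary is kept).
    """
    if len(group) < 2:
        raise ValueError("allele-SNP calling needs >= 2 accessions")
    sub = matrix[group].to_numpy()
    codes = calls_to_codes(sub)
    records = []
    index = matrix.index
    counts = np.stack([(codes == b).sum(axis=1) for b in range(4)])
    total = counts.sum(axis=0)
    nmax = counts.max(axis=0)
    poly = (total > 0) & (nmax < total)
    with np.errstate(invalid="ignore"):
        maf = np.where(total > 0, (total - nmax) / np.maximum(total, 1), 0.0)
    keep = poly & (maf >= maf_filter - 1e-12)
    for i in np.flatnonzero(keep):
        chrom, pos = index[i]
        present = np.flatnonzero(counts[:, i] > 0)
        records.append(SNPRecord(
            chrom, int(pos), "allele",
            tuple(_seq.BASES[b] for b in present), float(maf[i])))
    return records


def consensus_allele(
    calls: np.ndarray, agree_frac: float = 0.75
) -> str | None:
    """Majority allele among observed haploid calls, or None.

    Requires at least ``agree_frac`` of the observed (non-missing,
    non-heterozygous) calls to share one allele. With a single observed
    call the only allele trivially reaches 100%, which is the stricter rule
    single-accession species are held to.
    """
    codes = calls_to_codes(np.asarray(calls))
    obs = codes[codes >= 0]
    if obs.size == 0:
        return None
    counts = np.bincount(obs, minlength=4)
    top = counts.argmax()
    if counts[top] / obs.size >= agree_frac - 1e-12:
        return _seq.BASES[top]
    return None


def call_homoeo_snps(
    matrix: pd.DataFrame,
    accessions: list[str],
    consensus: float = 0.75,
) -> list[SNPRecord]:
    """Sites where the two subgenomes of a species disagree consistently.

    A site is a homoeo-SNP iff at least ``consensus`` of the observed
    A-subgenome calls share one allele and at least ``consensus`` of the
    observed D-subgenome calls share a different allele.
    """
    cols_a = [(a, "A") for a in accessions if (a, "A") in matrix.columns]
    cols_d = [(a, "D") for a in accessions if (a, "D") in matrix.columns]
    sub_a = matrix[cols_a].to_numpy()
    sub_d = matrix[cols_d].to_numpy()
    records = []
    for i in range(matrix.shape[0]):
        ca = consensus_allele(sub_a[i], consensus)
        cd = consensus_allele(sub_d[i], consensus)
        if ca is not None and cd is not None and ca != cd:
            chrom, pos = matrix.index[i]
            records.append(SNPRecord(chrom, int(pos), "homoeo",
                                     (ca, cd), float("nan")))
    return records


def diversity(
    matrix: pd.DataFrame, group: list[tuple[str, str]]
) -> float:
    """Mean pairwise difference rate over within-group polymorphic sites.

    For each accession pair, the ratio of differing sites to co-covered
    polymorphic sites; pairs with no co-covered polymorphic site are
    excluded. Polymorphic means >= 2 distinct haploid calls within the
    analyzed group. Returns NaN (with a warning) when no pair is valid.
    """
    if len(group) < 2:
        raise ValueError("diversity needs >= 2 accessions")
    codes = calls_to_codes(matrix[group].to_numpy())
    valid = codes >= 0
    # within-group polymorphism
    poly = np.zeros(codes.shape[0], dtype=bool)
    counts = np.stack([((codes == b) & valid).sum(axis=1) for b in range(4)])
    total = counts.sum(axis=0)
    poly = (total > 0) & (counts.max(axis=0) < total)
    if not poly.any():
        # a uniform group has zero diversity by definition
        return 0.0
    ratios = []
    n = codes.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            co = poly & valid[:, i] & valid[:, j]
            denom = int(co.sum())
            if denom == 0:
                continue
            diff = int((codes[co, i] != codes[co, j]).sum())
            ratios.append(diff / denom)
    if not ratios:
        warnings.warn("diversity undefined: no accession pair shares "
                      "coverage at any polymorphic site")
        return float("nan")
    return float(np.mean(ratios))


def write_vcf(path, records: list[SNPRecord], reference=None) -> None:
    """Minimal VCF for SNP records (1-based POS; kind and MAF in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=KIND,Number=1,Type=String,"
                 'Description="SNP kind: homoeo or allele">\n')
        fh.write("##INFO=<ID=MAF,Number=1,Type=Float,"
                 'Description="Minor allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            ref = r.alleles[0]
            alts = ",".join(r.alleles[1:]) if len(r.alleles) > 1 else "."
            info = f"KIND={r.kind}"
            if not np.isnan(r.maf):
                info += f";MAF={r.maf:.4f}"
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{ref}\t{alts}\t.\tPASS\t{info}\n"
            )


def write_genotype_matrix(path, matrix: pd.DataFrame) -> None:
    out = matrix.copy()
    out.columns = [f"{a}:{s}" for a, s in out.columns]
    out.to_csv(path, sep="\t", na_rep=MISSING)
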