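"""Per-read subgenome assignment.

Two strategies mirror the two established approaches for polyploid read
sorting. Homoeo-SNP voting assigns a read mapped to a single reference by
comparing its bases at indexed homoeo-SNP positions with the allele each
genome carries there; a strict majority of votes decides, ties and reads
spanning no indexed site abstain. Best-of-two-mappings compares the same
read's alignments against the two parental references and picks the genome
with fewer mismatches; equal mismatch counts abstain for determinism. The
voting strategy generalizes to any biallelic index, which is how the same
code categorizes cultivar reads as native-like or donor-like for
introgression detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .toymap import AlignmentRecord

UNCATEGORIZED = None


@dataclass
class CategorizedAlignment:
    record: AlignmentRecord
    label: str | None
    votes_a: int
    votes_b: int


def polycat_categorize(
    alignments: list[AlignmentRecord],
    index,
    phred_floor: int = 20,
) -> list[CategorizedAlignment]:
    """Homoeo-SNP voting over every indexed position a read overlaps.

    A base votes for the genome whose index allele it matches; bases below
    the PHRED floor (when qualities are present) and bases matching neither
    allele do not vote. Strict majority labels the read; ties and
    zero-evidence reads stay uncategorized.
    """
    label_a, label_b = index.labels
    out: list[CategorizedAlignment] = []
    pos_cache: dict[str, np.ndarray] = {}
    for rec in alignments:
        if not rec.mapped:
            out.append(CategorizedAlignment(rec, UNCATEGORIZED, 0, 0))
            continue
        chrom = rec.ref_id
        if chrom not in pos_cache:
            pos_cache[chrom] = index.positions(chrom)
        positions = pos_cache[chrom]
        lo = np.searchsorted(positions, rec.start)
        hi = np.searchsorted(positions, rec.end)
        if hi == lo:
            out.append(CategorizedAlignment(rec, UNCATEGORIZED, 0, 0))
            continue
        span = positions[lo:hi]
        bases = rec.query_codes[span - rec.start]
        ok = np.ones(span.shape[0], dtype=bool)
        if phred_floor > 0 and rec.quals is not None:
            ok = rec.quals[span - rec.start] >= phred_floor
        allele_a, allele_b = index.alleles_at(chrom, span)
        va = int(((bases == allele_a) & ok).sum())
        vb = int(((bases == allele_b) & ok).sum())
        if va > vb:
            label = label_a
        elif vb > va:
            label = label_b
        else:
            label = UNCATEGORIZED
        out.append(CategorizedAlignment(rec, label, va, vb))
    return out


def split_by_label(
    cats: list[CategorizedAlignment],
) -> dict[str, list[AlignmentRecord]]:
    out: dict[str, list[AlignmentRecord]] = {}
    for c in cats:
        if c.label is not None:
            out.setdefault(c.label, []).append(c.record)
    return out


def polydog_categorize(
    aln_a: AlignmentRecord, aln_d: AlignmentRecord,
    labels: tuple[str, str] = ("A", "D"),
) -> str | None:
    """Best-of-two-mappings: the genome with the better (fewer-mismatch)
    alignment wins; mapping to only one reference decides outright."""
    for aln in (aln_a, aln_d):
        if aln.mapped and aln.mismatch_count < 0:
            raise ValueError(
                f"mapped record {aln.read_id} lacks a mismatch count")
    if aln_a.mapped and not aln_d.mapped:
        return labels[0]
    if aln_d.mapped and not aln_a.mapped:
        return labels[1]
    if not aln_a.mapped and not aln_d.mapped:
        return UNCATEGORIZED
    if aln_a.mismatch_count < aln_d.mismatch_count:
        return labels[0]
    if aln_d.mismatch_count < aln_a.mismatch_count:
        return labels[1]
    return UNCATEGORIZED


def polydog_categorize_all(
    alns_a: list[AlignmentRecord],
    alns_d: list[AlignmentRecord],
    labels: tuple[str, str] = ("A", "D"),
) -> dict[str, str | None]:
    """Pair the two mapping runs by read id and categorize each read."""
    by_id_d = {r.read_id: r for r in alns_d}
    out = {}
    for ra in alns_a:
        rd = by_id_d.get(ra.read_id)
        if rd is None:
            rd = AlignmentRecord(ra.read_id, None, -1, "+", None, -1, False)
        out[ra.read_id] = polydog_categorize(ra, rd, labels)
    return out


@dataclass
class CategorizationStats:
    """Error and categorization rates against known read origins."""

    n_reads: int
    n_categorized: int
    n_wrong: int
    undefined: bool = False

    @property
    def error_rate(self) -> float:
        if self.n_categorized == 0:
            return math.nan
        return self.n_wrong / self.n_categorized

    @property
    def categorization_rate(self) -> float:
        if self.n_reads == 0:
            return math.nan
        return self.n_categorized / self.n_reads


def measure_categorization_error(
    labels: dict[str, str | None],
    truth: dict[str, str],
) -> CategorizationStats:
    """Score labels for reads of known single-genome origin.

    A zero-categorized outcome is flagged (``undefined=True``) rather than
    silently reported as a zero error rate.
    """
    n = len(labels)
    n_cat = 0
    n_wrong = 0
    for read_id, label in labels.items():
        if label is None:
            continue
        n_cat += 1
        if label != truth[read_id]:
            n_wrong += 1
    return CategorizationStats(n, n_cat, n_wrong, undefined=(n_cat == 0))


def write_label_table(path, cats: list[CategorizedAlignment]) -> None:
    with open(path, "w") as fh:
        fh.write("#read\tlabel\tvotes_a\tvotes_b\n")
        for c in cats:
            label = c.label if c.label is not None else "uncategorized"
            fh.write(f"{c.record.read_id}\t{label}\t{c.votes_a}\t"
                     f"{c.votes_b}\n")
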