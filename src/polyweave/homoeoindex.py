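"""Homoeo-SNP index construction by iterative map–call–remap.

The index records, for each reference position carrying a fixed difference
between the two parental genomes, the allele on each side. It is built from
diploid reads by an iterative procedure: map the other-genome diploid reads
to the chosen reference, call fixed inter-genome differences at covered
positions, add them to the SNP-tolerant mask, and remap previously unmapped
reads — repeating until no new sites appear. Reads rejected early for
carrying too many divergent alleles are rescued once those alleles are
masked, which in turn exposes further divergence. The same fixpoint loop
then augments the index with tetraploid-specific homoeo-SNPs called from
categorized subgenome reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .reads import Reads
from .snpcall import base_counts, calls_to_codes, consensus_allele
from .toymap import AlignmentRecord, map_reads

Genome = dict[str, np.ndarray]


class ConvergenceError(RuntimeError):
    """Index construction did not reach a fixpoint within the iteration cap."""


class HomoeoSNPIndex:
    """Positions with the allele carried by each of two genome classes.

    ``labels`` names the two classes — ("A", "D") for homoeo-SNPs, or
    ("native", "donor") when the same structure serves as a diagnostic-SNP
    index for introgression. Doubles as the SNP-tolerant mask for mapping
    (via :meth:`positions`).
    """

    def __init__(self, labels: tuple[str, str] = ("A", "D")):
        self.labels = labels
        self._entries: dict[str, dict[int, tuple[int, int, str]]] = {}
        self._pos_cache: dict[str, np.ndarray] = {}
        self.build_iterations: int = 0
        self.build_history: list[int] = []
        # final mapped read sets from the diploid build (coverage reuse)
        self.other_alignments: list = []
        self.own_alignments: list = []

    def add(self, chrom: str, pos: int, allele_a: int, allele_b: int,
            provenance: str = "diploid") -> bool:
        """Add an entry; existing entries are retained (idempotent)."""
        if allele_a == allele_b:
            raise ValueError("index alleles must differ")
        entries = self._entries.setdefault(chrom, {})
        if pos in entries:
            return False
        entries[pos] = (int(allele_a), int(allele_b), provenance)
        self._pos_cache.pop(chrom, None)
        return True

    def positions(self, chrom: str) -> np.ndarray:
        if chrom not in self._pos_cache:
            entries = self._entries.get(chrom, {})
            self._pos_cache[chrom] = np.array(
                sorted(entries), dtype=np.int64)
        return self._pos_cache[chrom]

    def get(self, chrom: str, pos: int) -> tuple[int, int, str] | None:
        return self._entries.get(chrom, {}).get(pos)

    def alleles_at(self, chrom: str, positions: np.ndarray):
        entries = self._entries[chrom]
        a = np.array([entries[int(p)][0] for p in positions], dtype=np.int8)
        b = np.array([entries[int(p)][1] for p in positions], dtype=np.int8)
        return a, b

    def __len__(self) -> int:
        return sum(len(e) for e in self._entries.values())

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        return pos in self._entries.get(chrom, {})

    def items(self):
        for chrom in sorted(self._entries):
            for pos in sorted(self._entries[chrom]):
                yield chrom, pos, self._entries[chrom][pos]

    def subset_by_provenance(self, prefix: str) -> "HomoeoSNPIndex":
        """Entries whose provenance starts with ``prefix`` (e.g. "diploid")."""
        out = HomoeoSNPIndex(self.labels)
        for chrom, pos, (a, b, prov) in self.items():
            if prov.startswith(prefix):
                out.add(chrom, pos, a, b, prov)
        return out

    def swapped(self) -> "HomoeoSNPIndex":
        """Exchange the two allele columns, keeping the labels.

        Categorizing with the swapped index must exchange the two labels
        exactly (the symmetry probe used by the tests).
        """
        out = HomoeoSNPIndex(self.labels)
        for chrom, pos, (a, b, prov) in self.items():
            out.add(chrom, pos, b, a, prov)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tallele_%s\tallele_%s\tprovenance\n"
                     % self.labels)
            for chrom, pos, (a, b, prov) in self.items():
                fh.write(f"{chrom}\t{pos}\t{_seq.BASES[a]}\t"
                         f"{_seq.BASES[b]}\t{prov}\n")

    @classmethod
    def from_tsv(cls, path, labels=("A", "D")) -> "HomoeoSNPIndex":
        idx = cls(labels)
        for line in open(path):
            if line.startswith("#"):
                continue
            chrom, pos, a, b, prov = line.rstrip("\n").split("\t")
            idx.add(chrom, int(pos), _seq.BASES.index(a),
                    _seq.BASES.index(b), prov)
        return idx


@dataclass
class IndexThresholds:
    """Fixed-difference calling thresholds used during index construction."""

    min_allele_cov: int = 5
    purity: float = 0.90  # minimum major-allele fraction per genome
    max_mismatch: int = 3
    max_iter: int = 10


def _fixed_allele(counts: np.ndarray, thr: IndexThresholds):
    """Per-position consensus allele under coverage and purity thresholds.

    Returns (allele_codes, ok_mask): allele is the most covered base; ok
    where it has >= min_allele_cov reads and >= purity of the site depth.
    """
    depth = counts.sum(axis=0)
    allele = counts.argmax(axis=0)
    top = counts.max(axis=0)
    with np.errstate(invalid="ignore"):
        pure = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    ok = (top >= thr.min_allele_cov) & (pure >= thr.purity)
    return allele.astype(np.int8), ok


def build_diploid_index(
    reads_a: Reads,
    reads_d: Reads,
    reference: Genome,
    reference_genome: str = "D",
    thresholds: IndexThresholds | None = None,
) -> HomoeoSNPIndex:
    """Iterate map -> call fixed differences -> remap to a fixpoint index.

    ``reference_genome`` says which parental genome the reference represents;
    reads from the *other* diploid are the divergence witnesses. A position
    enters the index when the other-genome reads support a consensus allele
    different from the reference base while the same-genome reads confirm
    the reference base, both at >= ``min_allele_cov`` reads and >= ``purity``
    allele fraction. Only previously unmapped reads are remapped after the
    mask grows, so the mapped set (and the index) grows monotonically.
    """
    thr = thresholds or IndexThresholds()
    if reference_genome not in ("A", "D"):
        raise ValueError("reference_genome must be 'A' or 'D'")
    other = reads_a if reference_genome == "D" else reads_d
    own = reads_d if reference_genome == "D" else reads_a
    chrom_lengths = {c: int(s.shape[0]) for c, s in reference.items()}

    own_aln = map_reads(own, reference, thr.max_mismatch)
    own_counts = base_counts(own_aln, chrom_lengths)
    own_allele = {}
    own_ok = {}
    for chrom, cts in own_counts.items():
        own_allele[chrom], own_ok[chrom] = _fixed_allele(cts, thr)

    index = HomoeoSNPIndex()
    other_counts = {
        chrom: np.zeros((4, L), dtype=np.int32)
        for chrom, L in chrom_lengths.items()
    }
    pending = other
    accumulated: list[AlignmentRecord] = []
    for iteration in range(1, thr.max_iter + 1):
        new_aln = map_reads(pending, reference, thr.max_mismatch,
                            snp_mask=index if len(index) else None)
        mapped = [r for r in new_aln if r.mapped]
        accumulated.extend(mapped)
        add_counts = base_counts(mapped, chrom_lengths)
        for chrom in other_counts:
            other_counts[chrom] += add_counts[chrom]
        unmapped_idx = np.array(
            [i for i, r in enumerate(new_aln) if not r.mapped], dtype=int)
        pending = pending.subset(unmapped_idx)

        n_new = 0
        for chrom, cts in other_counts.items():
            allele, ok = _fixed_allele(cts, thr)
            ref = reference[chrom]
            cand = ok & own_ok[chrom] & (own_allele[chrom] == ref) \
                & (allele != ref)
            for pos in np.flatnonzero(cand):
                pos = int(pos)
                if (chrom, pos) in index:
                    continue
                if reference_genome == "D":
                    a, d = int(allele[pos]), int(ref[pos])
                else:
                    a, d = int(ref[pos]), int(allele[pos])
                index.add(chrom, pos, a, d, "diploid")
                n_new += 1
        index.build_history.append(n_new)
        index.build_iterations = iteration
        if n_new == 0:
            # keep the final alignment sets for downstream coverage use
            index.other_alignments = accumulated
            index.own_alignments = [r for r in own_aln if r.mapped]
            return index
    raise ConvergenceError(
        f"no fixpoint after {thr.max_iter} iterations; "
        f"last pass added {index.build_history[-1]} sites"
    )


def augment_index_with_tetraploid(
    index: HomoeoSNPIndex,
    alignments_by_accession: dict[str, list[AlignmentRecord]],
    species: str,
    chrom_lengths: dict[str, int],
    consensus: float = 0.75,
    thresholds: IndexThresholds | None = None,
    phred_floor: int = 20,
) -> HomoeoSNPIndex:
    """Add tetraploid-specific homoeo-SNPs for one species, to a fixpoint.

    Each pass categorizes the species' mapped reads with the current index,
    genotypes each accession's subgenomes, and adds sites where at least
    ``consensus`` (75%) of observed per-accession calls carry one allele in
    one subgenome and a different allele in the other. Species with a single
    accession are automatically held to a 100% threshold, since one observed
    call must agree with itself. The loop repeats until no site is added.
    """
    from .categorize import polycat_categorize, split_by_label
    from .snpcall import genotype_from_counts

    thr = thresholds or IndexThresholds()
    if not alignments_by_accession:
        raise ValueError(f"no alignments supplied for species {species!r}")
    for iteration in range(1, thr.max_iter + 1):
        calls: dict[str, dict[str, list[np.ndarray]]] = {
            "A": {c: [] for c in chrom_lengths},
            "D": {c: [] for c in chrom_lengths},
        }
        for acc, alignments in alignments_by_accession.items():
            cats = polycat_categorize(alignments, index,
                                      phred_floor=phred_floor)
            by_label = split_by_label(cats)
            for sub in ("A", "D"):
                counts = base_counts(by_label.get(sub, []), chrom_lengths)
                for chrom, cts in counts.items():
                    calls[sub][chrom].append(
                        genotype_from_counts(cts, thr.min_allele_cov))
        n_new = 0
        for chrom, L in chrom_lengths.items():
            codes_a = calls_to_codes(np.stack(calls["A"][chrom]))
            codes_d = calls_to_codes(np.stack(calls["D"][chrom]))
            cons_a, ok_a = _matrix_consensus(codes_a, consensus)
            cons_d, ok_d = _matrix_consensus(codes_d, consensus)
            cand = ok_a & ok_d & (cons_a != cons_d)
            for pos in np.flatnonzero(cand):
                pos = int(pos)
                if (chrom, pos) in index:
                    continue
                index.add(chrom, pos, int(cons_a[pos]), int(cons_d[pos]),
                          f"tetraploid:{species}")
                n_new += 1
        index.build_history.append(n_new)
        if n_new == 0:
            return index
    raise ConvergenceError(
        f"tetraploid augmentation for {species} did not converge in "
        f"{thr.max_iter} iterations"
    )


def _matrix_consensus(codes: np.ndarray, frac: float):
    """Column-wise consensus of an (n_accessions, L) call-code matrix."""
    valid = codes >= 0
    counts = np.stack([((codes == b) & valid).sum(axis=0) for b in range(4)])
    total = counts.sum(axis=0)
    top = counts.max(axis=0)
    allele = counts.argmax(axis=0).astype(np.int8)
    with np.errstate(invalid="ignore"):
        ok = (total > 0) & (top / np.maximum(total, 1) >= frac - 1e-12)
    return allele, ok
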