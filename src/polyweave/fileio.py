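"""Reading and writing of the standard flat-file formats.

FASTA/FASTQ go through Biopython; BED, bedGraph, PHYLIP and the tab-separated
index/ledger formats are simple columnar writers. All genomic intervals are
0-based half-open on disk except where a format mandates 1-based (SAM, VCF).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from .reads import Reads

Genome = Mapping[str, np.ndarray]  # chrom -> coded sequence


def write_fasta(path: str | Path, genome: Genome) -> None:
    records = [
        SeqRecord(Seq(_seq.decode(codes)), id=chrom, description="")
        for chrom, codes in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    return {
        rec.id: _seq.encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fastq(path: str | Path, reads: Reads) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(reads.names):
            seq = _seq.decode(reads.codes[i])
            if reads.quals is None:
                qual = "I" * len(seq)  # PHRED 40
            else:
                qual = "".join(chr(q + 33) for q in reads.quals[i])
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Reads:
    names: list[str] = []
    seqs: list[str] = []
    quals: list[list[int]] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
        quals.append(rec.letter_annotations["phred_quality"])
    reads = Reads.from_sequences(names, seqs)
    reads.quals = np.asarray(quals, dtype=np.int16)
    return reads


def write_bed(
    path: str | Path,
    intervals: Iterable[tuple],
) -> None:
    """Write (chrom, start, end, name[, score]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    for line in open(path):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        name = f[3] if len(f) > 3 else "."
        out.append((f[0], int(f[1]), int(f[2]), name))
    return out


def write_bedgraph(path: str | Path, profile) -> None:
    """Serialize a windowed coverage profile as bedGraph."""
    with open(path, "w") as fh:
        for chrom, values in profile.values.items():
            ws = profile.window_size
            length = profile.chrom_lengths[chrom]
            for w, v in enumerate(values):
                fh.write(
                    f"{chrom}\t{w * ws}\t{min((w + 1) * ws, length)}\t{v:.4f}\n"
                )


def write_phylip(path: str | Path, taxa: list[str], matrix: np.ndarray) -> None:
    """Distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for i, t in enumerate(taxa):
            row = " ".join(f"{matrix[i, j]:.6f}" for j in range(len(taxa)))
            fh.write(f"{t[:10]:<10} {row}\n")
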