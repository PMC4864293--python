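"""Depth-of-coverage copy-number analysis against a diploid reference profile.

The tetraploid sample's windowed coverage (from categorized reads) is
compared with a pooled diploid coverage profile of the matching genome,
which absorbs locus-specific coverage biases shared between diploid and
tetraploid carriers of that genome. After median normalization the
per-window log2 ratio is segmented by simple thresholding: maximal runs of
at least ``min_windows`` consecutive windows at log2 >= +1.0 are
duplications, at log2 <= -1.0 deletions (a minimum 2-fold difference either
way). Windows whose reference depth falls below a quarter of the reference
median are treated as inaccessible and break runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .toymap import AlignmentRecord


@dataclass
class CoverageProfile:
    """Mean per-base depth in non-overlapping windows tiling each chromosome."""

    window_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]

    def scaled(self, factor: float) -> "CoverageProfile":
        return CoverageProfile(
            self.window_size, self.chrom_lengths,
            {c: v * factor for c, v in self.values.items()})

    def median(self) -> float:
        allv = np.concatenate(list(self.values.values()))
        return float(np.median(allv))


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    kind: str  # "duplication" or "deletion"
    mean_log2: float
    accession: str = ""
    genome: str = ""


def per_base_depth(
    alignments: list[AlignmentRecord], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Exact per-base depth via boundary differences."""
    diff = {c: np.zeros(L + 1, dtype=np.int64)
            for c, L in chrom_lengths.items()}
    for rec in alignments:
        if not rec.mapped or rec.ref_id not in diff:
            continue
        diff[rec.ref_id][rec.start] += 1
        diff[rec.ref_id][min(rec.end, chrom_lengths[rec.ref_id])] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diff.items()}


def coverage_profile(
    alignments: list[AlignmentRecord],
    chrom_lengths: dict[str, int],
    window_size: int,
) -> CoverageProfile:
    """Windowed mean depth; the tiling covers every base exactly once."""
    if window_size < 50:
        raise ValueError("window_size must be >= 50")
    depth = per_base_depth(alignments, chrom_lengths)
    if all(int(d.sum()) == 0 for d in depth.values()):
        warnings.warn("no mapped alignments: all-zero coverage profile")
    values = {}
    for chrom, d in depth.items():
        L = chrom_lengths[chrom]
        n_win = (L + window_size - 1) // window_size
        sums = np.add.reduceat(d, np.arange(0, L, window_size))
        sizes = np.full(n_win, window_size, dtype=float)
        if L % window_size:
            sizes[-1] = L % window_size
        values[chrom] = sums / sizes
    return CoverageProfile(window_size, dict(chrom_lengths), values)


def log2_ratio_segments(
    sample: CoverageProfile,
    diploid_ref: CoverageProfile,
    dup_thr: float = 1.0,
    del_thr: float = -1.0,
    min_windows: int = 3,
    margin: float = 0.0,
    eps: float = 0.5,
    ratio_floor: float = -8.0,
    accessible_frac: float = 0.25,
    accession: str = "",
    genome: str = "",
) -> list[CNVSegment]:
    """Threshold-run segmentation of the normalized log2 copy ratio.

    ``margin`` widens the window-qualification band to ``dup_thr - margin``
    / ``del_thr + margin``. A single extra copy doubles coverage exactly, so
    its expected log2 ratio sits exactly on the +1.0 call boundary and
    window-level sampling noise (about 0.25 at 20x coverage with 500 bp
    windows) would otherwise disqualify roughly half the windows of a true
    event; callers hunting exactly-2-fold events (the conversion overlap
    scan) pass a margin of about one window-level standard error.
    """
    if sample.window_size != diploid_ref.window_size or \
            sample.chrom_lengths != diploid_ref.chrom_lengths:
        raise ValueError("sample and reference profiles are not comparable")
    ref_med = diploid_ref.median()
    if ref_med <= 0:
        raise ValueError("all-zero diploid reference profile")
    samp_med = sample.median()
    scale = samp_med / ref_med if samp_med > 0 else 1.0
    segments: list[CNVSegment] = []
    for chrom, s in sample.values.items():
        r = diploid_ref.values[chrom] * scale
        accessible = diploid_ref.values[chrom] >= accessible_frac * ref_med
        ratio = np.log2((s + eps) / (r + eps))
        ratio = np.maximum(ratio, ratio_floor)
        for kind, qual in (
            ("duplication", (ratio >= dup_thr - margin) & accessible),
            ("deletion", (ratio <= del_thr + margin) & accessible),
        ):
            segments.extend(
                _runs_to_segments(qual, ratio, chrom,
                                  sample.window_size,
                                  sample.chrom_lengths[chrom],
                                  kind, min_windows, accession, genome))
    return segments


def _runs_to_segments(qual, ratio, chrom, window_size, chrom_len, kind,
                      min_windows, accession, genome):
    out = []
    n = qual.shape[0]
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j < n and qual[j]:
            j += 1
        if j - i >= min_windows:
            out.append(CNVSegment(
                chrom,
                i * window_size,
                min(j * window_size, chrom_len),
                kind,
                float(ratio[i:j].mean()),
                accession,
                genome,
            ))
        i = j
    return out


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the longer interval (min of the two
    one-way fractions)."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0], b[1] - b[0])


@dataclass
class ConservedBlock:
    chrom: str
    start: int
    end: int
    kind: str
    accessions: list[str]


def cnv_conservation(
    segments: list[CNVSegment], min_overlap_fraction: float = 0.5
) -> list[ConservedBlock]:
    """Cluster same-class segments across accessions by reciprocal overlap.

    Single-linkage union-find over pairs with >= ``min_overlap_fraction``
    reciprocal overlap; each block reports its member accessions.
    """
    accs = {s.accession for s in segments}
    if len(accs) < 2:
        warnings.warn("cnv_conservation with fewer than 2 accessions")
    n = len(segments)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = segments[i], segments[j]
            if a.kind != b.kind or a.chrom != b.chrom:
                continue
            if reciprocal_overlap((a.start, a.end), (b.start, b.end)) >= \
                    min_overlap_fraction:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    blocks = []
    for members in groups.values():
        segs = [segments[i] for i in members]
        blocks.append(ConservedBlock(
            segs[0].chrom,
            min(s.start for s in segs),
            max(s.end for s in segs),
            segs[0].kind,
            sorted({s.accession for s in segs}),
        ))
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def write_segments_bed(path, segments: list[CNVSegment]) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.kind}\t"
                     f"{int(round(s.mean_log2 * 100))}\n")
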