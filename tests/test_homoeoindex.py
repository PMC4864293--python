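import numpy as np
import pytest

from conftest import genome_of
from polyweave import _seq
from polyweave.homoeoindex import (
    ConvergenceError,
    HomoeoSNPIndex,
    IndexThresholds,
    augment_index_with_tetraploid,
    build_diploid_index,
)
from polyweave.reads import Reads
from polyweave.toymap import AlignmentRecord


def _reads_from(genome: np.ndarray, windows, copies, prefix):
    """Tiled error-free reads over [start, end) windows."""
    seqs = []
    names = []
    for n, (s, e) in enumerate(windows):
        for c in range(copies):
            names.append(f"{prefix}_{n}_{c}")
            seqs.append(genome[s:e])
    return Reads(names, np.stack(seqs))


class TestDiploidBuild:
    def test_identical_progenitors_give_empty_index(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 4, 60).astype(np.uint8)
        windows = [(0, 30), (15, 45), (30, 60)]
        reads = _reads_from(ref, windows, 6, "x")
        idx = build_diploid_index(reads, reads, {"chr1": ref}, "D")
        assert len(idx) == 0
        assert idx.build_iterations == 1

    def test_single_divergent_site_found_and_converged(self):
        rng = np.random.default_rng(1)
        ref = rng.integers(0, 4, 60).astype(np.uint8)
        genome_a = ref.copy()
        genome_a[10] = (genome_a[10] + 1) % 4
        windows = [(0, 30), (15, 45), (30, 60)]
        reads_a = _reads_from(genome_a, windows, 6, "a")
        reads_d = _reads_from(ref, windows, 6, "d")
        idx = build_diploid_index(reads_a, reads_d, {"chr1": ref}, "D")
        assert [(c, p) for c, p, _ in idx.items()] == [("chr1", 10)]
        a, d, prov = idx.get("chr1", 10)
        assert a == genome_a[10] and d == ref[10] and prov == "diploid"
        assert idx.build_history[-1] == 0  # converged by a no-change pass

    def test_masking_rescues_read_and_reveals_further_snp(self):
        # divergent sites at 10, 35, 45; reads [30,60) carry two of them
        # and exceed max_mismatch=1 until 35 is masked in a later pass
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 4, 60).astype(np.uint8)
        genome_a = ref.copy()
        for p in (10, 35, 45):
            genome_a[p] = (genome_a[p] + 1) % 4
        windows = [(0, 30), (15, 45), (30, 60)]
        reads_a = _reads_from(genome_a, windows, 6, "a")
        reads_d = _reads_from(ref, windows, 6, "d")
        thr = IndexThresholds(max_mismatch=1)
        idx = build_diploid_index(reads_a, reads_d, {"chr1": ref}, "D", thr)
        assert {p for _, p, _ in idx.items()} == {10, 35, 45}
        # 45 requires the rescue pass: history shows >1 productive pass
        assert len([h for h in idx.build_history if h > 0]) >= 2

    def test_nonconvergence_raises_with_cap(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 4, 60).astype(np.uint8)
        genome_a = ref.copy()
        for p in (10, 35, 45):
            genome_a[p] = (genome_a[p] + 1) % 4
        windows = [(0, 30), (15, 45), (30, 60)]
        reads_a = _reads_from(genome_a, windows, 6, "a")
        reads_d = _reads_from(ref, windows, 6, "d")
        thr = IndexThresholds(max_mismatch=1, max_iter=1)
        with pytest.raises(ConvergenceError):
            build_diploid_index(reads_a, reads_d, {"chr1": ref}, "D", thr)


def _alignment(name, start, codes):
    return AlignmentRecord(name, "chr1", start, "+",
                           np.asarray(codes, dtype=np.uint8),
                           0, True)


class TestTetraploidAugment:
    def _panel(self, ref, n_accessions, at_base, dt_base, site,
               discordant=()):
        """Accessions whose reads split into subgenomes at index site 5 and
        disagree between subgenomes at ``site``."""
        aln = {}
        for i in range(n_accessions):
            reads = []
            for c in range(6):
                a_read = ref.copy()
                a_read[5] = 0 if (0 != ref[5]) else 1  # A allele at site 5
                a_read[site] = at_base
                reads.append(_alignment(f"acc{i}_a{c}", 0, a_read))
                d_read = ref.copy()
                d_base = dt_base if i not in discordant else at_base
                d_read[site] = d_base
                reads.append(_alignment(f"acc{i}_d{c}", 0, d_read))
            aln[f"acc{i}"] = reads
        return aln

    def _base_index(self, ref):
        idx = HomoeoSNPIndex()
        a_allele = 0 if ref[5] != 0 else 1
        idx.add("chr1", 5, a_allele, int(ref[5]), "diploid")
        return idx

    def test_consistent_site_added_with_provenance(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 4, 40).astype(np.uint8)
        at, dt = (2, 3) if ref[20] not in (2, 3) else (0, 1)
        aln = self._panel(ref, 4, at, dt, site=20)
        idx = self._base_index(ref)
        augment_index_with_tetraploid(idx, aln, "AD1",
                                      {"chr1": 40})
        entry = idx.get("chr1", 20)
        assert entry is not None
        assert entry[:2] == (at, dt)
        assert entry[2] == "tetraploid:AD1"

    def test_three_quarters_rule(self):
        # 3 of 4 accessions concordant (75%) passes; 2 of 4 does not
        rng = np.random.default_rng(5)
        ref = rng.integers(0, 4, 40).astype(np.uint8)
        at, dt = (2, 3) if ref[20] not in (2, 3) else (0, 1)
        ok = self._panel(ref, 4, at, dt, site=20, discordant=(3,))
        idx = self._base_index(ref)
        augment_index_with_tetraploid(idx, ok, "AD1", {"chr1": 40})
        assert idx.get("chr1", 20) is not None

        bad = self._panel(ref, 4, at, dt, site=20, discordant=(2, 3))
        idx2 = self._base_index(ref)
        augment_index_with_tetraploid(idx2, bad, "AD1", {"chr1": 40})
        assert idx2.get("chr1", 20) is None

    def test_existing_entry_keeps_diploid_provenance(self):
        rng = np.random.default_rng(6)
        ref = rng.integers(0, 4, 40).astype(np.uint8)
        at, dt = (2, 3) if ref[20] not in (2, 3) else (0, 1)
        aln = self._panel(ref, 2, at, dt, site=20)
        idx = self._base_index(ref)
        idx.add("chr1", 20, at, dt, "diploid")
        augment_index_with_tetraploid(idx, aln, "AD1", {"chr1": 40})
        assert idx.get("chr1", 20)[2] == "diploid"


class TestIndexContainer:
    def test_equal_alleles_rejected(self):
        idx = HomoeoSNPIndex()
        with pytest.raises(ValueError):
            idx.add("chr1", 0, 2, 2)

    def test_tsv_round_trip(self, tmp_path):
        idx = HomoeoSNPIndex()
        idx.add("chr1", 3, 0, 2, "diploid")
        idx.add("chr1", 9, 1, 3, "tetraploid:AD2")
        idx.add("chr2", 1, 2, 0, "diploid")
        path = tmp_path / "idx.tsv"
        idx.to_tsv(path)
        back = HomoeoSNPIndex.from_tsv(path)
        assert list(back.items()) == list(idx.items())

    def test_swapped_exchanges_alleles(self):
        idx = HomoeoSNPIndex()
        idx.add("chr1", 3, 0, 2)
        sw = idx.swapped()
        assert sw.get("chr1", 3)[:2] == (2, 0)
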