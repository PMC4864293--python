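"""In-memory container for short sequencing reads."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq


@dataclass
class Reads:
    """A batch of equal-length single-end reads.

    ``codes`` is an ``(n_reads, read_length)`` uint8 matrix of base codes.
    ``quals`` holds PHRED scores with the same shape; the simulator emits a
    constant Q40, real FASTQ input carries whatever the file says.
    """

    names: list[str]
    codes: np.ndarray
    quals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.atleast_2d(np.asarray(self.codes, dtype=np.uint8))
        if self.quals is not None:
            self.quals = np.atleast_2d(np.asarray(self.quals))

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        return _seq.decode(self.codes[i])

    def subset(self, idx: np.ndarray) -> "Reads":
        idx = np.asarray(idx)
        return Reads(
            [self.names[i] for i in idx],
            self.codes[idx],
            None if self.quals is None else self.quals[idx],
        )

    @classmethod
    def from_sequences(cls, names: list[str], seqs: list[str]) -> "Reads":
        codes = np.stack([_seq.encode(s) for s in seqs])
        return cls(names, codes)

    @classmethod
    def concat(cls, batches: list["Reads"]) -> "Reads":
        names = [n for b in batches for n in b.names]
        codes = np.concatenate([b.codes for b in batches], axis=0)
        quals = None
        if all(b.quals is not None for b in batches):
            quals = np.concatenate([b.quals for b in batches], axis=0)
        return cls(names, codes, quals)
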