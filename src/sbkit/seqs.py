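"""Sequence containers shared by the simulator and the tree-building stages.

Bases are stored as uint8 codes: A=0, C=1, G=2, T=3, N=4 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


@dataclass
class GeneAlignment:
    """Equal-length per-sample sequences for one gene."""

    gene_id: str
    labels: list
    seqs: np.ndarray  # (n_samples, length) uint8 codes

    def __post_init__(self):
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.labels):
            raise ValueError("sequence matrix does not match label list")

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, label: str) -> str:
        return decode(self.seqs[self.labels.index(label)])

    def subset(self, labels) -> "GeneAlignment":
        idx = [self.labels.index(l) for l in labels]
        return GeneAlignment(self.gene_id, list(labels), self.seqs[idx])

    def to_fasta(self) -> str:
        out = []
        for lab, row in zip(self.labels, self.seqs):
            out.append(f">{lab}\n{decode(row)}\n")
        return "".join(out)

    @classmethod
    def concatenate(cls, alignments, gene_id="concat"):
        first = alignments[0]
        for aln in alignments[1:]:
            if aln.labels != first.labels:
                raise ValueError("alignments have inconsistent sample sets")
        return cls(
            gene_id,
            list(first.labels),
            np.concatenate([a.seqs for a in alignments], axis=1),
        )


@dataclass
class SiteRecord:
    """One infinite-sites mutation: biallelic by construction."""

    position: int  # 1-based within the gene
    ancestral: int  # base code
    derived: int  # base code
    carriers: np.ndarray = field(repr=False)  # bool mask over alignment rows
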