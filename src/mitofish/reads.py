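"""Paired-read container shared by the simulator and the assembly stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from . import seqio

__all__ = ["ReadSet"]


@dataclass
class ReadSet:
    """Paired reads with qualities and library metadata.

    Mates share a fragment id; a pair is always kept or dropped as a unit.
    Qualities are Phred+33 strings of the same length as their read.
    """

    ids: list[str] = field(default_factory=list)
    seq1: list[str] = field(default_factory=list)
    qual1: list[str] = field(default_factory=list)
    seq2: list[str] = field(default_factory=list)
    qual2: list[str] = field(default_factory=list)
    read_length: int = 250
    insert_range: tuple[int, int] = (400, 800)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("seq1", "qual1", "seq2", "qual2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"ReadSet field {name} length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def pair(self, i: int) -> tuple[str, str, str, str, str]:
        return self.ids[i], self.seq1[i], self.qual1[i], self.seq2[i], self.qual2[i]

    def iter_pairs(self) -> Iterator[tuple[str, str, str, str, str]]:
        for i in range(len(self)):
            yield self.pair(i)

    def all_sequences(self) -> list[str]:
        """Both mates flattened: ``[r1_0, r1_1, ..., r2_0, r2_1, ...]``."""
        return self.seq1 + self.seq2

    def subset(self, indices: Sequence[int]) -> "ReadSet":
        return ReadSet(
            ids=[self.ids[i] for i in indices],
            seq1=[self.seq1[i] for i in indices],
            qual1=[self.qual1[i] for i in indices],
            seq2=[self.seq2[i] for i in indices],
            qual2=[self.qual2[i] for i in indices],
            read_length=self.read_length,
            insert_range=self.insert_range,
        )

    def extend(self, other: "ReadSet") -> None:
        self.ids.extend(other.ids)
        self.seq1.extend(other.seq1)
        self.qual1.extend(other.qual1)
        self.seq2.extend(other.seq2)
        self.qual2.extend(other.qual2)

    # -- I/O ---------------------------------------------------------------

    def write(self, path1: str | Path, path2: str | Path) -> None:
        seqio.write_fastq_pairs(path1, path2, self.iter_pairs())

    @classmethod
    def read(
        cls,
        path1: str | Path,
        path2: str | Path,
        read_length: int | None = None,
        insert_range: tuple[int, int] = (400, 800),
    ) -> "ReadSet":
        pairs = seqio.read_fastq_pairs(path1, path2)
        rs = cls(
            ids=[p[0] for p in pairs],
            seq1=[p[1] for p in pairs],
            qual1=[p[2] for p in pairs],
            seq2=[p[3] for p in pairs],
            qual2=[p[4] for p in pairs],
            read_length=read_length
            or (max(len(p[1]) for p in pairs) if pairs else 250),
            insert_range=insert_range,
        )
        return rs
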