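"""Sequence records, circular coordinates, translation, and file I/O.

Conventions used throughout the package:

* All intervals are 0-based, half-open, on the forward strand.
* Circular coordinates are normalized to ``[0, L)``; an exon whose end is
  numerically smaller than its start on a circular record wraps the origin.
* Mitochondrial protein-coding genes are translated with the "Mold,
  Protozoan, and Coelenterate" genetic code (NCBI translation table 4,
  TGA = Trp), the code used by placozoan mitochondria.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.Data import CodonTable

__all__ = [
    "SequenceRecord",
    "Feature",
    "AnnotatedGenome",
    "TranslationError",
    "InternalStopError",
    "revcomp",
    "translate_cds",
    "extract_feature",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_feature_table",
    "write_feature_table",
    "write_gff3",
]

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Accepted CDS start codons for mitochondrial ORF validation.  ATG is
#: canonical; GTG initiation is common in invertebrate mtDNA.
DEFAULT_START_CODONS = ("ATG", "GTG")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_map(table: int) -> tuple[dict[str, str], set[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    return dict(tbl.forward_table), set(tbl.stop_codons)


_CODON_CACHE: dict[int, tuple[dict[str, str], set[str]]] = {
    1: _codon_map(1),
    4: _codon_map(4),
}


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated."""


class InternalStopError(TranslationError):
    """Raised when a CDS contains a premature stop codon.

    Attributes
    ----------
    codon_index : 0-based index of the offending codon.
    """

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(f"internal stop codon {codon!r} at codon {codon_index}")


def translate_cds(dna: str, table: int = 4) -> str:
    """Translate an in-frame CDS, stripping a terminal stop if present.

    Parameters
    ----------
    dna : in-frame coding sequence (length divisible by 3).
    table : NCBI translation table, 1 (standard) or 4 (mold/protozoan/
        coelenterate mitochondrial; TGA = Trp).

    Codons containing N translate to ``X``.  A terminal stop codon is
    stripped; an internal stop raises :class:`InternalStopError` carrying
    the codon position.
    """
    if table not in _CODON_CACHE:
        raise ValueError(f"unsupported translation table {table}")
    if len(dna) % 3 != 0:
        raise TranslationError(f"CDS length {len(dna)} not divisible by 3")
    fwd, stops = _CODON_CACHE[table]
    dna = dna.upper()
    n_codons = len(dna) // 3
    out = []
    for i in range(n_codons):
        codon = dna[3 * i : 3 * i + 3]
        if codon in stops:
            if i == n_codons - 1:
                break  # terminal stop, stripped
            raise InternalStopError(i, codon)
        aa = fwd.get(codon)
        out.append(aa if aa is not None else "X")
    return "".join(out)


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally circular."""

    id: str
    seq: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: illegal characters {sorted(bad)}")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; wraps the origin on circular records.

        A wrapping interval may be given either with ``end < start``
        (both in ``[0, L)``) or with ``end > L``.
        """
        L = len(self.seq)
        if 0 <= start <= end <= L:
            return self.seq[start:end]
        if not self.circular:
            raise ValueError(
                f"interval [{start},{end}) outside linear record {self.id!r}"
            )
        start %= L
        if end > L:
            end -= L
        if start <= end:  # normalization resolved the wrap
            return self.seq[start:end]
        return self.seq[start:] + self.seq[:end]


@dataclass
class Feature:
    """A strand-aware, possibly multi-exon gene model.

    ``exons`` are ordered 0-based half-open intervals in transcription
    order on the forward-strand coordinate system; for minus-strand
    features the first listed exon is the 5'-most exon of the transcript
    (i.e. the interval with the largest forward coordinate).
    """

    name: str
    kind: str  # CDS | rRNA | tRNA | ORF
    exons: list[tuple[int, int]]
    strand: str = "+"
    transl_table: int = 4

    KINDS = ("CDS", "rRNA", "tRNA", "ORF")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name!r}: no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]

    def span_length(self, genome_length: int) -> int:
        total = 0
        for s, e in self.exons:
            total += (e - s) if e > s else (genome_length - s + e)
        return total

    @property
    def start(self) -> int:
        """Forward-strand coordinate of the first listed exon's start."""
        return self.exons[0][0]


@dataclass
class AnnotatedGenome:
    """A sequence record plus its gene models."""

    record: SequenceRecord
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.record)
        seen = set()
        for f in self.features:
            key = (f.name, f.kind)
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)
            for s, e in f.exons:
                if not (0 <= s < L) or not (0 < e <= L):
                    if not self.record.circular:
                        raise ValueError(
                            f"feature {f.name!r}: exon ({s},{e}) outside [0,{L})"
                        )

    @property
    def id(self) -> str:
        return self.record.id

    def get(self, name: str) -> Feature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def feature_order(self) -> list[Feature]:
        """Features sorted by forward-strand start of their first exon."""
        return sorted(self.features, key=lambda f: min(s for s, _ in f.exons))


def extract_feature(genome: AnnotatedGenome, feature: Feature) -> str:
    """Spliced feature sequence: exons concatenated in transcript order,
    reverse-complemented for minus-strand features.  Origin-spanning exons
    on circular records are handled transparently."""
    parts = [genome.record.fetch(s, e) for s, e in feature.exons]
    if feature.strand == "+":
        return "".join(parts)
    return "".join(revcomp(p) for p in parts)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, circular: bool = False) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    name = None
    desc = ""
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(
                        SequenceRecord(name, "".join(chunks), circular, desc)
                    )
                head = line[1:].split(None, 1)
                name = head[0]
                desc = head[1] if len(head) > 1 else ""
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            records.append(SequenceRecord(name, "".join(chunks), circular, desc))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record ids in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline().rstrip()
            plus = fh.readline()
            qual = fh.readline().rstrip()
            if not head.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {head!r} in {path}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record {head.strip()!r}: sequence length {len(seq)} "
                    f"!= quality length {len(qual)}"
                )
            yield head[1:].split()[0], seq, qual


def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> list[tuple[str, str, str, str, str]]:
    """Read two synchronized FASTQ files.

    Returns a list of ``(fragment_id, seq1, qual1, seq2, qual2)``.  Mate ids
    must agree after stripping a trailing ``/1`` / ``/2``.
    """
    out = []
    it2 = _iter_fastq(path2)
    for name1, s1, q1 in _iter_fastq(path1):
        try:
            name2, s2, q2 = next(it2)
        except StopIteration:
            raise ValueError("pair files desynchronized: second file shorter")
        base1 = name1.rsplit("/", 1)[0]
        base2 = name2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"pair files desynchronized at {name1!r} vs {name2!r}")
        out.append((base1, s1, q1, s2, q2))
    try:
        next(it2)
    except StopIteration:
        pass
    else:
        raise ValueError("pair files desynchronized: second file longer")
    return out


def write_fastq_pairs(
    path1: str | Path,
    path2: str | Path,
    pairs: Iterable[tuple[str, str, str, str, str]],
) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for name, s1, q1, s2, q2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# Feature tables and GFF3
# ---------------------------------------------------------------------------

_TABLE_HEADER = "genome_id\tname\tkind\tstrand\texons\ttransl_table"


def write_feature_table(path: str | Path, genomes: Sequence[AnnotatedGenome]) -> None:
    """Tab-separated annotation table; exons serialized as ``s-e,s-e,...``."""
    with _open_text(path, "wt") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for g in genomes:
            for f in g.features:
                exons = ",".join(f"{s}-{e}" for s, e in f.exons)
                fh.write(
                    f"{g.id}\t{f.name}\t{f.kind}\t{f.strand}\t{exons}\t{f.transl_table}\n"
                )


def read_feature_table(
    path: str | Path, records: Sequence[SequenceRecord]
) -> list[AnnotatedGenome]:
    by_id = {r.id: r for r in records}
    feats: dict[str, list[Feature]] = {r.id: [] for r in records}
    with _open_text(path) as fh:
        header = fh.readline()
        if header.rstrip("\n") != _TABLE_HEADER:
            raise ValueError(f"unexpected feature-table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            gid, name, kind, strand, exons_s, table = line.rstrip("\n").split("\t")
            if gid not in by_id:
                raise ValueError(f"feature table references unknown genome {gid!r}")
            exons = [
                (int(p.split("-")[0]), int(p.split("-")[1]))
                for p in exons_s.split(",")
            ]
            feats[gid].append(Feature(name, kind, exons, strand, int(table)))
    return [AnnotatedGenome(by_id[r.id], feats[r.id]) for r in records]


_GFF_TYPE = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "ORF": "ORF"}


def write_gff3(path: str | Path, genomes: Sequence[AnnotatedGenome]) -> None:
    """GFF3 export (1-based inclusive coordinates, one row per exon)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            L = len(g.record)
            fh.write(f"##sequence-region {g.id} 1 {L}\n")
            for f in g.feature_order():
                for i, (s, e) in enumerate(f.exons):
                    if e <= s:  # origin-spanning exon: split at the origin
                        intervals = [(s, L), (0, e)]
                    else:
                        intervals = [(s, e)]
                    for s2, e2 in intervals:
                        attrs = f"ID={f.name};Name={f.name};exon={i + 1}"
                        fh.write(
                            f"{g.id}\tmitofish\t{_GFF_TYPE[f.kind]}\t{s2 + 1}\t{e2}\t."
                            f"\t{f.strand}\t.\t{attrs}\n"
                        )
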