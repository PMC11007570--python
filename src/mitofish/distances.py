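"""Distance framework: data matrices, uncorrected p-distances with
pairwise deletion, rank-wise group means, diagnostic-marker scanning, and
tree/alignment export.

Three concatenated matrices are built from annotated mitogenomes:

* ``CDS_nt`` -- codon-aware nucleotide alignment of the 12 protein genes
  (peptides aligned, gaps back-mapped onto codons),
* ``CDS_aa`` -- the corresponding amino-acid alignment,
* ``rDNA``   -- 12S plus the combined two-part 16S, aligned separately.

Distances are uncorrected p-distances: mismatches divided by compared
sites, where sites with a gap or ambiguity (N/X) in either sequence of a
pair are excluded (pairwise deletion).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AnnotatedGenome, extract_feature, translate_cds

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "RankPartition",
    "CDS_GENES",
    "RANK_PAIRS",
    "align_sequences",
    "build_matrices",
    "pdistance_matrix",
    "percent_identity",
    "rank_mean_distances",
    "diagnostic_marker_scan",
    "nj_tree",
    "write_phylip",
    "write_nexus",
]

CDS_GENES = (
    "ATP6", "COB", "COX1", "COX2", "COX3",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
)

RANK_PAIRS = (
    ("order", "class"),
    ("family", "order"),
    ("genus", "family"),
    ("species", "genus"),
    ("haplotype", "clade"),
)

_AA_VALID = set("ACDEFGHIKLMNPQRSTVWY")
_NT_VALID = set("ACGT")


@dataclass
class Alignment:
    """Equal-length rows with optional partition labels per column range."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "dna"  # dna | aa
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxa")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows are not equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # (n, n) float; NaN where no usable sites
    n_sites: np.ndarray  # usable-site counts per pair
    label: str = ""

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(np.diag(m), 0, equal_nan=True):
            raise ValueError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class RankPartition:
    """Nested group memberships: taxon -> {rank: group}."""

    memberships: dict[str, dict[str, str]]
    RANKS = ("class", "order", "family", "genus", "species", "clade", "haplotype")

    def __post_init__(self) -> None:
        nesting = (("order", "class"), ("family", "order"), ("genus", "family"),
                   ("species", "genus"), ("haplotype", "clade"))
        seen: dict[tuple[str, str], str] = {}
        for taxon, ranks in self.memberships.items():
            for child, parent in nesting:
                if child in ranks and parent in ranks:
                    key = (child, ranks[child])
                    if key in seen and seen[key] != ranks[parent]:
                        raise ValueError(
                            f"partition not nested: {child} {ranks[child]} appears "
                            f"under two different {parent} groups"
                        )
                    seen[key] = ranks[parent]

    def taxa(self) -> list[str]:
        return list(self.memberships)

    def group(self, taxon: str, rank: str) -> str:
        return self.memberships[taxon][rank]

    @classmethod
    def from_table(cls, path: str | Path) -> "RankPartition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df = df.set_index("taxon")
        return cls({t: row.dropna().to_dict() for t, row in df.iterrows()})

    def to_table(self, path: str | Path) -> None:
        df = pd.DataFrame.from_dict(self.memberships, orient="index")
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment (delegated to MAFFT)
# ---------------------------------------------------------------------------


def align_sequences(
    named_seqs: list[tuple[str, str]], alphabet: str = "dna"
) -> Alignment:
    """Multiple alignment of named sequences via MAFFT (``--auto``).

    Sequences that are empty are excluded from the aligner call and
    rendered as all-gap rows.
    """
    present = [(n, s) for n, s in named_seqs if s]
    if not present:
        raise ValueError("nothing to align")
    if len(present) == 1 or len({s for _, s in present}) == 1:
        width = len(present[0][1])
        aligned = {n: s for n, s in present}
    else:
        if shutil.which("mafft") is None:
            raise RuntimeError("mafft not found on PATH")
        with tempfile.TemporaryDirectory() as td:
            fa = Path(td) / "in.fa"
            with open(fa, "w") as fh:
                for n, s in present:
                    fh.write(f">{n}\n{s}\n")
            cmd = ["mafft", "--quiet", "--auto"]
            if alphabet == "aa":
                cmd.append("--amino")
            out = subprocess.run(
                cmd + [str(fa)], capture_output=True, text=True, check=True
            ).stdout
        aligned = {}
        name = None
        chunks: list[str] = []
        for line in out.splitlines():
            if line.startswith(">"):
                if name is not None:
                    aligned[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.strip())
        if name is not None:
            aligned[name] = "".join(chunks)
        width = len(next(iter(aligned.values())))
    rows = []
    for n, s in named_seqs:
        rows.append(aligned.get(n, "-" * width).upper())
    return Alignment([n for n, _ in named_seqs], rows, alphabet)


def _backmap_codons(aa_row: str, cds: str) -> str:
    """Map an aligned peptide row back onto its codons ('-' -> '---')."""
    out = []
    i = 0
    for ch in aa_row:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[3 * i : 3 * i + 3])
            i += 1
    return "".join(out)


def _gene_cds(genome: AnnotatedGenome, gene: str) -> str:
    f = genome.get(gene)
    if f is None:
        return ""
    seq = extract_feature(genome, f)
    if len(seq) % 3:
        seq = seq[: len(seq) - len(seq) % 3]
    return seq


def _peptide(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in ("TAA", "TAG"):
            if i >= len(cds) - 3:
                break
            out.append("X")  # internal stop in a gap-damaged CDS
            continue
        if "N" in codon:
            out.append("X")
            continue
        out.append(translate_cds(codon, 4))
    return "".join(out)


def build_matrices(
    genomes: list[AnnotatedGenome],
) -> tuple[dict[str, Alignment], dict[str, Alignment]]:
    """Build the ``CDS_nt`` / ``CDS_aa`` / ``rDNA`` matrices.

    Per-gene peptides are aligned and the gaps back-mapped onto codons, so
    ``CDS_nt`` columns come in codon triplets and its length is exactly
    three times the ``CDS_aa`` length.  Missing genes become all-gap rows.
    Returns ``(matrices, per_gene_aa)`` where ``per_gene_aa`` holds the
    individual protein alignments used for the rank analysis.
    """
    ids = [g.id for g in genomes]
    per_gene_aa: dict[str, Alignment] = {}
    nt_parts: list[Alignment] = []
    for gene in CDS_GENES:
        cds = {g.id: _gene_cds(g, gene) for g in genomes}
        peps = [(i, _peptide(cds[i])) for i in ids]
        aa_aln = align_sequences(peps, "aa")
        per_gene_aa[gene] = aa_aln
        nt_rows = [
            _backmap_codons(aa_aln.rows[k], cds[i]) if cds[i] else
            "-" * (3 * aa_aln.n_columns)
            for k, i in enumerate(ids)
        ]
        nt_parts.append(Alignment(ids, nt_rows, "dna"))

    def concat(parts: list[Alignment], labels: list[str], alphabet: str) -> Alignment:
        rows = ["".join(p.rows[k] for p in parts) for k in range(len(ids))]
        partitions = []
        off = 0
        for p, lab in zip(parts, labels):
            partitions.append((lab, off, off + p.n_columns))
            off += p.n_columns
        return Alignment(ids, rows, alphabet, partitions)

    cds_nt = concat(nt_parts, list(CDS_GENES), "dna")
    aa_parts = [per_gene_aa[g] for g in CDS_GENES]
    cds_aa = concat(aa_parts, list(CDS_GENES), "aa")

    def rna_seq(g: AnnotatedGenome, names: list[str]) -> str:
        segs = []
        for n in names:
            f = g.get(n)
            if f is not None:
                segs.append(extract_feature(g, f))
        return "".join(segs)

    aln_12s = align_sequences([(g.id, rna_seq(g, ["12S"])) for g in genomes], "dna")
    aln_16s = align_sequences(
        [(g.id, rna_seq(g, ["16S_a", "16S_b"])) for g in genomes], "dna"
    )
    rdna = concat([aln_12s, aln_16s], ["12S", "16S"], "dna")
    matrices = {"CDS_nt": cds_nt, "CDS_aa": cds_aa, "rDNA": rdna}
    return matrices, per_gene_aa


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _valid_mask(rows: list[str], alphabet: str) -> np.ndarray:
    valid = _AA_VALID if alphabet == "aa" else _NT_VALID
    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    mask = np.zeros(mat.shape, dtype=bool)
    for ch in valid:
        mask |= mat == ord(ch)
    return mask


def pdistance_matrix(aln: Alignment, label: str = "") -> DistanceMatrix:
    """Uncorrected p-distance with pairwise deletion.

    For each pair, alignment columns where either row carries a gap or an
    ambiguity (N for nucleotides, X for amino acids) are excluded; the
    distance is the fraction of mismatches among the remaining sites.
    Pairs with zero usable sites are reported as NaN.
    """
    n = len(aln.ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
    ok = _valid_mask(aln.rows, aln.alphabet)
    dist = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            sites[i, j] = sites[j, i] = m
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
            else:
                d = float((mat[i][both] != mat[j][both]).mean())
                dist[i, j] = dist[j, i] = d
    return DistanceMatrix(aln.ids.copy(), dist, sites, label or aln.alphabet)


def percent_identity(a: str, b: str) -> float:
    """Percent identical sites over columns where both rows are non-gap."""
    if len(a) != len(b):
        raise ValueError("rows must come from one alignment")
    comparable = ident = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            ident += 1
    if comparable == 0:
        raise ValueError("zero comparable sites")
    return 100.0 * ident / comparable


# ---------------------------------------------------------------------------
# Rank-wise group means and the diagnostic-marker criterion
# ---------------------------------------------------------------------------


def _between_child_mean(
    dm: DistanceMatrix, partition: RankPartition, child: str, parent: str,
    taxa: list[str],
) -> float:
    """Mean over parent groups of the mean distance between taxa belonging
    to different child groups inside that parent group."""
    ids = [t for t in taxa if t in dm.ids]
    parents: dict[str, list[str]] = {}
    for t in ids:
        parents.setdefault(partition.group(t, parent), []).append(t)
    group_means = []
    for members in parents.values():
        vals = []
        for i, t1 in enumerate(members):
            for t2 in members[i + 1 :]:
                if partition.group(t1, child) != partition.group(t2, child):
                    vals.append(dm.get(t1, t2))
        if vals:
            group_means.append(float(np.nanmean(vals)))
    return float(np.mean(group_means)) if group_means else np.nan


def rank_mean_distances(
    per_gene: dict[str, DistanceMatrix],
    partition: RankPartition,
    taxa_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-rank, per-gene mean between-group distances.

    Rows are the nested rank pairs (order-within-class down to
    haplotype-within-clade); columns are genes plus the concatenated
    matrix; a ``grand_mean`` column averages over genes.  A rank whose
    parent groups all contain a single child group yields NaN
    (not-applicable: no intra-group comparison possible).

    ``taxa_subset`` restricts the computation, e.g. to one class.
    """
    taxa = taxa_subset or partition.taxa()
    table = {}
    for gene, dm in per_gene.items():
        col = {}
        for child, parent in RANK_PAIRS:
            col[f"{child}_within_{parent}"] = _between_child_mean(
                dm, partition, child, parent, taxa
            )
        table[gene] = col
    df = pd.DataFrame(table)
    gene_cols = [g for g in df.columns if g != "concat"]
    df["grand_mean"] = df[gene_cols].mean(axis=1)
    return df


def diagnostic_marker_scan(
    per_gene: dict[str, DistanceMatrix],
    partition: RankPartition,
    rank: str = "genus",
    taxa_subset: list[str] | None = None,
) -> list[str]:
    """Genes that perfectly separate groups at a rank.

    A gene is diagnostic iff the maximum within-group distance is zero
    and the minimum between-group distance is positive.  Pairs with no
    usable sites disqualify the gene.
    """
    if rank not in RankPartition.RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    taxa = taxa_subset or partition.taxa()
    hits = []
    for gene, dm in sorted(per_gene.items()):
        ids = [t for t in taxa if t in dm.ids]
        within: list[float] = []
        between: list[float] = []
        undefined = False
        for i, t1 in enumerate(ids):
            for t2 in ids[i + 1 :]:
                d = dm.get(t1, t2)
                if np.isnan(d):
                    undefined = True
                    break
                if partition.group(t1, rank) == partition.group(t2, rank):
                    within.append(d)
                else:
                    between.append(d)
            if undefined:
                break
        if undefined or not between:
            continue
        if (not within or max(within) == 0.0) and min(between) > 0.0:
            hits.append(gene)
    return hits


# ---------------------------------------------------------------------------
# Trees and exports
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> str:
    """Neighbor-joining tree as a newick string.

    Negative branch lengths are clamped to zero; with ``outgroup`` the
    tree is rooted on the edge leading to that taxon.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    if np.isnan(dm.matrix).any():
        raise ValueError("distance matrix has undefined entries")
    sk = SkbioDM(dm.matrix, ids=dm.ids)
    tree = skbio_nj(sk)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if outgroup is not None:
        try:
            tip = tree.find(outgroup)
        except Exception as exc:
            raise ValueError(f"outgroup {outgroup!r} absent") from exc
        tree = tree.root_at(tip.parent)
    return str(tree).strip()


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Relaxed PHYLIP (name, two spaces, full row)."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.ids)} {aln.n_columns}\n")
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f"{name}  {row}\n")


def write_nexus(aln: Alignment, path: str | Path) -> None:
    """NEXUS with a sets block carrying the partition charsets."""
    dtype = "protein" if aln.alphabet == "aa" else "dna"
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(aln.ids)} NCHAR={aln.n_columns};\n")
        fh.write(f"  FORMAT DATATYPE={dtype} MISSING=? GAP=-;\n  MATRIX\n")
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f"    {name}  {row}\n")
        fh.write("  ;\nEND;\n")
        if aln.partitions:
            fh.write("\nBEGIN SETS;\n")
            for label, s, e in aln.partitions:
                fh.write(f"  CHARSET {label} = {s + 1}-{e};\n")
            fh.write("END;\n")
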