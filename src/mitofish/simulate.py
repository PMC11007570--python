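"""Synthetic predator-gut metagenome communities with known truth.

The generator emulates the study system: an abundant host (sea slug)
nuclear background plus one to a few circular prey mitogenomes of
~32-44 kb with placozoan-style architecture -- 12 protein-coding genes
(COX1-3, COB, ATP6, NAD1-6, NAD4L), a 12S rRNA, a two-part 16S rRNA
(four exons), interspersed tRNAs, split cox1 (eight exons, one micro
exon) and nad5 (two exons), and optional large ORFs (POLB, LAG, RVT-IM).
Libraries are 250 bp paired reads with 400-800 bp inserts and a
configurable substitution error rate, spanning sub-1x to several-hundred-x
prey coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reads import ReadSet
from .seqio import AnnotatedGenome, Feature, SequenceRecord, revcomp, translate_cds

__all__ = [
    "ArchitectureSpec",
    "LibraryParams",
    "TruthSet",
    "build_panel_genome",
    "derive_haplotype",
    "make_host_fragments",
    "simulate_library",
    "standard_mixture",
    "build_clocklike_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: table-4 stop codons; all other codons are legal inside a CDS
_STOPS = ("TAA", "TAG")

#: (name, kind, strand, length spec) in genome order.  CDS lengths are in
#: codons including the stop; rRNA/tRNA lengths in nt.  Multi-exon genes
#: carry per-exon lengths (nt) instead of a single length.
_CDS_CODONS = {
    "COX1": 510,
    "COX2": 240,
    "COX3": 260,
    "COB": 380,
    "ATP6": 230,
    "NAD1": 310,
    "NAD2": 340,
    "NAD3": 117,
    "NAD4": 480,
    "NAD4L": 98,
    "NAD5": 600,
    "NAD6": 165,
}
_ORF_CODONS = {"POLB": 350, "LAG": 280, "RVT-IM": 400}
_TRNA_LEN = 71
_R12S_LEN = 950
_R16S_EXONS = {"16S_a": (600, 500), "16S_b": (650, 550)}


@dataclass
class ArchitectureSpec:
    """Gene content and split-exon layout of a simulated prey mitogenome."""

    genome_length_range: tuple[int, int] = (32_000, 44_000)
    cds_names: tuple[str, ...] = tuple(_CDS_CODONS)
    cox1_exons: int = 8
    nad5_exons: int = 2
    r16s_parts: int = 2  # each part is split into two exons
    trna_names: tuple[str, ...] = (
        "tRNA-Met", "tRNA-Trp", "tRNA-Asp", "tRNA-Gly", "tRNA-Arg",
        "tRNA-His", "tRNA-Ser1", "tRNA-Leu", "tRNA-Thr", "tRNA-Lys",
        "tRNA-Ser2", "tRNA-Ile",
    )
    optional_orfs: tuple[str, ...] = ("POLB",)
    micro_exon_range: tuple[int, int] = (9, 20)

    def validate(self) -> None:
        if self.cox1_exons < 1 or self.nad5_exons < 1 or self.r16s_parts < 1:
            raise ValueError("exon counts must be >= 1")
        unknown = set(self.optional_orfs) - set(_ORF_CODONS)
        if unknown:
            raise ValueError(f"unknown optional ORFs {sorted(unknown)}")
        if set(self.cds_names) != set(_CDS_CODONS):
            raise ValueError("cds_names must be the 12 mitochondrial genes")


@dataclass
class LibraryParams:
    """Sequencing library model (paired-end, substitutions only by default)."""

    read_length: int = 250
    insert_range: tuple[int, int] = (400, 800)
    error_rate: float = 0.005
    indel_rate: float = 0.0

    def validate(self) -> None:
        if self.read_length > self.insert_range[0]:
            raise ValueError("read length must not exceed the minimum insert")
        if self.indel_rate != 0.0:
            raise NotImplementedError("indel errors are not modeled")


@dataclass
class TruthSet:
    """Planted community: genomes, abundances, library, and seed."""

    genomes: list[AnnotatedGenome]
    coverages: dict[str, float]
    host_fragments: list[SequenceRecord] = field(default_factory=list)
    host_coverage: float = 0.0
    library: LibraryParams = field(default_factory=LibraryParams)
    seed: int = 0
    divergences: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        self.library.validate()
        for gid, cov in self.coverages.items():
            if cov < 0:
                raise ValueError(f"negative coverage for {gid}")
        ids = {g.id for g in self.genomes}
        missing = set(self.coverages) - ids
        if missing:
            raise ValueError(f"coverages reference unknown genomes {sorted(missing)}")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free random codons + TAA, under translation table 4."""
    codons = []
    while len(codons) < n_codons - 2:
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _split_lengths(
    rng: np.random.Generator, total: int, n_parts: int, micro: int | None = None
) -> list[int]:
    """Partition ``total`` nt into ``n_parts`` exon lengths (>= 3 nt each);
    if ``micro`` is given, one randomly placed exon gets that length."""
    if n_parts == 1:
        return [total]
    min_exon = 60
    lens = [0] * n_parts
    slots = list(range(n_parts))
    remaining = total
    if micro is not None:
        i = int(rng.integers(0, n_parts))
        lens[i] = micro
        slots.remove(i)
        remaining -= micro
    spare = remaining - min_exon * len(slots)
    if spare < 0:
        raise ValueError("gene too short for requested exon count")
    w = rng.random(len(slots))
    extra_lens = (spare * w / w.sum()).astype(int)
    for j, slot in enumerate(slots):
        lens[slot] = min_exon + int(extra_lens[j])
    lens[slots[-1]] += remaining - (min_exon * len(slots) + int(extra_lens.sum()))
    return lens


def _layout(spec: ArchitectureSpec, rng: np.random.Generator):
    """Ordered (name, kind, strand, exon_lengths, cds_seq) tuples."""
    micro = int(rng.integers(*spec.micro_exon_range))
    plan = []

    def cds(name: str, strand: str = "+", exons: list[int] | None = None):
        seq = _random_cds(rng, _CDS_CODONS[name])
        plan.append((name, "CDS", strand, exons or [len(seq)], seq))

    def orf(name: str):
        if name in spec.optional_orfs:
            seq = _random_cds(rng, _ORF_CODONS[name])
            plan.append((name, "ORF", "+", [len(seq)], seq))

    def rna(name: str, kind: str, lens: list[int], strand: str = "+"):
        plan.append((name, kind, strand, lens, None))

    cox1_len = _CDS_CODONS["COX1"] * 3
    cds("COX1", exons=_split_lengths(rng, cox1_len, spec.cox1_exons, micro))
    rna("tRNA-Met", "tRNA", [_TRNA_LEN])
    rna("12S", "rRNA", [_R12S_LEN])
    cds("NAD1")
    orf("POLB")  # between NAD1 and NAD4L, the reference position
    cds("NAD4L")
    rna("tRNA-Trp", "tRNA", [_TRNA_LEN])
    cds("COX2")
    rna("tRNA-Asp", "tRNA", [_TRNA_LEN])
    cds("ATP6")
    cds("COX3")
    rna("tRNA-Gly", "tRNA", [_TRNA_LEN])
    cds("NAD3")
    rna("tRNA-Arg", "tRNA", [_TRNA_LEN])
    cds("NAD2")
    cds("NAD4")
    rna("tRNA-His", "tRNA", [_TRNA_LEN])
    nad5_len = _CDS_CODONS["NAD5"] * 3
    cds("NAD5", exons=_split_lengths(rng, nad5_len, spec.nad5_exons))
    part_names = ["16S_a", "16S_b"][: spec.r16s_parts]
    rna(part_names[0], "rRNA", list(_R16S_EXONS["16S_a"]))
    rna("tRNA-Ser1", "tRNA", [_TRNA_LEN], strand="-")
    cds("NAD6", strand="-")
    cds("COB")
    rna("tRNA-Thr", "tRNA", [_TRNA_LEN])
    rna("tRNA-Lys", "tRNA", [_TRNA_LEN])
    if spec.r16s_parts > 1:
        rna(part_names[1], "rRNA", list(_R16S_EXONS["16S_b"]))
    rna("tRNA-Leu", "tRNA", [_TRNA_LEN])
    orf("LAG")
    rna("tRNA-Ser2", "tRNA", [_TRNA_LEN])
    orf("RVT-IM")
    rna("tRNA-Ile", "tRNA", [_TRNA_LEN])
    for t in spec.trna_names:
        if not any(p[0] == t for p in plan):
            rna(t, "tRNA", [_TRNA_LEN])
    return plan


def build_panel_genome(
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
    genome_id: str = "mtg",
) -> AnnotatedGenome:
    """Generate a circular prey mitogenome with the default placozoan-style
    architecture.  Deterministic for a given seed; every CDS/ORF translates
    stop-free under translation table 4."""
    spec = spec or ArchitectureSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    plan = _layout(spec, rng)

    target = int(rng.integers(*spec.genome_length_range))
    feat_total = sum(sum(lens) for _, _, _, lens, _ in plan)
    n_fillers = sum(len(lens) for _, _, _, lens, _ in plan)  # one filler before each exon
    min_filler = 60
    budget = target - feat_total
    if budget < n_fillers * min_filler:
        raise ValueError(
            f"spec infeasible: features ({feat_total} nt) leave no room for "
            f"spacers in a {target} nt genome"
        )
    w = rng.random(n_fillers)
    fillers = (min_filler + (budget - n_fillers * min_filler) * w / w.sum()).astype(int)
    fillers[-1] += budget - int(fillers.sum())

    seq_parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    fi = 0
    for name, kind, strand, lens, cds_seq in plan:
        exon_seqs: list[str]
        if cds_seq is not None:
            exon_seqs, off = [], 0
            for ln in lens:
                exon_seqs.append(cds_seq[off : off + ln])
                off += ln
            if strand == "-":
                # lay minus-strand exons down 3'->5' on the forward strand so
                # transcript order corresponds to decreasing coordinates
                exon_seqs = [revcomp(s) for s in exon_seqs][::-1]
        else:
            exon_seqs = [_random_dna(rng, ln) for ln in lens]
        intervals = []
        for es in exon_seqs:
            spacer = int(fillers[fi]); fi += 1
            seq_parts.append(_random_dna(rng, spacer))
            pos += spacer
            intervals.append((pos, pos + len(es)))
            seq_parts.append(es)
            pos += len(es)
        if strand == "-":
            intervals = intervals[::-1]  # transcript order: 5'-most first
        features.append(Feature(name, kind, intervals, strand, 4))

    genome = AnnotatedGenome(
        SequenceRecord(genome_id, "".join(seq_parts), circular=True), features
    )
    _assert_translatable(genome)
    return genome


def _assert_translatable(genome: AnnotatedGenome) -> None:
    from .seqio import extract_feature

    for f in genome.features:
        if f.kind in ("CDS", "ORF"):
            translate_cds(extract_feature(genome, f), 4)


# ---------------------------------------------------------------------------
# Haplotype derivation
# ---------------------------------------------------------------------------


def _transcript_positions(genome_length: int, feature: Feature) -> np.ndarray:
    """Forward-strand genome positions in transcript order."""
    pos_parts = []
    for s, e in feature.exons:
        if e > s:
            p = np.arange(s, e)
        else:  # wraps origin
            p = np.concatenate([np.arange(s, genome_length), np.arange(0, e)])
        if feature.strand == "-":
            p = p[::-1]
        pos_parts.append(p)
    return np.concatenate(pos_parts)


def derive_haplotype(
    base: AnnotatedGenome,
    divergence: float,
    rearrangement: tuple | None = None,
    seed: int = 0,
    genome_id: str | None = None,
    conserved_factor: float = 0.5,
) -> tuple[AnnotatedGenome, float]:
    """Mutate a genome to a target p-distance, preserving ORFs.

    Substitutions are Bernoulli per site at rate ``divergence`` except in
    rRNA/tRNA features, which evolve at ``conserved_factor`` times the CDS
    rate (mimicking rDNA conservation).  Codons that would acquire an
    internal stop under table 4 are reverted; start and stop codons are
    never touched.  Returns ``(haplotype, realized_divergence)`` where the
    realized value is the exact per-site difference from ``base``.

    ``rearrangement`` may be ``("inversion", (name_a, name_b))`` --
    reverse-complement the block spanning the two named features -- or
    ``("translocation", name, (left, right))`` -- move the named
    single-exon feature between two other features.
    """
    if not 0 <= divergence <= 0.25:
        raise ValueError("divergence must be in [0, 0.25]")
    rng = np.random.default_rng(seed)
    L = len(base.record)
    codes = np.frombuffer(base.record.seq.encode(), dtype=np.uint8).copy()

    rate = np.full(L, divergence)
    protected = np.zeros(L, dtype=bool)
    coding: list[tuple[Feature, np.ndarray]] = []
    for f in base.features:
        tpos = _transcript_positions(L, f)
        if f.kind in ("rRNA", "tRNA"):
            rate[tpos] = divergence * conserved_factor
        else:
            coding.append((f, tpos))
            protected[tpos[:3]] = True
            protected[tpos[-3:]] = True

    hit = (rng.random(L) < rate) & ~protected
    idx = np.flatnonzero(hit)
    if idx.size:
        cur = _LUT_CODE[codes[idx]]
        shift = rng.integers(1, 4, idx.size)
        codes[idx] = _BASES[(cur + shift) % 4]

    # revert mutations that created internal stops (table 4)
    base_codes = np.frombuffer(base.record.seq.encode(), dtype=np.uint8)
    for f, tpos in coding:
        n_cod = tpos.size // 3
        tri = tpos[: n_cod * 3].reshape(n_cod, 3)
        seq_codons = _codons_as_strings(codes, tri, f.strand)
        for ci in range(1, n_cod - 1):
            if seq_codons[ci] in _STOPS:
                codes[tri[ci]] = base_codes[tri[ci]]

    realized = float(np.mean(codes != base_codes))
    hap = AnnotatedGenome(
        SequenceRecord(
            genome_id or f"{base.id}_hap{seed}",
            codes.tobytes().decode(),
            circular=True,
        ),
        [Feature(f.name, f.kind, list(f.exons), f.strand, f.transl_table) for f in base.features],
    )
    if rearrangement is not None:
        hap = _apply_rearrangement(hap, rearrangement)
    _assert_translatable(hap)
    return hap, realized


_LUT_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT_CODE[_b] = _i


def _codons_as_strings(codes: np.ndarray, tri: np.ndarray, strand: str) -> list[str]:
    flat = codes[tri]
    if strand == "-":
        comp = {65: 84, 84: 65, 67: 71, 71: 67}
        flat = np.vectorize(comp.get)(flat)
    return ["".join(chr(c) for c in row) for row in flat]


def _feature_span(g: AnnotatedGenome, name: str) -> tuple[int, int]:
    f = g.get(name)
    if f is None:
        raise ValueError(f"no feature {name!r} in {g.id}")
    return min(s for s, _ in f.exons), max(e for _, e in f.exons)


def _apply_rearrangement(g: AnnotatedGenome, descriptor: tuple) -> AnnotatedGenome:
    kind = descriptor[0]
    seq = g.record.seq
    L = len(seq)
    if kind == "inversion":
        name_a, name_b = descriptor[1]
        sa, ea = _feature_span(g, name_a)
        sb, eb = _feature_span(g, name_b)
        lo, hi = min(sa, sb), max(ea, eb)
        new_seq = seq[:lo] + revcomp(seq[lo:hi]) + seq[hi:]
        feats = []
        for f in g.features:
            if all(lo <= s and e <= hi for s, e in f.exons):
                exons = [(lo + hi - e, lo + hi - s) for s, e in f.exons]
                strand = "-" if f.strand == "+" else "+"
                feats.append(Feature(f.name, f.kind, exons, strand, f.transl_table))
            elif any(lo < e and s < hi for s, e in f.exons):
                raise ValueError(
                    f"inversion boundary splits feature {f.name!r}"
                )
            else:
                feats.append(Feature(f.name, f.kind, list(f.exons), f.strand, f.transl_table))
        return AnnotatedGenome(SequenceRecord(g.id, new_seq, True), feats)
    if kind == "translocation":
        name, (left, right) = descriptor[1], descriptor[2]
        f = g.get(name)
        if f is None or len(f.exons) != 1:
            raise ValueError("translocation requires an existing single-exon feature")
        s, e = f.exons[0]
        seg = seq[s:e]
        removed = seq[:s] + seq[e:]

        def shift_after_cut(p: int) -> int:
            return p - (e - s) if p >= e else p

        _, left_end = _feature_span(g, left)
        right_start, _ = _feature_span(g, right)
        left_end = shift_after_cut(left_end)
        right_start = shift_after_cut(right_start)
        if right_start < left_end:
            raise ValueError(f"features {left!r} and {right!r} not in order")
        insert_at = left_end + (right_start - left_end) // 2
        new_seq = removed[:insert_at] + seg + removed[insert_at:]
        feats = []
        for fo in g.features:
            if fo.name == name:
                feats.append(
                    Feature(fo.name, fo.kind, [(insert_at, insert_at + len(seg))],
                            fo.strand, fo.transl_table)
                )
                continue
            exons = []
            for es, ee in fo.exons:
                es2, ee2 = shift_after_cut(es), shift_after_cut(ee)
                if es2 >= insert_at:
                    es2 += len(seg)
                if ee2 > insert_at:
                    ee2 += len(seg)
                exons.append((es2, ee2))
            feats.append(Feature(fo.name, fo.kind, exons, fo.strand, fo.transl_table))
        return AnnotatedGenome(SequenceRecord(g.id, new_seq, True), feats)
    raise ValueError(f"unknown rearrangement kind {kind!r}")


# ---------------------------------------------------------------------------
# Host background and read simulation
# ---------------------------------------------------------------------------


def make_host_fragments(
    seed: int = 0,
    total_bp: int = 5_000_000,
    n_fragments: int = 200,
    prefix: str = "host",
) -> list[SequenceRecord]:
    """Random linear fragments totaling ``total_bp`` -- a non-homologous
    nuclear background for baiting specificity (not a realistic genome)."""
    rng = np.random.default_rng(seed)
    w = rng.random(n_fragments) + 0.5
    lens = (total_bp * w / w.sum()).astype(int)
    lens[-1] += total_bp - int(lens.sum())
    return [
        SequenceRecord(f"{prefix}_{i}", _random_dna(rng, int(ln)))
        for i, ln in enumerate(lens)
    ]


def _pair_count(coverage: float, genome_length: int, read_length: int) -> int:
    return int(round(coverage * genome_length / (2 * read_length)))


def _simulate_genome_reads(
    rng: np.random.Generator,
    gid: str,
    seq: str,
    circular: bool,
    coverage: float,
    lib: LibraryParams,
    out: ReadSet,
    origins: list[tuple[str, str, int, int]],
) -> None:
    L = len(seq)
    rl = lib.read_length
    lo, hi = lib.insert_range
    if L < (lo if circular else lo):
        return
    n = _pair_count(coverage, L, rl)
    if n == 0:
        return
    inserts = rng.integers(lo, hi + 1, n)
    if circular:
        starts = rng.integers(0, L, n)
        ext = np.frombuffer((seq + seq[: hi]).encode(), dtype=np.uint8)
    else:
        inserts = np.minimum(inserts, L)
        starts = rng.integers(0, np.maximum(L - inserts, 0) + 1, n)
        ext = np.frombuffer(seq.encode(), dtype=np.uint8)

    offs = np.arange(rl)
    r1 = ext[starts[:, None] + offs]
    r2 = ext[(starts + inserts - rl)[:, None] + offs]
    # reverse complement mate 2
    r2 = r2[:, ::-1]
    r2 = _COMP_LUT[r2]
    if lib.error_rate > 0:
        for mat in (r1, r2):
            errs = rng.random(mat.shape) < lib.error_rate
            n_err = int(errs.sum())
            if n_err:
                cur = _LUT_CODE[mat[errs]]
                mat[errs] = _BASES[(cur + rng.integers(1, 4, n_err)) % 4]
    qual = chr(33 + 37) * rl
    for i in range(n):
        rid = f"{gid}:{len(out.ids)}"
        out.ids.append(rid)
        out.seq1.append(r1[i].tobytes().decode())
        out.qual1.append(qual)
        out.seq2.append(r2[i].tobytes().decode())
        out.qual2.append(qual)
        origins.append((rid, gid, int(starts[i]), int(inserts[i])))


_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def simulate_library(
    truth: TruthSet,
) -> tuple[ReadSet, list[tuple[str, str, int, int]]]:
    """Simulate one paired-end library from a planted community.

    Fragment count per genome is ``round(coverage * L / (2 * read_length))``;
    fragment starts are uniform on the circle (uniform within linear host
    fragments), inserts uniform in the configured range, and substitution
    errors independent per base.  Returns the reads plus an origin table of
    ``(read_id, genome_id, start, insert)`` rows.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    lib = truth.library
    out = ReadSet(read_length=lib.read_length, insert_range=lib.insert_range)
    origins: list[tuple[str, str, int, int]] = []
    for g in truth.genomes:
        _simulate_genome_reads(
            rng, g.id, g.record.seq, g.record.circular,
            truth.coverages.get(g.id, 0.0), lib, out, origins,
        )
    for frag in truth.host_fragments:
        _simulate_genome_reads(
            rng, frag.id, frag.seq, False, truth.host_coverage, lib, out, origins,
        )
    return out, origins


# ---------------------------------------------------------------------------
# Ready-made study conditions
# ---------------------------------------------------------------------------


def standard_mixture(
    seed: int = 0,
    prey_coverages: tuple[float, ...] = (100.0, 70.0, 40.0, 0.5),
    host_coverage: float = 30.0,
    host_bp: int = 5_000_000,
    panel_divergence: float = 0.06,
    prey_to_ref_divergence: float = 0.05,
    error_rate: float = 0.005,
) -> tuple[list[AnnotatedGenome], TruthSet, ReadSet, list[tuple[str, str, int, int]]]:
    """The default benchmark community.

    One base architecture genome is diverged into a panel of reference
    mitogenomes (one per prey lineage, mutually ~2x ``panel_divergence``
    apart); each prey haplotype sits ``prey_to_ref_divergence`` from its
    panel reference, so prey lineages are mutually >= 3% divergent while
    remaining baitable.  Three prey are at enriched-regime coverages and a
    fourth at 0.5x (the non-enriched regime); the host background is 5 Mb
    at 30x.  Returns ``(panel, truth, reads, origins)``.
    """
    rng = np.random.default_rng(seed)
    base = build_panel_genome(seed=int(rng.integers(2**31)), genome_id="base")
    panel: list[AnnotatedGenome] = []
    preys: list[AnnotatedGenome] = []
    divs: dict[tuple[str, str], float] = {}
    for i in range(len(prey_coverages)):
        ref, _ = derive_haplotype(
            base, panel_divergence, seed=int(rng.integers(2**31)),
            genome_id=f"ref{i + 1}",
        )
        panel.append(ref)
        prey, d = derive_haplotype(
            ref, prey_to_ref_divergence, seed=int(rng.integers(2**31)),
            genome_id=f"prey{i + 1}",
        )
        preys.append(prey)
        divs[(prey.id, ref.id)] = d
    truth = TruthSet(
        genomes=preys,
        coverages={p.id: c for p, c in zip(preys, prey_coverages)},
        host_fragments=make_host_fragments(
            seed=int(rng.integers(2**31)), total_bp=host_bp
        ),
        host_coverage=host_coverage,
        library=LibraryParams(error_rate=error_rate),
        seed=int(rng.integers(2**31)),
        divergences=divs,
    )
    reads, origins = simulate_library(truth)
    return panel, truth, reads, origins


# ---------------------------------------------------------------------------
# Clock-like taxon panel for the distance framework
# ---------------------------------------------------------------------------


def build_clocklike_panel(
    seed: int = 0,
    diagnostic_gene: str = "NAD3",
    rank_divergences: dict[str, float] | None = None,
) -> tuple[list[AnnotatedGenome], dict[str, dict[str, str]]]:
    """A nested taxon panel with divergence decreasing down the ranks.

    Builds two classes; the larger class splits into two orders, each order
    into two families, each family into two genera, each genus into two
    species of two haplotypes each, giving 33 taxa.  ``diagnostic_gene`` is
    forced to be *identical within each genus* and *distinct between
    genera* (each genus inherits its ancestral copy; differences between
    genus ancestors are guaranteed by injecting a substitution when
    needed), while every other protein gene receives at least one
    within-genus amino-acid difference -- so exactly one gene is
    genus-diagnostic by construction.

    Returns ``(genomes, partition)`` where partition maps taxon id ->
    ``{rank: group}`` for ranks class/order/family/genus/species/clade/
    haplotype.
    """
    div = rank_divergences or {
        "class": 0.20, "order": 0.10, "family": 0.06,
        "genus": 0.035, "species": 0.018, "haplotype": 0.008,
    }
    rng = np.random.default_rng(seed)

    def child(g: AnnotatedGenome, d: float, gid: str) -> AnnotatedGenome:
        h, _ = derive_haplotype(g, d, seed=int(rng.integers(2**31)), genome_id=gid)
        return h

    root = build_panel_genome(seed=int(rng.integers(2**31)), genome_id="root")
    taxa: list[AnnotatedGenome] = []
    partition: dict[str, dict[str, str]] = {}

    # minor class: single representative (like Polyplacotomia)
    minor = child(root, div["class"], "T0")
    taxa.append(minor)
    partition["T0"] = {
        "class": "ClassB", "order": "OrderB1", "family": "FamB1",
        "genus": "GenB1", "species": "T0", "clade": "GenB1", "haplotype": "T0",
    }

    genus_ancestors: dict[str, AnnotatedGenome] = {}
    n = 0
    major = child(root, div["class"], "majorroot")
    for oi in range(2):
        o_anc = child(major, div["order"], f"o{oi}")
        for fi in range(2):
            f_anc = child(o_anc, div["family"], f"o{oi}f{fi}")
            for gi in range(2):
                g_name = f"GenA{oi}{fi}{gi}"
                g_anc = child(f_anc, div["genus"], g_name + "_anc")
                genus_ancestors[g_name] = g_anc
                for si in range(2):
                    s_name = f"{g_name}sp{si}"
                    s_anc = child(g_anc, div["species"], s_name + "_anc")
                    for hi in range(2):
                        n += 1
                        tid = f"T{n}"
                        leaf = child(s_anc, div["haplotype"], tid)
                        taxa.append(leaf)
                        partition[tid] = {
                            "class": "ClassA",
                            "order": f"OrdA{oi}",
                            "family": f"FamA{oi}{fi}",
                            "genus": g_name,
                            "species": s_name,
                            "clade": g_name,
                            "haplotype": tid,
                        }

    _plant_diagnostic(taxa, partition, genus_ancestors, diagnostic_gene, rng)
    return taxa, partition


def _gene_positions(g: AnnotatedGenome, name: str) -> np.ndarray:
    f = g.get(name)
    return _transcript_positions(len(g.record), f)


def _set_gene(g: AnnotatedGenome, name: str, new_cds: str) -> AnnotatedGenome:
    """Overwrite a gene's spliced sequence in place on the genome."""
    pos = _gene_positions(g, name)
    codes = np.frombuffer(g.record.seq.encode(), dtype=np.uint8).copy()
    new = np.frombuffer(new_cds.encode(), dtype=np.uint8)
    f = g.get(name)
    if f.strand == "-":
        new = _COMP_LUT[new[::-1]]
        pos = np.sort(pos)
    codes[pos] = new
    return AnnotatedGenome(
        SequenceRecord(g.id, codes.tobytes().decode(), g.record.circular),
        g.features,
    )


def _plant_diagnostic(
    taxa: list[AnnotatedGenome],
    partition: dict[str, dict[str, str]],
    genus_ancestors: dict[str, AnnotatedGenome],
    gene: str,
    rng: np.random.Generator,
) -> None:
    from .seqio import extract_feature

    # distinct ancestral copies between genera (at the protein level)
    anc_cds: dict[str, str] = {}
    seen_aa: set[str] = set()
    for g_name, anc in genus_ancestors.items():
        cds = extract_feature(anc, anc.get(gene))
        aa = translate_cds(cds, 4)
        while aa in seen_aa:
            cds = _mutate_one_codon(cds, rng)
            aa = translate_cds(cds, 4)
        seen_aa.add(aa)
        anc_cds[g_name] = cds

    by_genus: dict[str, list[int]] = {}
    for i, t in enumerate(taxa):
        gname = partition[t.id]["genus"]
        by_genus.setdefault(gname, []).append(i)

    for g_name, idxs in by_genus.items():
        if g_name in anc_cds:
            for i in idxs:
                taxa[i] = _set_gene(taxa[i], gene, anc_cds[g_name])
        if len(idxs) < 2:
            continue
        # every *other* protein gene must vary within the genus
        for other in taxa[idxs[0]].features:
            if other.kind != "CDS" or other.name == gene:
                continue
            aas = {
                translate_cds(extract_feature(taxa[i], taxa[i].get(other.name)), 4)
                for i in idxs
            }
            if len(aas) == 1:
                t0 = taxa[idxs[0]]
                cds = extract_feature(t0, t0.get(other.name))
                taxa[idxs[0]] = _set_gene(t0, other.name, _mutate_one_codon(cds, rng))


def _mutate_one_codon(cds: str, rng: np.random.Generator) -> str:
    """One random internal non-synonymous, stop-free codon change."""
    fwd4 = translate_cds(cds, 4)
    n_cod = len(cds) // 3
    while True:
        ci = int(rng.integers(1, n_cod - 1))
        codon = _random_dna(rng, 3)
        if codon in _STOPS:
            continue
        new = cds[: 3 * ci] + codon + cds[3 * ci + 3 :]
        if translate_cds(new, 4) != fwd4:
            return new
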