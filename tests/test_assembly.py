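"""De Bruijn seeding and iterative consensus extension."""

import numpy as np
import pytest

from mitofish.assembly import assemble_and_extend, debruijn_unitigs
from mitofish.reads import ReadSet
from mitofish.seqio import revcomp
from mitofish.simulate import (
    LibraryParams, TruthSet, build_panel_genome, derive_haplotype,
    simulate_library,
)


def olc_oracle(reads: list[str], min_overlap: int = 50) -> str:
    """Brute-force overlap-layout-consensus for error-free, forward-strand
    toy read sets with unambiguous layout: repeatedly merge the pair with
    the longest exact suffix/prefix overlap until one sequence remains."""
    seqs = [r for r in reads if not any(r in o and r != o for o in reads)]
    seqs = sorted(set(seqs))
    while len(seqs) > 1:
        best = None
        for a in seqs:
            for b in seqs:
                if a == b:
                    continue
                for ov in range(min(len(a), len(b)) - 1, min_overlap - 1, -1):
                    if a.endswith(b[:ov]):
                        if best is None or ov > best[0]:
                            best = (ov, a, b)
                        break
        if best is None:
            raise AssertionError("oracle: ambiguous or disconnected layout")
        ov, a, b = best
        seqs.remove(a)
        seqs.remove(b)
        seqs.append(a + b[ov:])
        seqs.sort()
    return seqs[0]


def _tiled_reads(target: str, read_len: int, step: int) -> ReadSet:
    seqs = [target[i : i + read_len]
            for i in range(0, len(target) - read_len + 1, step)]
    if (len(target) - read_len) % step:
        seqs.append(target[-read_len:])
    if len(seqs) % 2:
        seqs.append(seqs[-1])
    half = len(seqs) // 2
    return ReadSet(
        ids=[f"t{i}" for i in range(half)],
        seq1=seqs[:half], qual1=["I" * read_len] * half,
        seq2=[revcomp(s) for s in seqs[half:]],
        qual2=["I" * read_len] * half,
        read_length=read_len,
    )


def _target(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestOracleEquivalence:
    @pytest.mark.parametrize("length,seed", [(600, 1), (1200, 2), (2000, 3)])
    def test_reconstructs_toy_target_exactly(self, length, seed):
        target = _target(length, seed)
        reads = _tiled_reads(target, 100, 10)
        contigs = assemble_and_extend(reads, k_list=(33, 55, 77), iterations=10)
        assert len(contigs) == 1
        got = contigs[0].seq
        expect = olc_oracle(
            [target[i : i + 100] for i in range(0, length - 99, 10)]
            + [target[-100:]]
        )
        assert expect == target
        assert got in (expect, revcomp(expect))

    def test_seeded_extension_recovers_target(self):
        target = _target(600, seed=4)
        reads = _tiled_reads(target, 100, 10)
        seed_contig = target[250:350]
        contigs = assemble_and_extend(reads, iterations=10, seeds=[seed_contig])
        assert len(contigs) == 1
        assert contigs[0].seq in (target, revcomp(target))

    def test_seed_with_no_overlapping_reads_unchanged(self):
        target = _target(600, seed=5)
        reads = _tiled_reads(target, 100, 10)
        foreign = _target(120, seed=99)
        contigs = assemble_and_extend(reads, iterations=10, seeds=[foreign])
        assert any(c.seq in (foreign, revcomp(foreign)) for c in contigs)


class TestInvariants:
    def test_extension_monotone_in_iterations(self):
        target = _target(1500, seed=6)
        reads = _tiled_reads(target, 100, 10)
        seed_contig = target[700:800]
        prev = 0
        for it in (1, 3, 6, 10):
            contigs = assemble_and_extend(reads, iterations=it, seeds=[seed_contig])
            longest = max(len(c) for c in contigs)
            assert longest >= prev
            prev = longest

    def test_deterministic(self):
        target = _target(900, seed=7)
        reads = _tiled_reads(target, 100, 15)
        a = assemble_and_extend(reads, iterations=5)
        b = assemble_and_extend(reads, iterations=5)
        assert [c.seq for c in a] == [c.seq for c in b]

    def test_contigs_have_support_and_no_n(self):
        target = _target(800, seed=8)
        reads = _tiled_reads(target, 100, 10)
        for c in assemble_and_extend(reads, iterations=3):
            assert "N" not in c.seq
            assert (c.support >= 1).all()
            assert len(c.support) == len(c.seq)


class TestHaplotypeSeparation:
    def test_two_haplotypes_no_chimeric_contigs(self):
        """Two 5%-divergent haplotypes at high coverage assemble into
        contigs that each match exactly one truth sequence."""
        base = build_panel_genome(seed=31, genome_id="b")
        hapA, _ = derive_haplotype(base, 0.025, seed=1, genome_id="hapA")
        hapB, _ = derive_haplotype(base, 0.025, seed=2, genome_id="hapB")
        truth = TruthSet(
            genomes=[hapA, hapB], coverages={"hapA": 40.0, "hapB": 40.0},
            library=LibraryParams(error_rate=0.0), seed=3,
        )
        reads, _ = simulate_library(truth)
        contigs = assemble_and_extend(reads, iterations=4)
        import edlib

        for c in contigs:
            if len(c) < 500:
                continue
            dists = []
            for hap in (hapA, hapB):
                t = hap.record.seq * 2
                d = min(
                    edlib.align(c.seq, t, mode="HW", task="distance")["editDistance"],
                    edlib.align(revcomp(c.seq), t, mode="HW", task="distance")["editDistance"],
                )
                dists.append(d)
            assert min(dists) <= 2, "contig matches neither haplotype cleanly"


def test_unitigs_respect_min_count():
    reads = [_target(60, seed=42)] * 3
    unis = debruijn_unitigs(reads, k=31, min_count=4)
    assert unis == []
    unis = debruijn_unitigs(reads, k=31, min_count=2)
    assert len(unis) >= 1
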