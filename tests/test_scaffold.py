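"""Reference-guided scaffolding: anchoring, merging, N-fill, back-mapping."""

import numpy as np
import pytest

from mitofish.assembly import Contig
from mitofish.scaffold import (
    Gap,
    ScaffoldResult,
    anchor_contigs,
    backmap_qc,
    finalize_scaffold,
    merge_and_close,
)
from mitofish.seqio import SequenceRecord, revcomp
from mitofish.simulate import LibraryParams, TruthSet, simulate_library


def _contig(seq, depth=10):
    return Contig(seq, np.full(len(seq), depth, dtype=np.int32))


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(44)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    return SequenceRecord("ref", seq, circular=False)


class TestAnchoring:
    def test_exact_forward_placement(self, ref):
        pl = anchor_contigs([_contig(ref.seq[100:500])], ref)
        assert len(pl) == 1
        p = pl[0]
        assert (p.start, p.end, p.orientation) == (100, 500, "+")
        assert p.identity == 1.0

    def test_reverse_complement_placement(self, ref):
        pl = anchor_contigs([_contig(revcomp(ref.seq[100:500]))], ref)
        assert (pl[0].start, pl[0].end, pl[0].orientation) == (100, 500, "-")

    def test_random_contig_unplaced(self, ref):
        rng = np.random.default_rng(9)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        assert anchor_contigs([_contig(junk)], ref) == []


class TestMergeAndFinalize:
    def test_overlapping_contigs_merge_to_sum_minus_overlap(self, ref):
        a = _contig(ref.seq[0:600])
        b = _contig(ref.seq[550:1200])
        pl = anchor_contigs([a, b], ref)
        pre = merge_and_close(pl, [a, b], ref)
        assert len(pre.pieces) == 1
        assert len(pre.pieces[0][1]) == 600 + 650 - 50

    def test_completeness_arithmetic(self, ref):
        """619 aligned bases on a 1000 bp reference frame -> 61.9%."""
        ref1k = SequenceRecord("r1k", ref.seq[:1000])
        c = _contig(ref1k.seq[100:719])
        pl = anchor_contigs([c], ref1k)
        scaf = finalize_scaffold(merge_and_close(pl, [c], ref1k), ref1k)
        assert scaf.completeness == pytest.approx(61.9)
        assert scaf.seq[:100] == "N" * 100
        assert len(scaf.seq) == 1000

    def test_no_gaps_means_100_percent_and_zero_n(self, ref):
        c = _contig(ref.seq)
        pl = anchor_contigs([c], ref)
        scaf = finalize_scaffold(merge_and_close(pl, [c], ref), ref)
        assert scaf.completeness == 100.0
        assert "N" not in scaf.seq

    def test_empty_scaffold_zero_percent(self, ref):
        scaf = finalize_scaffold(merge_and_close([], [], ref), ref)
        assert scaf.completeness == 0.0
        assert set(scaf.seq) == {"N"}

    def test_every_n_run_has_a_gap_record(self, ref):
        a = _contig(ref.seq[0:500])
        b = _contig(ref.seq[800:1300])
        pl = anchor_contigs([a, b], ref)
        scaf = finalize_scaffold(merge_and_close(pl, [a, b], ref), ref)
        import re

        n_runs = [m.span() for m in re.finditer(r"N+", scaf.seq)]
        assert len(n_runs) == len(scaf.gaps)
        for (s, e), g in zip(n_runs, sorted(scaf.gaps, key=lambda g: g.ref_start)):
            assert (e - s) == g.fill_length

    def test_non_n_bases_never_altered(self, ref):
        a = _contig(ref.seq[0:900])
        pl = anchor_contigs([a], ref)
        scaf = finalize_scaffold(merge_and_close(pl, [a], ref), ref)
        assert scaf.seq[:900] == ref.seq[:900]

    def test_conflicting_overlap_logged_not_merged(self, ref):
        a = _contig(ref.seq[0:600], depth=30)
        rng = np.random.default_rng(5)
        noisy = list(ref.seq[550:1200])
        for i in range(0, 50, 3):  # corrupt the overlap region at ~30%
            noisy[i] = "A" if noisy[i] != "A" else "C"
        b = _contig("".join(noisy), depth=10)
        pl = anchor_contigs([a, b], ref)
        pre = merge_and_close(pl, [a, b], ref)
        assert pre.conflicts, "expected a haplotype-conflict warning"


class TestGapClosing:
    def test_gap_closed_with_reads(self, small_genome):
        """A missing middle chunk is re-assembled from recruited reads."""
        g = small_genome
        L = len(g.record)
        truth = TruthSet(
            genomes=[g], coverages={g.id: 50.0},
            library=LibraryParams(error_rate=0.0), seed=7,
        )
        reads, _ = simulate_library(truth)
        a = _contig(g.record.seq[0:12_000])
        b = _contig(g.record.seq[13_500 : L - 4])
        pl = anchor_contigs([a, b], g)
        pre = merge_and_close(pl, [a, b], g, reads)
        scaf = finalize_scaffold(pre, g)
        assert scaf.completeness >= 99.0
        assert sum(gp.fill_length for gp in scaf.gaps) <= 300

    def test_flank_default_is_300(self):
        import inspect

        sig = inspect.signature(merge_and_close)
        assert sig.parameters["flank"].default == 300


class TestBackmap:
    def test_mean_coverage_within_ten_percent(self, small_genome):
        cov = 50.0
        truth = TruthSet(
            genomes=[small_genome], coverages={small_genome.id: cov},
            library=LibraryParams(error_rate=0.0), seed=8,
        )
        reads, _ = simulate_library(truth)
        scaf = ScaffoldResult(
            seq=small_genome.record.seq, gaps=[], reference_id="self",
            completeness=100.0,
        )
        qc = backmap_qc([scaf], {"libA": reads})
        row = qc.rows[0]
        assert row.library == "libA"
        assert abs(row.mean_coverage - cov) / cov < 0.10
        assert not qc.has_conflicts

    def test_one_row_per_scaffold_per_library(self, small_genome):
        truth = TruthSet(
            genomes=[small_genome], coverages={small_genome.id: 5.0},
            library=LibraryParams(error_rate=0.0), seed=9,
        )
        reads, _ = simulate_library(truth)
        half = len(reads) // 2
        lib1 = reads.subset(range(half))
        lib2 = reads.subset(range(half, len(reads)))
        scaf = ScaffoldResult(
            seq=small_genome.record.seq, gaps=[], reference_id="self",
        )
        qc = backmap_qc([scaf], {"enriched": lib1, "non_enriched": lib2})
        assert {(r.scaffold_id, r.library) for r in qc.rows} == {
            ("scaffold_self", "enriched"), ("scaffold_self", "non_enriched"),
        }
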