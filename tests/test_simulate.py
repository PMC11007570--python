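"""Synthetic community generator: architecture, haplotypes, libraries."""

import numpy as np
import pytest

from mitofish.annotate import detect_rearrangements
from mitofish.seqio import extract_feature, revcomp, translate_cds
from mitofish.simulate import (
    ArchitectureSpec,
    LibraryParams,
    TruthSet,
    build_panel_genome,
    derive_haplotype,
    make_host_fragments,
    simulate_library,
)

CDS_12 = {"COX1", "COX2", "COX3", "COB", "ATP6",
          "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6"}


class TestArchitecture:
    def test_contains_the_twelve_protein_genes(self, small_genome):
        names = {f.name for f in small_genome.features if f.kind == "CDS"}
        assert names == CDS_12

    def test_split_exon_structure(self, small_genome):
        assert len(small_genome.get("COX1").exons) == 8
        assert len(small_genome.get("NAD5").exons) == 2
        assert len(small_genome.get("16S_a").exons) == 2
        assert len(small_genome.get("16S_b").exons) == 2

    def test_cox1_has_one_micro_exon(self, small_genome):
        lens = sorted(e - s for s, e in small_genome.get("COX1").exons)
        assert 9 <= lens[0] <= 20
        assert lens[1] >= 60

    def test_length_in_range_and_circular(self, small_genome):
        assert 32_000 <= len(small_genome.record) <= 44_000
        assert small_genome.record.circular

    def test_every_cds_is_a_table4_orf(self, small_genome):
        for f in small_genome.features:
            if f.kind in ("CDS", "ORF"):
                pep = translate_cds(extract_feature(small_genome, f), 4)
                assert "*" not in pep and len(pep) > 0

    def test_deterministic_for_seed(self):
        a = build_panel_genome(seed=7)
        b = build_panel_genome(seed=7)
        assert a.record.seq == b.record.seq
        assert [f.exons for f in a.features] == [f.exons for f in b.features]

    def test_infeasible_spec_rejected(self):
        spec = ArchitectureSpec(genome_length_range=(18_000, 18_001))
        with pytest.raises(ValueError, match="infeasible|room"):
            build_panel_genome(spec, seed=0)


class TestHaplotypes:
    def test_zero_divergence_is_identity(self, small_genome):
        h, d = derive_haplotype(small_genome, 0.0, seed=5)
        assert h.record.seq == small_genome.record.seq
        assert d == 0.0

    def test_realized_divergence_near_target(self, small_genome):
        """Realized p-distance within 3 binomial SD of the request (the
        rRNA/tRNA rate reduction lowers the genome-wide mean slightly)."""
        target = 0.02
        L = len(small_genome.record)
        h, d = derive_haplotype(small_genome, target, seed=6)
        sd = np.sqrt(target * (1 - target) / L)
        assert abs(d - target) < 3 * sd + 0.25 * target

    def test_conserved_features_mutate_at_half_rate(self, small_genome):
        h, _ = derive_haplotype(small_genome, 0.08, seed=9)
        a = np.frombuffer(small_genome.record.seq.encode(), dtype=np.uint8)
        b = np.frombuffer(h.record.seq.encode(), dtype=np.uint8)
        diff = a != b
        rna_mask = np.zeros(len(a), dtype=bool)
        for f in small_genome.features:
            if f.kind in ("rRNA", "tRNA"):
                for s, e in f.exons:
                    rna_mask[s:e] = True
        rate_rna = diff[rna_mask].mean()
        rate_rest = diff[~rna_mask].mean()
        assert rate_rna < 0.75 * rate_rest

    def test_cds_remain_stop_free(self, small_genome):
        h, _ = derive_haplotype(small_genome, 0.15, seed=10)
        for f in h.features:
            if f.kind in ("CDS", "ORF"):
                translate_cds(extract_feature(h, f), 4)  # raises on stops

    def test_planted_inversion_detected_exactly_once(self, small_genome):
        h, _ = derive_haplotype(
            small_genome, 0.02,
            rearrangement=("inversion", ("tRNA-Thr", "tRNA-Lys")), seed=2,
        )
        calls = detect_rearrangements(small_genome, h)
        assert len(calls) == 1 and calls[0].kind == "inversion"
        assert set(calls[0].features) == {"tRNA-Thr", "tRNA-Lys"}


class TestLibrary:
    def _truth(self, genome, coverage, error=0.0, seed=4):
        return TruthSet(
            genomes=[genome], coverages={genome.id: coverage},
            library=LibraryParams(error_rate=error), seed=seed,
        )

    def test_pair_count_closed_form(self, small_genome):
        cov = 50.0
        reads, _ = simulate_library(self._truth(small_genome, cov))
        L = len(small_genome.record)
        assert len(reads) == round(cov * L / (2 * 250))

    def test_read_length_and_inserts(self, small_genome):
        reads, origins = simulate_library(self._truth(small_genome, 5.0))
        assert all(len(s) == 250 for s in reads.seq1 + reads.seq2)
        assert all(400 <= ins <= 800 for _, _, _, ins in origins)

    def test_same_seed_identical_output(self, small_genome):
        r1, _ = simulate_library(self._truth(small_genome, 10.0))
        r2, _ = simulate_library(self._truth(small_genome, 10.0))
        assert r1.seq1 == r2.seq1 and r1.seq2 == r2.seq2 and r1.ids == r2.ids

    def test_error_free_reads_match_genome_exactly(self, small_genome):
        reads, origins = simulate_library(self._truth(small_genome, 3.0))
        doubled = small_genome.record.seq * 2
        for i in range(len(reads)):
            _, _, start, insert = origins[i]
            assert reads.seq1[i] == doubled[start : start + 250]
            assert reads.seq2[i] == revcomp(
                doubled[start + insert - 250 : start + insert]
            )

    def test_observed_coverage_within_ten_percent(self, small_genome):
        cov = 40.0
        reads, origins = simulate_library(self._truth(small_genome, cov))
        L = len(small_genome.record)
        depth = np.zeros(L)
        for _, _, start, insert in origins:
            for s in (start, start + insert - 250):
                idx = np.arange(s, s + 250) % L
                depth[idx] += 1
        assert abs(depth.mean() - cov) / cov < 0.10

    def test_host_fragments_total_and_count(self):
        frags = make_host_fragments(seed=1, total_bp=500_000, n_fragments=120)
        assert len(frags) == 120
        assert sum(len(f.seq) for f in frags) == 500_000

    def test_reads_never_contain_n(self, small_genome):
        reads, _ = simulate_library(self._truth(small_genome, 2.0, error=0.01))
        assert all("N" not in s for s in reads.seq1 + reads.seq2)
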