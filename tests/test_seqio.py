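"""Sequence records, translation table 4, feature extraction, file I/O."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitofish import seqio
from mitofish.seqio import (
    AnnotatedGenome,
    Feature,
    InternalStopError,
    SequenceRecord,
    TranslationError,
    extract_feature,
    revcomp,
    translate_cds,
)


class TestTranslation:
    def test_tga_is_trp_in_table_4_and_terminal_stop_stripped(self):
        assert translate_cds("ATGTGATTTTAA", 4) == "MWF"

    def test_tga_is_stop_in_table_1(self):
        with pytest.raises(InternalStopError) as exc:
            translate_cds("ATGTGATTTTAA", 1)
        assert exc.value.codon_index == 1

    def test_length_error(self):
        with pytest.raises(TranslationError):
            translate_cds("ATGTT", 4)

    def test_internal_stop_position_reported(self):
        with pytest.raises(InternalStopError) as exc:
            translate_cds("ATGAAATAGTTTTAA", 4)
        assert exc.value.codon_index == 2

    def test_n_codon_translates_to_x(self):
        assert translate_cds("ATGNNATTT", 4) == "MXF"

    def test_agrees_with_codon_lookup_brute_force(self):
        """Random in-frame, stop-free sequences translate identically to a
        literal codon-table walk."""
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[4]
        rng = np.random.default_rng(0)
        bases = "ACGT"
        n_checked = 0
        while n_checked < 1000:
            n_cod = int(rng.integers(2, 60))
            s = "".join(bases[i] for i in rng.integers(0, 4, 3 * n_cod))
            codons = [s[i : i + 3] for i in range(0, len(s), 3)]
            if any(c in tbl.stop_codons for c in codons):
                continue
            expected = "".join(tbl.forward_table[c] for c in codons)
            assert translate_cds(s, 4) == expected
            n_checked += 1


class TestExtractFeature:
    def _genome(self, seq, exons, strand="+", circular=True):
        rec = SequenceRecord("g", seq, circular=circular)
        f = Feature("X", "CDS", exons, strand)
        return AnnotatedGenome(rec, [f]), f

    def test_origin_spanning_exon(self):
        seq = "".join("ACGT"[i % 4] for i in range(100))
        g, f = self._genome(seq, [(90, 10)])
        assert extract_feature(g, f) == seq[90:] + seq[:10]
        assert len(extract_feature(g, f)) == 20

    def test_multi_exon_concatenation(self):
        seq = "AAACCCGGGTTT" * 10
        g, f = self._genome(seq, [(0, 6), (50, 56)])
        assert extract_feature(g, f) == seq[0:6] + seq[50:56]

    def test_minus_strand_reverse_complement(self):
        seq = "ACGTACGTACGTACGTACGT"
        g, f = self._genome(seq, [(0, 6)], strand="-")
        assert extract_feature(g, f) == revcomp(seq[:6])

    def test_out_of_range_on_linear_record(self):
        with pytest.raises(ValueError):
            SequenceRecord("g", "ACGT" * 10, circular=False).fetch(35, 45)

    def test_reinsertion_reproduces_genome_locally(self):
        """Extract-then-reinsert is the identity on the covered positions."""
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        g, f = self._genome(seq, [(20, 50), (100, 130)])
        ext = extract_feature(g, f)
        assert seq[20:50] == ext[:30] and seq[100:130] == ext[30:]


class TestFastx:
    def test_fasta_roundtrip(self, tmp_path):
        recs = [
            SequenceRecord("a", "ACGTN", description="first"),
            SequenceRecord("b", "ACGT" * 40),
            SequenceRecord("c", "TTTT"),
        ]
        p = tmp_path / "x.fasta"
        seqio.write_fasta(p, recs)
        back = seqio.read_fasta(p)
        assert [(r.id, r.seq, r.description) for r in back] == [
            (r.id, r.seq, r.description) for r in recs
        ]

    def test_gzip_and_plain_identical(self, tmp_path):
        recs = [SequenceRecord("a", "ACGTACGT")]
        seqio.write_fasta(tmp_path / "x.fasta", recs)
        seqio.write_fasta(tmp_path / "x.fasta.gz", recs)
        assert seqio.read_fasta(tmp_path / "x.fasta")[0].seq == \
            seqio.read_fasta(tmp_path / "x.fasta.gz")[0].seq

    def test_fastq_pair_roundtrip(self, tmp_path):
        pairs = [(f"frag{i}", "ACGT" * 10, "I" * 40, "TTTT" * 10, "F" * 40)
                 for i in range(3)]
        seqio.write_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq", pairs)
        back = seqio.read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert back == pairs

    def test_quality_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\n" + "A" * 250 + "\n+\n" + "I" * 249 + "\n")
        with pytest.raises(ValueError, match="length"):
            list(seqio._iter_fastq(p))

    def test_desynchronized_pairs_rejected(self, tmp_path):
        seqio.write_fastq_pairs(
            tmp_path / "a1.fastq", tmp_path / "a2.fastq",
            [("f1", "ACGT", "IIII", "ACGT", "IIII")],
        )
        (tmp_path / "b2.fastq").write_text("@g9/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="desynchronized"):
            seqio.read_fastq_pairs(tmp_path / "a1.fastq", tmp_path / "b2.fastq")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGTN", min_size=1, max_size=80),
                st.text(alphabet="ACGTN", min_size=1, max_size=80),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_fastq_roundtrip_fuzzed(self, tmp_path_factory, seqs):
        tmp = tmp_path_factory.mktemp("fq")
        pairs = [
            (f"p{i}", s1, "I" * len(s1), s2, "J" * len(s2))
            for i, (s1, s2) in enumerate(seqs)
        ]
        seqio.write_fastq_pairs(tmp / "1.fastq.gz", tmp / "2.fastq.gz", pairs)
        assert seqio.read_fastq_pairs(tmp / "1.fastq.gz", tmp / "2.fastq.gz") == pairs


class TestTables:
    def test_feature_table_roundtrip(self, tmp_path, small_genome):
        p = tmp_path / "feat.tsv"
        seqio.write_feature_table(p, [small_genome])
        back = seqio.read_feature_table(p, [small_genome.record])[0]
        assert [(f.name, f.kind, f.exons, f.strand) for f in back.features] == [
            (f.name, f.kind, f.exons, f.strand) for f in small_genome.features
        ]

    def test_gff3_export(self, tmp_path, small_genome):
        p = tmp_path / "ann.gff3"
        seqio.write_gff3(p, [small_genome])
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        body = [l for l in lines if not l.startswith("#")]
        n_exons = sum(len(f.exons) for f in small_genome.features)
        assert len(body) >= n_exons
        for l in body:
            cols = l.split("\t")
            assert len(cols) == 9
            assert 1 <= int(cols[3]) <= int(cols[4]) <= len(small_genome.record)
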