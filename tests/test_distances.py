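"""p-distances, rank tables, diagnostic scan, trees, exports."""

import numpy as np
import pandas as pd
import pytest

from mitofish.distances import (
    Alignment,
    DistanceMatrix,
    RankPartition,
    build_matrices,
    diagnostic_marker_scan,
    nj_tree,
    pdistance_matrix,
    percent_identity,
    rank_mean_distances,
    write_nexus,
    write_phylip,
)
from mitofish.simulate import build_panel_genome


def brute_force_pdistance(rows, alphabet):
    """Literal per-pair, per-column loop implementing pairwise deletion."""
    valid = set("ACGT") if alphabet == "dna" else set("ACDEFGHIKLMNPQRSTVWY")
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            used = mism = 0
            for a, b in zip(rows[i], rows[j]):
                if a in valid and b in valid:
                    used += 1
                    if a != b:
                        mism += 1
            out[i, j] = mism / used if used else np.nan
    return out


class TestPDistance:
    def test_simple_peptide_example(self):
        dm = pdistance_matrix(Alignment(["a", "b"], ["MKV", "MKL"], "aa"))
        assert dm.get("a", "b") == pytest.approx(1 / 3)

    def test_pairwise_deletion_example(self):
        dm = pdistance_matrix(Alignment(["a", "b"], ["MK-", "MKL"], "aa"))
        assert dm.get("a", "b") == 0.0
        assert dm.n_sites[0, 1] == 2

    def test_ambiguity_codes_excluded(self):
        dm = pdistance_matrix(Alignment(["a", "b"], ["ACGX", "ACGT"], "aa"))
        assert dm.n_sites[0, 1] == 3
        dm2 = pdistance_matrix(Alignment(["a", "b"], ["ACGN", "ACGT"], "dna"))
        assert dm2.n_sites[0, 1] == 3

    def test_zero_usable_sites_is_nan(self):
        dm = pdistance_matrix(Alignment(["a", "b"], ["--A", "A--"], "dna"))
        assert np.isnan(dm.get("a", "b"))

    def test_matches_brute_force_on_fuzzed_alignments(self):
        """200 random gapped alignments agree exactly with the site loop."""
        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(3, 61))
            alphabet = "dna" if trial % 2 else "aa"
            chars = "ACGT" if alphabet == "dna" else "ACDEFGHIKLMNPQRSTVWY"
            rows = []
            for _ in range(n):
                row = [
                    "-" if rng.random() < 0.10 else chars[rng.integers(0, len(chars))]
                    for _ in range(m)
                ]
                rows.append("".join(row))
            aln = Alignment([f"t{i}" for i in range(n)], rows, alphabet)
            got = pdistance_matrix(aln).matrix
            expect = brute_force_pdistance(rows, alphabet)
            np.testing.assert_array_equal(np.isnan(got), np.isnan(expect))
            np.testing.assert_allclose(
                np.nan_to_num(got), np.nan_to_num(expect), rtol=0, atol=0
            )

    def test_distances_symmetric_zero_diagonal_in_range(self):
        rng = np.random.default_rng(23)
        rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, 40)) for _ in range(6)]
        dm = pdistance_matrix(Alignment([f"x{i}" for i in range(6)], rows, "dna"))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert np.nanmax(dm.matrix) <= 1.0 and np.nanmin(dm.matrix) >= 0.0


class TestPercentIdentity:
    def test_identical_rows(self):
        assert percent_identity("ACGT", "ACGT") == 100.0

    def test_one_mismatch_in_hundred(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert percent_identity(a, b) == pytest.approx(99.0)

    def test_consistent_with_pdistance_on_gap_free_pairs(self):
        rng = np.random.default_rng(31)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        b = "".join(
            ch if rng.random() > 0.1 else "ACGT"[rng.integers(0, 4)] for ch in a
        )
        dm = pdistance_matrix(Alignment(["a", "b"], [a, b], "dna"))
        assert percent_identity(a, b) == pytest.approx(100 * (1 - dm.get("a", "b")))

    def test_zero_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            percent_identity("--", "A-")


def _dm(ids, entries):
    n = len(ids)
    m = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(ids, m, np.full((n, n), 100), "g")


class TestRankMeans:
    def test_between_group_mean_arithmetic(self):
        """Groups {A,B} and {C}: mean over between-group pairs = 0.3."""
        dm = _dm(["A", "B", "C"], {("A", "C"): 0.4, ("B", "C"): 0.2, ("A", "B"): 0.1})
        part = RankPartition({
            t: {"class": "K", "order": "O", "family": "F",
                "genus": g, "species": t, "clade": g, "haplotype": t}
            for t, g in [("A", "G1"), ("B", "G1"), ("C", "G2")]
        })
        df = rank_mean_distances({"g": dm}, part)
        assert df.loc["genus_within_family", "g"] == pytest.approx(0.3)

    def test_single_group_is_not_applicable(self):
        dm = _dm(["A", "B"], {("A", "B"): 0.2})
        part = RankPartition({
            t: {"class": "K", "order": "O", "family": "F",
                "genus": "G1", "species": t, "clade": "G1", "haplotype": t}
            for t in ["A", "B"]
        })
        df = rank_mean_distances({"g": dm}, part)
        assert np.isnan(df.loc["genus_within_family", "g"])

    def test_partition_nesting_enforced(self):
        with pytest.raises(ValueError, match="nested"):
            RankPartition({
                "A": {"class": "K1", "order": "O1", "family": "F", "genus": "G",
                      "species": "A", "clade": "G", "haplotype": "A"},
                "B": {"class": "K1", "order": "O2", "family": "F", "genus": "G",
                      "species": "B", "clade": "G", "haplotype": "B"},
            })

    def test_partition_table_roundtrip(self, tmp_path):
        part = RankPartition({
            "A": {"class": "K", "order": "O", "family": "F", "genus": "G",
                  "species": "A", "clade": "G", "haplotype": "A"},
        })
        p = tmp_path / "taxa.tsv"
        part.to_table(p)
        back = RankPartition.from_table(p)
        assert back.memberships == part.memberships


class TestDiagnosticScan:
    def _part(self):
        return RankPartition({
            t: {"class": "K", "order": "O", "family": "F", "genus": g,
                "species": t, "clade": g, "haplotype": t}
            for t, g in [("A1", "G1"), ("A2", "G1"), ("B1", "G2"),
                         ("B2", "G2"), ("C1", "G3")]
        })

    def test_planted_diagnostic_gene_found(self):
        ids = ["A1", "A2", "B1", "B2", "C1"]
        diag = _dm(ids, {
            ("A1", "B1"): 0.1, ("A1", "B2"): 0.1, ("A2", "B1"): 0.1,
            ("A2", "B2"): 0.1, ("A1", "C1"): 0.2, ("A2", "C1"): 0.2,
            ("B1", "C1"): 0.15, ("B2", "C1"): 0.15,
        })
        noisy = _dm(ids, {
            ("A1", "A2"): 0.01, ("B1", "B2"): 0.01, ("A1", "B1"): 0.1,
            ("A1", "B2"): 0.1, ("A2", "B1"): 0.1, ("A2", "B2"): 0.1,
            ("A1", "C1"): 0.2, ("A2", "C1"): 0.2, ("B1", "C1"): 0.15,
            ("B2", "C1"): 0.15,
        })
        hits = diagnostic_marker_scan(
            {"diag": diag, "noisy": noisy}, self._part(), "genus"
        )
        assert hits == ["diag"]

    def test_constant_gene_not_diagnostic(self):
        ids = ["A1", "A2", "B1", "B2", "C1"]
        flat = _dm(ids, {})
        assert diagnostic_marker_scan({"flat": flat}, self._part(), "genus") == []

    def test_within_group_mismatch_disqualifies(self):
        ids = ["A1", "A2", "B1", "B2", "C1"]
        g = _dm(ids, {("A1", "A2"): 0.01, ("A1", "B1"): 0.1, ("A1", "B2"): 0.1,
                      ("A2", "B1"): 0.1, ("A2", "B2"): 0.1, ("A1", "C1"): 0.2,
                      ("A2", "C1"): 0.2, ("B1", "C1"): 0.15, ("B2", "C1"): 0.15})
        assert diagnostic_marker_scan({"g": g}, self._part(), "genus") == []


class TestMatricesAndTrees:
    def test_identical_genomes_align_gap_free(self):
        g1 = build_panel_genome(seed=51, genome_id="g1")
        g2 = build_panel_genome(seed=51, genome_id="g2")
        matrices, per_gene = build_matrices([g1, g2])
        aa = matrices["CDS_aa"]
        assert "-" not in aa.rows[0] and aa.rows[0] == aa.rows[1]
        assert matrices["CDS_nt"].n_columns == 3 * aa.n_columns
        total = sum(e - s for _, s, e in matrices["CDS_nt"].partitions)
        assert total == matrices["CDS_nt"].n_columns
        assert percent_identity(*matrices["CDS_nt"].rows) == 100.0

    def test_nj_recovers_additive_topology(self):
        ids = ["A", "B", "C", "D"]
        #    ((A,B),(C,D)) with internal branch 1
        m = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float)
        dm = DistanceMatrix(ids, m, np.full((4, 4), 100), "t")
        nwk = nj_tree(dm, outgroup="A")
        from skbio import TreeNode
        from io import StringIO

        t = TreeNode.read(StringIO(nwk))
        names = {x.name for x in t.tips()}
        assert names == set(ids)
        # C and D must be sisters
        c = t.find("C")
        sisters = {x.name for x in c.parent.tips()}
        assert sisters == {"C", "D"}

    def test_newick_roundtrip(self):
        ids = ["A", "B", "C", "D"]
        m = np.array([
            [0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]
        ], dtype=float)
        dm = DistanceMatrix(ids, m, np.full((4, 4), 100), "t")
        nwk = nj_tree(dm)
        from skbio import TreeNode
        from io import StringIO

        t = TreeNode.read(StringIO(nwk))
        assert str(t).strip() == nwk

    def test_missing_outgroup_rejected(self):
        m = np.array([[0, 1.0, 1], [1, 0, 1], [1, 1, 0]])
        dm = DistanceMatrix(["A", "B", "C"], m, np.full((3, 3), 10), "t")
        with pytest.raises(ValueError, match="outgroup"):
            nj_tree(dm, outgroup="ZZZ")

    def test_phylip_and_nexus_exports(self, tmp_path):
        aln = Alignment(["tax1", "tax2"], ["ACGTAC", "ACGTTC"], "dna",
                        [("gene1", 0, 3), ("gene2", 3, 6)])
        write_phylip(aln, tmp_path / "a.phy")
        write_nexus(aln, tmp_path / "a.nex")
        phy = (tmp_path / "a.phy").read_text().splitlines()
        assert phy[0].split() == ["2", "6"]
        from Bio import AlignIO

        bio = AlignIO.read(tmp_path / "a.phy", "phylip-relaxed")
        assert str(bio[0].seq) == "ACGTAC"
        nex = (tmp_path / "a.nex").read_text()
        assert "CHARSET gene1 = 1-3;" in nex
        assert "CHARSET gene2 = 4-6;" in nex
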