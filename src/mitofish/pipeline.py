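"""End-to-end orchestration: simulate -> preprocess -> bait -> assemble ->
scaffold -> annotate (-> distances), with persisted artifacts and a
deterministic run report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from . import seqio
from .annotate import detect_rearrangements, transfer_annotations, validate_orfs
from .assembly import Contig, assemble_and_extend
from .baiting import bait_reads
from .preprocess import correct_reads, preprocess_reads
from .reads import ReadSet
from .scaffold import (
    ScaffoldResult,
    anchor_contigs,
    backmap_qc,
    finalize_scaffold,
    merge_and_close,
)
from .seqio import AnnotatedGenome, SequenceRecord
from .simulate import TruthSet, standard_mixture

__all__ = ["RunConfig", "run_pipeline", "truth_comparison", "write_report"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    ``simulate=True`` generates the standard benchmark community; with
    ``simulate=False`` the read/panel paths must point at existing files.
    """

    outdir: str = "mitofish_run"
    seed: int = 0
    simulate: bool = True
    # --- synthetic community (study conditions) ---
    prey_coverages: tuple[float, ...] = (100.0, 70.0, 40.0, 0.5)
    host_coverage: float = 30.0
    host_bp: int = 5_000_000
    panel_divergence: float = 0.06
    prey_to_ref_divergence: float = 0.05
    error_rate: float = 0.005
    # --- file inputs (simulate=False) ---
    reads1: str | None = None
    reads2: str | None = None
    panel_fasta: str | None = None
    panel_features: str | None = None
    # --- preprocessing ---
    quality_cutoff: int = 15
    k_correct: int = 21
    # --- baiting ---
    k_bait: int = 25
    min_shared_kmers: int = 2
    # --- assembly / extension ---
    k_list: tuple[int, ...] = (33, 55, 77)
    iterations: int = 10
    min_overlap: int = 50
    min_identity: float = 0.98
    # --- scaffolding ---
    flank: int = 300
    min_anchor_identity: float = 0.75
    # --- reporting ---
    persist_reads: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_list"] = list(self.k_list)
        d["prey_coverages"] = list(self.prey_coverages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "k_list" in d:
            d["k_list"] = tuple(d["k_list"])
        if "prey_coverages" in d:
            d["prey_coverages"] = tuple(d["prey_coverages"])
        return cls(**d)


def _identity_of_runs(seq_with_n: str, truth_seq: str) -> tuple[int, int]:
    """(non-N bases, total mismatches) of a scaffold against a circular
    truth genome, summed over its contiguous non-N runs."""
    import re

    target = truth_seq + truth_seq
    total = mism = 0
    for m in re.finditer(r"[ACGT]+", seq_with_n):
        run = m.group(0)
        d = edlib.align(run, target, mode="HW", task="distance")["editDistance"]
        rc = seqio.revcomp(run)
        d2 = edlib.align(rc, target, mode="HW", task="distance")["editDistance"]
        mism += min(d, d2)
        total += len(run)
    return total, mism


def truth_comparison(
    scaffolds: list[ScaffoldResult],
    truths: list[AnnotatedGenome],
    min_run: int = 100,
) -> dict[str, dict]:
    """Per-scaffold comparison against the planted truth genomes.

    Reports the best-matching truth genome, the identity over non-N bases,
    the completeness against that truth, and the number of chimeric
    columns -- positions where the scaffold disagrees with its own truth
    haplotype but matches a different one (truth genomes are colinear in
    the synthetic benchmark, so columns are compared by coordinate).  An
    isolated such column is indistinguishable from a consensus error that
    happens to coincide with another haplotype, so columns only count as
    chimeric when two or more fall within ``cluster_window`` bases of each
    other -- the signature of a genuine haplotype switch.
    """
    cluster_window = 100
    import re

    out: dict[str, dict] = {}
    truth_seqs = {t.id: t.record.seq for t in truths}
    for sc in scaffolds:
        per_truth = {}
        for tid, tseq in truth_seqs.items():
            nn, mm = _identity_of_runs(sc.seq, tseq)
            per_truth[tid] = (nn, mm)
        best = min(per_truth, key=lambda t: per_truth[t][1])
        nn, mm = per_truth[best]
        identity = 1 - mm / nn if nn else 0.0

        best_seq = truth_seqs[best]
        target = best_seq + best_seq
        others = [s for t, s in truth_seqs.items() if t != best]
        candidate_cols: list[int] = []
        for m in re.finditer(r"[ACGT]+", sc.seq):
            run = m.group(0)
            if len(run) < min_run:
                continue
            fwd = edlib.align(run, target, mode="HW", task="locations")
            rcseq = seqio.revcomp(run)
            rev = edlib.align(rcseq, target, mode="HW", task="locations")
            if rev["editDistance"] < fwd["editDistance"]:
                run, res = rcseq, rev
            else:
                res = fwd
            ls = res["locations"][0][0] or 0
            L = len(best_seq)
            for i, ch in enumerate(run):
                p = (ls + i) % L
                if ch != best_seq[p] and any(ch == o[p] for o in others):
                    candidate_cols.append(p)
        candidate_cols.sort()
        chimeric = sum(
            1
            for i, p in enumerate(candidate_cols)
            if (i > 0 and p - candidate_cols[i - 1] <= cluster_window)
            or (i + 1 < len(candidate_cols) and candidate_cols[i + 1] - p <= cluster_window)
        )
        out[sc.scaffold_id] = {
            "best_truth": best,
            "non_n_bases": nn,
            "identity_to_truth": identity,
            "completeness_vs_truth": 100.0 * nn / len(best_seq),
            "chimeric_columns": chimeric,
        }
    return out


def _bin_contigs(
    contigs: list[Contig],
    panel: list[AnnotatedGenome],
    min_identity: float,
) -> dict[str, list]:
    """Assign each contig to the panel reference it anchors best to."""
    best: dict[int, tuple[float, str, object]] = {}
    for ref in panel:
        for p in anchor_contigs(contigs, ref, min_identity):
            cur = best.get(p.contig_index)
            if cur is None or p.identity > cur[0]:
                best[p.contig_index] = (p.identity, ref.id, p)
    bins: dict[str, list] = {g.id: [] for g in panel}
    for _, (ident, rid, p) in sorted(best.items()):
        bins[rid].append(p)
    return bins


def run_pipeline(
    config: RunConfig,
    panel: list[AnnotatedGenome] | None = None,
    reads: ReadSet | None = None,
    truth: TruthSet | None = None,
    origins: list[tuple[str, str, int, int]] | None = None,
) -> dict:
    """Execute the full pipeline and return the run report (also written
    to ``outdir`` as JSON and TSV).  Fully deterministic for a given
    config and seed.  Preloaded inputs may be passed to skip simulation.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 0: inputs -----------------------------------------------------
    if panel is None or reads is None:
        if config.simulate:
            panel, truth, reads, origins = standard_mixture(
                seed=config.seed,
                prey_coverages=config.prey_coverages,
                host_coverage=config.host_coverage,
                host_bp=config.host_bp,
                panel_divergence=config.panel_divergence,
                prey_to_ref_divergence=config.prey_to_ref_divergence,
                error_rate=config.error_rate,
            )
        else:
            recs = seqio.read_fasta(config.panel_fasta, circular=True)
            panel = (
                seqio.read_feature_table(config.panel_features, recs)
                if config.panel_features
                else [AnnotatedGenome(r, []) for r in recs]
            )
            reads = ReadSet.read(config.reads1, config.reads2)
    seqio.write_fasta(outdir / "panel.fasta", [g.record for g in panel])
    if any(g.features for g in panel):
        seqio.write_feature_table(outdir / "panel_features.tsv", panel)
    if truth is not None:
        seqio.write_fasta(outdir / "truth.fasta", [g.record for g in truth.genomes])
        seqio.write_feature_table(outdir / "truth_features.tsv", truth.genomes)
    if config.persist_reads:
        reads.write(outdir / "reads_1.fastq.gz", outdir / "reads_2.fastq.gz")

    origin_map = {r: g for r, g, _, _ in origins} if origins else None
    prey_ids = {g.id for g in truth.genomes} if truth else None

    # -- stage 1: trim -------------------------------------------------------
    trimmed = preprocess_reads(reads, quality_cutoff=config.quality_cutoff)

    # -- stage 2: bait -------------------------------------------------------
    bait = bait_reads(
        trimmed,
        panel,
        min_shared_kmers=config.min_shared_kmers,
        k_bait=config.k_bait,
        truth_prey_ids=prey_ids,
        origins=origin_map,
    )

    # -- stage 3: error-correct the recruited pool ---------------------------
    n_corrected = correct_reads(bait.reads, k=config.k_correct)

    # -- stage 4: assemble + extend ------------------------------------------
    contigs = assemble_and_extend(
        bait.reads,
        k_list=config.k_list,
        iterations=config.iterations,
        min_overlap=config.min_overlap,
        min_identity=config.min_identity,
    )
    seqio.write_fasta(
        outdir / "contigs.fasta",
        [
            SequenceRecord(f"contig_{i}", c.seq, description=f"depth={c.mean_depth:.1f}")
            for i, c in enumerate(contigs)
        ],
    )
    with open(outdir / "contigs.tsv", "w") as fh:
        fh.write("contig\tlength\tmean_depth\tmax_iteration\n")
        for i, c in enumerate(contigs):
            fh.write(
                f"contig_{i}\t{len(c)}\t{c.mean_depth:.2f}\t{int(c.provenance.max())}\n"
            )

    # -- stage 5: scaffold per best reference --------------------------------
    bins = _bin_contigs(contigs, panel, config.min_anchor_identity)
    scaffolds: list[ScaffoldResult] = []
    for ref in panel:
        placements = bins.get(ref.id, [])
        pre = merge_and_close(
            placements, contigs, ref, trimmed,
            flank=config.flank, k_list=config.k_list,
            min_anchor_identity=config.min_anchor_identity,
            panel=panel,
        )
        scaffolds.append(finalize_scaffold(pre, ref))
    recovered = [s for s in scaffolds if s.completeness > 0]
    seqio.write_fasta(
        outdir / "scaffolds.fasta",
        [
            SequenceRecord(s.scaffold_id, s.seq,
                           description=f"completeness={s.completeness:.1f}%")
            for s in recovered
        ],
    )
    with open(outdir / "gaps.bed", "w") as fh:
        for s in recovered:
            for g in s.gaps:
                fh.write(f"{s.scaffold_id}\t{g.ref_start}\t{g.ref_end}\n")

    # -- stage 6: back-mapping QC (trimmed, uncorrected reads) ---------------
    truth_assignment = None
    if truth is not None:
        comparison = truth_comparison(recovered, truth.genomes)
        truth_assignment = {}
        for sid, v in comparison.items():
            prev = truth_assignment.get(v["best_truth"])
            if prev is None or (
                comparison[prev]["identity_to_truth"] < v["identity_to_truth"]
            ):
                truth_assignment[v["best_truth"]] = sid
    else:
        comparison = {}
    qc = backmap_qc(
        recovered,
        {"lib1": trimmed},
        origins=origin_map,
        truth_assignment=truth_assignment,
    )
    with open(outdir / "backmap_qc.tsv", "w") as fh:
        fh.write("scaffold\tlibrary\tn_pairs\tmean_coverage\tn_conflict_positions\n")
        for row in qc.rows:
            fh.write(
                f"{row.scaffold_id}\t{row.library}\t{row.n_pairs}\t"
                f"{row.mean_coverage:.2f}\t"
                f"{len(qc.conflict_positions.get(row.scaffold_id, []))}\n"
            )

    # -- stage 7: annotate + rearrangements ----------------------------------
    annotations: list[AnnotatedGenome] = []
    annot_summaries = {}
    for s in recovered:
        ref = next(g for g in panel if g.id == s.reference_id)
        rec = SequenceRecord(s.scaffold_id, s.seq, circular=True)
        try:
            ann, rep = transfer_annotations(rec, ref)
        except ValueError:
            continue
        orf = validate_orfs(ann)
        try:
            rearr = detect_rearrangements(ref, ann)
        except ValueError:
            rearr = []
        annotations.append(ann)
        annot_summaries[s.scaffold_id] = {
            "features_transferred": len(rep.transferred),
            "features_missing": rep.missing,
            "orf_ok": len(orf.transferred),
            "orf_issues": [
                {"name": o.name, "status": o.status, "reason": o.reason}
                for o in orf.failed
            ],
            "rearrangements": [str(c) for c in rearr],
        }
    if annotations:
        seqio.write_gff3(outdir / "annotations.gff3", annotations)

    # -- report ---------------------------------------------------------------
    coverage_by_scaffold: dict[str, dict[str, float]] = {}
    for row in qc.rows:
        coverage_by_scaffold.setdefault(row.scaffold_id, {})[row.library] = round(
            row.mean_coverage, 2
        )
    report = {
        "parameters": config.to_dict(),
        "baiting": {
            "n_recruited_pairs": len(bait.reads),
            "recall": None if bait.recall is None else round(bait.recall, 4),
            "precision": None if bait.precision is None else round(bait.precision, 4),
            "n_reads_corrected": n_corrected,
        },
        "n_contigs": len(contigs),
        "scaffolds": [
            {
                "id": s.scaffold_id,
                "reference": s.reference_id,
                "completeness_pct": round(s.completeness, 2),
                "n_gaps": len(s.gaps),
                "gap_bp": sum(g.fill_length for g in s.gaps),
                "mean_coverage": coverage_by_scaffold.get(s.scaffold_id, {}),
                "n_haplotype_conflicts": len(s.conflicts),
                "n_backmap_conflict_positions": len(
                    qc.conflict_positions.get(s.scaffold_id, [])
                ),
                "partial": s.completeness < 95.0,
                **{
                    k: (round(v, 5) if isinstance(v, float) else v)
                    for k, v in comparison.get(s.scaffold_id, {}).items()
                },
                **annot_summaries.get(s.scaffold_id, {}),
            }
            for s in recovered
        ],
        "cross_assignment_fraction": qc.cross_assignment_fraction,
        "warnings": [w for s in scaffolds for w in s.conflicts],
    }
    write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.tsv", "w") as fh:
        cols = [
            "id", "reference", "completeness_pct", "n_gaps", "gap_bp",
            "n_haplotype_conflicts", "partial",
        ]
        fh.write("\t".join(cols) + "\n")
        for s in report["scaffolds"]:
            fh.write("\t".join(str(s.get(c, "")) for c in cols) + "\n")
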