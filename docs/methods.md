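# Methods

`mitofish` recovers low-abundance prey mitochondrial genomes from
whole-body predator metagenomes and compares them across taxonomic
ranks.  The motivating system is placozoan prey DNA persisting in the
gut of rhodopid sea slugs: a gastropod nuclear background dominates the
read pool, while one to a few circular prey mitogenomes of ~32–44 kb are
present at anywhere from a fraction of 1× to several hundred ×.  This
note describes the models and procedures, the parameters that matter,
and what the synthetic benchmarks do and do not demonstrate.

## Recovery pipeline

### Read preprocessing

Reads are quality-trimmed with a sliding-window rule (window 4, mean
Phred cutoff 15, 3′ cut at the first failing window), adapter suffixes
clipped at ≥ 10 bp exact prefix match, and pairs dropped whole when
either mate falls under 50 bp.  Error correction uses a k-mer spectrum
(k = 21, odd, 15–31 allowed): a base whose covering k-mers are all
*solo* (count 1) is replaced by the unique alternative that makes every
covering k-mer *solid* (count ≥ 5); ambiguous candidates are left
untouched, and up to three corrections are attempted per read.
Correction is applied to the *baited* read pool rather than the whole
metagenome: the recruited pool is prey-dominated, so its spectrum is not
drowned by host k-mers, and the cost is proportional to the target, not
the metagenome.

### Baiting

Candidate prey pairs are recruited by exact canonical k-mer containment
against the reference panel: a pair is kept when either mate shares at
least `min_shared_kmers = 2` canonical 25-mers with any panel genome.
At k = 25 a 250 bp read retains on the order of
`226 × (1−d)²⁵` clean k-mers at per-site divergence *d* — ≈ 63 at 5%,
≈ 16 at 10%, ≈ 4 at 15% — so recruitment is reliable out to ~15%
divergence, while the chance that an unrelated 250-mer shares two
25-mers with a ~35 kb panel is far below 10⁻⁶ (verified empirically on
10⁵ random reads in the test suite).  This replaces alignment-based
(BLAST-style) baiting with a dependency-free primitive whose operating
range is explicit.

### Seed assembly

Initial contigs are unitigs of a both-strand de Bruijn graph built over
a cascade of k-mer sizes (77, then 55, then 33; reads ≥ 90% represented
by already-accepted unitigs are withheld from the smaller-k graphs, so
the largest k that resolves a region wins).  The solid-k-mer threshold
is coverage-adaptive: `max(2, 0.25 × median count of k-mers seen ≥ 2×)`.
A fixed threshold of 2 is not enough because *pairs* of reads sharing an
error at the same position and base create k-mers of count 2 in
quantity (the count scales with the square of the error load times the
k-mer span), and each such k-mer is a spurious branch point.  A final
rescue pass at the smallest k with threshold 1 retains unitigs ≥ 150 bp
from regions too thin for solid coverage — this is what produces the
partial assemblies in the sub-1× regime.

Because no sequenced fragment spans two haplotypes, chimeric k-mers do
not occur in the input and unitigs cannot switch haplotypes; branch
points at the boundaries of segments shared between haplotypes simply
terminate unitigs.

### Iterative extension

Contig ends are lengthened for `iterations = 10` rounds.  Reads
overlapping a contig end by ≥ `min_overlap = 50` bases at ≥
`min_identity = 0.98` are recruited (both orientations, located by a
31-mer index), and bases are appended one at a time under a strict 80%
base-majority rule; ties break lexicographically, so the procedure is
deterministic.  Extension halts at any position where no base reaches
the majority — the signature of a haplotype boundary — rather than
branching: ambiguity is deferred to the reference-guided stage.

After extension, contigs are merged on *exact* suffix/prefix overlaps
only when the join is unambiguous: each participating contig end must
have exactly one overlap partner (the overlap-layout uniqueness rule),
and a read must span the junction with ≥ 98% identity and ≥ 20 bp on
each side.  Both conditions are load-bearing.  When two haplotypes break
at a shared identical segment, four contig ends carry the same shared
sequence and the exact overlaps are real but ambiguous; uniqueness
rejects them.  The junction-read requirement additionally blocks joins
no fragment supports.

### Reference-guided scaffolding

Contigs are anchored to each panel genome by best infix alignment
(edlib, both orientations, circular references handled by doubling) and
assigned to the reference with the highest identity; the default
anchoring floor is 0.75 identity, low enough to anchor across
inter-genus divergence.  Within a reference bin, placements adjacent on
the reference are merged when they overlap by ≥ 30 bp at ≥ 99%
identity — contig sequence always wins over the reference, and where two
contigs disagree the deeper one is kept and a haplotype-conflict
warning is recorded instead of a merge.

Remaining reference gaps are closed locally: reads sharing ≥ 2 canonical
25-mers with the gap region plus 300 bp of flanking context are
recruited from the *trimmed* read pool, error-corrected, re-assembled
over the k cascade, re-anchored, and merged again, to a fixpoint or at
most 3 rounds.  Gap-fill contigs are kept only if the current reference
is their best anchor across the whole panel; without this filter a
low-coverage prey whose scaffold is mostly gap recruits reads of
co-occurring lineages ~10% divergent from its reference and assembles a
chimera of the wrong species.

Residual gaps are filled with one N per missing reference base, so gap
lengths and completeness are approximations inherited from the
reference alignment — reference bases are never copied into the
scaffold.  Completeness is `100 × covered reference positions / L`.  If
the scaffold ends overlap on the circle by ≥ 30 bp at ≥ 99% identity the
molecule is closed and emitted from reference position 0.

### Back-mapping QC

Trimmed (uncorrected) reads are re-assigned to their best scaffold by
shared 25-mer count, located by a 31-mer anchor, and compared base by
base.  Per-scaffold, per-library mean coverage is reported, and
positions where > 20% of covering reads disagree with the scaffold base
(at depth ≥ 5) are flagged as potential chimera/haplotype-mixing sites.
Uncorrected reads are used deliberately: if correction had homogenized
co-occurring haplotypes, the disagreement track would reveal it.

### Annotation transfer and validation

Gene models are projected from the annotated reference through a global
edlib alignment (N matches anything); transfer is refused below 60%
identity.  Exons landing wholly inside N runs are reported missing;
projected protein genes whose length breaks frame are snapped to the
nearest in-frame boundary within ±6 nt — the declared remedy for exons
too short to anchor an alignment unambiguously (the cox1 micro exon).
Every CDS/ORF is then validated under translation table 4 (TGA = Trp):
frame, start codon (ATG or GTG accepted, configurable), internal stops
(reported with codon position), terminal stop.  A CDS truncated by an N
gap is reported *incomplete*, not failed.

Gene orders are compared as signed circular permutations rotated to a
shared anchor (COX1): maximal reversed blocks are inversions, single
features whose removal reconciles the orders are translocations, and up
to four sequential events are peeled off before a residual difference
is reported as `complex`.  Events spanning the anchor gene are a known
blind spot; the anchor is configurable.

## Distance framework

Per-gene coding sequences are translated (table 4; codons containing N
become X), peptides aligned with MAFFT (`--auto`), and the gaps
back-mapped onto codons, so the concatenated nucleotide matrix is
exactly three times the width of the amino-acid matrix.  The rDNA
matrix concatenates the 12S alignment and an alignment of the combined
two-part 16S.  Missing genes become all-gap rows.

Distances are uncorrected p-distances under pairwise deletion: for each
pair of rows, columns with a gap or ambiguity (N/X) in either row are
excluded and the distance is the mismatch fraction over the remaining
sites; pairs with zero usable sites are undefined (NaN) and recorded
with their usable-site counts.  Percent identity uses columns where
both rows are non-gap as denominator, which reduces to `100 × (1 − p)`
on gap-free pairs.

Rank-wise tables average, for each child-rank-within-parent-rank pair
(orders within classes … haplotypes within clades), the mean distance
over taxon pairs belonging to different child groups inside one parent
group, then average over parent groups; per-gene values are averaged
into a per-rank grand mean, with the concatenated matrix carried as a
thirteenth column.  Averaging is over taxon pairs within each parent
group (then over parent groups) — one of several defensible
conventions, pinned here and used consistently.  A rank with a single
group is not applicable and reported as NaN.

A gene is a *diagnostic marker* at a rank iff its maximum within-group
distance is exactly zero and its minimum between-group distance is
positive, with undefined pairs disqualifying the gene — the criterion
that makes a short protein usable as a group-membership barcode.

Neighbor-joining trees (scikit-bio, negative branches clamped to zero,
rooted on a designated outgroup) serve as an internal sanity check on
the matrices; model-based tree inference is intentionally out of scope,
and the matrices are exported as FASTA/relaxed PHYLIP/NEXUS (with
charset blocks) for external programs.

## The synthetic community

The generator is the package's ground-truth instrument and emulates the
study system:

* **Architecture** — circular genomes of 32–44 kb carrying the 12
  mitochondrial protein genes (COX1-3, COB, ATP6, NAD1-6, NAD4L), 12S,
  a two-part 16S split into four exons, twelve tRNAs, and optional large
  ORFs (POLB between NAD1 and NAD4L by default; LAG, RVT-IM).  COX1 has
  eight exons including one 9–20 bp micro exon; NAD5 has two.  One CDS
  (NAD6) and one tRNA lie on the minus strand.  Spacer and intron
  lengths are drawn to hit a target genome length exactly.  Every CDS
  translates stop-free under table 4 by construction.
* **Haplotypes** — per-site substitutions at a target divergence, with
  rRNA/tRNA evolving at half the rate (conservation mimicry,
  configurable), start/stop codons protected, and codons that would
  acquire internal stops reverted; the realized divergence is recorded.
  Optional rearrangements: an inversion spanning two named features or a
  translocation of a single-exon feature, with annotations updated.
* **Libraries** — fragment count per genome is
  `round(coverage × L / (2 × 250))`, starts uniform on the circle,
  inserts uniform in 400–800 bp, 250 bp mates, independent per-base
  substitution errors (default 0.5%); no indels (an indel-rate flag
  exists but the error model is substitution-only).  The host background
  is 100–500 random linear fragments totaling 5 Mb — non-homologous
  background for baiting specificity, not a real genome.
* **Benchmark mixture** — one base architecture diverged into one panel
  reference per prey lineage (6% each, hence ~11–12% between panel
  genomes) and one prey haplotype 5% from its reference; prey coverages
  100/70/40/0.5×, host 30×.  These are the conditions under which the
  acceptance checks run.
* **Clock-like taxon panel** — 33 taxa in two classes (one class with a
  single representative, blocking intra-group comparison at the top
  rank exactly as a monotypic class does), nested 2×2×2×2×2 with rank
  divergences 0.20/0.10/0.06/0.035/0.018/0.008.  NAD3 is planted as the
  genus-level diagnostic *by construction*: every leaf inherits its
  genus ancestor's NAD3 (ancestral copies forced distinct at the protein
  level), and every other protein gene is forced to vary within each
  genus.  The uniqueness of the scan hit is therefore structural, not a
  property of a particular seed.

What passing on this generator does **not** show: robustness to indels
and structural error modes of real sequencers, amplification and
enrichment bias, repeat content of real mitogenomes (the synthetic
sequence is repeat-free apart from the planted architecture), chimeric
library artifacts, or divergences so high that baiting recall decays.
The discrimination floor between co-occurring haplotypes is likewise
idealized: at 0.3% divergence the pipeline is *expected* to emit mosaic
scaffolds and must instead flag back-mapping disagreement positions,
which is what the corresponding check asserts.

## Numerical and procedural choices

* Intervals are 0-based half-open on the forward strand; circular
  coordinates normalized to `[0, L)`; minus-strand exons are listed in
  transcript order.
* Pairwise alignment throughout is edlib edit-distance alignment with
  N treated as matching any base.  Identity is `1 − dist/len`.  An
  affine-gap scorer would differ only on indel-rich comparisons, which
  the substitution-dominated data here do not produce.
* Consensus ties in extension break lexicographically; contig output is
  sorted by length then sequence; all randomness flows from a single
  integer seed fanned out through `numpy.random.default_rng`.
* Reported problem sizes: the benchmark community is ~310 k read pairs
  (5 Mb host at 30× plus four prey), the two-haplotype floor runs use
  ~28 k pairs, and the rank analysis runs on the 33-taxon panel — sizes
  chosen so a full verification pass completes on a laptop-class single
  CPU.

## Known limitations

* Gap lengths and completeness inherit reference-alignment
  approximation; a prey whose true genome differs structurally from its
  nearest reference will be mis-measured (flagged by the rearrangement
  detector only when annotation transfer succeeds).
* The rearrangement detector handles up to four sequential simple
  events and does not attempt minimal signed-reversal distances.
* tRNA annotation is positional (projection), with no secondary
  structure validation.
* The assembler is designed for a handful of small circular targets at
  mixed coverage, not for general metagenome assembly; the host is never
  assembled.
* GenBank flat files are not parsed or written; annotations travel as
  tab-separated feature tables and GFF3.
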