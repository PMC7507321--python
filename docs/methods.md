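# Methods

This note documents the models, parameter choices and numerical conventions
behind `circnigra`, and what the synthetic benchmarks do and do not show
about real data.

## Coordinates and sequence conventions

All intervals are 0-based half-open internally; conversion happens only at
the format boundaries (GTF 1-based closed, SAM POS 1-based, BED unchanged).
Bases are encoded A=0, C=1, G=2, T=3 so complementation is `3 - code`.
Junction identity is the tuple (chrom, start, end, strand) with `start` the
first base of the circle (acceptor side) and `end` one past its last base
(donor side).

## The synthetic cohort generator

The generator emulates the statistical structure a circRNA analysis of
rRNA-depleted brain RNA-seq assumes, at desk scale:

- **Genome.** Random nucleotide background; genes laid out sequentially with
  2–4 exons of 150–400 nt, introns of 200–600 nt. Every exon boundary gets a
  canonical splice signal in transcribed orientation (GT just past the donor,
  AG just before the acceptor; their reverse complements AC/CT on the plus
  strand for minus-strand genes), so both linear and back-splice junctions
  are canonically flanked. About half the genes carry one circularizable
  exon (an interior exon when available, as for single-exon circles such as
  the circularized second exon of SLC8A1), with a per-gene circularized
  fraction drawn uniformly from 0.1–0.4 and lognormal expression (σ = 1).
- **Alu elements.** Annotated intervals (the background sequence is random;
  no Alu consensus is modelled because the editing index only needs interval
  membership and reference bases) placed inside circularizable exons, in
  their flanking introns, and at low density intergenically, with a 50/50
  sense/antisense mix.
- **Editing.** Per-site rates at Alu adenosines of the transcribed strand,
  Beta(2, 48) by default (mean 4%, the order of bulk-brain Alu editing), or
  a uniform rate for calibration experiments. Editing is applied on the
  transcribed strand before sequencing error, so minus-strand genes show
  T-to-C on the plus-strand pileup — exactly the orientation rule the index
  later applies.
- **Reads.** Single-end, fixed length (default 100 nt), fixed quality.
  Within a gene, reads come from the circular exon (with wrap-around and
  uniform start positions, giving the closed-form junction-crossing fraction
  (R−1)/L), from the spliced transcript, or from unspliced pre-mRNA. The
  unspliced fraction (default 0.15) models the intronic signal of
  rRNA-depleted total-RNA libraries; without it, flanking-intron regions
  would receive no coverage and the circRNA-proximal editing report would be
  undefined. Sequencing error is a uniform substitution to one of the three
  other bases (no indels, no quality model).
- **Cohort effects.** Group multipliers ((column, level) → multiplier on the
  circularized fraction and on editing rates), an age slope on circular
  output restricted to one region, optional per-sample lognormal variation
  of the circularization factor, and an optional inverse coupling that sets
  the editing multiplier to that factor to the power −g. All randomness
  derives from the design seed; identical seeds give byte-identical FASTQ
  and SAM output.
- **Truth.** Expected junction-read counts per sample (n·p·cf·(R−1)/L),
  realized junction-crossing counts, per-sample multipliers and editing
  means, and an error-free truth alignment for every read. Linear spliced
  reads use N-skip CIGARs; the wrapped part of a junction read is written as
  a supplementary-style second record.

What the generator does **not** emulate: paired-end chemistry, quality-score
or GC biases, PCR duplicates, rRNA carry-over, SNPs (so no dbSNP masking is
needed or implemented), hyper-editing clusters, multi-exon circle internal
structure, and realistic repeat sequence. Passing benchmarks therefore show
the *algorithms* are correct under their stated models, not that real-data
alignment artifacts are handled.

## Back-splice detection

Anchors are the first and last 20 nt of the read, matched exactly against a
k-mer index of both genome strands; error tolerance lives entirely in the
extension step (≤ 2 mismatches by default). A candidate requires both
anchors unique on one chromosome with the 3′ anchor upstream of the 5′
anchor and span ≤ 100 kb. Because the circle span is fixed by the anchor
positions, head-to-tail geometry is rejected in O(1) before any extension
work. The breakpoint is the mismatch-minimizing split; ties and near-ties
within ±2 nt slide to the placement with a canonical signal.

Two conventions are worth spelling out:

- **Strand.** Back-splice geometry is orientation-symmetric, so the read
  alone cannot distinguish a plus-strand circle from its mirror. The
  reported strand follows the read's mapping orientation, and the canonical
  check accepts GT/AG in either transcribed orientation. With a stranded
  library (reads in transcript orientation, as simulated) the reported
  strand equals the circle's transcribed strand; reverse-complementing a
  read flips only the strand, never the coordinates.
- **Slide consensus.** A read carrying a sequencing error near the junction
  can legitimately place the breakpoint at an alternative canonical position
  within the ambiguity window. Junctions with identical span on the same
  strand whose starts differ by at most the window are therefore collapsed
  onto the majority-supported placement before the support filter. Without
  this, a handful of error reads can fabricate a phantom junction 1–2 nt
  from a real one.

Per-junction support below `min_support` (default 2 reads cohort-wide) is
dropped. "Total mapped reads" for normalization counts reads with at least
one anchor hit — a documented stand-in for an external aligner's mapped
totals, adequate on synthetic genomes where essentially every read maps.
The sample QC threshold (default 5,000 detected circRNAs, strict `<`) can
count either distinct junctions or junction reads; distinct junctions is the
default since the two readings are both in circulation and the choice is a
config switch, not a result.

## Alu editing index

Eligible positions lie in an Alu element, have coverage ≥ `min_coverage`
(default 1 — any expressed Alu counts) and transcribed-strand reference base
equal to the mismatch's reference base. Strand context: containing gene
strand first, the Alu's own strand when intergenic, and positions under two
opposite-strand genes are excluded rather than guessed. For minus-strand
context the plus-strand pileup is complement-mapped (A>G measured as T>C).
The index is a pooled ratio, so it satisfies an exact pooling identity: on
any partition of the region set, summing numerators and denominators
reproduces the whole-set result. A zero denominator yields an undefined,
flagged result — never 0.

Pileups count primary *and* supplementary mapped segments (the wrapped part
of a junction read is real read sequence carried by a supplementary-style
record); only unmapped and secondary records are skipped. Deletions and
clipped bases contribute nothing.

Under uniform per-site editing ρ with uniform substitution error ε, the
expected index is `100·p_G/(p_G+p_A)` with `p_G = ρ(1−ε) + (1−ρ)ε/3` and
`p_A = (1−ρ)(1−ε) + ρε/3` — numerically ρ + ε/3 to first order, which is
what the recovery benchmark asserts to ±0.5 percentage points.

Flanking-intron windows (1,000 / 5,000 / 10,000 nt) are clipped to the host
gene's span; by default the host gene's exons are subtracted so flanks are
strictly intronic (clip-only behaviour is available, since which of the two
the original analyses used is not decidable from their description). The
host gene is found by coordinate containment, preferring a strand match;
junctions without a host are excluded with a warning.

## Cohort statistics

- "t-test" means Welch (unequal variance), two-sided. Both groups constant
  → p = 1 with a flag rather than a NaN.
- "Wilcoxon" means the rank-sum (Mann–Whitney) test, exact null when
  min(n) ≤ 12 without ties, tie-corrected normal approximation otherwise.
- Multiple testing is Benjamini–Hochberg throughout (the convention of the
  GLM frameworks this pipeline's simple test replaces); raw and adjusted
  values are both reported.
- `simple_de` is deliberately *not* a negative-binomial GLM: counts are
  scaled by median-of-ratios size factors, log2(x+1)-transformed and tested
  per feature with the two-group test; the effect size is the difference of
  log-means. It is conservative on discrete counts (the null benchmark shows
  a false-positive rate well under the nominal q < 0.05) and is labelled as
  what it is. Size factors follow the DESeq convention (geometric-mean
  reference over features positive in all samples); note that scaling one
  sample by c scales only factor *ratios* by c, since the reference moves by
  c^(1/n).
- The cell-type expression rule is grammatically ambiguous in its usual
  phrasing; the default here is the leave-one-out conjunction — called for
  type c iff expr_c ≥ 10 × mean(others) AND expr_c ≥ mean(others) + 5 ×
  sd(others), with sd(one value) = 0 — and both the 10×/5×SD parameters and
  the alternative readings (include-self, combined threshold) are options.
- Correlations are Pearson with the t-based two-sided p-value (n ≥ 3
  required; zero variance → flagged undefined). The pipeline's "circRNA
  output per sample" for correlations is the junction-read total per million
  mapped reads: distinct-junction counts saturate on small simulated
  genomes where every circle is detected, carrying no per-sample signal.

## miRNA seed sites, enrichment, stoichiometry

Sites are anchored at matches of the reverse complement of miRNA positions
2–7 (for miR-128, core ACUGUG) and upgraded by the m8 base (one position
upstream) and/or a target A at position 1 to 7mer-m8 / 7mer-A1 / 8mer; each
core yields exactly one site, classified at its strongest, positioned at the
start of the full motif. Circular scanning uses modular indexing, so a site
spanning the back-splice junction is reported with its start modulo the
circle length; a linear mode exists for comparison with junction-blind
scans. No 3′-supplementary pairing or context scoring is attempted — the
analyses this supports count canonical sites.

Enrichment is the one-sided hypergeometric upper tail (Fisher exact,
"greater") of the DE/target overlap within the expressed universe, BH across
miRNAs, with a 0.5 continuity correction on the odds ratio only when a cell
is zero (flagged). Standard curves are least-squares fits of Cq on
log10(copies); efficiency `10^(−1/slope) − 1` is flagged outside [0.8, 1.1].
Stoichiometry is `n_sites · [circRNA]/[miRNA]`.

**The circSLC8A1 surrogate.** The real circularized human SLC8A1 exon is not
bundled. `mirtools.synthetic_circslc8a1()` builds a deterministic synthetic
surrogate — a 1,832 nt random circle carrying exactly 7 embedded canonical
miR-128 sites (the count reported for the real circle), one spanning the
junction, with the background rejection-screened by plain substring search
so no accidental cores exist. It exercises the full circular-scanning path
and reproduces the reported site count and ~1:1 site-per-miRNA stoichiometry
at a 1:7 molar ratio, but it is *not* the human sequence; conclusions about
the real exon require supplying it as FASTA (`circnigra mir --circle ...`).

## Benchmark problem sizes

The shipped benchmarks use one ~100 kb chromosome with 30 genes (20
circularizable) and 200k reads per sample for detector fidelity; a 20 kb /
6-gene genome at ~800× exonic coverage for editing-index recovery; and 100
seeded cohorts of 10–20 samples at 2,500–3,000 reads each for the
anti-correlation and age-trend recovery rates. The age slope (0.025 per
year, i.e. roughly a factor 2 across a 55–90-year range, with 0.10
per-sample lognormal noise) was chosen so the design has comfortably more
than 80% power at n = 10 per region; the inverse editing coupling uses unit
elasticity with 0.4 lognormal spread. These are fixture choices for a
laptop-scale testbed, not estimates of any real cohort's effect sizes.

## Known limitations

- Anchor matching is exact, so reads with an error or edit inside either
  anchor are unmapped for detection purposes; this costs recall (~8% of
  junction reads at 0.2% error), never precision.
- The detector reports single-exon circles by their outer coordinates only;
  multi-exon circle structure, fusion and trans-splicing are out of scope.
- The editing index is computed without SNP masking; on real data a dbSNP
  filter belongs upstream.
- `simple_de` trades the power of a count-model GLM for transparency; with
  strong mean–variance coupling it is conservative.
- The pipeline's mapped-read totals come from anchor hits, not an external
  aligner; on real data, supply alignments and use the SAM-based pileup
  path.
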