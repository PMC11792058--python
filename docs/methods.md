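# Methods

This note documents the models, statistics and numerical choices behind
`chromdyn`, and what the bundled synthetic-data generator does and does not
emulate.

## Coordinates and formats

All internal coordinates are 0-based, half-open (BED convention); GTF input
(1-based, inclusive start) is converted on read. Chromosome names compare as
exact strings, with a `normalize_chrom` helper to move between "chr1" and
"1" styles. Gene models carry a strand-aware TSS (start on +, end−1 on −)
and TTS (the opposite end). The distance between a locus and a gene is
measured from the gene's TSS to the nearer locus edge, 0 if the TSS lies
inside the locus; the alternative of measuring to the peak summit is
exposed (`associate_loci(anchor="summit")`) because either reading of
"within 2000 bp of the locus" is defensible — edge distance is the default
as the more inclusive convention.

## Peak atlas and occupancy patterns

The atlas is the single-linkage merge of all samples' peaks: loci are
connected components of the ≥ 1 bp-overlap graph, each spanning the union of
its members (bookended peaks do not merge; the minimum overlap is
configurable). Presence of a sample at a locus requires ≥ 1 bp overlap of
any of that sample's peaks. Sample order is arm-major, time-minor
(control arm first), so a locus's row reads as a control 4-bit vector
followed by a knockdown 4-bit vector.

The pattern taxonomy is a deterministic, exhaustive and mutually exclusive
partition of all admissible (control, knockdown) pairs (the all-zero pair
cannot occur — a locus exists only because some sample had a peak):

1. control all-0 → `kd_specific_open`;
2. control all-1 → `permanently_open` if the knockdown arm is also all-1,
   else `kd_specific_closed`;
3. any arm with more than one 0↔1 transition → `complex`;
4. identical non-constant arms → `stable_other`;
5. otherwise the control arm is a non-constant staircase. Its direction
   (opening 0→1 or closing 1→0) is read off, and each arm's *settling
   index* — the position after which it stays in the control arm's final
   state, with the arm length used when it never settles — is compared:
   knockdown earlier → accelerated, later → decelerated, equal →
   `stable_other`.

The settling-index rule also fixes the cases the plain wording leaves open:
a knockdown arm that is constant, or that moves in the opposite direction
from the control arm, never settles in the control's final state and is
therefore read as decelerated. Ties are deliberately `stable_other` —
neither accelerated nor decelerated.

Because peak dropout only *deletes* presence calls, the optional smoothing
pre-pass (`smooth=True`, off by default) repairs a non-monotone arm to the
monotone **superset** reachable with the fewest 0→1 additions — the
maximum-likelihood correction under a deletion-only noise model — breaking
ties toward the latest first-open index (open late rather than early). No
smoothing is ever applied to already-monotone arms: a deletion that happens
to leave a monotone pattern (e.g. all-open losing its last time point) is
indistinguishable from a real change, which bounds achievable recovery
under dropout. With the default category mix at 10 % dropout, repair-based
recovery is ≈ 0.86 versus ≈ 0.73 without; permanently-open rows are the
fragile class, since any single knockdown-arm deletion legitimately reads
as knockdown-specific closing.

Dynamic loci are those whose row is not constant-1. No score threshold is
applied on top; the selection is purely pattern-based.

## Specificity statistics

**Differential call.** Naive/primed-specific gene sets come from the
ESC-vs-EpiSC replicates: per-gene log2 fold change on pseudocounted
(+1) replicate means, a two-sided t-test on log2(x+1) values, BH
correction, and the thresholds |FC| ≥ 2, q < 0.01. With typical replicate
counts (n = 3) a per-gene variance estimate has ~4 degrees of freedom and a
plain Welch test has almost no power at q < 0.01, so the default test is a
**moderated t**: the pooled within-gene variance is shrunk toward an
empirical-Bayes prior fitted across genes by method of moments on log
variances (the spread of log s² beyond the χ² sampling component
trigamma(df/2) sets the prior degrees of freedom; no excess spread means a
common variance and a normal reference). This is the standard
small-replicate remedy in expression analysis; `moderated=False` restores
the plain Welch test. The call is a deliberate simplification of a
negative-binomial count model: it is validated against the generator's
planted truth, not against any count-model implementation.

**Specificity Z.** `z_g = (log2FC_g − mean_genes)/SD_genes` with the
population SD (ddof = 0; a flag switches to sample SD). Positive = higher
in naive ESCs. Mean 0 / SD 1 holds by construction, and swapping the
cell-type labels negates every z.

**Category enrichment.** Genes are pooled per category via the locus→gene
association and deduplicated within the category (several loci flanking
one gene would otherwise pseudo-replicate it). Each category's z-values are
compared to the permanently-open reference by a two-sided Mann–Whitney U;
p-values are reported raw and BH-adjusted across categories; a category
with fewer than two genes gets an undefined (NaN) p rather than 1. The
per-category sum of log2 fold changes is reported alongside. Genes (not
loci) are the test unit.

**Gene-set time-course score.** Each gene's expression is standardized
across the time-course samples (population SD; a constant gene yields an
all-zero row and is flagged, not dropped). The set score at a sample is the
sum of member-gene Z there; significance is a two-sided Welch t of the
set's Z-values against the unchanged genes' Z-values at that sample. Both
the per-sample sums and the full per-gene Z matrix are emitted, since the
distributional unit of the corresponding boxplots is ambiguous.

## Coverage quantification

Tracks are per-chromosome arrays of mean coverage per fixed-width bin
(default 50 bp; resolutions are declared defaults, not claims about any
particular upstream pipeline), loaded from bedGraph with interval signal
split proportionally to bin overlap. CPM normalization rescales bins to
total 1e6. Window means are evaluated from the cumulative signal at bin
edges with linear interpolation — exact for the piecewise-constant binned
representation, including fractional bin overlap — which is why a constant
track gives exactly constant profiles and ratios of 1.

Scaled metagene profiles use 3 kb flanks at native bin resolution and the
gene body resampled to 100 equal bins; minus-strand genes are mirrored so
the TSS is always left. Genes shorter than two bins or with flanks leaving
the chromosome are skipped and counted (zero-padding clipped windows would
bias means). Expression classes: not expressed if the summary value is
≤ 100 (strictly greater counts as expressed), expressed genes ranked
descending with ties broken by gene id and split into quartiles Q1 (top) to
Q4, remainders going to the earlier quartiles (10 genes → 3,3,2,2).

The TSS/body ratio divides the mean coverage in [TSS−500, TSS+500]
(1001 bp) by the mean in the gene body strictly between the promoter window
and 500 bp inside the TTS; the two windows are disjoint by construction.
Genes whose body window is empty (length ≤ 1002 bp) are excluded with a
reason, and a zero body mean flags the ratio as undefined rather than
substituting a pseudo-signal (an option exists but is off). Summit profiles
bin [summit−2000, summit+2000) into 100 windows; clipped windows are
dropped and counted.

## AP-MS filter

Four rules, tested in a fixed order so the first failing reason is
deterministic: unique peptides ≥ 1 → bait intensity ≥ 1e6 → bait ≥ 2 ×
control → name not starting with one of the 18 contaminant prefixes
(case-sensitive on capitalized symbols; a case-insensitive flag exists).
A control intensity of 0 passes the ratio rule — absence from the control
pulldown is the strongest evidence of a specific interaction. The filter
is monotone in every threshold and independent of record order.

## Synthetic-data generator

The generator emulates the study design: two shRNA arms × four time points,
ESC/EpiSC replicates, one synthetic chromosome tiled with non-overlapping
genes (2–8 kb, 5–15 kb gaps, margins for flanks). Defaults: 300 genes
(40 naive-, 40 primed-, 60 lineage-specific split over two germ layers),
log2 baseline N(7, 1.5), log2 noise SD 0.3, planted |log2FC| 2, three
cell-type replicates, two time-course replicates; 1000 planted loci
(200 permanently open, 200 knockdown-specific open, 100 in each remaining
category), 10 % presence dropout, ±50 bp boundary jitter; Poisson
background rate 5 per 50 bp bin, Gaussian peak enrichment (amplitude 20,
σ = 200 bp), promoter enrichment factor 2 over ±500 bp of every TSS;
20 interactors per cell type (10 shared), 100 background proteins, 5 named
contaminants. These sizes keep every stage comfortably within a desk-scale
run while leaving all planted effects recoverable at their stated
thresholds.

Time-course expression follows piecewise-linear log2 schedules: in the
knockdown arm primed and lineage genes are suppressed from day 0 and naive
genes activate only late, while the control arm drifts slowly in the same
directions — the qualitative accelerated-suppression / late-activation
structure. Ideal occupancy patterns per category are monotone staircases;
noise enters only through dropout, which keeps the classifier oracle
tractable. Knockdown-specific open loci are placed in fixed non-overlapping
slots within 2 kb of naive-specific TSSs; all other categories sit in slots
around unchanged-gene TSSs so their associated genes are expression-neutral
by construction. True interactors are drawn with bait/control ratio ≥ 4 and
intensity ≥ 4e6, passing every filter rule by construction; background
proteins pass at well under 5 %.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level sampling and mappability, replicate
peak-calling variability (noise is presence dropout, not caller behaviour),
fragment-length and GC effects in coverage, count overdispersion beyond
log-normal noise, correlated genes, multiple chromosomes, and
abundance-dependent MS missingness. Recovery results on synthetic data
demonstrate correctness of the computations, not performance on real
libraries.

## Determinism and degenerate inputs

Every generator draws from a seeded stream; the pipeline writes only
sorted, explicitly ordered tables, so a rerun under the same config is
byte-identical for all TSV outputs (the manifest records config hash, seed,
version, row counts and warning counts; timestamps are deliberately
excluded). Degenerate inputs fail loudly: zero-SD fold-change vectors,
zero-total tracks for CPM, fewer than two replicates for the differential
call, mismatched arm lengths for pattern classification, and the
inadmissible all-zero pattern pair all raise errors rather than returning
placeholder values.

## Known limitations

* The pattern taxonomy is an explicit reconstruction of a figure-level
  clustering whose exact membership rules are not published; boundary
  conventions (ties → stable-other, direction conflicts → decelerated) are
  this package's declared choices.
* The moderated-t differential call approximates, but is not, a
  negative-binomial model; on strongly overdispersed counts it will be
  anticonservative.
* The end-to-end driver orchestrates synthetic runs; on real data the stage
  subcommands (`atlas`, `enrich`, `genescore`, `metagene`, `ratio`,
  `summitplot`, `apms`) are run against user files.
* bigWig input is not read directly; convert to bedGraph first.
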