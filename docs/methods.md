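# Methods

## Coordinate and strand conventions

All coordinates are 0-based, half-open; the CX report alone is 1-based.
On a circular genome every position index is taken modulo the length, and
trinucleotide context wraps across the origin; linear mode (for amplicon
references and spike-ins) pads missing context with N, which makes a
terminal cytosine CpH by the "following base is G" rule.

The deposited plus strand is treated as the light (L) strand by default,
since both the mouse mitochondrial reference and the human rCRS are C-rich
on the plus strand; `l_strand_is_plus=False` flips the naming without
touching the physics. All internal logic keys on the *physical* strand a
read derives from: plus-derived reads report C/T at plus-C positions,
minus-derived reads report G/A at plus-G positions (directional libraries
only; the complementary PCR strands of non-directional protocols are not
modelled).

## Methylation calling

Counting is defined per reference position. A read contributes to a site
only when its class matches the site's strand and its base is one of the
two informative states; anything else (sequencing error, N) contributes to
neither count. Reads are skipped whole below `min_mapq` (default 0 — mtDNA
is sequenced so deeply that mapping-quality filters mostly trade NUMT
leakage against coverage; a MAPQ-30 policy is one flag away). Overlapping
mates are counted once, first mate wins, to avoid pseudo-replication.
Alignments with indels are projected onto the reference: inserted bases are
dropped, deleted positions yield no observation.

Zero-depth sites are retained and reported as undefined, never 0, so that
summaries cannot be deflated by silent missingness; there is deliberately
no depth cutoff (depth on mtDNA is a relative quantity — QC, not calling,
decides what to trust). Summaries report both the pooled level
(100·Σm/Σd) and the mean of per-site levels, because "average methylation"
is ambiguous between the two; they differ exactly when depth and level
co-vary, which is itself a bias symptom.

## QC diagnostics

- **Strand depth**: mean per-site depth per strand, zero-depth sites
  included; H/L ratio undefined when the L mean is 0.
- **Binned profile**: mean per-position read coverage (both strands) in
  consecutive 200-bp windows, first and last 150 bp ignored, trailing
  partial window dropped rather than padded. Mean × width sums exactly to
  the coverage over the tiled interval.
- **Depth–methylation correlation**: Spearman by default — the
  relationship produced by degradation bias is monotone but far from
  linear — Pearson by flag. Undefined (not 0) when either variable is
  constant.
- **Flags**: only sites whose level exceeds `signal_threshold` (default
  5%) are examined. The depth rules are: absolute depth < 10; depth < 1%
  of the own-strand mean; and, reported alongside, the same 1% rule
  against the ±1 kb own-strand window ("adjacent region"). The
  conversion-floor flag marks levels ≤ 100·(1−r) for a supplied conversion
  rate r. Threshold comparisons are strict (> for the signal, < for the
  depth rules).

## NUMT attribution

A catalog records, per nuclear locus, the homologous mtDNA interval and
its single-base differences (SBDs). The catalog builder places each
nuclear sequence by a seed-vote over 16-mers (both orientations,
wrap-aware) and reads SBDs off the gapless alignment — adequate for the
interval-scale homologies the catalog is meant to hold; it is not a
genome-wide NUMT discovery tool.

Classification works in bisulfite space: for the read's class, C→T (or
G→A) is applied to read, mtDNA allele and NUMT allele alike, which removes
exactly the evidence conversion destroys. An SBD whose two alleles
collapse together in that space is recorded but carries no weight for that
class. Per locus, the read's matches to NUMT vs mtDNA alleles are
tallied; the verdict is the locus with a strictly positive and strictly
winning margin, MT when mtDNA alleles win everywhere, and AMBIGUOUS on any
tie or zero informative coverage — indistinguishable reads are never
assigned. Reads overlapping no catalog interval are MT by convention.

The co-occurrence test partitions site-covering reads of the site's class
into a 2×2 table by (carries ≥ 1 NUMT allele) × (unconverted at the site)
and applies the two-sided Fisher exact test; the odds ratio uses the
Haldane 0.5 correction when a cell is empty. Filtering drops NUMT (and
optionally AMBIGUOUS) reads and rebuilds the methylome from scratch, so
counts are conserved exactly: original = corrected + dropped.

## Simulator

The generator draws fragments uniformly on the circle (wrap-around
allowed; linear mode forbids it, mirroring pre-/post-linearization
libraries), normal fragment lengths (mean 250, SD 30 by default — sonicated
~250-bp inserts), and single-end 100-bp reads from the fragment's 5′ end on
its strand. Per-read class counts are set by the target mean depths.
Methylation states are drawn per site from `true_profile` (default: fully
unmethylated, the realistic null for mtDNA), then conversion is applied at
the read's rate.

Mechanism models, chosen where the underlying chemistry is described only
qualitatively:

- **Conversion failure** is a two-component mixture: most reads convert at
  `conversion_rate` (0.99 is typical of real libraries; 1.0 isolates other
  mechanisms), and a `poor_conversion_fraction` subpopulation converts at
  `poor_conversion_rate`. The poor rate defaults to 0.5 and the
  mechanism studies below use 0.2: genuinely failed conversions retain
  most of their cytosines, and this retention is also what lets such
  fragments escape degradation.
- **Degradation** acts on deaminated cytosines, so fragment survival is
  exp(−k · n_converted), with `degrade_c_rich = k` per converted cytosine.
  This single rule produces both artifacts at once: C-rich (L-strand)
  fragments die more often (H/L ratio grows as ≈ exp(k·ΔC) for a
  fragment-level C-count difference ΔC), and poorly-converted fragments —
  having deaminated fewer cytosines — survive preferentially, concentrating
  exactly in the low-coverage regions. The k grid used in tests
  (0.005–0.03) spans mild to severe bias (H/L ≈ 1.2–2.4 at 250-bp
  fragments); the strength of the real effect varies by library and is not
  pinned to a published constant.
- **NUMT contamination** draws the configured fraction of reads from the
  NUMT allele sequence (catalog SBDs substituted into the mtDNA interval),
  methylates their cytosines at `numt_methylation` (default 1.0 — the
  fully-methylated nuclear copy is the worst case), converts, and maps
  them at the homologous mtDNA coordinates, emulating an aligner forced to
  place them on the mitochondrial reference.
- **Sequencing errors** (uniform substitutions, default 0) exist to
  stress-test classification; they are off in the headline runs so that
  classification accuracy has an exact expectation (100%).

Output is deterministic given the config (seed included): reads, truth
records and emitted files are byte-identical across runs.

### What the simulator does not model

Quality-score realism, PCR duplicates, paired-end insert-size structure
(paired emission exists only for mate-overlap tests), mapping ambiguity
(the simulator is a perfect aligner; real aligners add MAPQ noise), and
sonication/secondary-structure physics beyond the exponential survival
law. Passing tests therefore demonstrate that the *mechanisms* produce the
documented signatures and that the pipeline detects and removes them —
not that any particular real library matches these parameter values.

## Synthetic study genome

Tests and the acceptance script use a 16,299-bp random circular genome
with plus-strand base frequencies A/C/G/T = 0.35/0.24/0.12/0.29,
matching the strong C-over-G excess of the mammalian mitochondrial plus
strand that drives the strand asymmetry. A random genome has no gene
structure, no origin-of-replication composition gradients and no real NUMT
homologies; NUMT loci are planted explicitly with known SBDs instead.

## Problem sizes and statistical checks

Headline runs use per-strand target depths of 20–120 on the 16.3-kb
genome (10⁴–4·10⁴ reads, seconds each), which already puts binomial
standard errors well below the effect sizes being demonstrated. Sampling
tolerances are derived, not tuned: realized mean depth is compared at 3
Poisson-block standard errors (coverage is correlated over a read length,
giving ≈ length/read_len independent blocks), and the apparent level at
99% conversion at 3 binomial standard errors of 1.0% with n = total
informative observations.

## ΔΔCt

Replicate Ct values are averaged per (condition, target) cell before
ΔΔCt = (Ct_t − Ct_c)_treated − (Ct_t − Ct_c)_untreated; the per-cell
replicate SD is reported alongside rather than propagated. Linearization
efficiency is 100·(1 − 2^−ΔΔCt) (the target amplicon spans the cut site,
so the remaining fraction is the uncut circle); enrichment mode reports
2^−ΔΔCt itself as the fold change.

## Known limitations

- The catalog builder assumes gapless homology; indel-bearing NUMTs would
  need the catalog TSV to be curated externally.
- Read-origin classification is only as good as the catalog: a NUMT absent
  from it is invisible, which is why the identical-region scan and the
  co-occurrence test exist as catalog-independent red flags.
- Amplicon mode requires end-to-end, equal-length clone alignments (QUMA-
  style gapless comparison with a 90% identity gate in bisulfite space);
  indel-containing Sanger reads are rejected rather than realigned.
- The Spearman p-value at thousands of autocorrelated sites overstates
  independence; the package reports it as a direction-and-significance
  diagnostic, not as a calibrated test.
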