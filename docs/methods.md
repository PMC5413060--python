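# Methods

## The analysis

`mirprecis` reproduces a fold-change-based small RNA-seq analysis, not a
model-based differential test. All stages operate on *collapsed reads*
(unique clean sequences with per-library multiplicities).

**Clean-up.** The 3' adapter is located by scanning candidate trim
positions left to right; the first position where the read suffix matches a
prefix of the adapter with overlap ≥ `min_overlap` (default 6) and mismatch
fraction ≤ `max_mismatch_rate` (default 0.1) wins, so a full internal
adapter occurrence trims at its leftmost start. Adapter-less reads are
discarded by default (in a small RNA protocol they imply an insert longer
than the read; `keep_untrimmed` retains them). Inserts containing N are
dropped — the downstream matcher is exact and could never place them.
Size selection keeps 18–30 nt inclusive. Base qualities are ignored
throughout.

**Mapping and quantification.** Genome matching is exact and full-length
on both strands, implemented as a per-length hash of forward-strand windows;
a query is looked up as itself and as its reverse complement (minus-strand
hits on the same forward interval). A palindromic query reports each window
once, as a plus-strand hit. Mature miRNAs are counted by strict identity to
the catalog (RNA U→T and case normalized at load); any end shift or
mismatch counts zero. Catalog entries sharing one sequence (families) are
merged into a single row labeled `name1/name2`, since identity cannot
distinguish them. RPTM = raw / (genome-matched total) × 10^7, where the
genome-matched total sums multiplicities of sequences with ≥ 1 placement —
once per read regardless of how many loci it hits, because the normalizer
counts molecules, not placements. Internal coordinates are 0-based
half-open; all GFF3/report coordinates are 1-based inclusive.

**Differential accumulation.** miRNAs with WT mean RPTM ≥ 10 (over
replicates; a per-replicate variant is available) are classified per
mutant: reduced iff mean(mutant)/mean(WT) ≤ 1/fold with fold = 2 by
default. The boundary is inclusive ("at least two-fold"); a strict mode
(`< 1/fold`) is one flag away, since conventions differ on whether exactly
two-fold counts. Replicates are combined by arithmetic mean of RPTM before
the ratio; no statistical test or multiple-testing correction is applied —
the design is a pure fold-change threshold. Reduced sets of two mutants are
compared as an only-A / shared / only-B partition.

**Processing precision.** A sequence is assigned to a hairpin when one of
its placements lies entirely inside the hairpin interval on the annotated
strand; antisense placements are excluded (processing is strand-defined)
and logged. A read is *precise* iff both ends are within ±2 nt
(configurable) of the annotated mature ends, or of the star ends when a
star is annotated — the both-ends rule; loci without a star annotation are
evaluated against mature only. Multi-assigned (family) sequences contribute
full multiplicity to each locus and are classified against each locus's
own annotation. Only loci with ≥ 10 assigned reads in every replicate of
every compared genotype enter genotype summaries; replicate fractions are
averaged per locus before the per-genotype median and the two-sided
Wilcoxon rank-sum test versus wild type (reported, never thresholded;
skipped below 3 eligible loci).

**Size classes.** Per library, the fraction of genome-matched reads at
each length 18–30 nt; the 24-nt class ratio is mutant/WT of replicate-mean
fractions. The default uses all genome-matched reads; feeding a
structural-RNA-excluded read set gives the "non-structural" variant.

**qPCR.** ΔCt = Ct(target) − Ct(reference) per sample and replicate;
per-replicate fold = 2^−(ΔCt − mean ΔCt of the calibrator sample), so
calibrator replicates scatter around 1 (geometric mean exactly 1).
Mean and sample SD (ddof = 1) are taken on the fold scale, matching
mean ± SD error bars. Efficiency is fixed at 2; no Pfaffl correction.

## The simulator

The simulator emulates a small RNA sequencing study well enough to
exercise every analysis decision, with exact bookkeeping:

* **Genome/loci.** Random i.i.d. genome at a configurable GC fraction
  (default 0.36, Arabidopsis-like). Hairpins (default 120 nt) are planted
  as literal subsequences — no RNA folding is enforced, because the
  analysis consumes annotations, not structures. Mature (20–22 nt, default
  21) and star windows sit ≥ 10 nt inside the hairpin, separated by a loop
  gap (default 16 nt); the margin guarantees that slid (misprocessed)
  windows never cross the hairpin boundary at default offsets. Each mature
  sequence is verified unique genome-wide (both strands) and the hairpin is
  regenerated on collision.
* **Counts.** Per-locus insert counts are Gamma–Poisson (negative
  binomial) with mean `baseline_abundance × genotype_multiplier`. The
  `dispersion` parameter is the **biological coefficient of variation** of
  the Gamma mixture (NB size = 1/dispersion²); 0.1 — a typical value for
  genetically identical model organisms — means ~10% between-replicate
  variability. `dispersion = 0` gives Poisson counts.
* **Species and ends.** Each locus read is mature or star with probability
  set by `mature_to_star_ratio` (default 4). With probability
  `misprocessing_rate` the whole window slides by a magnitude drawn from
  `offset_magnitude_range` (default 3–5 nt, direction random), so both ends
  shift equally: the read is imprecise under the ±2 rule yet keeps a
  plausible insert length and survives size selection. Magnitudes below
  3 nt are rejected at configuration time — they would blur the
  precise/imprecise boundary. An optional benign-isomiR rate (default 0)
  produces 1–2 nt slides that remain precise.
* **Background.** A 24-nt siRNA-like class sampled uniformly from
  sense-strand non-hairpin windows; its count is Binomial(depth,
  `background_24nt_fraction`). The default fraction is 0.70: plant
  rosette-leaf libraries are dominated by 24-nt heterochromatic siRNAs, so
  miRNA loci contributing ~30% of genome-matched reads is the realistic
  regime. Background windows cannot collide with mature sequences because
  matures are unique and confined to hairpins.
* **Reads.** Emitted read = insert + 3' adapter (default Illumina TruSeq
  small RNA), truncated to the read length (default 50 cycles); constant
  quality `I`. Read length and adapter are configuration defaults, not
  claims about any particular deposited dataset.
* **Truth.** Every read's placement and label (precise / imprecise /
  background), per-locus true counts, and per-genotype abundance
  multipliers are recorded. Locus counts are independent NB draws and the
  background count is an independent binomial, so the *realized* library
  size equals the nominal depth in expectation (exactly aligned when
  `Σ baselines = depth × (1 − background fraction)`, which the pipeline's
  auto-baseline guarantees); bookkeeping (FASTQ records = Σ locus counts +
  background) is exact.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: sequencing errors and quality decay, PCR
duplication, structural RNA (tRNA/rRNA) contaminants, strand biases,
ligation biases, multi-locus miRNA families with shared mature sequences
(matures are unique by construction; the family code paths are covered by
handcrafted fixtures instead), and real hairpin secondary structure.

## Default study conditions

The bundled run configuration is a three-genotype, two-replicate design at
depth 2×10^5 over 60 loci (auto-baseline 1,000 reads/locus): wild type
(misprocessing 0.05), a *hyl1*-like mutant (misprocessing 0.4; loci 1–15 at
multiplier 0.4) and a *snrk2*-like mutant (misprocessing 0.05; loci 6–20 at
multiplier 0.4 — ten loci shared with the first set). These sizes keep a
full run under a minute on one core while leaving per-locus counts large
enough (hundreds) that fold-change and imprecision estimates are limited by
biological dispersion, not counting noise. Validation sub-studies use
smaller dedicated panels (20 loci × ~500 assigned reads per replicate for
imprecision recovery; 50 loci for the precision contrast).

## Numerical conventions and edge cases

* Exactly-boundary values are kept: lengths 18 and 30, WT mean RPTM 10,
  end offsets of exactly ±2, ratio exactly 0.5, ≥ 10 reads per replicate.
* Zero genome-matched reads in a library is a normalization error naming
  the library; a locus with zero assigned reads yields a non-evaluable
  record (fraction NaN), not a zero.
* A mutant mean of 0 gives ratio 0 (reduced); the expression filter
  guarantees WT means are positive.
* Ties in the rank-sum test are handled by `scipy.stats.ranksums`
  (normal approximation); the test is two-sided and only reported.
* Determinism: every random choice flows from `numpy.random.default_rng`
  seeded from the config; identical config + seed gives byte-identical
  outputs. Per-library seeds are derived via `SeedSequence([master, k])`.
* Overlapping hairpin annotations produce a warning and dual assignment;
  single-replicate qPCR samples report SD 0 with a warning.

## Known limitations

* The exact matcher indexes every window of each query length; fine up to
  a few hundred kb of genome, but not a substitute for a real aligner at
  chromosome scale.
* Strict-identity quantification ignores isomiR abundance entirely (by
  design — isomiRs are handled by the precision statistic, not counted as
  mature).
* The ≥ 2-fold rule has no error control; with two replicates and
  biological CV ≈ 0.1, true 2.5-fold reductions are recovered with ~90–100%
  sensitivity at the default depth, and composition shifts (a mutant losing
  many miRNAs inflates every other RPTM by a few percent) slightly erode
  the margin — visible in the validation numbers.
* The precision statistic assumes the annotation's mature/star ends are
  the biological truth; mis-annotated loci appear imprecise in every
  genotype.
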