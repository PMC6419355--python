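# Methods

## The measurement model

Escape from X-inactivation is inferred from allele-specific expression at
heterozygous SNPs (hSNPs) in single cells. The unit of observation is a
read-count pair at one hSNP in one cell: (#Ref, #Alt) when haplotypes are
unknown, (#Mat, #Pat) when a phased diploid genome assigns each allele to
a parent. An hSNP covered by at least `min_reads` total reads in a cell
is an informative SNP (iSNP) and receives an allelic ratio

AR = #Alt/(#Alt+#Ref) (unphased) or AR = #Pat/(#Pat+#Mat) (phased)

and a categorical label: monoallelic when AR ≤ `mono_low` or
AR > `mono_high`, biallelic when `mono_low` < AR ≤ `mono_high`. The
defaults are `min_reads = 7`, `mono_low = 0.1`, `mono_high = 0.9`. The
band is deliberately asymmetric — AR exactly 0.1 is monoallelic while AR
exactly 0.9 is biallelic — and since counts are integers the comparisons
are done on exact rationals (`Fraction(n_major, total) ≤ 1/10`), so
labels can never flip on a floating-point epsilon. Float thresholds
supplied by a user are converted through their decimal string, so
`mono_low=0.1` means exactly 1/10.

## Coordinates and conventions

VCF and count-table positions are 1-based; gene annotations are 0-based
half-open (BED). Conversion is centralized (`io.pos_to_0based`).
Chromosome names are normalized at read time (`chrX` ≡ `X`). In phased
VCFs the side of `|` that carries the paternal haplotype is a
configuration key (`paternal_first`, default true). An hSNP inside
overlapping genes contributes to each of them and carries an `ambiguous`
flag; callers may exclude ambiguous iSNPs (`CallConfig.exclude_ambiguous`,
default off). Strand is carried but never used: allele counting is
strand-agnostic.

## Doublet QC

A library that captured two cells with opposite inactive X chromosomes
shows biallelic expression along the whole X. For each cell the
biallelic ratio (biallelic iSNPs / total iSNPs on the QC chromosome,
default X) is compared to the population: cells above
mean + `z_cut`·SD (default 3, sample SD, strict inequality) are flagged
and excluded everywhere downstream. The test is one-sided — a low
biallelic ratio is the expected state on X, never suspicious — and
single-pass: mean and SD are computed once over all cells, candidates
included. A consequence worth knowing: when far more doublets are drawn
than expected, the candidates themselves inflate the SD and a marginal
doublet can be masked. Doublets whose two component cells silenced the
*same* X are statistically invisible to this screen by construction; the
synthetic truth table therefore distinguishes `doublet_mixed_xi`, and
recovery claims are made only about mixed-Xi doublets.

## Calling protocols and evidence flags

* **Unphased iSNP protocol** (primary cells, per-cell random Xi): a gene
  is an escapee candidate when it has ≥ `min_biallelic_isnps` (default 2)
  biallelic iSNPs, counted across cells and across sites within a cell.
  A single biallelic iSNP is not sufficient. `evidence_poor` marks genes
  with < `poor_isnp_cut` (10) iSNPs or biallelic support from ≤ 1 cell.
  Strict mode additionally requires support from ≥ `strict_min_cells`
  (2) distinct cells and can only shrink the escapee set.
* **Phased iSNP protocol** (clonal cells): any iSNP labeled paternal or
  biallelic (expression from the silenced haplotype, with the maternal-Xa
  convention configurable) suffices for an escapee call. `evidence_poor`
  marks a within-cell consistency failure or < `poor_read_cut` (50)
  paternal reads with a single supporting cell.
* **Phased read-based protocol**: paternal and total reads are summed
  per gene over all cells and sites; escapee iff paternal reads ≥
  `read_min` (7).
* **Pooled protocol**: no cell dimension; gene AR = paternal/total over
  summed counts, escapee iff AR > `pooled_ar_cut` (0.1) and total ≥
  `min_reads`.

The reported phased call set is the **intersection** of the iSNP and
read-based protocols (conservative); the union is available via
`combine_phased_calls(..., mode="union")` or `--union`.

**Consistency**: a (gene, cell) pair with ≥ 2 iSNPs at ≥ 2 sites is
inconsistent when it contains both a maternal-monoallelic and a
paternal-monoallelic iSNP — one haplotype cannot be transcribed in two
opposite exclusive states, so the assignment is unreliable. A gene is
fully inconsistent if such a pair exists and no biallelic iSNP does;
partially inconsistent when biallelic observations coexist.

**PAR bookkeeping**: pseudoautosomal genes are expressed from both
alleles by construction, so the fraction of expressed PAR genes the
caller misses estimates its false-negative rate
(`par_detection_rates`).

## Statistics

Catalog overlap uses the exact hypergeometric tail with
(N, k, n, x) = (catalog genes with a label other than no-data, catalog
escapee-associated genes, called escapees, overlap). The default tail is
the standard enrichment convention P[X ≥ x]; the strict P[X > x] is
exposed via `tail="gt"`. The escapee-associated set is the six catalog
categories {PAR, escapee, mostly-escapee, variable-escapee,
mostly-variable-escapee, discordant}.

Positional comparison uses the asymptotic two-sample Kolmogorov–Smirnov
test on gene start coordinates (midpoints optional).

AR distribution summaries use a *strict* monoallelic notion (AR exactly
0 or 1) that intentionally differs from the labeling thresholds; the two
notions are named apart in code (strict-monoallelic vs label-monoallelic)
and must not be conflated.

The autosomal mislabeling bound is the sum of the maternal- and
paternal-monoallelic gene fractions observed on an autosome, valid under
the assumption of no systematic allelic bias there.

The confidence partition tiers each called escapee by external support:
`confirmed` (both primary external resources), `approved` (exactly one),
`probable` (only the third, independent resource), `possible` (none).

## The generative model

`simulate.SimConfig` draws, per cell × gene:

1. haplotype rates — autosomal/PAR genes: both alleles at rate 1;
   X-inactivated genes: Xi allele at 0; escapee genes: Xi allele at
   `xi_fraction/(1−xi_fraction)` of the Xa rate so the Xi share of gene
   output is `xi_fraction`;
2. per-allele burst indicators ~ Bernoulli(`burst_p`), independent
   across alleles — this is what makes biallelic genes look monoallelic
   in any single cell;
3. a per-(cell, gene, allele) gamma expression level (shape
   `dispersion`, mean = `depth_mean`·rate) shared by the gene's hSNPs,
   with Poisson read counts per hSNP — a negative-binomial depth model;
4. reference-assignment bias: each alternative-origin read is miscounted
   as reference with probability `ref_bias` (binomial thinning), which
   shifts the AR distribution mode below 0.5 and does nothing at 0;
5. doublets: with probability `doublet_rate` the library merges the
   counts of a second, independently drawn cell (same Xi in clonal mode;
   random Xi otherwise, recorded as `doublet_mixed_xi` when opposite).

All draws flow through a single `numpy.random.default_rng(seed)`, so
outputs are byte-identical given the config.

Defaults and why: `burst_p = 0.3` makes a biallelic gene show both
alleles in p/(2−p) ≈ 18% of the cell-gene pairs where it is seen at all,
matching the biallelic iSNP fraction observed on autosomes in single
cells; `depth_mean = 30` reads per expressed hSNP allele and
`dispersion = 2` give realistically overdispersed coverage;
`ref_bias = 0.05` reproduces a visible but modest reference skew;
`doublet_rate = 0.03` matches the ~3% doublet incidence typical of
single-cell libraries; `xi_fraction = 0.3` places escapee Xi output in
the range where the low-expressing allele is detectable but clearly the
minor one. Clonal (phased) configurations are simulated with
`ref_bias = 0` because aligning to both parental haplotypes of a phased
diploid genome removes single-reference mapping bias.

Problem sizes used by the pinned test/acceptance simulations, chosen to
mirror the two study designs at desk scale: a clonal 25-cell experiment
with 150 X genes (50 escapees, 96 inactivated, 4 PAR, 2 hSNPs each) for
read-based sensitivity, and a primary 104-cell experiment with ~230
expressed X genes (200 inactivated, 24 escapees, 10 PAR, 3 hSNPs each)
at 3% doublet rate for the QC screen.

## What the simulation does and does not show

The generator reproduces the *statistical* structure the pipeline relies
on: burst-driven monoallelic dominance, Xi silencing and partial escape,
PAR biallelism, reference bias, depth variation, doublets, and pooling
behavior (`pool_counts` restores biallelic labels on autosomes). It does
not model alignment artifacts, positional read correlation along a gene,
shared bursting between neighboring genes, cell-cycle or batch effects,
or genomic DNA contamination. Passing synthetic tests therefore
demonstrates correctness of the decision rules and bookkeeping under the
assumed model, not performance on any particular real dataset.

## Numerical and degenerate-input choices

* Label boundaries: exact rational comparison (no epsilons).
* Report ratios: 3 decimal places, round-half-even; internal values keep
  full precision.
* QC with < 3 cells: error (SD undefined); SD = 0: only cells strictly
  above the mean can be flagged (none when all are identical).
* Empty gene input: `not_expressed`; zero-total AR: error.
* Hypergeometric N = 0: P[X ≥ 0] = 1 (scipy is bypassed for the empty
  population).
* PAR rates with no expressed PAR gene: error ("rate undefined").
* KS test with < 2 positions per sample: error.

## Known limitations

* The unphased protocol cannot see escape expressed below the biallelic
  band (AR ≤ 0.1), so its false-negative rate is intrinsically high —
  the PAR-based rate makes that measurable rather than fixable.
* Single-pass 3-SD doublet screening loses power when doublets are
  numerous enough to inflate the population SD (see QC section).
* No beta-binomial or other inferential model of Xi expression level is
  fitted; all calls are threshold rules, by design.
* Read counts are taken as given; de-duplication of reads spanning two
  hSNPs of the same gene is upstream of this package.
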