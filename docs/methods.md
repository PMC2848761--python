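# Methods

This document records the statistical model behind each stage, the default
parameters and their rationale, the deliberate numerical choices, and the
known limitations of the synthetic-data generator.

## 1. Region demarcation (`seedqtl.region`)

A marker *segregates* when its genotype calls across the NIL-derived lines
contain at least two distinct non-missing classes (`A`/`B`/`H`; `-`, `NA` and
empty strings are treated as missing, and a marker with only missing calls is
an error).  The QTL region runs from the closest non-segregating marker left
of the segregating block to the closest non-segregating marker on the right.
When a flank is missing the region falls back to the chromosome start (1) or
the supplied chromosome length, with a warning — the demarcation is then a
bound, not an interval between typed markers.  Segregating markers on more
than one chromosome are an error; demarcation is independent of marker input
order.

Gene overlap with the region is inclusive: a single shared base pair counts.

## 2. Expression-array condensation and contrasts (`seedqtl.microarray`)

Probe-level condensation follows the RMA convention without background
correction (deliberately: the generator produces no optical background):

1. **Quantile normalization** across arrays on the linear scale (rank → mean
   of order statistics, average ranks for ties via interpolation), after
   which all arrays share one sorted intensity vector exactly.
2. **Median polish** per probeset on log2 intensities (up to 10 iterations,
   tolerance 1e−6); the condensed value is overall + column effect.
3. **Global rescale** so the experiment-wide *linear* median equals 10,000,
   making expression values comparable across runs.

The genotype contrast pools all 12 arrays per genotype (3 replicates × 4
stages) — an open design decision; the alternative (per-stage contrasts with
3 vs 3) is available through `stage_contrast`.  Tests are equal-variance
pooled t-tests on log2 values; ratios are computed from *linear* means, so a
probeset is significant when BH q ≤ 0.05 **and** the ratio passes a 1.5-fold
screen in either direction.  Zero-variance probesets use the convention
p = 1 when the group means are equal and p = 0 otherwise.

BH FDR is delegated to `statsmodels.stats.multitest.fdrcorrection` after
validating p ∈ [0, 1].

The two-way ANOVA requires a balanced genotype × stage layout and decomposes
the sums of squares directly (equivalent to type-II on balanced data; the
test suite cross-checks every p-value against `statsmodels.anova_lm`).  The
table's `significant` column is keyed to the genotype main-effect q-value —
another open decision, chosen because the genotype effect is what nominates
candidates.

## 3. SFP detection (`seedqtl.sfp`)

Under the additive model log2 S(i,j,a) = log2 I(i,a) + A(i,j) + ε, the
affinity estimate for probe j on array a is log2(normalized probe intensity)
− log2(condensed probeset expression).  Per probe:

- delta = mean affinity (LoPro) − mean affinity (HiPro);
- d = delta / (s + s0) with s the pooled standard error and s0 the **median
  of s over all probes** (the SAM fudge-factor convention; pass `s0=0` for an
  unmoderated t).

The null distribution of |d| comes from random permutations of genotype
labels (default 200, seeded; fewer than 10 is an error).  For each probe,
q = (expected null count of |d| ≥ |d_probe|, averaged over permutations) /
(observed count at that threshold), made monotone in |d| and clipped to
[0, 1].  A probeset "contains an SFP" when any probe is significant
(q ≤ 0.05 by default).

## 4. Read-count differential accumulation (`seedqtl.htts`)

**Retention rule.** A read alignment is kept iff mapping quality equals 99
(the aligner's unique-best code), or it has no mismatches, or the summed
Phred quality of its mismatched bases is ≤ 6 (mismatches confined to
unreliable base calls).

**Counting.** A retained read increments a gene when it overlaps the genomic
span of the gene's *longest splice variant* by ≥ 1 bp; a read overlapping
several genes increments each, but each gene at most once per read.

**Normalization.** Treatment-sum: factor(lib) = mean(all library totals) /
total(lib).  Post-normalization totals all equal the pre-normalization mean
exactly (a property test).

**Test.** For each gene and comparison (per stage: one library vs one
library; "overall": normalized counts summed over the four stages per
genotype), the normalized pair is rounded half-up to integers and the smaller
count tested against Binomial(n, 1/2): p_one = Σ_{k≤c_small} C(n,k)·2^−n
computed by log-space summation (lgamma + logsumexp, exact to ~1e−15;
verified against arbitrary-precision rationals for all n ≤ 200), p_two =
min(1, 2·p_one).  Significance needs p_two ≤ 0.001 **and** fold ≥ 2, where
fold is max/min of the *unrounded* normalized pair (∞ when the smaller is
0).  Genes with a 0/0 pair are untestable and omitted from that comparison.
No multiple-testing correction is applied here — the stringent α stands in
for it, as is conventional for this test.

## 5. Integration, enrichment, validation (`seedqtl.integrate`)

Significant features from both platforms are mapped to genome coordinates
(start/stop printed in reverse orientation are re-oriented first), restricted
to the region (≥ 1 bp overlap), and clustered single-linkage by interval
overlap.  Each cluster becomes one candidate with the union of platform
evidence (`microarray`, `htts`, or `both`) and a majority vote direction
(`mixed` on ties).

GO enrichment is a flat per-category Fisher exact test (two-tail by the
standard minimum-likelihood rule, delegated to `scipy.stats.fisher_exact`
and verified against exhaustive enumeration) of DE genes against the
expressed universe (≥ 1 read across libraries), Bonferroni-multiplied by the
*total* number of categories on the platform (which may exceed the number
tested).  Only over-represented categories below α are reported by default.

qRT-PCR folds use the comparative-CT method: ΔCT = target − reference per
sample, ΔΔCT = mean ΔCT(A) − mean ΔCT(B), fold = 2^−ΔΔCT; the reported
spread is the s.d. of per-replicate folds of group A against the group-B
mean.

## 6. Synthetic generator (`seedqtl.simulate`)

All randomness flows from `SimulationConfig.seed` through named substreams
(`np.random.default_rng([seed, stream_id])`), so every artifact is
reproducible byte-for-byte and stages can be regenerated independently.  One
truth-DE gene set drives both platforms, so cross-platform integration can
be checked against a single table.

| parameter | default | rationale |
|---|---|---|
| `n_genes` / `n_probesets` | 2000 / 500 | desk-scale stand-ins for genome/chip scale |
| `probes_per_probeset` | 11 | matches the emulated chip design |
| `n_replicates` × `n_stages` | 3 × 4 | the emulated array design (24 arrays) |
| `introgression_interval` | chr1:3–5 Mb | interior segment, flanking markers exist |
| `de_fraction_in_region` | 0.3 | enough truth genes for stable sensitivity |
| `de_fold` | 4 | the fold the acceptance criterion probes |
| `sfp_fraction` / `sfp_shift` | 0.04 / 2.0 | ~20 SFPs, shift matching the criterion |
| `library_depth_range` | 150k–250k | ~200k uniquely mapped reads per library |
| `count_dispersion` | 0.05 | mild NB overdispersion; 0 gives Poisson |
| `intensity_sigma` | 0.2 | log2 array noise, typical replicate CV |
| `stage_factors` | 1, 1.5, 2.5, 4 | monotone seed-fill accumulation |

Intensities follow the additive log2 model: probeset expression (uniform
6–12) + stage term + genotype DE term + probe affinity (Normal(0, 0.8)) +
SFP shift (HiPro arrays only, one probe per affected probeset) + Normal
noise.  Counts are Gamma–Poisson with log-normal gene weights; truth-DE
genes are never silenced.  `simulate_alignments` emits reads that reproduce
the count table exactly (and optional junk reads that fail every retention
rule), so filter → count → normalize is testable end to end.

### Known artifacts (real phenomena, not bugs)

- **Quantile-normalization leakage.** With strong DE concentrated in one
  genotype, forcing both genotypes onto a common intensity distribution
  shifts non-DE probes genotype-dependently.  On small simulations this
  produces a handful of spurious moderate-|d| SFP calls and occasionally an
  extra significant probeset.  The injected SFPs still outrank all of them
  by |d_stat| (the acceptance criterion), and region intersection removes
  out-of-region extras from the candidate list.
- **Binomial anti-conservativeness under overdispersion.** The exact
  binomial test assumes Poisson sampling of a fixed split; with
  `count_dispersion > 0`, biological variation inflates per-stage false
  positives (single library vs single library).  This is the documented
  weakness of the test itself.  The end-to-end "candidates equal truth"
  test therefore uses `count_dispersion=0`; the default config is used for
  the sensitivity criterion, which it passes at 1.0.

## 7. Numerical choices

- Exact binomial in log space (lgamma + logsumexp) to avoid underflow at
  n ~ 10^5; verified against `Fraction` arithmetic for n ≤ 200.
- Rounding of normalized counts is half-up (`floor(x + 0.5)`), not banker's
  rounding, so x.5 always tests the larger integer.
- Median polish operates on log2; condensed values are re-exponentiated
  before the global median-10,000 rescale, so ratios of linear means match
  the published convention.
- Coordinates are 1-based inclusive internally (GFF3 convention) and
  converted to 0-based half-open only on BED output.
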