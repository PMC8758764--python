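# Methods

This note documents the models implemented in goldmapper, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real
data.

## The locus model

A locus is a reference ("d") haplotype plus an alternate ("G")
haplotype constructed as

```
alt = ref[1..b] + arm + loop + arm2 + ref[b+1..]
```

with `b` the 1-based breakpoint, `arm2` the reverse complement of `arm`
carrying a configurable number of single-base deletions. The default
geometry — 4,100 bp arms, 50 bp loop, 2 deletions, hence an 8,248 bp
insertion — mirrors the transposon-derived inverted repeat at the gold
locus (an ~8.2 kb insert whose two arm copies differ at two single-base
indels and form a ~4.1 kb cruciform stem). Arm differences are modeled
as deletions in the second copy, placed at least 10 bp from the arm
ends so the stated arm boundaries are well defined.

Two normalizations keep the constructed truth identifiable:

* the representation is left-aligned — if the insertion's last base
  equaled the reference base at the breakpoint, the same alternate
  haplotype could be written with the insertion one base further left,
  so that reference base is nudged to remove the ambiguity;
* the loop's outer bases are resampled if they would base-pair, so the
  stated stem/loop geometry coincides with the maximal inverted repeat
  of the insert.

Without these, breakpoint and stem length would be correct only up to
the (real and unavoidable) representational ambiguity of repetitive
flanks; with them, tests can assert exact recovery.

## The cohort and phenotype model

Diploid genotypes are drawn under Hardy–Weinberg equilibrium at
G-allele frequency `g`. The phenotype is Mendelian-dominant with
incomplete penetrance at sampling time: carriers are gold unless still
untransformed (probability `p_untransformed_het` = 0.08 for Gd,
`p_untransformed_hom` = 0.01 for GG; the constraint hom ≤ het encodes
the dosage dependence of the color transition), and dd individuals are
gold only as phenocopies (`phenocopy_rate` = 0.005). Defaults
(`n_individuals` = 300, `g` = 0.2) emulate a mapping panel enriched for
the rare gold morph — roughly one third gold, comparable to a published
panel of 88 gold / 185 dark fish — not a wild population, where gold
frequency is on the order of a few percent. Background markers are
independent binomial dosages with MAFs uniform on [0.05, 0.5] and 5%
marker-wise missingness; they carry kinship information only in the
trivial (unstructured) sense, which is exactly what the null-calibration
tests need.

## Read simulation

Single-end reads (default 100 bp, 40× total coverage, error-free) are
sampled uniformly from each haplotype at half coverage. Alignment is
emulated analytically: a read from the alternate haplotype crossing the
left insertion junction is written as `<m>M<c>S` ending exactly at the
breakpoint; one crossing the right junction as `<c>S<m>M` starting at
breakpoint + 1; one wholly inside the insertion is unmapped-flagged
(the transposon would multi-map, and such reads carry no breakpoint
signal). Substitution errors are injected from a separate random
stream after placement, so error injection can never move a clip
boundary. Output is valid, coordinate-sorted SAM.

Consequences worth knowing:

* a heterozygote's expected split fraction is not 1/2 but
  2(rl−1) / (2(rl−1) + (rl−9)) ≈ 0.69 at rl = 100 with the default
  ±5 bp rules, because the insertion exposes two junctions while the
  reference haplotype exposes one spanning window; both values sit
  comfortably inside the (0.1, 0.9) heterozygote band;
* the default 40× coverage is chosen so the absolute-count override
  (≤ 2) in the caller is reliable: a heterozygote needs enough
  reference-supporting reads (~15 expected at 40×) that the chance of
  total − split ≤ 2 is negligible across thousands of samples. At 20×
  that override mis-scores a realistic fraction (~0.5%) of
  heterozygotes as GG — which is precisely why the original analysis
  backed low-coverage calls with manual inspection, a step this
  pipeline replaces with the explicit no-call state.

What the simulator does **not** model: paired-end insert-size evidence,
indel/structural read errors, base qualities, mapping ambiguity in
repetitive flanks, or coverage heterogeneity. Passing tests therefore
demonstrate the correctness of the counting and calling logic under
the stated evidence model, not robustness to real aligner artifacts.

## Split-read genotyping

A read is classified at the breakpoint as:

* **excluded** if unmapped, duplicate-flagged, malformed, or
  overlapping the breakpoint by fewer than `min_overlap` = 5 aligned
  bases on either side without a qualifying clip;
* **split** if a clip boundary (reference coordinate where soft- or
  hard-clipping begins/ends) lies within `clip_window` = ±5 bp of the
  breakpoint — either insertion edge is accepted, since both collapse
  to one reference coordinate for a pure insertion;
* **reference** otherwise, if the aligned span covers ≥ 5 bases on both
  sides.

Hard clips are treated like soft clips: both mark the same boundary,
only sequence storage differs. Genotypes follow the ratio thresholds
(strictly below 0.1 / strictly above 0.9) with absolute-count overrides
(n_split ≤ 2 → dd, n_total − n_split ≤ 2 → GG). When both overrides
fire at once — possible only at very low totals — the caller emits an
explicit no-call rather than guessing; the same applies to samples with
no classifiable reads.

## Mixed-model association

The linear mixed model y = Wα + xβ + u + ε, u ~ N(0, σ²λK), is fitted
by full maximum likelihood (not REML, so the nested null and
alternative models are directly comparable in an LRT). The binary
phenotype is treated as quantitative 0/1, the standard practice for
case/control mixed-model scans. K is the centered kinship
(1/p) Σ (xₖ−x̄ₖ)(xₖ−x̄ₖ)ᵀ over retained markers, with per-variant mean
imputation of missing dosages before both kinship and testing. One
eigendecomposition of K per scan reduces every fit to weighted least
squares; λ is profiled on a 41-point log-spaced grid over [1e−5, 1e5]
followed by bounded scalar refinement (tolerance 1e−8 on log₁₀λ).
P-values come from χ²₁; values below double-precision underflow are
floored at 5e−324 and flagged rather than reported as zero. Constant
dosage vectors are flagged untestable. Filters: MAF ≥ 0.05 on
non-missing calls, missingness ≤ 20%, no Hardy–Weinberg filter.

With K = I the profile likelihood is independent of λ and the scan
reduces exactly to OLS likelihood-ratio tests — the identity used as an
independent oracle in the tests. Known property: when kinship is
estimated from the same markers being tested, each variant's 1/p share
of K absorbs a sliver of its own signal; at the test sizes used here
(300 samples, ≥ 500 markers) the effect on calibration is within the
Monte-Carlo band.

## Insertion discovery and inverted-repeat geometry

Insertion discovery uses MUM-like anchors: k-mers (k = 31) unique in
both haplotypes, chained by longest increasing subsequence over
positions; a positive alternate-minus-reference gap between adjacent
chained anchors is an insertion, with the breakpoint at the last
reference base of the left anchor and the call left-aligned by rotating
trailing homology. This is exact when the insertion flanks are unique
at k, the regime the method assumes; it is not a general-purpose
aligner and does not attempt megabase whole-assembly alignment.

The inverted-repeat finder matches 15-mers between the sequence and its
reverse complement, keeps the canonical half of the mirror-symmetric
match set, merges matches into near-diagonal runs (gap ≤ 3 words),
chains runs across diagonal shifts up to `band_width` = 16 (single-base
indels shift the diagonal by one), and polishes arm boundaries by
stepwise complement extension that resynchronizes across isolated
substitutions or single-base indels (8-base lookahead). Arms that run
into each other (near-perfect palindrome) are trimmed to non-overlap
and flagged. Arm differences are enumerated from a unit-cost global
alignment of arm1 against the reverse complement of arm2 (edlib);
`stem_length` is the arm1 length, `loop_length` the separation between
arms, and each difference is reported with its position on arm1, so
identical-arm and edited-arm cases are separable. N bases never seed
matches. `band_width` = 16 comfortably covers the two-indel default
while keeping spurious chaining negligible.

The self-dotplot records all exact word matches (forward and
reverse-complement) merged into runs; run length is in bases covered,
so a perfect inverted repeat with a 4,100 bp arm shows a single
anti-diagonal run of length 4,100.

## Concordance and coordinate arithmetic

Percentages (dark carriers among dark; gold dd among gold) and kb
distances are rounded half-even to one decimal, which reproduces
printed values such as 4.3% (8/185) and −5.7 kb
(7,069,471 → 7,063,765) from their raw inputs. A percentage with a
zero denominator is reported as undefined, never as 0. Note that
100 × 1/88 = 1.136 rounds to 1.1; the package always reports the
computed value. Distances are signed ((b − a)/1000);
upstream/downstream labels are left to the caller since they depend on
gene orientation.

## Pipeline and reproducibility

A single global seed is expanded via `SeedSequence.spawn` in a fixed
stage order (locus, cohort, reads; per-sample read seeds spawned from
the reads child in cohort order), so stages can be re-run in isolation
and identical configurations produce byte-identical outputs — verified
by SHA-256 digests recorded in the run manifest. The SV genotype is
added to the marker set for the scan unless it fails the MAF filter
(e.g. a monomorphic locus), in which case the skip is logged with its
reason.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
relevant statistics sharp: full-size locus geometry (10 kb reference,
8,248 bp insertion) for structure recovery across 10 seeds; scaled-down
loci (1.2 kb reference, 532 bp insertion) for read-level cohort
genotyping (180 samples × 10 seeds at 40×); association scans at
n = 300 with 500–1,000 markers, 20 replicates for null calibration; and
a 40,000-individual cohort for the closed-form concordance
convergence check. Reported real-data quantities that depend on the
deposited sequencing data (the genome-wide scan's headline p-value,
expression analyses) are out of scope.

## Known limitations

* The genotyper assumes the breakpoint is known; de novo breakpoint
  discovery from reads, discordant-pair and assembly-based genotyping
  are out of scope.
* The LMM implements the LRT only (no Wald/score tests, covariates
  beyond an intercept are supported but unexercised by default, no
  multi-trait models).
* The insertion caller reports deletions implicitly (negative gaps are
  ignored) and is undefined for rearrangements that break anchor
  collinearity.
* The inverted-repeat finder targets a single dominant repeat; nested
  or multiple repeats return only the longest stem.
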