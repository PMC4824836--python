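# Methods

## The mixture model

A tumor sample is modelled as a mixture of an aberrant clone (fraction
ρ ∈ [0, 1] of the DNA) with integer allele-specific copy numbers
(nA ≥ nB ≥ 0) constant within genomic segments, and diploid normal cells
(fraction 1 − ρ). At a SNP inside a segment with total copy number
n = nA + nB, the mixture copy number is n_mix = 2(1 − ρ) + ρn and the two
array signals are

- LRR = γ · log2(n_mix / ψ_mix), where ψ_mix is the SNP-averaged n_mix of the
  whole sample — the track is centered the way a tumor-vs-matched-normal
  ratio is centered — and γ is a platform compression factor
  (default 0.55, typical of genotyping-array LRR response; configurable);
- BAF = (1 − ρ + ρ·nB′)/n_mix at germline-heterozygous ("informative") SNPs,
  where nB′ is nB or nA with equal probability per segment (the B allele is
  equally likely to sit on the retained or the lost haplotype), making the
  BAF distribution symmetric about 0.5; germline-homozygous SNPs sit near 0
  or 1 and carry no allelic information.

Gaussian noise is added to both channels (defaults LRR SD 0.25, BAF SD 0.03)
and BAF is clipped to [0, 1]. The noise defaults are *calibration
placeholders*: array platforms do not publish their per-SNP noise, so these
were chosen once such that sample QC behaves sensibly on synthetic cohorts
(clean tumors pass; zero-purity tumors are flagged flat-BAF), and they are
exposed as parameters rather than asserted as measured values.

## Estimation

`AllelicCopyNumberModel.fit()` inverts the model in four stages.

**QC.** Three exclusion reasons, mirroring how uninterpretable arrays fail
in practice: *noisy LRR* (median absolute successive LRR difference > 0.5 —
a track the segmenter cannot smooth), *flat BAF* (fewer than 0.5 % of het
SNPs with |BAF − 0.5| > 0.1 — no allelic imbalance anywhere, the signature
of near-zero tumor content), and *low content* (neither of the above, but
segmented LRR variance < 0.003 and mean BAF divergence < 0.015 — too little
signal to fit). Thresholds are package defaults calibrated on synthetic
data only, and are configurable.

**Segmentation.** Greedy binary splitting of the two-dimensional signal
(LRR, mirrored BAF = 0.5 + |BAF − 0.5|) over informative SNPs, each channel
standardized by a robust successive-difference noise estimate
(1.4826·median|Δ|/√2, floored at 1e-4 so noise-free input still
segments); a split is accepted when the within-segment SSE reduction exceeds
`penalty · log n` (default penalty 10, minimum 5 het SNPs per segment).
Chromosome boundaries are always changepoints; chromosomes without het SNPs
are reported unassessable rather than dropped. Two estimator details matter
for accuracy:

- the segment **LRR mean uses all probes** (total-copy signal is carried by
  homozygous SNPs too), restricted to the span between the segment's first
  and last het SNP where probe assignment is unambiguous;
- the segment **BAF divergence** is the mean of folded per-SNP deviations
  |BAF − 0.5| with an analytic noise-bias deconvolution (inverting
  E|N(δ, σ)|). The naive "fold the mean" estimator cancels to zero when a
  segment merges opposite-phase pieces of the same allelic state; the folded
  mean does not, and the deconvolution removes its upward bias on balanced
  segments.

**Grid fit.** For each (ρ, ψ_t) on a grid (ρ from 0.10 to 1.00 step 0.01,
tumor ploidy ψ_t from 1.0 to 5.5 step 0.05 — finer steps add runtime without
accuracy, since every local minimum is subsequently refined continuously),
the continuous allele copy numbers of each segment are obtained by
inverting the generative equations, and the goodness is the
informative-SNP-weighted mean squared distance to the nearest non-negative
integers. Two robustness choices:

- segments with fewer than 10 informative SNPs are excluded from the
  goodness (they often straddle a sub-resolution true breakpoint and their
  mixture means are meaningless), though they still receive integer
  assignments in the output profile;
- the worst-fitting segments, up to 3 % of total weight, are trimmed at
  every grid point. Trimming is applied identically everywhere, so it cannot
  favor one solution family; what it does is keep a handful of
  breakpoint-straddling segments from deciding between exact solution
  aliases.

Candidates are the local minima of this surface (strictly below all 8
neighbors; equal-valued plateaus collapse to their lowest-ψ, highest-ρ
cell), each refined by an 11×11 zoom grid plus Nelder–Mead within ±2 grid
steps.

**Degeneracy and selection.** The model has an exact whole-genome-doubling
alias: replacing every (nA, nB) by (2nA, 2nB) and ρ by ρ/(2 − ρ) reproduces
LRR and BAF identically. Under noise the alias fits ~4× worse (its
copy-number scale amplifies residuals twofold), so candidates within 1.5× of
the best goodness are treated as ties and resolved toward **lower ploidy**
(then higher ρ) — parsimony decides only when the data genuinely cannot.
A genome that is exactly balanced everywhere (every segment nA = nB and flat
LRR) is unidentifiable and reported as such rather than fitted. Finally, if
the best solution implies more than 10 Mb of homozygous deletion —
incompatible with cell survival at that scale — the next-best candidate at
strictly higher average ploidy (and admissible homozygous-deletion load) is
selected instead; if none exists the best is kept with a warning.

Reported ψ is the informative-SNP-weighted mean total copy number of the
integer profile. A per-segment reliability score,
1 − residual/√0.5 (residual = Euclidean distance of the continuous copy
numbers from the assigned integers), is descriptive only and never used for
selection.

## Calling conventions

- **Loss**: total copy number strictly below 0.7·ψ. The threshold scales
  with ploidy so that near-tetraploid genomes are not called wholesale.
- **LOH**: minor copy number 0, *including* homozygous deletions — with
  minor = total = 0 a gene is both lost and in LOH. Nothing in the loss/LOH
  definitions excludes them, and the two tracks are reported separately; the
  convention is a config switch for users who want homozygous deletions
  excluded from LOH.
- **Gene-level copy number**: length-weighted mean of overlapping segment
  totals (a small intragenic sliver of loss should not call a whole gene
  lost); minor copy number is the minimum over overlapping segments (any
  overlapping LOH segment confers LOH). Genes in segment-free gaps are
  missing, excluded from denominators downstream.
- Cohort fractions and tracks are computed over autosomes; frequency tracks
  are evaluated at SNP positions (the data's native resolution), with
  per-position denominators counting only tumors assessable there.
- **Recurrent regions**: maximal runs at frequency ≥ 0.2, merged across
  gaps < 0.5 Mb, reported when spanning strictly more than 1 Mb, each with
  its maximum internal frequency. Note the region *count* is not monotone in
  the frequency threshold (raising it can fragment a merged region); the
  monotone invariant — tested — is coverage containment.

## Enrichment analysis

Genes are filtered to those whose per-sample relative copy number
(total/ψ) correlates positively with expression (Spearman ρ > 0, two-sided
p < 0.05; α is configurable since only "significant positive correlation"
is specified by the analysis design), then ranked ascending by cohort-mean
relative copy number, ties broken by descending ρ, residual ties by a
seeded random permutation. Because several orderings are possible, the
analysis can be repeated over orderings and the maximum p reported.

The classic (unweighted) enrichment score walks the ranking adding 1/n_hit
per set member and subtracting 1/(N − n_hit) otherwise; ES is the running
sum at its maximum absolute deviation, so a loss-enriched set — concentrated
at the *top* of the ascending list — scores positive. Significance:

- **Permutation NES/p**: null ES from random same-size gene sets drawn from
  the ranked universe; NES = ES / mean(|null ES| of matching sign); p is the
  matching-sign tail fraction.
- **Empirical p**: n_resample random same-size sets, each normalized against
  the same null; p = (number with NES strictly greater than observed)/n,
  so 4 exceedances in 1000 draws report 0.004. A (k+1)/(n+1) variant is
  available for conservatism. The resampling universe is the post-filter
  ranked list by default (drawing from all genes is offered; members absent
  from the ranking cannot contribute to a rank statistic either way).

Calibration runs (uniformity of the empirical p under null cohorts) disable
the correlation filter: with no CN–expression coupling the filter retains
~2.5 % of genes by chance, emptying the universe; p-uniformity is a property
of the resampling machinery, not of the filter.

## CYCLOPS analysis

"Deleted" is the same 0.7·ψ gene-level call as everywhere (single source of
truth). Deletion-associated downregulation is a one-sided Wilcoxon rank-sum
(deleted < intact, asymptotic) at nominal α = 0.05 with minimum group size 3
— below that a gene is *untestable*, never silently negative. No
multiple-testing correction is applied by default (the candidate set is
small and curated); α and the correction are config options. Qualifying
genes are those deleted in ≥ 1 tumor and downregulated; percentages follow
display conventions (integer for set fractions, one decimal for tumor
coverage). Cross-cohort deletion-frequency comparisons use the exact
two-sided Fisher test (summing table probabilities ≤ the observed).

## Synthetic study conditions

The generator emulates: ~1 SNP per 3.3 kb (the density of a ~906k-probe
array); tumors as mixtures with ρ drawn from a configurable range; losses as
contiguous multi-megabase segments — background events log-uniform between
1 Mb and chromosome-arm scale placed to cover each gene with the background
rate in expectation, plus focal (1–5 Mb) events anchored on designated
stop-like genes raising their per-tumor loss probability to the in-set rate;
ploidy states beyond diploid built from a tetraploid base (ψ > 2.8) or by
spreading ±1-copy segments; overlaid losses never create homozygous
deletions (implausible at segment scale, and they would rightly trigger the
estimator's homdel adjustment against the generating truth); expression for
a labelled fraction of genes as baseline + slope·(relative CN) + noise,
CN-independent otherwise. Default set sizes are 878 stop-like and 55
cyclops-like on full-scale genomes, scaled proportionally (e.g. 30 and 10 on
a 300-gene test genome) in tests.

What the generator does **not** emulate: probe-level intensity artifacts,
GC/fragment-length waves, subclonal (non-integer) copy numbers, genuine
focal homozygous deletions, correlated noise, or realistic gene-length and
gene-density variation. Passing tests therefore demonstrate correctness of
the inference machinery under the stated model, not robustness to every
artifact of real arrays.

Problem sizes used by the test suite and the acceptance script — chosen as
the smallest that leave the estimators comfortably in their asymptotic
regime: 3 chromosomes × 40 Mb; SNP spacing 3.3 kb for purity/ploidy
recovery (≈ 36k SNPs), 10–30 kb for cohort-level analyses; 120–300 genes;
cohorts of 20–74 tumors; resampling at 200–1000 draws.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seeds give bit-identical p-values and
  byte-identical pipeline reports.
- Loss calls use strict inequality at the threshold; Fisher tables compare
  probabilities with a 1 + 1e−12 relative tolerance as usual for exact
  two-sided tests; goodness near-ties use max(1.5×, +1e−9).
- Empty tracks, empty candidate lists, empty post-filter gene universes,
  gene sets disjoint from (or equal to) the ranking, and zero assessable
  extent all raise typed errors rather than returning silent defaults.
- Spearman correlations are vectorized via ranks with the t-approximation —
  identical to `scipy.stats.spearmanr`'s asymptotic p (tested) — with NaN
  for constant vectors and for genes with fewer than 8 complete pairs.

## Known limitations

- ρ is only estimable when some segment is allelically imbalanced; samples
  with ρ below ~0.25–0.3 at default noise lose recovery accuracy and are
  expected to be caught by QC instead (flat BAF / low content).
- Purely balanced aneuploidies (e.g. an exact tetraploid genome with no
  odd-copy segments) are indistinguishable from diploid by construction;
  the lower-ploidy tie-break then reports the diploid interpretation.
- Breakpoints can only be placed at het-SNP resolution; truth segments
  holding fewer informative SNPs than the segmentation minimum are absorbed
  by neighbors (the fit is protected from them by the small-segment
  exclusion and trimming).
- The segment-profile entry point trusts its input ψ and ρ; no
  re-estimation is attempted.
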