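# Methods

This note documents the models, parameter choices and numerical
conventions behind `methepi`, and what the synthetic-data generator does
and does not emulate.

## Genetic-interaction model

A genotype's fitness for a phenotype channel is the per-fish metric
normalized to the wild-type mean of that metric: the thymopoietic index
(rag1 in-situ area / gh area, dimensionless; gh is a hypophysis marker
serving as technical and tissue-specificity control) or eye size.
W is the arithmetic mean of the normalized values and δ their sample
standard deviation (ddof 1); the wild type's own W is 1 by construction.
The arithmetic mean (not the median) is used for normalization because
fitness is reported as mean ± s.d. throughout.

The null model is multiplicative: E(W_xy) = W_x · W_y. It assumes the
two mutations act on independent multiplicative components of the
phenotype; deviations are summarized by the log2 fold change
I = log2(W_xy / E). The propagated error of E is the standard
first-order expression for a product of independent measurements,

    eps = W_x W_y sqrt((d_x/W_x)^2 + (d_y/W_y)^2).

An alternative "as printed" mode evaluates the literal inverse-square
form [(d_x/W_x)^2 + (d_y/W_y)^2]^(-2). It is retained only for
auditability: for typical 20–40% relative dispersions it returns values
like 25, four hundred times the fitness scale, and is clearly not a
usable error model. The square-root form is the default on the package's
own judgement that the inverse-square exponent is a typographical slip.

Significance: no coupling procedure between observed and expected
fitness is canonical here, so the package uses a z statistic
(W_xy − E) / sqrt(δ_xy²/n_xy + eps²) against the normal reference —
the double mutant's standard error of the mean combined in quadrature
with the propagated error of the expectation. This inflates the
denominator relative to a plain t-test and is deliberately conservative:
in the null-calibration simulations the non-interacting call rate at
α = 0.05 is well above 95%. Classification: p ≤ α and I > 0 ⇒
alleviating; p ≤ α and I < 0 ⇒ synthetic; otherwise non-interacting.
Multiple mutant pairs are reported without cross-pair multiplicity
correction (each pair is its own experiment); a correction can be
applied downstream on the reported p-values.

Degenerate inputs: if all double-mutant values are identical and the
propagated error is zero, p is set by exact equality (0 if the means
differ, 1 otherwise) and the result is flagged. Fish with gh_area ≤ 0
(failed internal control) are excluded with a warning, never imputed.

## Cytosine contexts and site filters

Contexts are read from the two bases downstream of the cytosine on its
own strand: CG, CHG, CHH with H ∈ {A, C, T}. Minus-strand cytosines
(forward-strand G) are classified on the reverse complement, reading
leftward. Sites with fewer than two downstream bases or an N in the
trinucleotide window are unclassified and excluded — a conservative,
easily testable convention.

Coordinates are 0-based half-open throughout (bedGraph convention).
Symmetric CG strand pairs are merged by summing counts onto the
forward-strand C of the dinucleotide, reported on strand + over
[p, p+2); merging is idempotent and count-conserving, and every CG
record is widened to the dinucleotide interval whether or not both
strands were covered (the destranding convention of methylation
extractors). CHG sites, although partially palindromic, are *not*
merged: per-strand CHG records match how extraction tools emit
non-CG contexts. A future flag could merge them; the package keeps the
per-strand convention as the default.

Filters, applied per coverage file before any pooling:

- `min_depth` (default 4 informative reads) — below this, ratios are
  too quantized to be meaningful.
- `max_variant_frac` (default 0.25) — sites where ≥ 25% of reads carry
  illegitimate bases (neither C nor T evidence) are treated as SNP
  contamination and removed. The denominator is all reads at the site
  (methylated + unmethylated + illegitimate).
- ratio > 0 (default) — covered but fully unmethylated sites are
  removed before distributional summaries, preventing the zero spike
  from dominating sparse non-CG contexts.
- `high_stringency_min_ratio` (optional, 0.25 when enabled) — some CHH
  coverage files show dense fixed-value artefact bands between 0 and
  25% methylation; this floor removes them. The filter *excludes*
  ratios below 0.25 (the artefact band) rather than retaining them;
  the opposite reading of "values less than 25%" would summarize the
  artefacts themselves, which cannot be the intent.

Methylation ratios are always recomputed from read counts; the rounded
percent column of coverage files is validated on parse but never used.

## Summaries

Two site universes are used deliberately:

- **counts** use the union of sites across a condition's replicates
  (a site is "methylated" if it passes the filters in at least one
  replicate); wild type is normalized to exactly 100;
- **ratio statistics** (mean, median, m.a.d.) pool the per-site ratios
  of all replicate columns over the intersection of sites covered in
  every replicate of every condition, so distributions are compared on
  a common support.

The m.a.d. is scaled by 1.4826 — the literal constant of R's `mad()`
default, not scipy's 1/Φ⁻¹(3/4) — because that is the convention of the
statistical environment these summaries are exchanged with; a raw-m.a.d.
flag exists. Even-length medians are the mean of the two middle values.

The restoration fraction ρ̂ = (m_double − m_single)/(m_wt − m_single)
operationalizes "what fraction of the single-mutant change is reversed
in the double mutant" on intersected-site mean ratios. It is invariant
under affine rescaling of the ratio axis, can exceed 1 (overshoot past
wild type, as non-CG contexts can show), and is undefined when the
single mutant equals wild type.

TSS meta-profiles bin sites by signed distance to the transcription
start in fixed windows (default ±3000 bp, 100-bp half-open bins);
minus-strand genes are mirrored so negative distance is always upstream
of transcription. A site exactly at the TSS falls in the first
downstream bin. Empty bins report n = 0 and an undefined mean.

## DMR caller

The caller honours the parameter semantics maxDist 300 bp, minCpGs 10,
minCoverage 5 (per site in *every* sample — intersection semantics),
minMethDiff 0.1 and FDR 0.1, but is an intentionally transparent
re-specification rather than a clone of metilene's 2-D KS segmentation:

1. CG sites covered ≥ minCoverage in all samples form the matrix.
2. Candidate blocks are maximal runs with consecutive-site gaps
   ≤ maxDist; runs under minCpGs are discarded.
3. Each block is segmented top-down: if the mean per-site group
   difference reaches minMethDiff in absolute value the block is
   emitted; otherwise it is split after the site where the CUSUM of
   mean-centred differences is largest in magnitude (leftmost on ties)
   and both halves with ≥ minCpGs sites are recursed on. Emitted
   regions are disjoint by construction.
4. Candidates are tested with a two-sided Mann–Whitney U on per-site
   ratios pooled across replicates, corrected by Benjamini–Hochberg
   (the threshold is named FDR, so BH rather than Bonferroni), and
   retained at q ≤ 0.1.

Candidates with fewer than two ratio values in a group are dropped with
a warning. Swapping the groups negates the signed difference and leaves
the regions unchanged. Real-data DMR counts from the original tools are
not expected to be reproduced by this caller; its contract is the
parameter semantics and the directional behaviour.

## Synthetic-data generator

The generator encodes the study conditions the analyses assume. Defaults
(one number each, chosen once):

- genome: 50 kb at GC 0.37 (zebrafish-like composition); 3 replicates
  per genotype; Poisson coverage, mean 20 reads/site.
- wild-type baselines: CG p_meth 0.80 with mean ratio 0.80 (heavily
  methylated CG compartment); CHG/CHH p_meth 0.05 with mean ratios
  0.35/0.30 (sparse, low-level non-CG methylation). Methylated-site
  ratios draw from a Beta with concentration 20 around the context
  mean — broad but unimodal, like observed violin shapes.
- hypomethylating genotype ("dnmt1"): ratios × 0.5; methylated CHG
  sites lost entirely with probability 0.5 and CHH with 0.3
  (maintenance failure hits partially palindromic CHG hardest).
- hypermethylating genotype ("pole1"): ratios × 1.15 capped at 1
  (slowed replication leaves more time for maintenance methylation);
  unmethylated CHG/CHH sites gain methylation with probability
  0.02/0.05.
- double mutant: latent ratio r_d + ρ (r_wt − r_d) with ρ = 0.75 —
  three quarters of the loss restored — then the CHH gain step, so
  doubles can overshoot wild type at CHH. Restoration acts on latent
  ratios, not counts, because the claim it models is about mean
  methylation ratios.
- noise: conversion failure and over-conversion 0.005 each; 1% of
  sites carry SNP contamination at allele fraction 0.5 (heterozygous),
  emitted as the illegitimate-base count.
- phenotypes: 30 fish/genotype; gh area ~ positive-truncated
  N(1.0, 0.15); rag1 = gh × κ × W × lognormal noise with κ = 2 and
  noise CV 0.2 (so the index cancels the gh channel exactly); true
  fitness W_x = 0.4, W_y = 0.15, ε_true = 2.0 for the thymopoietic
  channel (a strong alleviation) and 1.0/0.8 with ε = 0.5 for the eye
  channel (one mutant eye-normal, the other mildly affected).

Latent truth tables are returned alongside observed counts so recovery
tests have ground truth. RNG streams are keyed per (genotype,
replicate) from the seed, so adding replicates never perturbs existing
ones; identical configs give bit-identical output. Zero-coverage sites
are emitted deliberately to exercise the depth filter.

Not emulated: read-level bisulfite sequences, alignment and duplication
artifacts, replicate batch effects, copy-number variation, chromosome
structure (one synthetic chromosome), and CpG-island spatial clustering
— simulated CG sites are spread at random-sequence density, so DMRs on
synthetic data are few and broad. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not
robustness to alignment or batch pathologies in real libraries.

## Problem sizes in the validation suite

The validation runs use downscaled problems chosen to keep Monte-Carlo
error far below the asserted tolerances: a ~50k-site methylome at
coverage 50 with conversion errors disabled for restoration recovery
(binomial error of the genotype means is ~10⁻³, against a ±0.05
assertion), 200 simulated crosses per true interaction score (standard
error of the mean score ≈ 0.006 against ±0.1), and ten independent
10-kb genomes for DMR directionality. The full test suite runs in well
under a minute.

## Known limitations

- The z-test coupling of observed and expected fitness is a design
  choice, not a canonical procedure; with very few fish it is
  conservative rather than exact.
- ρ̂ is estimated on the intersection of sites covered and methylated
  in all replicates of all conditions; strong site loss in a mutant
  shifts that intersection toward robustly methylated sites and can
  bias ρ̂ slightly upward at low coverage.
- The DMR caller's CUSUM split is greedy; pathological difference
  profiles can split sub-optimally where an exhaustive segmentation
  would not. Equivalence tests cover instances ≤ 100 sites against an
  independent implementation of the same specification.
- CHG destranding is off by default and not currently exposed as a
  merge option.
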