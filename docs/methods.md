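# Methods

## Design and count model

The experiment is a 2×2 factorial: *hsf-1* knockdown (RNAi vs empty
vector) crossed with a 30-minute heat shock, in biological replicates
(duplicates by default). The synthetic generator models read counts per
miRNA and sample as negative binomial with mean μ and variance
μ + αμ², with a single dispersion α shared across miRNAs (α = 0 recovers
Poisson). Sequencing-depth variation is a per-sample lognormal
multiplicative factor (σ = `library_size_spread`, default 0.1).

Planted regulatory classes modulate the per-condition means by
2^`effect_log2fc`:

| class | C0 | C1 | C2 | C3 |
|---|---|---|---|---|
| hs_dep_up | μ | μ·2ᵉ | μ | μ |
| hs_dep_down | μ | μ/2ᵉ | μ | μ |
| hs_indep_up | μ | μ | μ/2ᵉ | μ/2ᵉ |
| hs_indep_down | μ | μ | μ·2ᵉ | μ·2ᵉ |
| unclassified | μ | μ | μ | μ |

The heat-shock-independent classes alter *both* knockdown conditions
equally — that is what a clean "no C2 vs C3 difference" signal requires.
Generator defaults are the study conditions used throughout the tests:
1,000 miRNAs, 2 replicates, baseline mean 500, α = 0.05, e = 3, and 5% of
miRNAs per regulated class (80% unclassified).

What the generator deliberately does **not** emulate: the wide abundance
distribution of real miRNA populations (a single shared baseline is used,
so replicate-scatter R² on synthetic data is lower than on real data and is
tested separately with an abundance spread), per-miRNA dispersion
variation, 3p/5p arm competition, and genomic alignment context. Passing
recovery tests therefore demonstrates the decision logic and its error
control under the assumed noise model, not robustness to every property of
real libraries.

## Quantification rules

Reads are 3'-adapter-trimmed at the leftmost occurrence of an adapter
prefix (≥ 5 nt overlap; the adapter defaults to the Illumina TruSeq
small-RNA sequence, configurable). A quality surrogate removes reads with
> 10% N calls — no base-quality metric is modelled — then reads shorter
than 18 nt are dropped (threshold inclusive: 18-nt reads are kept).

Mapping is positional (Hamming) against the mature-miRNA reference: a hit
requires zero mismatches in the first 18 nt and at most two mismatches at
positions ≥ 18; no indels. Reads longer than a reference are compared over
the reference length with up to 3 nt of untemplated 3' overhang tolerated;
shorter reads over the read length. Reads with more than five
(copy-count-weighted) hits are discarded; ties at the minimum mismatch
count are assigned 1/k to each of k references, so column totals equal the
number of counted reads (a seeded random-winner mode is available).
Mapping to mature sequences rather than the genome is a desk-scale
substitution that preserves the stated mismatch and multimapping rules;
per-record genome copy counts can inflate hit multiplicity to mimic
multi-locus miRNAs.

## Normalization

Two depth estimators are provided:

* `size_factors` — total-count factors, factorₛ = totalₛ / mean(totals).
* `median_ratio_size_factors` — DESeq-style median-of-ratios (median over
  miRNAs of countₘₛ divided by the miRNA's geometric mean across samples),
  rescaled to mean 1.

The model front end defaults to median-of-ratios. The reason is
compositional: under the default study conditions, 20% of miRNAs change
8-fold in some conditions, shifting library *totals* by ~30% and imprinting
a spurious ≈ −0.4 log₂FC on every unregulated miRNA in the knockdown
contrasts — enough to produce hundreds of false heat-shock-independent
calls. The median over a majority of unregulated miRNAs is insensitive to
this. Total-count factors remain available (`normalization="total"`) and
are what the simple worked examples use.

Fold changes are log₂ ratios of mean normalized counts (condition b over
condition a), computed as a difference of logs so orientation reversal
negates them exactly. The default pseudocount is 0 (zeros are removed by
the detection filter: a miRNA must have ≥ 1 read in every replicate;
a laxer per-condition mode is available); 0.5 can be configured.

## Tests and multiple-testing correction

The per-miRNA test is selectable:

* **exact** (default for `contrast`) — a two-sided exact conditional
  binomial test: replicate counts are pooled within each side and,
  conditional on the pooled total n, the side-b count is Binomial(n, π)
  under the null with π the side-b share of the summed size factors. The
  two-sided p-value uses the minimum-likelihood rule. This test is exact
  under Poisson sampling and is deterministic at any replicate number; it
  is **anti-conservative under biological overdispersion** (at μ = 500 and
  α = 0.05 the variance is ~26× Poisson), which is why the calibration
  check runs it under its own sampling model (α = 0).
* **nb_wald** — an overdispersion-aware Wald test on log mean normalized
  counts, Var(log m̄) ≈ (1/n)(1/μ + α) by the delta method, with the common
  dispersion α estimated by moment matching (regression of s² − m on m²
  through the origin, pooled over all miRNA × condition cells, clipped at
  0). With ~1,000 miRNAs the pooled estimate is tight even at n = 2
  replicates. Zero-mean sides are floored at 0.5 for the test only. This is
  the test to use on overdispersed data, and the one the recovery analyses
  use; with it, planted-class recovery at the default conditions is
  essentially exact (sensitivity ≈ 0.99, FDP ≈ 0.05).

q-values are Benjamini–Hochberg step-up adjusted **per contrast** over all
retained miRNAs (statsmodels' `fdr_bh` behind the module surface; the test
suite checks it against an independent brute-force implementation of the
step-up definition to 1e-12). Significance is strict: q = 0.05 exactly is
*not* significant. −log₁₀(q = 0) is capped at 300 for volcano tables (a
display bound with no inferential effect).

## Class calling

Candidates are defined directly by the relevant control contrast
(C1 vs C0 for heat-shock-dependent, C3 vs C0 for independent), with the
confirmatory pairwise tests binding: q(C1 vs C2) < α confirms dependence;
q(C2 vs C3) ≥ α confirms independence. The independence criterion is
literal non-significance, not an equivalence test — with duplicate
replicates an equivalence test would be hopelessly underpowered, and
non-significance is what the decision rule states; the provenance columns
retain all q-values so a TOST-style reanalysis is possible downstream.
A miRNA meeting both criteria receives the dependent label, with both
memberships kept in provenance (`dual`). Heat-shock-independent calls
report the negated C3-vs-C0 log₂FC so that signs reflect HSF-1's normal
regulatory direction.

## Target integration, networks, enrichment

"Inverse correlation" is discrete sign opposition with a significance
gate — an edge (m, g) survives iff m is classified, g is significant in
the named mRNA contrast, and sign(g) is opposite to m's direction — not a
correlation coefficient; the rule is asserted on every run. Interaction
edges are undirected. Unaffected genes enter the expanded network only as
neighbors shared by ≥ 2 affected genes. Linkers are nodes adjacent to both
the up- and down-cluster (equivalently, on an up–X–down path of length
≤ 2) plus direct up–down edges; this generalizes the worked three-gene
bridging pattern to a graph rule.

Term over-representation is the upper-tail hypergeometric p-value
P(X ≥ overlap) with the universe defaulting to all annotated genes
(overridable). Functional grouping is single-linkage on Jaccard similarity
(threshold 0.5) of the terms' overlapping-gene sets — a deliberate,
documented stand-in for kappa-statistic clustering, whose exact parameters
are external — while the cluster score is implemented exactly:
mean(−log₁₀ p) over member terms, the negative log of their geometric mean
p-value. An EASE-style jackknifed variant is not implemented.

## Determinism and numerics

All generator functions take integer seeds and derive independent
`SeedSequence` streams; the CLI splits one root seed per stage via SHA-256
(values kept below 2³¹). Identical config + seed reproduce byte-identical
output files (checksummed in the run manifest). Degenerate inputs are
handled explicitly: empty count matrices pass through filters; zero-total
libraries, empty references/universes, and out-of-range p-values raise
`ValueError`; a pooled total of zero gives p = 1; conditions with a single
replicate yield a flagged (None) R² rather than an error.

## Problem sizes

The default test and acceptance runs use 1,000–2,000 miRNAs, 10–20
simulation seeds, 5,000-gene target universes, and ≤ 50-node brute-force
graph oracles — sizes at which every oracle comparison is exhaustive or
tightly bounded (3 SE) while the whole suite runs in well under a minute
on one core.

## Known limitations

* The exact binomial test ignores biological variance; use `nb_wald` for
  real replicated data (the package will not switch automatically).
* A single shared dispersion; no per-miRNA shrinkage (edgeR/DESeq2-style
  moderation is out of scope).
* The Venn shaded-region totals of the original figure-based analysis are
  not reconstructible from decision rules alone; the class criteria are
  implemented as stated, and region membership is reported for all seven
  regions instead.
* Hamming-only mapping cannot place reads with indels; quality filtering
  is an N-fraction surrogate.
* Kappa-based annotation grouping and GO graph propagation (true-path
  rule) are not implemented.
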