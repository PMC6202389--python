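# Methods

This note records the statistical model, the generator that stands in for
real data, the numerical choices, and the limitations a user should know
before trusting a result.

## Per-cytosine selection test

Methylation levels (percent) at one cytosine are modelled by ordinary least
squares on the population factor POP with four levels: the ancestral
population D0 and three independently selected populations D1/D5/D6.  The
3-df population effect is split into

* `evoPOP` — the 1-df contrast `D0 − (D1 + D5 + D6)/3`, weights
  (+1, −1/3, −1/3, −1/3);
* `remPOP` — the 2-df remainder among D1/D5/D6.

With the default design (8 ancestral, 4 per selected population) the two
pieces are orthogonal, so `SS_evo + SS_rem = SS_POP` exactly; for data
unbalanced across the selected populations the decomposition is sequential
(type-I) with evoPOP entered first, computed as the regression SS of the
centred contrast coding.  Both F-tests use the shared residual mean square
with df = n − 4.  The implementation is vectorised over sites from per-group
counts and sums; missing values (zero coverage) reduce the per-group n at
that site, and a site with any population entirely missing is skipped and
flagged.  If the residual SS is numerically zero, p is set to 0 when the
corresponding contrast SS is positive and to 1 otherwise, with a
`degenerate` flag.

A cytosine is a DMC when `q_evo < α` and `q_rem ≥ α` (α = 0.05): the shift
must be shared by the replicate selections, and divergence among them
disqualifies the site.  Each genotype is analysed separately.  Levels enter
unweighted by coverage; a variance-stabilising transform is deliberately
not applied so that `delta` (mean selected-population mean minus ancestral
mean) stays in percentage points.

## Storey q-values

π₀ is estimated as `#{p > λ}/(m(1 − λ))` on λ = 0.05, 0.10, …, 0.95, a
cubic polynomial is fit to the grid values and evaluated at λ = 0.95, then
clamped to (0, 1].  q-values are the π₀-scaled step-up quantities, so they
are bounded above by Benjamini–Hochberg adjusted p-values.  For families
with m < 100 the grid estimate is too noisy and π₀ falls back to 1 (plain
BH); this is logged.  The evoPOP and remPOP p-value families are adjusted
separately.

## Diversity (MPD) and parental similarity

The distance between two individuals for one context and chromosome is the
mean absolute level difference over cytosines covered in both (pairwise
complete); MPD is the unweighted mean over all unordered pairs.  Because
every pair contributes equally, the expected MPD does not depend on the
number of individuals — the average MPD over all 4-subsets of an
8-individual population equals the full MPD identically, which the tests
assert.  Absolute (not signed) differences are used: signed differences
cancel and could not measure diversity.  A genome-wide per-context roll-up
(all sites pooled, so chromosomes weight by covered cytosines) is provided
and labelled `chromosome = "genome"`.  Similarity to the two parental
accessions is reported per 10-kb bin as (mean |sample − parent A|) −
(mean |sample − parent B|); empty bins are missing.

## DMRs, binary-state scan, genomic context

DMRs are greedy single-linkage runs of called DMCs: consecutive gaps ≤
`max_gap` join, clusters with ≥ `min_dmc` members span first→last DMC
(size = end − start + 1).  Because the DMR count is strongly
parameter-dependent, `dmr_parameter_sweep` emits the full (min_dmc,
max_gap) surface.  The binary-state scan counts sites whose level is below
5% or above 95% in *all* individuals; the default requires all individuals
in the same tail (the `same_tail=False` variant lets individuals sit in
either tail), and sites with any missing value are excluded from numerator
and denominator.

Feature mapping uses 1-based inclusive intervals (half-open only inside the
interval trees).  A position overlapping k scored features (exon, intron,
UTRs, 1-kb flanks, TE, siRNA target) gives each 1/k so scores sum to one;
no overlap scores `intergenic = 1`.  Gene-level DMC summaries instead count
a DMC fully for every gene whose body ± 1 kb window contains it: fractional
scores serve genome-wide tallies, full counts serve per-gene candidate
lists.  Metagene profiles use 100 equal body bins
(`floor(100·(pos − start)/length)`, clamped, strand-flipped for minus-strand
genes), genes ≥ 100 bp and ≥ 1 kb from chromosome ends, and 1-bp flank
tracks smoothed with a centred 50-bp moving average (the window is a free
choice; edge bins are renormalised).

## Resampling nulls

All empirical tests draw position sets from the tested cytosines, without
replacement within a draw, preserving per-stratum (context, genotype)
counts exactly where stratification is requested.  Empirical p-values use
the add-one rule (1 + #as-or-more-extreme)/(draws + 1), so the minimum is
1/(draws + 1) — 1/501 at the 500 draws used for feature co-localisation,
1/10001 at the 10,000 draws used for cross-genotype overlap.  Distances are
measured to the nearest region edge on the same chromosome (0 inside);
queries on chromosomes without regions contribute a large sentinel and are
the caller's concern.  siRNA target regions merge 24-nt loci strictly
closer than 10 bp (a `strict=False` flag gives the ≤ reading).  Because the
statistics are discrete, ties between observed and null draws make the
p-values mildly conservative; the calibration experiments therefore use
query sizes large enough that the statistic's support is wide (hundreds of
gaps or overlaps), which the acceptance checks document.

## GO robustness grid

Candidate genes at a grid cell have ≥ n DMCs (n ∈ {1, 2, 4, …, 20}) and
|mean change| ≥ δ (δ ∈ {0, 5, …, 50}%), 121 cells in total; the magnitude
is used so hyper- and hypo-methylated genes both qualify.  Each cell runs a
one-sided hypergeometric over-representation test per term against the
protein-coding universe with annotation propagated to ancestors.  A term is
robust when significant (p < 0.05) in ≥ 50 cells, with union semantics
across genotypes.  The decorrelating "weight" refinement of GO-graph tests
is intentionally not re-implemented; the classic test is the default and an
"elim"-style variant (genes of already-significant smaller terms removed
from later tables) is available.  p-values are therefore expected to be
somewhat anti-conservative for nested terms relative to decorrelated
methods, which the robustness grid partly absorbs.

## Downstream statistics

Phenotypes follow a crossed factorial GEN × RIL × POP fit sequentially:
GEN first as a time-confounded block (reported but flagged
non-interpretable), then RIL, evoPOP, remPOP, and all interactions; each
term reports df, SS, percent of total SS (summing to 100), F and p.  Empty
cells abort with an explicit list.  ddPCR expression is log2(count + 1) of
the test gene minus the mean log2(count + 1) of ≥ 2 reference genes (the
log-space mean is the geometric-mean normalisation); RT− counts are carried
for the contamination check but never enter the ratio.  Group comparisons
are two-sided Welch t-tests on the ratios, BH-adjusted within each gene
across its comparisons; fold-change is 2^(mean difference).  The accession
analysis splits samples by average methylation with an exact 1-d 2-means
(midpoint threshold reported); splitting a single Gaussian yields a
separation/within-SD ratio near 2.7, so inputs below a ratio of 3.5 are
flagged non-bimodal and split at the 50% level instead.  A plain Welch
t-test is used per variable (empirical-Bayes moderation is a cross-gene
construct and only one locus is tested here), BH-adjusted across variables.

## Variant filters

SNP candidates from 2 ancestral + 7 selected lines must have every
evaluated line's coverage in [20, 200] (the per-line reading is stricter
than a position-mean rule and is the default), a two-sided Fisher exact
p < 0.05 on pooled ancestral vs pooled selected allele counts (a
`worst_line` pooling variant exists), and ≥ 4 selected lines whose majority
allele differs from at least one ancestral line.  TE insertions need ≥ 30
supporting read pairs, ≥ 4 kb from the reference TE copy, presence in ≥ 4
selected lines and absence from both ancestral lines.  All filters are
monotone in their thresholds.

## Synthetic-data generator

The generator is the package's stand-in for deposited sequencing data and
defines the conditions under which the pipeline's statistical guarantees
are measured.

* **Design.** Two genotypes × (8 ancestral + 3 × 4 selected) individuals;
  phenotypes add a 2-level generation block with 17 individuals per
  GEN × RIL × POP cell; ddPCR uses 4 individuals per population with two
  reference genes; pooled resequencing uses 2 ancestral + 7 selected lines.
* **Sites.** Uniform random positions; contexts drawn from (CG, CHG, CHH) =
  (0.13, 0.15, 0.72), the genome-wide mixture with 13% CG.  CG baseline
  levels are bimodal (≈35% of sites near 0.7–0.95, the rest near
  0.02–0.10); CHG/CHH levels are low-skewed betas.
* **Counts.** Coverage ~ NB(mean 36, shape 10) per individual and site
  (mean 36 matches a post-filter genome coverage in the mid-30s); an
  individual's biological level ~ Beta around its epihaplotype level with
  concentration 30; methylated reads ~ Binomial(coverage, level) — i.e.
  beta-binomial methylation counts over negative-binomial coverage.
* **Signal.** Two epihaplotypes per genotype.  Planted DMC sites put all
  ancestral individuals on epihaplotype A and all selected individuals on B
  (|level difference| = `planted_delta`, sign random but kept inside
  [0, 1]): epialleles fixed by selection.  Epihaplotype diversity sites
  (default 1000) give each individual one joint epihaplotype drawn at
  frequency 0.5 in the ancestral and 1.0 in the selected populations
  (level difference 0.6); the frequency shift lowers selected-population
  MPD without divergence among D1/D5/D6.  Optional single-population sites
  put only one selected population on B — divergence the remPOP guard must
  reject.  The *null* configuration removes all planted sites and equalises
  the epihaplotype frequencies.
* **Determinism.** Each output table draws from its own RNG stream derived
  from (seed, fixed stream id), so regenerating one table never perturbs
  another; identical configs give bit-identical outputs.

What the generator does **not** emulate: read-level artefacts (alignment,
bisulfite conversion error, clonal reads), linkage between neighbouring
cytosines beyond the joint epihaplotype, strand-symmetric CG pairing,
chromosome-scale methylation landscapes (pericentromeric enrichment), and
genotype-specific epimutation spectra.  Passing tests therefore demonstrate
the statistical machinery, not robustness to alignment artefacts or to
spatial correlation structures absent from the generator.

## Problem sizes and measured behaviour

The statistical guarantees are measured at 2×10⁵ cytosines × 20 samples for
false-discovery and power runs (10 and 1 seeds respectively), 2×10⁴ sites ×
20 seeds for the diversity direction, 30 replicate experiments for ddPCR
recovery, and 200 replicates × 99–149 draws for resampling calibration —
sizes chosen so each check completes in seconds to a couple of minutes on
one CPU while keeping Monte-Carlo error well inside the asserted margins.

One measured property deserves a caveat.  Under the no-selection null the
false-discovery proportion of the DMC caller degenerates to a
family-wise-error quantity (any call is false), and the per-site F-test's
extreme tail is inflated roughly four-fold at the BH-relevant threshold
(~2.5×10⁻⁷) because levels drawn from skewed beta-binomial distributions
with 16 residual df are not Gaussian.  The same test is exactly calibrated
under normal noise.  In consequence, the probability that a 2×10⁵-site null
methylome yields at least one (false) DMC is ≈ 0.12 rather than the nominal
≈ 0.05, and the 10-seed average FDP hovers at the 0.10 boundary: honest
runs land on either side of it.  With genuine signal present the realized
FDP among calls is far below 0.05, since true discoveries dominate the
denominator.  No attempt is made to hide this by tempering the generator's
noise or the caller's thresholds.

## Known limitations

* The per-site linear model treats percentages as homoscedastic responses;
  coverage-weighted or count-based models are out of scope by design.
* The GO test is the classic hypergeometric, not a decorrelated GO-graph
  method; robust-term lists are comparable in spirit but not in exact
  p-values to decorrelated implementations.
* Empirical p-values are conservative under heavy ties (small query sets or
  sparse targets).
* The DMR surface is descriptive; no DMR-level significance is attached.
* The SNP and TE filters implement evidence rules, not genotyping; they
  assume the caller upstream produced sensible per-line counts.
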