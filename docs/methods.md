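# Methods

This note documents the models, conventions and numerical choices behind
`gutmir`, in the spirit of a statistical-software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design assumed throughout

A repeated-measures factorial: two mouse strains (default labels BALB/c and
C57BL/6) × three treatments (CON, AMP+NEO, ERY) × two timepoints (pre, post
antibiotic exposure), with a default of 6 mice per strain per treatment.
Each mouse contributes exactly one sample per timepoint; strain and
treatment are constant within a mouse. All coordinates are 0-based,
half-open; all tables are plain TSV; RNA letters (U) are mapped to T on
read so the package works in a single DNA alphabet.

## Diversity

* **Rarefaction** is a multivariate hypergeometric draw (subsampling without
  replacement; the output sums exactly to the requested depth). Samples below
  the depth are excluded and listed, never silently dropped.
* **Chao1** uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`;
  **Shannon** uses the natural log (the convention of the classical ecology
  packages), so `H' ≤ ln(richness)`.
* **PCoA** double-centers `−½D²` (Gower) and eigendecomposes. Negative
  eigenvalues — expected for Bray-Curtis — are reported but excluded from the
  percent-variance denominator, which is the sum of positive eigenvalues.
  Axis signs are fixed by making the largest-magnitude loading positive.
* **Multiple-rarefaction PCoA** repeats rarefaction+distance+PCoA
  (default 100 runs at depth 11,353, the default minimum of the simulated
  depth range), sign-aligns the axes of every run to the first run (flip an
  axis when its dot product with the reference axis is negative; no
  rotation/Procrustes — a deliberate minimal choice since eigenvector sign
  is the only systematic ambiguity between runs of the same data), then
  takes per-coordinate medians and IQRs and the median percent variance.
* **PERMANOVA** uses the standard pseudo-F from among/within sums of squared
  distances with p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm). The default
  100,000 permutations match the headline analysis convention; tests and
  examples use smaller counts, stated inline.

## Differential abundance

Relative abundances come from the unrarefied table; genus-level collapse
pools OTUs by their (phylum…genus) lineage key, so unresolved genera
(`f_X;g_`) remain separate per parent clade rather than being merged into
one "unknown" column.

* **Baseline tests** are two-sample permutation tests on the difference in
  means, exhaustive (exact p = count/total) whenever the number of
  arrangements is within the permutation budget, Monte-Carlo with the +1
  correction otherwise. Effect categories follow the median-difference
  ladder (> 10 percentage points, > 1, > 0, presence-only), with ties
  resolving to the weaker category.
* **Blocked RM permutation ANOVA.** With exactly two timepoints, the
  split-plot decomposition collapses: for per-mouse differences
  `d = post − pre`, the treatment×time F-ratio of the full factorial equals
  the treatment F of a two-way (strain × treatment) ANOVA on `d`, and the
  three-way interaction equals the strain×treatment interaction on `d`.
  Sums of squares are Type II (treatment after strain, ignoring the
  interaction; deterministic and order-invariant for unbalanced data), with
  F-ratios against the full-model residual. The permutation null swaps
  (or not) the pre/post pair within each mouse independently — a sign flip
  of `d` — enumerated exhaustively when `2^n_mice` fits the budget and
  Monte-Carlo sampled with the +1 correction otherwise. This matches the
  stated permutation scheme of multi-stratum permutation-ANOVA software at
  the level of the design; value-for-value equality with any particular
  implementation's per-stratum statistic is not claimed. Degenerate taxa
  (all differences zero) get p = 1.
* **Post hoc tests** are paired sign-flip permutation tests of the mean
  difference within each strain×treatment cell. BH FDR (statsmodels step-up)
  is applied across taxa per term.

## miRNA profiling

Per-lane background is `mean + 2·SD` (sample SD, n−1) of the negative
control probes; at least two negatives and two positives are required.
Normalization scales each lane by (grand geometric mean of positive-control
sums)/(lane positive-control sum), applies the same construction to ligation
controls when present, then subtracts the background computed on the scaled
negatives, flooring at zero. The abundance call (mean across all samples
strictly > 24) is applied to normalized, background-subtracted counts — the
source convention is ambiguous between raw and normalized counts, and the
chosen reading is recorded in the stage's output metadata. Group tests are
Welch t-tests on normalized counts with log2 fold changes of group means
(pseudocount 1); zero-variance probes get p = 1 by convention. The
ordination transform is log2(count+1) with the top-k (default 50) variance
probes; a shrinkage-based regularized-log transform used by some pipelines
is deliberately not reimplemented — the plain log transform is documented as
a divergence in the output metadata.

## Target prediction

The search is an ungapped seed-and-extend nucleotide scan with short-query
scoring: match +1, mismatch −3, exact word size 7, both strands. Because
queries are miRNA-length (≤ ~25 nt), the intersection of any diagonal with
the query is tiny, so extension computes the *exact* maximum-scoring segment
containing a seed word on each seeded diagonal (ties: shortest, then
leftmost). The X-drop parameter is kept in `ScoringParams` for interface
completeness but cannot change results under exact extension. This exactness
is what the brute-force-oracle test asserts: on random instances the best
hit per strand equals an exhaustive all-diagonal, all-segment scan.

Karlin–Altschul statistics: `B = (λS − ln K)/ln 2` with the published
ungapped constants λ = 1.374 nats and K = 0.711 for +1/−3 at uniform base
composition; λ is re-derived by bisection on
`0.25e^{λ} + 0.75e^{−3λ} = 1` at load and must agree within 1e-3.
E-values are `m·n·2^{−B}` with m the query length and n the *total catalog
length*; no finite-size length adjustment is applied (the adjusted search
space of production BLAST implementations is not reproducible without their
internals), so E-values are labelled uncorrected and differ from
length-adjusted ones — bit scores do not. Default hit filter: identity
fraction ≥ 0.90; requiring alignment length ≥ 90% of the query is exposed
as a flag (`require_query_coverage`) because the "90–100% coverage"
phrasing in this analysis tradition conflates identity and coverage, and
the intent is not guessed. Low-complexity filtering is off (short queries).

Taxonomy collapse of hits: a gene without lineage yields no target
(the unclassified catalog fraction); a genus-level lineage maps directly
when the genus occurs in the 16S table; a family-level lineage collapses to
a genus only when that genus holds ≥ 99% (`dominance_threshold`) of the
family's 16S counts; a species-level lineage expands to every OTU of the
parent genus, for OTU-level correlations. Lineage strings use rank prefixes
`p_/c_/o_/f_/g_` plus `s_` for the species rank needed by catalog
annotations.

## Correlation integration

Spearman rho uses average ranks; p comes from the t-approximation with
n−2 df, replaced by the exact permutation distribution of rho when n ≤ 9
(all n! pairings). Samples are matched between the miRNA and 16S tables by
id intersection, requiring n ≥ 4; mismatched designs are rejected rather
than aligned heuristically. The Table-2-style report flags significance at
raw p < 0.05 — matching the emulated analysis, which applied no correction
at this step — and emits a BH column alongside for users who want one.
Zero-variance vectors are flagged and excluded from significance counts.

## Barrier assays

FITC permeability is `(serum mg/ml) / (body weight g) × 10⁴` — the unit
string `(mg/ml/g)×10⁴` read literally. Treated mice are z-scored against
their own strain's control group using the control sample SD (the source
convention names only "distances away from control group means"; the SD
normalization is declared in output metadata). The permeability ANOVA is a
two-way factorial with permutation p-values: main effects by permuting the
factor's labels, the interaction by Freedman-Lane permutation of residuals
under the additive model. ddCt combines the two reference genes by the
arithmetic mean of their Cts (equivalently the geometric mean of expression
levels — standard multi-reference practice), subtracts the control-group
mean ΔCt as calibrator, and reports RQ = 2^(−ΔΔCt). Expression tests are
unpaired t-tests with a per-gene Mann-Whitney switch (exact for n ≤ 8
without ties, normal approximation with tie correction otherwise); the
correlation battery uses Spearman for taxa↔FITC (BH over the targeted taxon
list only) and both Pearson and Spearman for expression↔FITC, since the
source conventions for that pairing conflict — neither is privileged.

## Synthetic data generator

The generator produces inputs with the statistical structure the analyses
assume, with serializable planted truth for recovery tests. What it emulates
and what it does not:

* **16S counts.** Per-strain base composition is log-normal across taxa
  (σ = 1.5 nats — heavy dominance structure typical of gut communities);
  each mouse adds its own log-normal offset (σ = 0.6, the large
  inter-individual variability real cohorts show); effects (strain,
  treatment×time, strain-specific post shifts) act as log2 fold changes on
  the composition before a Dirichlet-multinomial draw (concentration =
  1/overdispersion, default 50) at a per-sample depth uniform in
  [11,353, 139,193] (the read-depth range the analyses assume). Taxa named
  in `base_log2_taxa` have their baseline pinned instead of drawn, so power
  experiments can plant effects on a consistently common taxon — under the
  random baseline, an affected taxon's abundance (hence any test's power)
  is a lottery. Not emulated: phylogenetic correlation between taxa,
  chimeras/contamination, read-level errors — so passing recovery tests
  demonstrates the statistics, not robustness to upstream artefacts.
* **miRNA counts.** Endogenous probes are log-normal (log2 mean 8, SD 0.35)
  with planted group fold changes; negatives are Poisson(8); positives
  follow the fixed ladder 8000/2000/500/125/32/8 with 5% per-lane scale
  jitter; coupled probes are monotone (log-linear) transforms of a taxon's
  relative abundance with reduced noise. Not emulated: probe cross-talk,
  saturation.
* **Catalog.** Background genes are i.i.d. uniform ACGT (appropriate for
  chance-hit calibration: the expected number of chance exact w-mers is
  analytic), planted sites embed exact complementary windows; default
  unclassified fraction 0.322 mirrors a catalog where about a third of genes
  lack taxonomy. Not emulated: codon structure, GC skew, paralogy.
* **Barrier.** FITC values are log-normal per strain/treatment (antibiotic
  arms shifted −0.5 on the log scale, emulating barrier tightening), with a
  Gaussian copula of configurable rank correlation to a taxon's
  post-treatment abundance. Ct values are baseline − log2 effect + N(0,0.2)
  noise with reference genes near 18/20 cycles.

Reproducibility: each generator takes one seed and derives independent
streams as `default_rng([seed, stream_index])` with fixed per-component
stream indices, so enlarging one table never perturbs another. Identical
config+seed gives byte-identical serialized output.

## Problem sizes and budgets

Calibration experiments in the tests and the acceptance script are sized to
give stable Monte-Carlo estimates while staying comfortably runnable on one
CPU: 500 null studies (20 taxa, 999 permutations) for the type-I bracket,
100 studies for each power/recall estimate in the test suite (60 and 50 in
the faster acceptance script), 500 random instances for the aligner oracle,
and a ~5 Mb catalog (≈2.5 Mb in the acceptance script) for planted-site
recall. These sizes are the package's own choice of precision/runtime
trade-off; all are parameters, not constants.

## Known limitations

* E-values are uncorrected; absolute E-value comparisons against
  length-adjusted implementations will differ (bit scores will not).
* The RM-ANOVA reduction is exact only for two timepoints; more timepoints
  would need the full multi-stratum machinery.
* The exact-extension aligner is designed for short queries; cost grows
  quadratically in query length per seeded diagonal and it is not intended
  for queries much beyond ~50 nt.
* Family-to-genus collapse uses a count-dominance threshold (default 0.99)
  computed on the supplied OTU table; with very sparse families the
  dominance estimate is itself noisy.
* The exact Spearman permutation p enumerates all n! pairings and is
  therefore capped at n ≤ 9.
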