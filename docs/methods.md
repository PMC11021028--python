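# Methods

This note documents the models, parameter choices, and numerical decisions
behind `mpp_eqtl`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design assumed

A panel of recombinant inbred strains descended from F founders (default
F = 8), each strain genotyped as additive founder-ancestry probabilities on
a common marker grid, with bulk RNA-seq counts per strain in a factorial
layout: two tissues (head, gut) × two treatments (control, copper), one
library per strain × tissue × treatment, plus a pooling-batch label
capturing plate/pool/flowcell technical structure. Strains carry a binary
resistance class. Analyses treat strains as independent (inbred lines, no
kinship correction) and each gene separately.

## Differential expression

* **Filtering.** Genes are kept when total counts are non-zero and at
  least `min_count = 10` counts appear in at least `min_samples = 47`
  samples — 47 being the size of one full three-way design cell in a
  96-strain study. Both numbers are parameters; the rule is deliberately
  one flag away from its opposite reading.
* **Normalization.** TMM with trim fractions 0.30 (log-ratios) and 0.05
  (abundance), inverse-variance weighting, and the reference sample chosen
  as the one whose upper-quartile count fraction is closest to the mean —
  verified in the test suite against edgeR's `calcNormFactors` to ~1e-12.
  Expression enters the linear model as log2 counts-per-million with
  TMM-adjusted effective library sizes and a 0.5 prior count. A trend-free
  moderated model is used (no precision weights); with desk-scale NB counts
  the mean–variance trend is mild and the calibration tests confirm
  near-nominal behavior.
* **Design.** Factors are coded ±½ so each coefficient equals the classical
  factorial contrast of cell means; pool enters as 0/1 dummies (first pool
  dropped). Rank is checked by pivoted QR and a deficiency error names the
  confounded columns: pooling structures nested within tissue (tissue-
  specific plates) are rejected rather than silently repaired.
* **Moderation.** Prior df `d0` and prior variance `s0²` come from moment
  matching on log variances via digamma/trigamma inversion (Newton, tol
  1e-10, `d0` capped at 1e6 to represent infinity) — algebraically the same
  estimator as limma's `fitFDist`, and cross-checked against
  `limma::squeezeVar` in the suite. One deliberate divergence: when the
  observed spread of log variances is below pure sampling noise, the prior
  is taken as a point mass at the *geometric mean* of the variances, so
  that identical variances are an exact fixed point of the shrinkage
  formula. Genes with zero residual variance are excluded from
  hyperparameter estimation.
* **Multiple testing.** Benjamini–Hochberg within each term across genes
  (statsmodels implementation behind a validated wrapper), FDR 5% default.

## Trait preparation

Six datasets: {Head, Gut} × {Control, Copper, Response}.

* **Log offset.** +1 on counts and on |response| before log2: zeros are
  common in both, and the offset makes zero differences map to exactly 0
  after signed normalization.
* **Quantile normalization (across strains).** Columns are mapped onto the
  mean empirical distribution. Ties receive the average of the reference
  quantiles at the tied ranks — deterministic and symmetric, at the cost of
  the "sorted columns identical" property holding exactly only for
  tie-free columns.
* **Response.** Copper − control raw counts per strain; both treatments
  must be present, otherwise the strain is dropped with an explicit error
  listing offenders. Magnitudes are normalized as log2(|d|+1) and the sign
  restored, preserving induction/repression direction.
* **PC removal.** PCs are computed over strains; a PC is removed when its
  variance share exceeds `var_fraction = 0.02` or when it associates with a
  technical covariate (one-way ANOVA for categorical, Pearson for numeric,
  α = 0.05 per PC × covariate, no multiplicity correction). Association is
  screened only for the 20 leading PCs: batch structure loads on
  high-variance components, and screening the full spectrum at α would
  remove ~5% of all PCs by chance, measurably eroding genetic signal.
  **Scale caveat:** the fixed 2% share rule presumes transcriptome-scale
  trait counts. At 500 traits × 96 strains the null eigenvalue bulk edge
  sits near 2.1%, so the rule removes several noise PCs that partially
  align with the strongest single-gene genetic signals. The recovery
  studies therefore run at 1,000 genes, where the rule behaves as at full
  scale; with only a few hundred traits, users should raise `var_fraction`
  or rely on the covariate screen alone.
* **Final transform.** Per-gene rank-based inverse normal,
  Φ⁻¹((rank − ½)/n), average ranks for ties. The across-strain step-1
  normalization and the per-gene step-3 transform are distinct operations
  and both are exposed separately.

## Genome scans

Haley–Knott regression: at each marker the trait is regressed on the F
probability columns with no separate intercept (the columns sum to one and
span it); the null model is intercept-only; `LOD = (n/2)·log10(RSS0/RSS1)`.

* Each marker's design is reduced once to an orthonormal basis by SVD with
  a rank tolerance, so markers where a founder is unrepresented (rank
  deficient) are handled by projection onto the realized column space. A
  whole scan is then one matrix product, and batched results equal the
  per-gene path to < 1e-10 (the suite also checks a brute-force two-model
  OLS oracle at 1e-8).
* `RSS1 < 1e-12·RSS0` is treated as a perfect fit and the LOD capped at 50
  to keep noise-free fixtures finite.
* **Permutation thresholds.** Per gene, the threshold is the empirical
  order statistic ⌈(1−α)·n_perm⌉ of the genome-wide maximum LOD over
  `n_perm = 1000` strain-label permutations (α = 0.05). Permutation index
  sets are shared across genes per round — one shuffle applied to the whole
  trait block — which keeps each round a single matrix product; fully
  independent per-gene permutations are available by flag
  (`shared_permutations=False`). Under the null the measured genome-wide
  per-gene type-I error is ~0.05 (the exceedance probability of the k-th of
  n order statistics, (n+1−k)/(n+1), is 0.0547 at n_perm = 200).

## Peaks, classification, effects

* Candidates are above-threshold local maxima, leftmost marker on
  plateaus. Secondary peaks on a chromosome are accepted only when
  separated from every accepted peak by a valley at least `lod_drop` below
  the lower of the two peaks — a documented choice; interval-mapping
  practice varies and no published rule exists for this design.
* Support intervals extend outward to the first markers more than
  `lod_drop = 3` below the peak, *including* those flanking markers
  (matching common `lodint` behavior), clipped at chromosome ends. A drop
  of 3 rather than 2 is the default because small panels (~96 strains)
  produce overly narrow 2-LOD intervals.
* Filters: peaks whose above-threshold run is a single marker, or whose
  position falls outside their own interval, are removed.
* **cis/trans.** Gene position is the bp midpoint linearly interpolated to
  cM on the marker map. A peak is cis when the gene is inside the interval
  or within `cis_window_cM = 1.5` of either boundary on the same
  chromosome; cross-chromosome peaks are always trans.
* Founder effects are OLS coefficients at the peak marker (pseudo-inverse
  with a logged note under rank deficiency), reported mean-centered, in
  post-normalization trait units. Percent variance is
  `100·(1 − RSS1/RSS0)`, which is algebraically `100·(1 − 10^(−2·LOD/n))`;
  the identity is verified to ~1e-13 at every called peak. Percent-variance
  estimates at detected peaks are upward-biased by selection (Beavis
  effect): planted 40%-variance loci average ~47% at their detected peaks
  in the recovery study.

## Sharing and enrichment

Sharing is per gene: same-chromosome peaks match when positions are within
`window_cM = 1.5` *or* intervals overlap (literal disjunction; both clause
outcomes are recorded). Greedy nearest-distance matching with
marker-id tie-breaks resolves multi-peak ambiguity and makes the matching
symmetric. Founder-effect correlations at shared peaks are plain Pearson.
Enrichment is an upper-tail hypergeometric per user-supplied gene set with
BH correction — no ontology retrieval or graph propagation.

## Synthetic data: what it emulates, and what it does not

The generator produces: Poisson(λ = 2 per chromosome) crossovers uniform in
cM with no interference, founder switches at every breakpoint (uniform over
the other F−1, so ancestry is marginally uniform); smoothed one-hot
probabilities (default smoothing 0.02) standing in for HMM posteriors;
negative-binomial counts (dispersion 0.05) around per-gene log2 baselines
(mean 5, SD 1), per-sample library-size factors (uniform 0.75–1.25), and
additive log2 pool shifts (SD 0.25) shared by all genes in a pooling batch.
Planted eQTL act through founder dosage at a causal marker, restricted by
tissue and treatment; `differential` effects act under copper only, so the
copper-minus-control response carries the full effect while control
expression carries none.

Desk-scale defaults: 96 strains, 2 chromosomes of 20 cM (201 markers each
at 50 kb spacing, 2 cM/Mb — a round fly-like autosomal average; the
genetic-map density is a free parameter, not calibrated to a particular
genome), ~500 genes. Pooling batches are strain blocks shared across
tissues with resistance classes alternating along the strain order, so the
pooling term is estimable alongside tissue and resistance in the factorial
model; real plate pools are often tissue-specific, a structure the DE model
intentionally rejects as confounded.

Planted effect sizes are expressed as the across-founder SD of the effect
vector in log2 units: 0.42 gives ≈ 40% of trait variance at the default
noise level; treatment-differential effects use 0.6 (≈ √2 larger) so they
occupy the same ~40% regime *of the response trait*, which accumulates
count noise from both treatments.

Not emulated: realistic founder linkage disequilibrium and haplotype
sharing, crossover interference, ancestry-estimation error structure (HMM
posteriors correlate along the genome; the smoothing here does not),
gene–gene correlation, mean-dependent dispersion, and sequence/read-level
artifacts. Passing recovery tests therefore demonstrates the *machinery* —
calibration of thresholds, localization, classification, sharing — not
performance under real LD or real technical noise.

## Problem sizes and runtime

The packaged studies run at: 500 null genes × 201 markers × 200
permutations (threshold calibration), 1,000 genes × 402 markers × 200
permutations (recovery and response studies), 1,000 genes × 384 samples
(DE calibration/power), all single-core in about a minute total. The
permutation default for real analyses remains 1,000; 200 is used in the
packaged studies as the smallest count giving a stable 95% order statistic
(the scan engine's batched permutations make 1,000 equally feasible at
these sizes).

## Known limitations

* No kinship/mixed-model correction and no covariates inside the scan
  model; strains are assumed exchangeable under the null.
* Multi-QTL models, epistasis, and bootstrap intervals are out of scope;
  the multi-peak separation rule is heuristic.
* The Response construction inherits the published design: differencing
  raw counts confounds expression scale with library depth for strongly
  expressed genes, and the signed-magnitude normalization is lossy for
  near-zero differences (sign flips under noise). Treatment-constant
  genetic effects cancel only in expectation; the false-positive rate of
  constant eQTL in Response scans is verified empirically to stay at the
  nominal level.
* TMM under strongly asymmetric differential expression retains a small
  residual normalization bias (~0.09 log2 at 10% one-sided DE of 4-fold),
  which very large designs can flag on null genes; the packaged power
  study plants direction-balanced effects.
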