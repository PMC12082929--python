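# Methods

This note documents the statistical model behind `csfnet`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Synthetic cohort model

The generator emulates a two-platform, six-group CSF proteomics study
design. Log2 abundances follow a latent-factor model

    x_ps = b_p + λ_p (f_{m(p),s} + δ_{m(p),g(s)}) + β_p (age_s − 55)/10
           + γ_p 1[sex_s = F] + batch_{p,b(s)} + ε_ps

- **Baselines** `b_p ~ N(20, 2)` log2 units — the spread of protein-level
  abundances in a quantified CSF proteome.
- **Modules.** Twelve planted modules with sizes geometrically spaced from
  476 down to 29 members (the range reported for real CSF networks), plus
  one module of 10 members deliberately below the detection minimum of 15,
  as a negative control. Default proteome size 2,300; the ~12% remainder is
  unstructured noise. A latent-factor model was chosen because the module
  eigenprotein — the first principal component of the members — is a
  consistent estimator of the factor under it, which makes eigenprotein
  and kME behavior directly testable.
- **Loadings** `λ_p ~ U(0.4, 0.95)` for module members, 0 otherwise. This
  yields within-module correlations of roughly 0.4–0.75 at the default
  noise, and makes the planted kME ordering testable (higher-λ members are
  hubs).
- **Group effects** `δ` shift the module factor (unit variance), so their
  magnitude is in pooled-SD units. Defaults mirror the qualitative ALS CSF
  pattern: matrix/microglial/ubiquitination-like modules (M5, M7, M10) up
  by 1.0–1.2 SD in symptomatic disease, neuronal/synaptic modules (M1, M4,
  M11, M12) down 0.8 SD in C9orf72 ALS, attenuated genotype-dependent
  shifts (±0.4–0.8) in asymptomatic carriers, and two modules (M6, M9)
  with no disease effect. The recovery contract (eigenprotein ANOVA
  q < 0.05 after the full pipeline) is asserted for effects of ≥1 SD;
  weaker planted effects are realistic decoration, not guaranteed
  detections — median-based normalization necessarily absorbs part of any
  globally coordinated shift.
- **Covariates.** Ages are truncated-normal (18–90) per group with the
  means ± SD of the two study tables; sex fractions likewise. 20% of
  proteins carry an age slope `~N(0, 0.03)` log2/decade, 10% a sex offset
  `~N(0, 0.2)`; batch (TMT) offsets are `N(0, 0.3)` per (protein, batch).
  Known CSF marker genes (NEFL, CHIT1, CHI3L1, UCHL1, GFAP, the published
  panel members, and SOD1 under its canonical accession P00441) are placed
  in direction-appropriate modules so named fixtures exist.
- **Missingness.** Each value is blanked completely at random (rate 0.03)
  plus an abundance-dependent term, logistic in the global abundance rank
  and scaled by `mnar_strength = 0.5`, emulating the censoring of
  low-abundance peptides.
- **Reference channels.** TMT-like cohorts append one pooled-reference
  (GIS) channel per batch carrying the per-batch mean subject signal plus
  0.1 log2 measurement noise — the average to first order, without a
  degenerate zero-variance channel.
- **Seeding.** One master seed; every stochastic operation derives a child
  seed from (master, operation name), so stages are reproducible
  independently of execution order.

What the generator does **not** emulate: peptide-to-protein rollup,
reporter-ion interference or ratio compression, heteroscedastic
protein-specific noise, non-Gaussian outliers, and correlated missingness
across samples. Passing tests therefore demonstrate correctness of the
pipeline's statistics under a clean factor model, not robustness to every
artifact of real LC-MS data.

## Normalization (TAMPOR)

Values are converted to log2 ratios against a per-batch denominator — the
median over the batch's GIS channels (`gis_denominator`, the TMT default)
or over all samples in the batch (`all_sample_denominator`, the label-free
default) — then alternately centered by per-protein and per-sample medians
until both residual medians are ≤ 1e-4 log2 units (max 250 iterations;
convergence is typically < 30 iterations). The global per-protein median
is added back so the output stays on the abundance scale. Missing values
are ignored in all medians, never imputed.

Blocking comes from the batch column only. A cohort without batches (the
multicenter label-free design) is treated as one cohort-wide block. This
matters: when enrollment is confounded with center — in the emulated
design two centers contribute exclusively symptomatic patients — a
per-center denominator would subtract the disease signature of those
patients by construction. We verified this on planted data: per-center
blocking reduced a planted 0.36 log2 disease contrast to 0.03, while
cohort-wide blocking preserves it. Center-specific protein effects that
survive are treated like any other residual variance.

## Covariate adjustment

Per protein, OLS of abundance on [group (protected) + nuisance covariates]
over 200 case-resampled bootstrap datasets (multinomial weights on the
complete cases); the bootstrap-mean nuisance coefficients are subtracted,
protected terms never. Categorical covariates are indicator-encoded
against a reference level, numeric covariates centered; terms constant
within the complete cases are dropped with a warning; proteins with fewer
than 10 complete cases pass through flagged. Samples lacking a covariate
(e.g. reference channels without an age) are excluded from every fit and
pass through unadjusted. Coefficients are summarized by the bootstrap mean
and its SD; 200 resamples keep the residual adjustment noise well below
the planted effect sizes at desk scale.

## Differential abundance

Equal-variance one-way ANOVA per protein on the two comparison groups'
observed values (proteins with fewer than 2 observed values in either
group are reported untested), BH correction across the tested proteins of
one comparison. Two-group p-values are computed on the two groups alone,
not as post-hoc contrasts of a six-group fit, matching the per-figure
sample counts of the emulated study. Effect-size concordance between two
comparisons restricts to proteins with raw p < 0.05 in both, correlates
the log2 differences by bicor, and tests it against Student's t with
n − 2 degrees of freedom.

## Network construction

- **bicor** centers by the median, scales by 9×MAD, and applies Tukey
  biweights; a side-specific cap keeps at most 5% of samples per side at
  zero weight. Variables with MAD = 0 fall back to Pearson for every pair
  they join. The matrix path standardizes each protein on its own observed
  values with missing entries contributing zero — exact for complete data,
  a standard approximation otherwise; the vector path (kME, trait
  association, concordance) is exactly pairwise-complete.
- **Adjacency/TOM** follow the signed soft-threshold recipe with β = 4 and
  the standard topological-overlap formula; entries live in [0, 1].
- **Dynamic hybrid cut.** Branches of the average-linkage dendrogram of
  `1 − TOM` are scored by a *separability ratio*: mean within-branch
  dissimilarity over mean branch-to-outside dissimilarity, computable for
  every node in one bottom-up pass. A branch is a module when it has ≥ 15
  members and a ratio below a deepSplit-mapped ceiling (0.90 … 0.98 for
  deepSplit 0 … 4); it is split further when some descendant branch of at
  least core size improves the ratio by a deepSplit-mapped margin (0.10 …
  0.02). This keeps the published algorithm's ingredients — size floor,
  tightness, separation, sensitivity control — while replacing its
  height-scatter heuristics, which do not separate structure from chained
  noise on dense dendrograms at this scale: planted branches score ≤ 0.95,
  random-network branches ≥ 0.99. Detection then repeats on the
  unassigned residual (large modules' shared-neighbor weight otherwise
  masks small ones), with a PAM stage between passes assigning stragglers
  to the nearest module medoid when they fall inside its member/non-member
  midpoint distance. The cut is fully deterministic; ties in module
  ranking break on the lexicographically smallest member.
  A branch criterion based on an outside reference cannot, by design,
  detect a single module spanning the entire matrix.
- **Merging** iteratively joins module pairs with eigenprotein
  dissimilarity (1 − Pearson) < 0.07, recomputing eigenproteins after each
  join; labels are then re-ranked by size (M1 largest).
- **Eigenproteins** are the leading right-singular vectors of the z-scored
  member rows (median-imputing residual missing values), standardized and
  sign-aligned so the mean member correlation is positive; kME uses bicor
  to match the network estimator (the reference implementation defaults to
  Pearson here — a documented difference).

## Module association and enrichment

Eigenprotein–trait association subsets to one disease group plus controls,
codes the trait 0/1, and reports bicor with its Student-t p (star levels
at raw p 0.05/0.01/0.001, BH q also emitted). Eigenprotein ANOVA runs
across all groups with BH across modules. Fisher enrichment is upper-tail
(enrichment-only) hypergeometric against the detected network proteins as
background — CSF detectability is itself a strong filter, so a genome
background would overstate enrichment; sets are intersected with the
background and kept when 5–1000 genes remain; odds ratios use a 0.5
continuity correction only when a cell is zero.

## Cross-cohort preservation

For each reference module, three statistics are computed in the test
cohort: density (mean within-module signed adjacency), correlation of
intramodular connectivity between cohorts, and correlation of
correlation-matrix entries. Nulls come from 500 uniformly drawn same-size
protein sets; `Z_density` is the density Z, `Z_connectivity` the median of
the two correlation Zs, and `Z_summary` their mean, with the conventional
thresholds (>10 strong, 2–10 moderate; upper-tail normal p ≤ 1e-23 and
≤ 0.05 respectively). In synthetic cohorts that share one planted truth,
co-expression is preserved *globally*, so the null connectivity
correlations are themselves high and the density term carries most of the
discrimination; targeted ablations (shuffling one module's test-cohort
profiles) still drive that module's Z_summary below 2 while intact modules
stay above 10. The reduced statistic set keeps the published compositional
rule without reproducing all seven-plus statistics of the reference
implementation. Synthetic eigenproteins rank members by reference kME,
take the top 20% (at least 4 found in the test cohort, extending down the
ranking as needed), and use the hubs' first principal component in the
test matrix.

## Biomarker panels

Panels are the top-k (default 12) proteins by ANOVA p, ties broken by
larger |log2 difference| — a pure function of the DAP table, so panels are
byte-reproducible. PCA and two-way average-linkage clustering operate on
the z-scored panel submatrix (z-scoring per protein keeps variance
outliers from dominating); samples missing more than half the panel are
excluded and reported; the sample tree is cut into exactly two classes and
cross-tabulated against diagnosis.

## Problem sizes and numerical choices

The default verification scale is the full emulated study: 2,300 proteins,
101 + 259 samples, 12 planted modules, 200 bootstrap resamples, 500
preservation permutations; unit tests use 100–600-protein cohorts. Median
polish tolerance is 1e-4 log2 units; eigenprotein/PCA computations use
thin SVD; all stochastic steps derive child seeds from one master seed and
are bit-reproducible; the pipeline manifest carries no timestamps so
fixed-seed runs are byte-identical.

## Known limitations

- The hybrid cut is not statistic-for-statistic identical to the reference
  R implementation; planted-structure recovery, determinism, and the
  published parameter semantics are the contract.
- The fast matrix bicor slightly attenuates correlations between proteins
  with disjoint missingness patterns.
- Preservation's connectivity Z is weakly informative when the whole
  proteome is preserved between cohorts (see above); density dominates.
- The bootstrap regression assumes complete-case exchangeability; no
  mixed-effects or shrinkage estimators are provided by design.
- Null calibration (type-I) is verified for two-group ANOVA at the study's
  group sizes; heavy-tailed or strongly heteroscedastic data would need
  the robust limma-style moderation the emulated study does not use.
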