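# Methods

This note documents the statistical models, parameter choices and known
limitations of the `liversig` pipeline, in the spirit of the model
documentation shipped with simulation and statistics packages.

## Negative-binomial differential expression

Counts for gene *g* in sample *j* are modelled as
`K_gj ~ NB(μ_gj, α_g)` with `μ_gj = q_g(group_j) · s_j` and
`Var(K) = μ + α μ²`.

* **Size factors** are plain median-of-ratios: reference genes are those
  with nonzero counts in every sample; `s_j = median_g (k_gj / gm_g)`
  with `gm_g` the geometric mean across samples. Factors are reported
  as-is (no renormalization); the fitted group abundances absorb any
  common constant. If no gene is expressed in all samples the procedure
  refuses rather than silently shrinking the reference set.
* **Dispersion** is a per-gene method-of-moments estimate on normalized
  counts, computed within groups (so planted group differences do not
  inflate it) and pooled with weights `n_g − 1`, floored at `1e−8`.
  There is deliberately no empirical-Bayes shrinkage toward a
  mean-dispersion trend and no outlier refitting: calibration is
  demonstrated by simulation (below) rather than by replicating any
  specific tool's output.
* **Group fits** maximize the NB likelihood per gene per group by
  Newton iteration on `log q`, solving
  `Σ_j (k_j − q s_j)/(1 + α q s_j) = 0` (the score equation of a
  log-link NB GLM with a group intercept), vectorized over genes.  A
  group with all-zero counts sits at the likelihood boundary; its `q`
  is clamped at half a normalized count (`0.5/Σ s_j`) so the fold
  change stays finite while the Fisher information correctly reflects
  near-zero abundance.  Genes with zero counts in both contrast groups,
  or with undefined dispersion (all-zero rows), carry NaN statistics
  and are excluded from the BH family.
* **Wald test**: `log2FC = (log q_c − log q_r)/log 2`, standard error
  from the observed Fisher information `I = Σ μ/(1 + αμ)` of each
  group fit, two-sided normal p value, BH step-up adjustment across
  tested genes.  The reference group is always NAS 0–1.

**Calibration.** On planted-null simulations (26 samples as 8/12/6,
dispersion 0.05, gene means 20–2000), the empirical type-I error at
nominal 0.05 is ≈ 0.06 and the Kolmogorov–Smirnov distance of the p
values from uniform is ≈ 0.02. The mild anticonservativeness is the
cost of plugging in a noisy per-gene dispersion with ~20 samples and a
normal (rather than t) reference; with the true dispersion supplied the
rate is ≈ 0.05. This is documented rather than corrected because the
moment estimator and the normal reference are part of the documented
method surface.

**PCA.** Samples are embedded by SVD of the centered
`log2(normalized + 1)` matrix restricted to the 500 most variable genes
(sample variance).  Component signs follow the convention that each
component's largest-magnitude gene loading is positive, making plots
reproducible across runs.  The log transform choice is a convention;
any variance-stabilizing transform would serve.

## Directional Stouffer enrichment

Per-gene signed scores `z = sign(log2FC) · Φ⁻¹(1 − p/2)` are combined
per gene set as `Z = Σ z_i / √n` after intersecting the set with the
tested universe; sets smaller than 3 after intersection are dropped;
two-sided normal p values are BH-adjusted across tested sets.  This is
a deliberate simplification of directional p-class gene-set methods:
only the aggregate direction is scored, and no gene-permutation
empirical null is provided.  p = 0 inputs are clipped to the smallest
positive float before the quantile.

## Liver-selectivity scoring

`CV = sd/mean` of the gene's TPM vector across all tissues, liver
included, with the **sample** (n−1) standard deviation.  Under this
convention a one-hot liver gene across T tissues has exactly `CV = √T`
(the regression test uses T = 33 → 5.7446), and CV is invariant to
scaling the gene's row.  Genes with zero mean TPM are excluded with a
log entry.

A gene is flagged *selective* iff

* liver TPM ≥ 10 (absolute floor, TPM units),
* CV ≥ the empirical 0.90 quantile of CV across scored genes,
* CV > 0 (a constant-expression gene is never selective, even when the
  empirical quantile degenerates to zero), and
* liver is the gene's maximal tissue.

The floor, quantile and liver-is-max requirement are all configurable.
The thresholds deterministically reproduce top-right-corner reasoning
that is otherwise done by eye on a CV-versus-liver-TPM scatter; no
universally accepted numeric cut-offs exist for "high CV" or "high
liver expression", so these defaults are the package's own and are
deliberately conservative (decile + absolute floor + argmax).

## Secretion evidence and candidate selection

Evidence is case-insensitive exact symbol membership in three lists
(hepatocyte secretome, blood-proteome detection, predicted secreted);
`secreted` is their OR; no alias resolution is attempted (that would
require an external identifier database).  Candidates are
`DEGs ∩ selective ∩ (secreted ∪ indirect)`, where the indirect map
carries non-secreted enzymes whose catalytic product is measurable in
plasma; such rows are marked `marker_mode = indirect_metabolite` with
the analyte name.  The composite rank averages three ranks — padj
ascending, |log2FC| descending, CV descending — with lexicographic
tie-break; it is a reproducible stand-in for what is otherwise a manual
inspection step, not a validated scoring model.

## Validation

Independent cohorts are re-analyzed with the same NB-Wald machinery and
reference convention, restricted to the candidate genes; BH is applied
within the candidate set per dataset (confirmation, not discovery).
Direction concordance is the fraction of datasets (among those where
the gene is present) whose fold-change sign matches discovery; with
several contrasts per dataset, all tested contrasts must agree for the
dataset to count as concordant.

## Cohort statistics

* NAS = steatosis (0–3) + lobular inflammation (0–3) + ballooning
  (0–2); groups NAS 0–1 / 2–3 / 4–6.  Totals of 7–8 raise an error
  rather than being silently binned: the grouping is defined only up
  to 6, and silent binning would misclassify the most severe cases.
* NASH rule: steatosis ≥ 1 AND ballooning ≥ 1 AND inflammation ≥ 1.
  Note that clinical NASH adjudication can disagree with this purely
  arithmetic rule (pathologists weigh morphology, not just presence);
  the encoded reference frequency table in `datasets.py` carries the
  adjudicated counts and is the source for printed-count summaries.
* Fibrosis sub-stages 1a/1b/1c collapse to stage 1.
* Eligibility screening: FIB-4 ≥ 1.30, or NAFLD fibrosis score
  ≥ −1.455, or transient elastography ≥ 7.0 kPa (inclusive; the score
  formulas themselves are inputs, not computed here).
* Kruskal–Wallis uses midranks and the standard tie correction with a
  chi-square(k−1) reference.  The chi-square approximation is accurate
  to ~0.02 against full permutation enumeration in the tail region
  where the test operates (shifted groups, three groups of ~4–6), but
  mid-range p values at very small, unbalanced sizes can deviate by up
  to ~0.1 because H is heavily discrete there; an exact-enumeration
  oracle in the test suite documents both regimes.
* Dunn's post hoc z compares each group to the reference only, with BH
  across those comparisons — matching a design that contrasts each
  severity group against the no/mild group; classical all-pairs Dunn
  is intentionally not performed.
* Spearman rho is the Pearson correlation of midranks with a t(n−2)
  approximation; an exact permutation p is available for n ≤ 9.
* Summaries report median (Q1;Q3) with linear-interpolation quantiles
  (a convention; clinical software varies) and Kruskal–Wallis p per
  continuous variable, plus grade-frequency rows whose group sums are
  conserved by construction.

## Synthetic study generator

The generator emulates, at desk scale, every input the pipeline
consumes; its defaults are the study conditions under which the
acceptance checks run:

* **Counts**: 2000 genes × 26 samples (8/12/6 per NAS group), gene
  means log-uniform in [20, 2000], NB dispersion 0.05, per-sample size
  factors log-uniform in [0.7, 1.4] so normalization is non-trivially
  exercised.  Planted log2 fold changes are applied per group;
  everything planted is returned in a truth table.
* **Atlas**: 33 tissues (liver plus 32 named tissues), planted
  liver-selective genes at 500 TPM in liver versus 1 TPM background,
  other genes flat across tissues at a gene-specific level, all with
  10% multiplicative lognormal noise.
* **Secretome lists**: materialized from a per-gene evidence-source
  membership map; the union of the three lists equals the planted
  secreted set.
* **Cohort**: histology sub-scores drawn uniformly from the
  combinations compatible with each group's NAS range (totals in range
  by construction), fibrosis stages from group-specific frequencies
  with 1a/1b/1c labels to exercise collapsing, and continuous
  covariates through a Gaussian copula on the rank scale (target
  Spearman ρ converted to latent Pearson via `2 sin(πρ/6)`), mapped to
  clinically plausible marginals. Infeasible correlation targets are
  rejected naming the offending pair.  A Gaussian copula matches a
  Spearman-only correlation specification and is the simplest structure
  that does; tail dependence is not modelled.
* **Default planted scenario**: four candidate genes — three secreted
  (spread across the three evidence sources) and one non-secreted
  enzyme mapped to the plasma metabolite S-adenosylmethionine — all
  liver-selective and downregulated (−1.5 at NAS 2–3, −2.0 at NAS 4–6,
  mirroring severity-progressive downregulation); forty non-selective
  DEGs (mixed directions, half restricted to the advanced group so the
  DEG Venn structure is non-degenerate); six selective non-DEGs; ~150
  background genes with random secretion evidence.  Every filter
  therefore removes something, and exact recovery of the four planted
  candidates is a meaningful end-to-end test.

**What the generator does not emulate**: read-level artifacts
(sequencing depth is desk-scale, no GC/length bias), batch effects,
dispersion-mean trends, correlated genes, population stratification,
protein-level measurement noise.  Passing the planted-recovery tests
therefore shows the pipeline's logic and calibration are correct, not
that real cohorts of this size would yield stable candidates — the
motivating use case itself found that plasma-level confirmation of
transcript-level candidates can fail.

## Numerical choices

* Newton iterations on `log q` (60 max, step clipped at ±4) with the
  Poisson-style initial value `Σk/Σs`; convergence tolerance 1e−10 on
  the score.
* Dispersion floor 1e−8; abundance floor half a normalized count.
* BH implemented as the literal step-up (`min_{j≥i} m p_(j)/j`,
  clipped at 1), verified against brute force and statsmodels.
* Ranks use midranks throughout; ordering ties in candidate ranking
  break lexicographically by gene id so output order is total and
  stable.
* All generators are pure functions of (config, seed); derived seeds
  are small fixed offsets of the user seed.

## Known limitations

* No covariate adjustment in the DE model (group is the only design
  term), matching the intended single-factor design.
* The Wald test is mildly anticonservative (~0.06 at nominal 0.05) at
  n ≈ 26 with estimated dispersions; users needing strict control at
  small n should interpret borderline adjusted p values accordingly.
* Gene symbols are matched exactly (case-insensitive); orthologs,
  aliases and identifier versions are out of scope.
* The enrichment stage's parametric null assumes independent gene
  z-scores; co-expressed sets will be anticonservative.
* The candidate composite rank is a convenience ordering, not a
  calibrated score.
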