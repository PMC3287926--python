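# Methods

`pathscore` tests whether biological pathways are associated with a
binary disease phenotype in a case-control cohort genotyped on an
exome-style array, by combining the effects of rare and common variants
inside each pathway into a single genetic risk score.  This note
documents the statistical procedure, the synthetic-data model used to
validate it, the numerical choices, and the method's known limitations.

## The pathway association model

Let individual *i* carry additive minor-allele dosages
*g<sub>ij</sub>* ∈ {0, 1, 2} at SNP *j*, with covariates Age, Sex,
Smoking, population of origin and (optionally) quantitative traits
q1–q3.  A SNP is *rare* when its minor allele frequency (MAF) is below
1% and *common* at 1% or above; monomorphic SNPs are dropped.  SNPs map
to exactly one gene, genes map to (possibly many) pathways, and a
pathway is analysed when at least 5 of its genes carry at least one
QC-passing SNP.

**Step 1 — rare-variant collapsing score.**  For each pathway,
RS<sub>rare,i</sub> = Σ<sub>j∈rare</sub> g<sub>ij</sub> (the *count*
mode; a *proportion* mode divides by twice the number of observed rare
genotypes).  Collapsing trades per-variant resolution for power: single
rare variants are individually untestable, their aggregate burden is
not.

**Step 2 — LASSO-selected common-variant score.**  The pathway's common
variants enter an L1-penalized logistic regression of disease status in
which the covariate block is always present and *unpenalized*; only SNP
coefficients are shrunk.  SNP columns are standardized before
penalization (as glmnet does), and the penalty is chosen on a 15-knot
geometric path by 10-fold cross-validated deviance with the
one-standard-error rule (see *Choice of the penalty rule* below).
Selecting nothing is a meaningful outcome — the pathway then has no
common-variant component.  For each selected SNP the *risk allele* is
fixed by an unadjusted univariate fit (minor allele if its OR ≥ 1,
major otherwise), and RS<sub>common,i</sub> counts risk alleles across
the selected SNPs, so effect directions are aligned before summing.

**Step 3 — OR-weighted combination.**  Each component score is
dichotomized at its sample median m, and the odds ratio of the
indicator 1{RS > m} is estimated by unadjusted logistic regression.
The combined score is

    RS_final,i = 1{OR_r > 1} · OR_r · 1{RS_rare,i  > m_r}
               + 1{OR_c > 1} · OR_c · 1{RS_common,i > m_c}

The gate 1{OR > 1} zeroes a component whose dichotomized OR does not
exceed 1, so protective or null components contribute exactly 0 for
every sample.  A *continuous* mode that weights the raw scores by the
same gated ORs is available (`combine_mode="continuous"`); the
indicator form is the default.  In indicator mode RS_final takes at
most four values per pathway.  RS_final is tested against disease
status by logistic regression — unadjusted, and adjusted for Age, Sex,
Smoking and population — with Wald Z and two-sided asymptotic p.

**Step 4 — empirical p-values for the top pathways.**  Because steps
2–3 select variants, align directions and gate weights on the same
data, the asymptotic p-values of the best-looking pathways are
optimistic.  Pathways are ranked by |Z| of the combined unadjusted
test; the Z statistics of all pathways *except* the top k (default
k = 10) form an empirical null, and each top-k pathway receives

    p_emp = (#{z ∈ null : |z| ≥ |z_obs|} + 1) / (n_null + 1)

The add-one correction bounds p_emp below by 1/(n_null+1): the
correction can only be more conservative than the asymptotic claim.

**Population follow-up.**  Three further questions: (1) does disease
prevalence differ across populations (Pearson chi-square on the
population × affection table; Fisher's exact test for sparse 2×2
tables); (2) does a pathway's risk score differ across populations
(one-way F test of rs ~ population); (3) does population predict
disease *given* the risk score (likelihood-ratio test of
`affected ~ rs` vs `affected ~ rs + population`, chi-square with
n_pop − 1 df)?  Significant (1) and (2) with a non-significant (3) is
the signature of prevalence differences mediated by genetic
differences.  For this analysis the continuous combined score is the
more informative statistic — the dichotomized default deliberately
discards within-group risk variation, which leaves residual
population signal in the LRT.

## Quality control

Per SNP: folded MAF; genotype counts; the conditional exact
Hardy-Weinberg test (sum of probabilities of heterozygote counts no
more likely than observed, given the allele counts; monomorphic → p = 1;
mid-p not applied) computed *within each subpopulation* — pooling
stratified samples would produce spurious heterozygote deficits (the
Wahlund effect).  The default removal rule excludes a SNP only when it
fails p < 1e-6 in **every** subpopulation (`hwe_rule="all_groups"`);
the more aggressive `any_group` rule is available.  A univariate
logistic screen of every SNP (unadjusted or covariate-adjusted) is
reported but never used for filtering.  Non-convergent or separated
fits are flagged, with missing p, rather than dropped.

## Choice of the penalty rule

The penalty-selection rule is the one genuinely consequential tuning
choice.  Minimizing cross-validated deviance ("cv") selects spurious
SNPs in roughly a quarter of truly null pathways; because every later
step (risk-allele alignment, OR gating) then amplifies that noise, the
combined test's null rejection rate at α = 0.05 rises to ≈0.23.  The
one-standard-error rule ("cv_1se" — the strongest penalty whose mean CV
deviance is within one SE of the minimum) selects in under 1% of null
pathways and restores the nominal rate, at a modest cost in power that
the combined score largely absorbs.  `cv_1se` is therefore the default;
`cv` remains available for users who prefer maximal selection
sensitivity and will rely on the empirical-null correction.  Folds are
stratified by case status with a fixed shuffle seed, so runs are
reproducible.

Residual anticonservatism remains by construction: in the rare event
that the 1-SE rule still selects under the null, that pathway's
combined test is inflated.  This is intrinsic to testing a
data-selected score and is precisely what the Step-4 empirical
correction addresses for the pathways anyone would act on (the top k).

## The synthetic-data generator

The generator emulates the structure of a mini-exome case-control study
of unrelated individuals from three continental populations (Asian,
African, European), with known ground truth:

* **Allele frequencies.**  Ancestral MAFs are log-uniform within a rare
  band [5e-4, 0.01) and a common band [0.01, 0.5], with 75% of SNPs
  rare — a rare-dominated spectrum typical of exome content.
  Per-population frequencies drift under the Balding–Nichols model:
  p_pop ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F_st = 0.1 per population
  by default (mean p₀, variance F·p₀(1−p₀)); F = 0 reproduces p₀
  exactly.
* **Genotypes.**  Binomial(2, p_pop) per SNP and sample — so
  Hardy-Weinberg holds within populations by construction, and the HWE
  filter removes ~0 SNPs on null data (verified: < 0.1%).
* **Ascertainment.**  Real variant panels list sites *because* they
  were observed segregating.  Without that conditioning,
  Balding–Nichols drift at per-mille ancestral MAFs (Beta shapes ≪ 1)
  silently fixes most rare alleles at 0 in every population, and the
  majority of the "rare" panel would be monomorphic in the sample.
  The generator therefore redraws the drifted frequencies and
  genotypes of sample-monomorphic SNPs (bounded at 25 rounds;
  `ascertain_segregating=True` by default).  A realistic consequence:
  accepted rare variants are often population-private, i.e. strongly
  drifted.
* **Structure.**  Each SNP belongs to one gene (Poisson SNP counts,
  ≥ 1); pathways sample genes without replacement and may overlap.  For
  truth-recovery experiments `reserve_causal_genes=True` withholds the
  causal pathways' genes from other pathways' sampling pools — with
  overlap, any pathway containing causal genes is arguably causal, and
  rank-based recovery would be ill-defined.
* **Phenotype.**  logit P(affected) = baseline + Σ β_j g_ij + covariate
  effects (Age per 10 years, Sex, Smoking, direct population offsets) +
  an optional latent liability shared with the quantitative traits.
  The default baseline −0.85 gives ≈30% prevalence, matching the scale
  of the emulated study (209 cases of 697).  Causal SNPs are confined
  to designated causal pathways, drawn preferentially from genes
  private to that pathway, with causal common variants taken at
  ancestral MAF ≥ 0.05 so planted effects are detectable at realistic
  sample sizes.
* **Determinism.**  A fixed config + seed reproduces every output file
  byte-for-byte.

What the generator does *not* emulate: linkage disequilibrium between
SNPs (dosages are independent given population), family structure,
genotyping error and missingness patterns, X-chromosome dosages, and
the synthetic-rare-variant linkage that motivates the combined model.
Passing tests therefore demonstrate the statistical machinery under
idealized sampling, not performance on real LD-structured data.

## Validation experiments (problem sizes)

The calibration and power suites run at desk scale, chosen so the whole
test suite completes in minutes while keeping each check meaningful:

* **Global-null type-I error:** 700 samples, 500 overlapping pathways
  (~2,400 SNPs), no causal effects.  Among the pathways the pipeline
  actually tests — a pathway gated to a constant score produces no test
  statistic, which is the standard conditioning for the size of a test —
  the combined unadjusted test must reject within 3 binomial SE of
  0.05.  The per-pathway rate (untestable pathways counted as
  non-rejections) is reported alongside it by the reproduction script.
* **Recovery:** 1,000 samples, 1 causal pathway among 50 (10 rare
  causal SNPs at log-OR 0.4, 3 common at 0.5), 25 replicates; the
  causal pathway must rank first by combined p in ≥ 80%.  The sample
  size and causal counts were fixed by a pilot power calculation before
  freezing the suite.
* **Mediation:** 3,000 samples, population offsets zero, 25 replicates;
  the score-adjusted population LRT is expected non-significant in
  ≥ 80%.  This is the hardest property for the method: the combined
  score is a diluted, OR-weighted one-degree-of-freedom summary of the
  causal architecture, and measurement error in a mediator leaves
  residual confounding that a large-sample LRT can detect — so the
  suite's check of this bound is expected to sit near (and can fall
  short of) the threshold.  The continuous combined score is used here
  because the dichotomized default discards within-group risk
  variation outright.
* **Oracles:** the HWE test against full enumeration (all tables up to
  n = 25 plus 400 random tables to n = 200, tolerance 1e-10); fitted
  ORs against the 2×2 cross-product on random tables (1e-8); empirical
  p-values against direct tail counts (exact).

## Numerical choices

* **Logistic fits** use statsmodels Newton iterations; a fit is flagged
  as separated when any |β| > 15 or a standard error is non-finite.
* **L1 path.**  λ_max = max_j |x_jᵀ(y − ȳ)| on standardized columns
  (the smallest penalty with an all-zero SNP solution, up to covariate
  adjustment); the path runs geometrically from 1.5·λ_max to
  0.01·λ_max in 15 knots.  The penalized solver is liblinear; the
  unpenalized covariate block is standardized and up-scaled by 1e3, so
  its coefficients carry a ~0.1% share of the penalty — this
  reproduces the exact per-parameter-penalty solution (verified against
  a statsmodels L1 fit with per-parameter alpha, agreement to ~1e-3 on
  coefficients and exactly on the selected set) at a fraction of the
  cost.
* **Medians and ties.**  I(rs > m) is strict; a component whose
  indicator is constant (heavy ties at the median) is flagged unusable,
  as is a constant score.  Risk-allele ties (OR exactly 1) resolve to
  the minor allele.
* **MAF boundary.**  Exactly 1% is common; MAF 0 is excluded from both
  classes.
* **Missing dosages** contribute 0 to score sums (and leave the sample
  out of that SNP's univariate fit); the proportion-mode denominator
  counts only observed genotypes.
* **Degenerate inputs** fail loudly: all-missing SNP columns, constant
  predictors, single-class outcomes, top-k exceeding the pathway count,
  and GMT/genotype format violations all raise with file/line context.

## Limitations

* The combined-score asymptotic p-values of top-ranked pathways are
  optimistic by construction; only the empirical p-values correct for
  selection, and they are floored at 1/(n_null+1).
* The empirical null assumes the non-top pathways are representative
  nulls; with many truly associated pathways the correction is
  conservative.
* Dichotomization at the median loses information; heavy-tailed or
  zero-inflated burden distributions make the rare indicator coarse.
* The LASSO step needs enough common variants per pathway to be
  meaningful; pathways with none fall back to rare-only inference.
* Population structure is handled by adjustment and stratified QC, not
  by ancestry inference; admixed individuals are out of scope.
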