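# Methods

`longimet` re-implements, as a tested pipeline, a longitudinal analysis of
plasma metabolic profiles in a two-year wellness cohort: repeated plasma
sampling every three months in the first year and roughly every six months in
the second, with metabolome and proteome profiling at each visit, whole-genome
genotypes at baseline, and clinical/lifestyle covariates throughout.  The
cohort data such studies rest on are access-restricted, so the package ships a
synthetic-cohort generator with planted ground truth and validates every
estimator by parameter recovery rather than by reproducing any real-data
result.

## Synthetic cohort

The generator draws `n_subjects` (default 100) with sex assigned 1:1, age
uniform on 50–65 years, baseline BMI ~ N(25, 3²) kg/m² with a per-visit
random-walk drift (sd 0.3 kg/m², a free parameter: real within-subject BMI
dynamics over two years are poorly characterised), and a per-subject start
month uniform over the calendar.  Visits follow the study design: months
0, 3, 6, 9 in year one, then 6-month steps.

Genotypes are biallelic dosages drawn binomial(2, MAF) per variant — exactly
Hardy–Weinberg equilibrium — with MAF uniform on a configurable range.

Metabolites (log2 scale) follow the additive model

    y_ij = mu_j + b_i + A_j sin(2*pi*m/12 + phi_j) + sum_k beta_jk G_ik
           + gamma_j sex_i + delta_j BMI_iv + eta_j age_i + eps_ij

with subject intercepts b_i ~ N(0, sigma_b²) and residuals
eps ~ N(0, sigma_e²).  Defaults: sigma_b = sigma_e = 0.5 log2 units (so
between-subject variation dominates the per-visit noise once visits are
averaged), 20% of metabolites seasonal with amplitudes 0.1–0.5 and uniform
phase, three planted mQTLs of 1 log2 unit per allele at MAF ≥ 0.2, 30% of
metabolites carrying modest sex/BMI/age effects, and 5% of cells missing
completely at random.  The generator intentionally mirrors the fitted
models — additive, linear, no interactions — so each downstream estimator is
unbiased under its own model and parameter recovery is a clean test of the
implementation.  It therefore does *not* emulate several features of real
data: informative missingness (detection limits), heavy-tailed measurement
error, LD between variants, batch effects, or correlated metabolite modules
beyond what the planted effects induce.  Passing tests demonstrate that the
estimators recover what they claim under their stated assumptions, not that
those assumptions hold in any particular cohort.

Proteins carry one cis-pQTL each (1 log2 unit/allele); a configurable subset
causally shifts a distinct metabolite with slope theta (default 0.5) while
both load on a subject-level latent confounder U (loadings 0.5/0.5, sd 1), so
the naive regression of metabolite on protein is biased upward and the
instrumental-variable estimand equals theta.

Clinical indicators (BMI, HDL, SBP, glucose, TG, plus ALAT/GGT/urate/
troponin-T/WBC) are affine transforms of a latent two-component risk factor:
`indicator = base + scale * (sex_offset*sex + loading*z_i + N(0,1))`, where
z_i = separation for high-risk subjects (35% of the cohort) and 0 otherwise,
and HDL's loading is negative.  At the default separation 3 the groups
overlap realistically; at 6 they are linearly separable on BMI alone.

## Quality control

Analyte filters, in order: (1) detection — missing fraction ≥ 30% of samples
(inclusive); (2) stability — max/min interquartile range across the first
four visits > 2 (an IQR of 0 against a positive one counts as unstable; an
all-zero-IQR analyte is constant and kept); (3) duplicates — identical
column ids, then identical value vectors, reported separately because
"duplicated" is ambiguous in the field's usage.  Subjects with fewer than
four attended visits are removed.  Variant filters: subject call rate
< 95%, variant missingness > 5%, empirical MAF < 5% (monomorphic variants
fall under this rule), and the exact Hardy–Weinberg test at P < 1e-6.  The
HWE test enumerates heterozygote counts conditional on the allele counts
(the classical exact test, PLINK's default), implemented with log-gamma
arithmetic and verified against an exact-rational oracle.  Every rule logs
the exact items removed; counts reconcile with matrix shapes by construction.

## Variability and seasonality

Inter-individual CV is the sd/|mean| across participants within each visit,
summarised by the median over visits; intra-individual CV mirrors this within
participants across visits.  CVs are computed on the analysis (log2) scale —
the scale every other stage consumes; users with linear-scale conventions
can pass a linear matrix.  The median summary across strata is a choice the
output metadata records (the field's usage does not fix it).

The seasonal model per analyte is the cosinor linear mixed model

    y ~ sin(2*pi*month/12) + cos(2*pi*month/12) + sex + BMI + age + (1 | subject)

fitted by REML (statsmodels MixedLM).  The amplitude sqrt(bs² + bc²) is
invariant to the phase of the underlying oscillation (verified to 1e-8 by a
rotation test).  Seasonality is the joint 2-df Wald F test of the sine and
cosine coefficients.  Denominator degrees of freedom use a containment-style
count, n_obs − n_subjects − n_fixed + 1: Kenward–Roger and Satterthwaite
corrections are not available for this model in the Python stack, and at the
study size (~600 observations, 100 subjects, ddf ≈ 495) all three are
essentially identical — the type-I-error benchmark (below) confirms nominal
calibration.  Degenerate fits (zero residual variance, singular random
effects) fall back to a fixed-effects OLS fit and are flagged; analytes with
fewer than 10 observations are skipped and excluded from the FDR family.
Benjamini–Hochberg correction is applied across the fitted family
(statsmodels, verified against a brute-force step-up oracle).

Significant analytes are clustered on their z-scaled 12-month mean profiles
(months without samples filled by circular linear interpolation and
recorded), using Ward linkage on Euclidean distance — scipy's `ward` on raw
observations, which implements the squared-distance ("ward.D2") criterion.
Cluster enrichment uses the two-sided Fisher exact test per (cluster, term)
over the annotation universe with BH correction across all pairs.

## Co-variation clustering

Analytes (scaled to zero mean, unit variance) are points in sample space.
The shared-nearest-neighbour graph connects two analytes when they share at
least `min_shared` (default 1) of their `k_snn` = 5 nearest neighbours
(exact Euclidean distances, ties broken by input order); `k_nn` = 20 is the
stored neighbour-list length.  The exact edge-threshold convention is not
standardised across implementations, so it is configurable.  Louvain
modularity optimisation (networkx, seeded) yields initial communities;
community mean profiles are then merged by Ward clustering cut at
`n_groups` (default 8).  `SNNCommunityClusterer` packages the two steps as
a scikit-learn estimator.

## mQTL mapping

The GWAS phenotype is the per-subject coefficient from a fixed-effects
regression of each metabolite on subject and visit indicators — the
visit-effect-corrected subject mean.  (The parameterisation is a design
choice; a balanced-design equivalence test pins the interpretation.)
Associations are OLS of adjusted level on dosage with sex, age and baseline
BMI as covariates — baseline BMI because the phenotype is per-subject and
one covariate value is needed.  The scan residualises phenotype and dosages
on the covariates once (Frisch–Waugh–Lovell) and is numerically identical to
per-variant multiple regression (verified to 1e-10 against statsmodels OLS).

The significance threshold is 5e-8 divided by the effective number of
independent metabolites, by default the Li–Ji eigenvalue estimator
sum(I(lambda >= 1) + frac(lambda)) over the metabolite correlation spectrum
(eigenvalues within 1e-8 of an integer are snapped — the Li–Ji step function
is discontinuous there and solver noise would otherwise flip exact-block
spectra); a variance-explained-95% alternative is provided because the
eigendecomposition convention varies across studies.  Independent signals:
greedy pruning by ascending p keeps a variant unless it sits within 1 Mb of
a kept variant with dosage r² > 0.1 (composite LD — squared Pearson
correlation of dosages, appropriate for unphased data); conditional analysis
then refits each non-lead signal with the metabolite's lead dosage as a
covariate, keeping conditional P < 0.01.  Meta-analysis is the
inverse-variance fixed-effect model: weights 1/se², beta the weighted mean,
se 1/sqrt(sum of weights).

## Variance partition

Sequential (Type-I) ANOVA: terms enter in a declared order (defaulting to
genetic → clinical → lifestyle → sex/age → visit), each term's sum of
squares is the R² increment times the total SS (identical to classical
Type-I, verified against statsmodels `anova_lm`), and term SS are pooled
into user-defined components.  Fractions of correlated predictors are
order-dependent; rather than guess a decomposition of shared variance, the
output flags non-orthogonal designs (`order_dependent`) and records the
order used.  Rank-deficient designs raise an error naming the offending
term.

## Protein–metabolite network and Mendelian randomization

The association scan fits, per pair, `metabolite ~ protein + sex + age +
BMI` with crossed random intercepts for subject and visit (single-group
variance-component formulation in MixedLM; if that fit fails the visit
intercept is dropped and flagged, with fixed-effects OLS as last resort).
Slope p-values are t-tests with containment df; BH correction runs over the
full scanned family.

Instruments for a protein are its genome-wide-significant pQTLs
(P < 5e-8), LD-pruned, excluding variants associated with more than five
proteins (a pleiotropy guard; strictly more than five).  Phenotypes are
collapsed to subject level with the same visit-adjusted coefficients as the
GWAS phenotype, because genotypes are subject-level.  The 2SLS estimator is
implemented directly: stage one regresses the exposure on instruments plus
covariates, stage two the outcome on the fitted exposure plus covariates;
the reported variance uses the 2SLS residual (actual exposure), and the
first-stage F statistic flags weak instruments below 10.  For one instrument
the estimate reduces exactly to the covariate-residualised Wald ratio
(tested to 1e-10).

The network integrates LMM-significant pairs as edges, upgraded when the MR
q-value is also significant; edge weight is −log10(q) (metadata only).
Node tiers use unnormalized shortest-path betweenness on the unweighted
graph: Tier 1 above median + 2 MAD, Tier 2 above median + 1 MAD, raw MAD
without the 1.4826 consistency constant (the conventional "median absolute
deviation" reading; a scaled variant is a one-line change).  With MAD = 0
the thresholds collapse onto the median and the strict inequalities still
apply, so a star graph's hub is Tier 1 and its leaves are not.  Scores
within a 1e-9 relative tolerance of a threshold do not cross it — betweenness
values are sums of rational path fractions and different summation orders
otherwise flip exact ties.  Betweenness is verified against a brute-force
path-enumeration oracle on random graphs up to 12 nodes.

## Risk stratification and prediction

The five metabolic-syndrome indicators are sex-centred (subtracting the
sex-specific mean — a regression-residual variant is available) and divided
by the all-samples sd of the centred values, then k-means with k = 2
(50 restarts, seeded) stratifies samples.  The "high" cluster is the one
whose centroid wins a majority vote over indicator directions (HDL
reversed), ties broken by the BMI centroid.  Auxiliary markers are compared
between groups by Welch t or Kruskal–Wallis tests; per-subject label
sequences across visits summarise stability.

The prediction benchmark repeats (default 100×) a grouped 7:3 split —
every subject's samples on one side — standard-scales features on the
training fold, and fits an XGBoost binary classifier with row subsampling
0.5 and `scale_pos_weight` equal to the training negatives/positives ratio
(logistic-regression fallback keeps the benchmark usable without a boosting
backend).  Validation AUCs are summarised by their mean and percentile 95%
interval; ROC curves are averaged on a common 101-point FPR grid.

## Validation benchmarks and problem sizes

All empirical claims in this document are computed by the test suite or
`scripts/acceptance.py`; sizes were chosen once as study-realistic:

- **Seasonal recovery** — 100 replicates of one analyte (100 subjects × 6
  visits, amplitude 0.5, noise sd 0.5): the amplitude estimate falls within
  ±0.1 in ≥ 90 replicates.  **Calibration** — 1,000 null analytes: the joint
  test rejects at 5% within the 3-SE binomial band [0.036, 0.064].
- **mQTL pipeline** — 20 runs of 96 subjects × 200 metabolites × 500
  variants with 3 planted effects (beta 1, MAF ≥ 0.2): ≥ 2/3 recovered with
  ≤ 1 false positive in ≥ 90% of runs.
- **MR** — 100 confounded replicates (theta 0.5, n 500): |mean 2SLS − 0.5|
  < 0.05 while the OLS slope is biased by > 0.15 by construction.
- **Tiers** — 200 random graphs (≤ 12 nodes): tier assignments equal the
  brute-force oracle on every graph.
- **Risk** — stratification agreement ≥ 0.95 at 6-sd separation; the null
  prediction benchmark uses 300 subjects × 2 samples so that the mean AUC
  over 100 repeats concentrates in [0.45, 0.55] (with ~100 subjects the
  finite label draw alone moves the mean by ±0.05); train/validation subject
  sets are disjoint in all repeats.
- The LMM pair-scan calibration uses 500 null pairs with the matching
  binomial band [0.021, 0.079].

## Known limitations

- The crossed-random-intercept scan costs ~0.25 s per pair; genome-scale
  pair families (10⁵+) need chunking or coarser models.
- Containment df slightly differ from Kenward–Roger in very small or very
  unbalanced cohorts; a parametric bootstrap is the safe alternative there.
- MR assumes valid instruments: the pleiotropy guard and the weak-instrument
  flag are heuristics, not guarantees.
- The LD-pruning and conditional-analysis conventions (greedy by p, lead as
  covariate) match standard practice but are not the only defensible ones;
  both thresholds are parameters.
- k-means stratification is pooled across visits by default (per-visit
  stratification is a flag): the pooled reading matches stratifying
  "samples", but longitudinal drift in indicator scales would argue for
  per-visit.
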