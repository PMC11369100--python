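# Methods

This note documents the statistical model, the procedure each module
implements, the default parameters and why they were chosen, and the known
limitations. Notation: the cohort is a table of N subjects × V variables,
with subjects partitioned into three diagnostic groups (control, affective,
non-affective) and variables tagged with a *kind* (continuous, ordinal,
binary, categorical) and a *role* (feature, covariate, clinical, medication,
network_volume).

## 1. Preprocessing (`cogsubtype.preprocess`)

**Filtering.** Variables with role feature or covariate are dropped when
their missingness fraction is strictly greater than `var_thresh = 0.10`;
subjects are then dropped when their missingness fraction *over the retained
feature/covariate variables* is strictly greater than `subj_thresh = 0.20`.
The order matters: removing high-missingness variables first prevents a few
bad variables from knocking out otherwise complete subjects. Clinical,
medication and network-volume columns are never filtered (they are
patient-only by design, so missingness there is structural, not a quality
signal).

**Imputation.** Missing entries are imputed within two strata — controls,
and the pooled patient groups — under the assumption that controls and
patients come from different distributions but that the two patient groups
are close enough to share estimates (and individually too small for stable
stratum statistics). Continuous variables take the stratum mean; ordinal
variables take the stratum mean snapped to the nearest observed level;
binary/categorical variables take the stratum mode, breaking ties toward the
smallest value so the result is deterministic. A fully missing stratum is an
error, not a silent fallback.

**Normalisation.** Continuous variables are z-scored with the population
standard deviation (ddof = 0); ordinal variables are min-max scaled to
[0, 1]; binary variables pass through. Zero-variance columns either raise or
are dropped, by configuration. Population SD is used because normalisation
here is a rescaling of the realised sample, not an inference about a
superpopulation; it also keeps the PCA input exactly unit-variance.

**Volume correction.** Grey-matter network volumes are residualised against
total intracranial volume (TIV), age and sex by ordinary least squares with
an intercept (`numpy.linalg.lstsq`); a rank-deficient design raises. TIV is
stored as a covariate but excluded by name from the PCA input, since it is a
nuisance regressor rather than a cognitive measure.

## 2. Permutation-validated PCA (`cogsubtype.dimred`)

PCA is fit on the normalised features plus covariates with scikit-learn's
full SVD solver. Signs are fixed so the largest-magnitude loading of each
component is positive, making output order- and sign-deterministic.

Component significance is assessed by permutation: each of `n_perm = 5000`
null datasets shuffles every column independently across subjects,
destroying between-variable correlation while preserving marginals. The null
explained-variance ratios are computed per component, and component *k* is
significant when its observed EVR exceeds the empirical (1 − α) quantile of
its own null distribution (α = 0.05). This is a per-component comparison
against a rank-matched null, the standard "parallel-analysis by
permutation" construction; 5000 permutations give ≈ 0.003 Monte-Carlo SE on
a 0.05 tail. For smoke tests a few hundred permutations suffice, and the
code warns below 100.

Feature importance is the variance a feature carries through the retained
subspace, contribution(f) = Σ_{k ∈ sig} evr_k · loading(f, k)²; ties are
broken lexicographically by variable name so rankings are reproducible.

## 3. Fuzzy K-means (`cogsubtype.fuzzycluster`)

Bezdek's fuzzy C-means minimises J(U, C) = Σ_i Σ_j u_ij^m ‖x_j − c_i‖² with
row-stochastic membership U. Updates alternate

- u_ij = 1 / Σ_l (d_ij / d_lj)^{2/(m−1)}, and
- c_i = Σ_j u_ij^m x_j / Σ_j u_ij^m,

until max |ΔU| < `tol = 1e-6` or `max_iter = 300`. When a point coincides
with one or more centres (d² below 1e-300), membership mass is split
equally across those centres — the standard singularity rule. Memberships
are initialised uniformly at random and re-normalised; `n_restarts = 10`
independent starts are run and the lowest final J kept, which in practice
removes initialisation sensitivity at these problem sizes.

Defaults: k = 3 clusters and fuzzifier m = 2. k = 3 encodes the
spared/intermediate/deficit hypothesis and is checked post hoc by an inertia
elbow (`sweep_k`, elbow = largest second difference of hard-assignment
inertia over a k range) and by the partition coefficient
PC = (1/N) Σ u² and partition entropy PE = −(1/N) Σ u ln u. m = 2 is the
conventional middle ground: m → 1 recovers crisp K-means (verified in tests
against scikit-learn at m = 1.05), larger m washes memberships toward
uniform.

Hard labels are argmax memberships; exact ties are reported as `tie_rows`
and resolved toward the lowest cluster index. Cluster composition is
summarised as the group-in-cluster ratio, count(group i in cluster j) /
count(group i), rendered as integer percentages with half-away-from-zero
rounding (so 9.5 % prints as 10 %).

## 4. Group statistics (`cogsubtype.groupstats`)

All test statistics are implemented in the package from first principles;
scipy, statsmodels and pingouin appear only in the test suite as independent
oracles.

**Subject-correlation blocks.** The N × N Pearson correlation matrix of raw
(imputed, unnormalised) profiles is partitioned into group blocks. Between-
and within-group comparisons use a pooled two-sample t-test over the *full
square blocks, diagonal included*, giving df = n_a² + n_b² − 2. This
flattening treats every correlation entry as an observation; the entries are
not independent, so these t-tests are descriptive effect-size summaries, not
calibrated inferences. Within-group homogeneity is each subject's mean
correlation with the other members of their group (self excluded);
homogeneity *variance* is compared between groups with the classic Levene
test (centre = mean), df2 = n_a + n_b − 2, Bonferroni-corrected over pairs.

**Four-group comparisons.** Cognitive variables are compared across pooled
controls plus the three patient clusters with the tie-corrected
Kruskal–Wallis H (χ²_{g−1} reference) and Dunn's z post-hocs using the
tie-corrected pooled variance, Bonferroni over the g(g−1)/2 pairs.
Categorical demographics use the Pearson chi-square of independence.
Continuous post-hocs that must tolerate unequal variances use Welch's ANOVA
with Welch–Satterthwaite df2 = (g² − 1)/(3 Σ …), which yields the fractional
denominator degrees of freedom characteristic of that test.

**Network volumes.** Corrected volumes are analysed in long format with a
two-way ANOVA on the jointly ranked response (group × network). The
interaction F compares the residual sums of squares of the main-effects
model and the full model, both fit by least squares on treatment-coded
dummies. Ranking first makes the test distribution-free in spirit
(an aligned-ranks-style approximation); the F reference is approximate, and
the test is calibrated empirically in the suite (null rejection rate within
a binomial band at α = 0.05 over 200 replicates). Only when the interaction
is significant are per-network Welch post-hocs run, Bonferroni-corrected
over networks.

**Partial correlations.** Partial Pearson correlations between cognition,
clinical scores and network volumes control for chlorpromazine-equivalent
dose by the residual method: both variables are residualised on the
covariates by OLS (with intercept), the residuals correlated, and p obtained
from the t transform with df = n − 2 − k covariates. Degenerate pairs
(zero-variance residuals) return NaN with a flag rather than raising.

**Multiplicity.** `adjust_pvalues` implements Bonferroni, Holm and
Benjamini–Hochberg by hand (verified against statsmodels). The pipeline
default is Holm.

## 5. Synthetic cohort (`cogsubtype.synthetic`)

The generator emulates the *structure the analysis assumes*, not any real
cohort:

- three diagnostic groups, default sizes (56, 52, 118), chosen as a
  realistic control / affective / non-affective split at N = 226;
- three latent cognitive clusters with mean offsets (0, −1, −2) SD applied
  to all features, mixed into the diagnostic groups with group-specific
  proportions (controls mostly spared, non-affective shifted toward
  deficit) so that diagnosis and cluster are correlated but not identical;
- group heterogeneity scaling (1.0, 1.2, 1.5): patient groups are noisier
  than controls, which is what the homogeneity Levene tests look for;
- clinical (PANSS-like) and medication (CPZ-equivalent) scores increasing
  with latent severity, patients only, NaN for controls — structural
  missingness the pipeline must route around;
- 30 network volumes coupled to TIV, with deficit-dependent effects planted
  in a small configurable subset (defaults: networks 17, 28, 29) so the
  ranked-ANOVA post-hoc has a known answer;
- MCAR missingness: a base per-cell rate (5 %) plus a small fraction of
  "flagged" subjects at 20 % to exercise the subject filter.

What it does **not** emulate: item-level test structure, practice or site
effects, non-MCAR missingness mechanisms, longitudinal drift, or realistic
covariance between cognitive domains beyond the single planted cluster
factor. Recovery results on synthetic data therefore validate the
*machinery*, not any empirical claim.

Ground truth (latent cluster, severity) is written alongside the cohort for
recovery scoring and is never read by the pipeline itself.

## 6. Determinism and numerics

A single global seed is expanded with `numpy.random.SeedSequence` into
independent per-stage seeds (masked to < 2³¹), so changing the permutation
count cannot perturb the clustering stage. Reruns with the same
configuration are byte-identical: no timestamps are written and the manifest
records a SHA-256 hash of the configuration. Numerical choices worth noting:
squared distances via `einsum` (no explicit loops), membership singularity
threshold 1e-300 (absolute, since distances are in standardised units),
correlation clipping to [−1, 1] before the t transform, and population-SD
z-scoring as discussed above.

## 7. Open decisions and limitations

- The square-block correlation t-tests inherit the dependence problem noted
  above; they are kept because they are the field's reporting convention,
  but the Levene homogeneity tests on per-subject summaries are the better
  calibrated of the two.
- Permutation PCA tests components marginally against rank-matched nulls;
  it does not protect the joint family of components.
- Fuzzy memberships at m = 2 are intrinsically soft: points between two
  well-separated blobs hold split membership, so pointwise membership
  thresholds near 1 are not meaningful acceptance criteria — central
  tendency of own-cluster membership is.
- The ranked two-way ANOVA is an approximation; its empirical calibration
  is part of the test suite rather than a theoretical guarantee.
- Imputation pools the two patient groups; with larger patient samples a
  three-stratum scheme would be preferable and is a one-line change.
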