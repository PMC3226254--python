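# Methods

`cnvnet` implements a case/control analysis framework for copy-number
signal derived from SNP genotyping arrays: per-SNP Log R Ratio (LRR)
features, a nearest shrunken centroid classifier that both predicts
disease status and selects the relevant SNPs, pairwise logistic epistasis
tests among the selected SNPs, SNP networks with a resampling
significance statistic, GO semantic-similarity gene networks, and
hypergeometric GO enrichment. This note records the models, the defaults
and why, the numerical choices, and what the synthetic test bed does and
does not establish.

## Log R Ratio

For a sample's normalized allele intensities (X, Y) at one SNP, the
polar coordinates are R = X + Y and theta = (2/pi)·arctan(Y/X), so theta
runs from 0 (pure A signal) to 1 (pure B signal). Each SNP carries three
canonical genotype cluster centers (theta, R) for AA, AB and BB; the
expected intensity at a sample's theta is the piecewise-linear
interpolation of R through those three knots, and

    LRR = log2(R_observed / R_expected).

Diploid samples fluctuate around LRR = 0; duplications push LRR up
(one extra copy of a diploid locus gives about log2(1.5) = +0.58),
deletions push it down.

Choices made where the convention is not forced:

* **Theta convention.** The 2/pi-arctan coordinate standard for this
  array family. Any strictly monotone allelic-contrast axis would give
  an equivalent interpolation; this one keeps theta in [0, 1].
* **Clamping, not extrapolation.** Theta outside [theta_AA, theta_BB]
  takes the nearest knot's R. Linear extrapolation can produce negative
  expected intensities for extreme thetas; clamping cannot.
* **Zero intensities are rejected**, not floored: a marker with X + Y = 0
  is a failed assay, and silently flooring it would fabricate an LRR.
  Upstream marker QC is assumed to have removed such probes.

## Nearest shrunken centroid classifier

With n samples, p LRR features and K classes (n_k in class k), the
standardized contrast between class centroid x̄_ik and overall centroid
x̄_i for feature i is

    d_ik = (x̄_ik − x̄_i) / (m_k · (s_i + s0)),

where s_i is the pooled within-class standard deviation (denominator
n − K), m_k = sqrt(1/n_k + 1/n) scales s_i to a standard error of the
contrast, and s0 guards against tiny-variance features dominating.
Soft thresholding by the shrinkage parameter Δ,

    d'_ik = sign(d_ik) · (|d_ik| − Δ)_+,

zeroes weak contrasts; features with d'_ik = 0 for all k leave the model.
Prediction assigns a sample t to the class minimizing

    δ_k(t) = Σ_i (t_i − x̄'_ik)² / (s_i + s0)² − 2·log π_k,

with shrunken centroids x̄'_ik = x̄_i + m_k(s_i + s0)·d'_ik and priors
π_k.

Defaults and rationale:

* **s0** = median of {s_i} (`s0_quantile = 0.5`), the standard choice for
  this estimator family; configurable in [0, 1].
* **m_k variant**: sqrt(1/n_k + 1/n) by default; the sqrt(1/n_k − 1/n)
  variant exists in the literature and is selectable (`mk_variant`).
  The two differ by O(1/n) and never change feature ordering.
* **Priors**: empirical class proportions by default, uniform by flag.
* **Δ grid**: 0 to max|d_ik| of the full-data fit in 30 steps. The upper
  bound is data-adaptive and guarantees the grid ends at the fully
  shrunken (empty, prior-only) model.
* **Δ tuning**: stratified 10-fold cross-validation with seeded fold
  assignment; accuracy is the pooled fraction of correct held-out
  predictions. Among grid points attaining the maximal accuracy the
  *largest* Δ is chosen: on an accuracy plateau the sparsest model wins,
  which matches how a reporting threshold is picked from the top of a
  plateau in practice.
* **Missing cells are rejected at load.** No imputation: marker-level
  filtering is assumed upstream, and silent imputation would leak class
  information through the feature means.
* Prediction ties (exactly equal scores) break toward the lower class
  code; ranking ties keep input feature order (stable sort).

The per-feature contribution score reported in rankings is
max_k |d'_ik|, the largest surviving shrunken offset.

## Pairwise epistasis test

For SNPs with minor-allele dosages A, B ∈ {0, 1, 2} and case indicator
Y, the interaction model is

    logit P(Y = 1) = b0 + b1·A + b2·B + b3·A·B,

fitted by iteratively reweighted least squares (Newton steps on the
log-likelihood; at the canonical link the observed and expected
information coincide). The interaction test is the 1-df Wald chi-square
(b3/SE(b3))² by default — SE from the inverse information at the
optimum — with exp(b3) as the interaction odds ratio (1.0 = no effect).
A likelihood-ratio variant (refit without the product term, 2·Δloglik)
is available by flag; at the sample sizes used here the two agree
closely, and which one the original toolchain applied is not
reconstructible, hence both are provided.

Numerical policy: at most 50 iterations, relative log-likelihood
tolerance 1e-10; a coefficient exceeding 15 in absolute value flags
quasi-separation. Rank-deficient designs (a constant SNP, a product
column collinear with its parents), non-varying outcomes, or
non-convergence mark the pair *degenerate*: no test is produced and the
pair contributes no network edge and is excluded from mean-pairwise-P
numerators and denominators alike.

Dosage is recoded per SNP so it counts the sample minor allele (mean
observed dosage > 1 flips d → 2 − d); this changes b3's sign pattern but
provably not the chi-square. Missing dosages are deleted casewise per
pair, with the complete-case count recorded.

## SNP networks and resampling significance

Pairs with interaction P strictly below a threshold are edges; connected
components with more than one SNP are the SNP networks, ordered by
descending size then smallest member id. A network's coherence statistic
is the arithmetic mean of P over *all* its unordered member pairs (not
just edges). The null distribution draws the same number of SNPs
uniformly without replacement from a pool — by default every SNP in the
tested universe — n_reps = 500 times, computing the same mean each time.
The reported significance is the Gaussian lower tail

    Φ((observed_mean − null_mean) / null_sd),

with null_sd the sample standard deviation (n − 1) of the 500 null
means. The empirical rank p-value (r + 1)/(n_reps + 1) is reported
alongside; the Gaussian figure is the headline for comparability, the
empirical one is the distribution-free check (it cannot go below
1/(n_reps + 1), so extreme Gaussian tails are necessarily
extrapolations). In the published summary tables this implementation
reproduces, the random-network dispersion column is a standard
deviation: plugging it into Φ(z) as an SD reproduces every printed
significance value to better than 0.2% relative, whereas reading it as a
variance is off by orders of magnitude.

## Gene similarity and gene networks

Annotation probabilities are computed per namespace from
ancestor-propagated annotations: p(t) = (genes annotated to t or any
descendant) / (genes with any annotation in t's namespace), giving
p(root) = 1 and information content ic(t) = −ln p(t) non-increasing
toward the root. Term similarity is Schlicker's relevance measure,

    sim(t1, t2) = max over common ancestors c of
                  [2·ic(c) / (ic(t1) + ic(t2))] · (1 − p(c)),

zero when ic(t1) + ic(t2) = 0. The log base is immaterial: it rescales
numerator and denominator of the ic ratio identically (asserted as a
test). Self-similarity is 1 − p(t), so even identical terms score below
1 unless infinitely rare — the measure discounts generic matches.

Gene-level similarity is the best-match average (BMA) over the two
genes' *direct* term sets, computed separately for molecular function
and biological process, then averaged over the namespaces where both
genes are annotated; a pair sharing no namespace is excluded from
networks. BMA is the cited similarity tool's default aggregation; `max`
and `avg` are selectable. How the original analysis merged MF and BP
into one thresholded value is unstated; the arithmetic mean with
fallback to the single available namespace is this package's choice.
Gene networks are components of pairs with similarity strictly greater
than the threshold, singletons dropped, reported as pair and network
counts.

All GAF evidence codes are accepted by default (an exclusion set, e.g.
{"IEA"}, is available), and NOT-qualified annotations are skipped.

## Hypergeometric enrichment

For a term with m annotated genes among t background genes and q
annotated genes among the k in the query (all counts on
ancestor-propagated annotations, "directly or indirectly"),

    P = Σ_{i=q}^{min(m,k)} C(m,i)·C(t−m,k−i) / C(t,k),

computed through the hypergeometric survival function (log-space
stable). Counts are namespace-specific — t and k count genes with at
least one annotation in the term's namespace — which keeps
q ≤ min(m, k) ≤ t by construction. Raw p-values are thresholded by
default (reported cuts in this analysis style are raw); a
Benjamini–Hochberg column is available by flag. Results report the
"q/m|t/k(p)" convention.

## Synthetic cohort generator

The generator is the framework's test bed and emulates, at desk scale,
the data a real cohort provides:

* **Genotypes** drawn per SNP under Hardy–Weinberg at a minor-allele
  frequency sampled uniformly from (0.1, 0.5) by default.
* **Canonical clusters** at theta = 0.05/0.5/0.95 with per-cluster total
  intensity jittered log-normally (sd 0.05) around a common baseline
  R = 2, so the interpolation is exercised with non-flat knots.
* **Intensities**: theta scatters (sd 0.02) around the genotype's
  cluster center; the total intensity is the cluster interpolation at
  the sample's theta times 2^LRR, with LRR drawn N(0, lrr_noise_sd).
  The planted copy-number effect multiplies case intensities at the
  `n_relevant` relevant SNPs by 2^lrr_shift, making the case-minus-
  control mean LRR difference equal `lrr_shift` in expectation (the
  standard conditions used throughout the tests are 100 cases, 100
  controls, 300 SNPs, 10 relevant SNPs, shift 0.3 on noise 0.15 — a
  shift-to-noise ratio of 2, comparable to the per-SNP case/control LRR
  separations such data shows after marker selection).
* **Phenotype**: a logistic model whose linear predictor carries the
  planted interaction terms b3·A·B for each of `n_epistatic_pairs`
  disjoint SNP pairs; the intercept is calibrated by root-finding so
  the expected case fraction matches the request, and a latent
  logistic-utility draw enforces exact group sizes (exact counts keep
  stratified CV folds balanced). With no planted terms this reduces to
  a uniformly random split.
* **Missingness** is off by default; a `missing_rate` knob inserts NA
  dosages for exercising casewise deletion.

Everything is a deterministic function of the seed, byte-for-byte
through the fixture writers.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (features are independent), probe-level normalization artifacts,
GC waves, batch effects, population stratification, or genotype-calling
error. Passing recovery tests on this cohort therefore demonstrates the
estimators' correctness and calibration under their own assumptions,
not performance on a real genome-wide cohort; the real cohorts behind
the published analysis are access-controlled and out of scope.

A companion generator builds a toy ontology (three namespaces, a
two-level DAG with diamond shapes so common-ancestor scans are
non-trivial) and gene annotations, plus a SNP-to-gene map with an
"intergenic" class, so the gene-network and enrichment stages run end to
end on generated data.

## Pipeline conventions

Intergenic selected SNPs stay in the epistasis and SNP-network stages
but leave the gene stage: the gene analysis operates on
{selected SNPs} ∩ {SNPs with a gene mapping}. The SNP→gene map is an
input file, not a live annotation lookup, keeping runs offline and
reproducible. Every stage writes self-describing TSVs plus a JSON
manifest with the seed and per-stage filter counts; reruns with the same
configuration are byte-identical (no timestamps are written).

## Problem sizes

The test suite and the acceptance script run the standard cohort
conditions above (200 samples × 300 SNPs for classification over
10 seeds; 2000 independent pairs at n = 500 for null calibration;
n = 5000 for coefficient recovery; 30-SNP cohorts of 1000 samples with
three planted pairs at log-odds 0.7 for end-to-end interaction
detection; 500 null replicates for network significance). These sizes
were chosen as the smallest at which the stochastic checks are stable,
and they are the package's documented study conditions.

## Known limitations

* The Gaussian network significance assumes approximate normality of
  the null mean; for very small networks (2–3 SNPs) the null is closer
  to the raw P distribution and the empirical rank p is the safer
  figure.
* Gene similarity uses direct (unpropagated) term sets in the BMA, the
  cited tool's convention; propagated-set similarity would differ.
* K-class support is native throughout the classifier, but the
  downstream network stages assume binary phenotypes.
* All-pairs epistasis is intended for the post-selection SNP set
  (tens of SNPs), not genome-wide scans.
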