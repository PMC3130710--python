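# Methods

This note documents the models, the tunable parameters, the simulation
world, and the numerical and design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. iTRAQ quantification model

A multiplexed run labels up to eight samples with isobaric reagents whose
reporter ions (m/z 113, 114, 115, 116, 117, 118, 119, 121) quantify each
channel in every MS/MS spectrum. One channel carries an internal standard
(IS) pooled from equal protein mass of all samples; all ratios are
sample/IS.

**Through-origin regression.** For a protein, each spectrum gives a pair
(x, y) = (IS intensity, sample intensity). If the protein's relative
concentration is b, then E[y] = b·x with zero intercept — no sample signal
without reference signal for a shared peptide. The least-squares slope
constrained through the origin,

    b̂ = Σ x_i y_i / Σ x_i² ,

is therefore the ratio estimate; its implicit x²-weighting concentrates
influence on high-intensity pairs, which have the best counting statistics.
This closed form is asserted against a brute-force oracle on every input in
the tests.

**R² convention (important).** The reported fit quality is the
through-origin (uncentered) definition R² = 1 − SS_res/Σy², clipped to
[0, 1]. A no-intercept fit has no meaningful centered R²; the uncentered
value is NOT comparable to the centered convention and is typically larger.
All R² thresholds below refer to this definition.

**Isotope-impurity correction.** With the column-stochastic convention
observed = C·true (column j of C = where channel j's signal lands), the
correction solves the linear system per spectrum rather than applying a
nominal-purity approximation; negative solutions (measurement noise) are
floored at zero. A singular matrix is a configuration error.

**Outlier trimming.** The original procedure was visual; a pipeline needs a
deterministic rule. Ours: with ≥ 4 pairs, fit, standardize residuals by
their RMS, drop pairs with |z| > 3 (worst first), refit; at most 2 rounds;
never below 3 remaining pairs. Limitation (measured in the tests and the
analysis run): a gross outlier landing on the *highest-intensity* pair
inflates both the slope and the RMS scale, so this rule can miss it. Under
the default simulation's 1% outlier contamination this attenuates the
replicate-concordance slope to ~0.89–0.94; with the outlier process off the
slope is ~0.97 (errors-in-variables attenuation from estimation noise in
the x-axis replicate accounts for the remaining ~3%). The rule is kept
because it is the prescribed contract; a robust-scale (MAD) variant was
evaluated and not adopted.

**Channel bias adjustment.** Reagent channels carry multiplicative biases.
Within each run and channel, the bias factor is the geometric mean of the
slopes of high-confidence proteins (R² > 0.9 AND ≥ 3 unique peptides); all
slopes in the channel are divided by it, making the high-confidence
geometric mean exactly 1.0 (tested to 1e−12) and the operation idempotent.
Geometric rather than arithmetic mean because ratios compose
multiplicatively ("mean fold change = 1" is read in fold-change space); an
arithmetic mode is available (`QuantParams.bias_mean`). A channel with no
high-confidence protein keeps factor 1.0 with a warning. Caveat: the
adjustment also absorbs any genuine average shift of the sample's proteome;
with a small, sign-balanced differential fraction this is a ≲ 2% effect.

**Filtering and compositing.** Estimates are kept iff R² > 0.70 (strict)
AND ≥ 2 unique peptides AND ≥ 4 observations, observations counted per run.
The two technical replicates are composited by geometric mean; if only one
replicate captured the protein, its value is used; replicates disagreeing
by more than `mismatch_log2_threshold` (default 1.0, i.e. 2-fold) are
flagged and excluded downstream. The threshold default is a package choice;
no published value exists.

## 2. Differential analysis

All layers are tested identically on the log2 scale. Strictly positive
linear-scale inputs (metabolite concentrations, protein ratios) are
log2-transformed with a floor at half the smallest positive value
(configurable) to guard sparse zeros.

Per feature: two-group means, pooled variance s² on d = n₁+n₂−2 df (the
two-level one-way ANOVA). The variance prior s² ~ s₀²·d₀/χ²(d₀) has
hyperparameters estimated by the method of moments on log s²: the mean and
variance of log s² are matched to their digamma/trigamma expressions, with
the trigamma inverse found by Newton iteration. If log-variances are
underdispersed relative to chi-square sampling noise the prior degenerates
to d₀ = ∞ with s₀² = mean(s²) (limma uses exp(mean(log s²)) in this branch;
the two agree to first order and the branch only triggers in degenerate
worlds). The posterior variance s̃² = (d₀s₀² + d·s²)/(d₀+d) yields the
moderated t on d + d₀ df (normal when d₀ = ∞). The implementation is
cross-checked against Bioconductor limma::eBayes to ~1e−8 relative on a
shared fixture.

BH step-up is hand-written (stable sort, reverse cumulative minimum,
clipped to [p, 1]) and verified against both a literal step-up enumeration
and statsmodels. Significance threshold: adjusted p < 0.02 (configurable).

Signed fold change: r = 2^(mean_KO − mean_WT), displayed as r if r ≥ 1 else
−1/r, so −10.2 means 10.2-fold lower in the knockout; the transform is an
involution under ratio inversion (property-tested).

**QC screens.** PCA outliers: samples whose score on any of the first k
(default 2) components lies > 3 robust SDs (1.4826·MAD) from the component
median, on centered, feature-standardized data — robust so the outlier
cannot inflate its own yardstick. Contamination: samples whose mean
marker-protein abundance (e.g. hemoglobin subunits) exceeds the cohort mean
by > 3 SD. Flagged samples are listed and excluded from differential
testing when each group retains ≥ 2 samples.

## 3. Enrichment

One-sided over-representation only: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), BH-adjusted within a collection, reported with
sample frequency 100·k/n and background frequency 100·K/N to one decimal.
The tail is computed by scipy's stable implementation and verified against
exhaustive enumeration of all draws for every configuration with N ≤ 12.
Differential features missing from the declared universe are dropped with a
logged count (the background defines the sampling frame), and set members
outside the universe are clipped. The published report's own adjustment
method is unknown, so only the frequency arithmetic — not adjusted
p-values — is expected to reproduce.

## 4. Concordance

Matched by case-insensitive gene symbol (optional identifier→symbol maps);
one-to-many mappings resolved by the largest-|t| representative.
Correlation is computed on signed-log2 transforms l = sign(fc)·log2|fc|,
not on signed fold changes directly: the signed-FC scale has no values in
(−1, 1), and that discontinuity distorts a linear correlation. Both r and
r² are reported, without arbitrating which a reader should quote.

## 5. The simulated world

Defaults are the study design: transcripts 34,273 features × 5 samples per
group with frac_de = 899/34273; proteomics 7 samples per group, 8-channel
runs, two technical replicates with channel assignment rotated between
replicates (making bias and ratio separately identifiable); metabolites 205
features × 9 per group (the source reports both 205 and "up to 210"; 205 is
the default, configurable).

* Peptides per protein: minimum 2, mean 6 (Poisson-shifted); 25% of
  peptides yield a second spectrum. Base intensities lognormal (ln-scale
  mean 9.2, sd 1.0).
* Reporter noise: mean-one multiplicative lognormal with CV 0.2 by default;
  `noise_cv = 0` is exactly noise-free, which the end-to-end identity tests
  exploit.
* The IS channel reads the unweighted mean of per-sample true abundances
  (equal-mass pooling); consequently the expected sample/IS ratio is
  exactly 2^(true log2 ratio) × channel bias.
* Channel bias: per replicate and channel, log-uniform in [1/1.5, 1.5];
  the IS channel's bias is pinned at 1.0 because only bias ratios relative
  to the IS are identifiable.
* Outlier peptides: 1% of sample-channel observations multiplied by a
  log-uniform [3, 10] factor (sample channel only, producing clear
  regression outliers).
* Transcript effects: a differential minority gets log2 effects of
  magnitude U(0.3, 2.5) with random sign — spanning the 1.2–6-fold range
  typical of the study's reported tables; per-feature variances are scaled
  inverse-chi-square (d₀ = 4, s₀² = 0.05) so the EB prior estimator can be
  validated against the generating values. Metabolite effects use
  magnitude U(0.4, 8.0) log2 (up to ~250-fold, matching bile-acid-sized
  surges) with lognormal noise of 0.5 log2 units.
* Gene sets: random sizes in a configured range; planted sets draw half
  their members from the differential pool.

Everything is a pure function of (config, seed) via independent named
RNG streams, so identical inputs are byte-identical outputs.

**What a green test does and does not establish.** The generator emulates
multiplicative noise, channel bias, outlier peptides, replicate structure
and a known differential minority — so passing tests establish estimator
correctness, calibration (FDR, type-I error) and contract compliance under
that world. It does not emulate peptide misidentification, shared/razor
peptides, missing-not-at-random intensities, interference/ratio
compression, correlated biological variability, or probe-level microarray
artifacts; conclusions about robustness to those phenomena are out of
scope.

## 6. Degenerate inputs and tie-breaks

* Pairs with zero on either axis are dropped and counted (a ratio against
  zero is undefined; the pooled IS should never truly be zero).
* Empty pair lists → protein skipped and logged, never an estimate.
* BH ties: stable sort preserves input order; adjusted p clipped to ≤ 1.
* r_squared clipped to [0, 1]; slope > 0 enforced by construction (all
  intensities ≥ 0, at least one positive pair).
* Boundary R² = 0.70 is rejected (strict inequality, per the published
  filter wording).
* Duplicate (protein, sample) estimates within a replicate are an error:
  upstream must have aggregated runs.

## 7. Known limitations

* The automated outlier rule cannot reproduce the original visual curation
  (see §1); gross outliers on top-intensity pairs can slip through.
* Bias adjustment assumes a sign-balanced differential minority; a strongly
  one-sided proteome shift would be partially normalized away.
* The concordance stage matches one representative per symbol; protein
  groups and cross-species mappings are out of scope.
* Enrichment does no ontology-graph propagation; sets are taken as given
  (GMT).
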