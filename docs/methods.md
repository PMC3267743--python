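# Methods

## Data model

A Ct matrix holds cycle-threshold values for gene assays (rows) across
samples (columns). Ct is a log2-scale quantity: each PCR cycle doubles the
template, so a ten-fold dilution of input RNA raises every Ct in that
sample by log2(10) ≈ 3.32 cycles. Reactions that never cross the detection
threshold within the run are **non-determined (ND)**: right-censored at the
cap `ct_max` (default 40 cycles). ND is stored as an explicit missing
marker (NaN), never as the number 40 — "detected" means a *numeric* value
strictly below the threshold, and any method that wants "ND behaves like
the censoring bound" performs that substitution locally and deliberately.
Values read from instrument exports that exceed `ct_max` are converted to
ND at parse time; a stored value exactly equal to a detection threshold
counts as not detected (strict inequality throughout).

## Normalization methods

Sample-level technical variation (input amount, extraction yield, dilution)
is additive on the Ct scale, so the estimand of array-level normalization
is a per-sample constant `t_j`.

**MCR (mean-centering restricted).** The restricted set R is the set of
genes detected in every sample at the configured threshold. Each sample is
centered on `m_j = mean_{i in R} Ct[i,j]`. Since every member of R is
observed in every sample, `m_j` shifts one-for-one under any per-sample
constant, making MCR exactly shift-invariant; censored cells never touch
the estimate. With `recentre=True` (default) the grand mean of the `m_j` is
added back so outputs stay on a Ct-like scale; this is a single global
constant — it cannot affect any SD or variance metric (tested), and the
shift-invariance property is exact with `recentre=False`. If R is empty the
method refuses with advice to raise the threshold (RNA-depleted samples) or
drop outlier samples, rather than silently degrading.

**MC (whole-array mean-centering).** Identical, except the mean runs over
*all* genes with ND cells entering at `ct_max`. Substituting the censoring
bound is the most literal way to let "all miRNAs, including non-determined"
into a mean: the censored cell is known to exceed 40, and 40 is its sharpest
lower bound. The consequence — the mean no longer tracks sample shifts
one-for-one once the censoring fraction varies across samples — is the
documented failure mode that motivates MCR, and the test suite demonstrates
it directly. An available-case mean is available via `nd_as_ct_max=False`.

**Scale (median/MAD).** Per sample: center on the median, divide by the raw
median absolute deviation (no 1.4826 consistency constant), multiply by the
geometric mean of all samples' MADs, and add back the median of the
per-sample medians. After the transform every sample has the same MAD (the
geometric-mean target) and the same median; the recentering constant is
cosmetic, chosen so that a matrix of identical samples passes through
unchanged. A sample with zero MAD is an error naming the sample.

**Quantile.** Classic rank-mean quantile normalization on the numeric
cells. With equal numeric counts per sample the k-th smallest value in each
sample becomes the mean of the k-th smallest values across samples, and
tied input values share the mean of their tied ranks' reference values.
Censoring makes counts unequal; each sample's empirical quantile function
is then linearly interpolated onto a common grid of the maximum count to
form the reference, and mapped back the same way. This keeps the method
total without imputing ND cells; the equal-count case reduces to the
classic algorithm exactly.

**Delta-Ct against chosen genes.** Subtract the per-sample mean Ct of a
normalizer set from all assays. Normalizers must be numeric in every sample
— a reference assay that drops out cannot anchor the samples where it is
missing.

All methods preserve the ND mask exactly: normalization never invents or
removes detections.

## Normalizer selection

**Lin's concordance correlation coefficient.** With n-divisor moments,
`rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)`. The confidence
interval transforms `rho_c` by Fisher's z and uses Lin's (1989) asymptotic
standard error

    Var(z) = [ (1 - r^2) rho^2 / ((1 - rho^2) r^2)
             + 2 rho^3 (1 - rho) u^2 / (r (1 - rho^2)^2)
             - rho^4 u^4 / (2 r^2 (1 - rho^2)^2) ] / (n - 2),

with `u = (x_bar - y_bar)/sqrt(s_x s_y)` and r the Pearson correlation,
then back-transforms. At |rho_c| = 1 (or an undefined Pearson r) the
interval degenerates to a point. Two equal constant vectors are an error
(concordance undefined); one constant vector yields rho_c = 0 with an
undefined Pearson r.

**CCR.** Candidates are the genes fully detected at the CCR threshold
(default Ct < 35 — determinations between 35 and 40 cycles are too noisy to
anchor a reference assay; the threshold is adjustable in both directions).
The target vector is the restricted sample means computed *at the same
threshold*; using one threshold for both candidates and target is the
consistent reading, and a separate `target_threshold` flag exists. Greedy
forward selection re-scores the full remaining candidate set each round
against the running mean of the selected genes. Convergence accepts a new
normalizer only when the concordance gain is at least `epsilon = 0.01` — a
round value inside the interval that reproduces single-normalizer
convergence when the second-best gene adds ≈ 0.006 concordance. With a
fixed `max_normalizers`, epsilon is ignored and exactly that many genes are
taken (the trajectory is then not guaranteed monotone; the non-decreasing
invariant applies to convergence mode).

**geNorm.** The stability of gene j is the mean over partners k of
SD_samples(Ct_k − Ct_j), n−1 divisor — equivalent to the SD of the log2
ratio of relative quantities 2^(−Ct). Because pairwise SDs do not depend on
which genes remain under consideration, the iterative worst-gene exclusion
is computed from a single pairwise SD matrix; each gene's reported M is the
value at its exclusion step, the final pair keeping their values from the
last three-gene stage. Ties are broken in favor of earlier input order. The
pairwise-variation statistic for choosing the number of normalizers is not
implemented; the selection count is fixed by the caller.

**NormFinder.** Ct is already log-scale, so values enter the model
directly. After removing each sample's across-gene mean, for each gene i
and origin group g the intragroup variance is estimated by method of
moments: with k genes, sample variances `s2_ig` of the centered values
satisfy `E[s2_ig] = sigma2_ig (1 - 2/k) + sum_i' sigma2_i'g / k^2`, giving
`sigma2_ig = (s2_ig - T_g/k^2) / (1 - 2/k)` with
`T_g = (k/(k-1)) sum_i s2_ig`, truncated at zero (for k < 3 the raw `s2_ig`
is used). The gene-by-group deviation `d_ig` (group mean of centered values
minus the gene's across-group mean) is shrunk toward zero by
`gamma2 / (gamma2 + sigma2_ig/n_g)`, where `gamma2` is the
across-genes-and-groups variance of the true deviations, itself estimated
by moments and truncated at zero. The stability value is the group average
of `|d_shrunk| + sqrt(shrink * sigma2_ig/n_g)`; lower is more stable. With
a single group (or no annotation) the stability is simply the gene's
cross-sample variance of the sample-mean-centered values, so the
single-group ranking coincides exactly with the variance ranking.

Selectors take raw Ct restricted to fully detected genes; they do not
pre-normalize.

## Evaluation metrics

**Within-group per-gene SD.** For each gene and origin group, the SD (n−1)
of the numeric normalized values across the group's samples; cells with
fewer than two numeric observations are undefined (NaN), excluded from —
not zeroed into — the group summaries. Summaries are the arithmetic mean
over genes, over all genes or over the restricted set. Within an origin
group the samples differ only technically (input level), so this measures
residual technical variance.

**Variance PCA.** The normalized matrix is completed by imputing ND at
`ct_max` (keeping "weakly/not detected" informative rather than dropping
genes), column-centered per gene, and decomposed by SVD with samples as
observations; eigenvalues use the n−1 divisor. For each of the first K
(default 3) score vectors a one-way random-effects model with origin as the
random factor is fitted by the ANOVA method of moments with the
unbalanced-design coefficient `n0 = (N - sum n_g^2/N)/(G-1)`; the origin
fraction is `f = sigma2_origin/(sigma2_origin + sigma2_resid)` with a
negative origin component truncated to zero. The summary is
`100 * sum(lambda_k f_k)/sum(lambda_k)`. Components whose eigenvalue is
numerically null (≤ 1e−12 of the leading one) contribute zero. Method of
moments is the default because it is closed-form and testable against a
hand oracle; a REML variant is available via `use_reml=True`.

## Synthetic titration series

The generator draws `Ct[i,j] = b_i + g_{i,o(j)} + t_j + e_ij`, then censors
values above `ct_max` to ND:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 377 | assays per array |
| `origins` | brain 6, placenta 6, serum 5 levels × 1 replicate | titration design |
| `dilution_factor` | 10 | per-level dilution; Ct step = log2(10) ≈ 3.32 cycles |
| `base_ct_range` | [18, 34] | gene baselines `b_i`, uniform |
| `group_effect_sd` | 1.5 cycles | SD of `g_{i,o}` ~ Normal, per gene × origin |
| `noise_base_sd` | 0.25 cycles | measurement noise below the knee |
| `noise_highct_sd` | 1.0 cycles | noise above the knee |
| `noise_knee` | 35 cycles | pre-noise Ct where noise inflates |
| `ct_max` | 40 | censoring bound |

The titration design mirrors a reference-RNA dilution ladder (e.g. 100 ng
down to 0.005 ng) and a serum volume ladder; baselines spanning 18–34
cycles put a realistic fraction of assays near the censoring bound at high
dilutions, so the fraction of ND calls rises steeply with the sample's mean
Ct — the regime that separates restricted-set from whole-array
normalization. Noise magnitudes are not pinned down by published data;
0.25 cycles reflects good-quality replicate concordance at moderate Ct and
1.0 cycles the well-known unreliability of 35–40 Ct determinations, chosen
once as realistic values. The two-regime step (rather than a continuous
inflation curve) is the simplest shape that exercises the threshold logic;
the knee applies to the pre-noise expected Ct. Dilution maps to Ct with
perfect PCR efficiency; censoring is applied after noise, so genes near the
bound are partially detected — the case that distinguishes MCR from MC.
Planted normalizer genes receive zero origin effect and noise SD 0.01,
giving simulations a known ideal reference assay. `simulate_flat` produces
an uncensored i.i.d. matrix (e.g. 500 × 20) for scaling smoke tests.

What the simulator does *not* emulate: amplification-efficiency variation,
preamplification bias, inter-plate batch effects, correlated miRNA
co-regulation, or heavy-tailed noise. Tests passing on these simulations
therefore certify the algorithms' contracts (shift invariance, censoring
robustness, recovery of planted structure), not performance on any
particular real dataset.

## Problem sizes and numerics

The test suite and the acceptance script run at the study scale of 377
genes × 17 samples (20 replicates where replicate noise matters) and 20
planted-normalizer recovery runs; the whole benchmark takes seconds. The
CCR benchmark uses a single-origin, five-level series: with the full
three-origin design the censoring at the default baselines leaves no gene
fully detected at Ct < 35 — exactly the situation in which the detection
threshold should be raised — and the single-biofluid series is the
migration use case CCR is for.

Exact-equality contracts (restricted-set membership, quantile sorted-value
identity) are tested exactly; algebraic identities at 1e−9; oracle
agreement for concordance moments at 1e−12. Ties: quantile ties share mean
reference values; geNorm and NormFinder ties resolve by input gene order;
geNorm's tied exclusion drops the later gene so earlier input order ranks
first. Degenerate inputs (constant samples in MAD scaling, equal-constant
vectors in concordance, empty restricted sets, singleton groups) raise
typed errors naming the offender instead of returning NaN.

## Known limitations

- MC's treatment of censored cells in the original benchmark is not
  publicly specified; both plausible choices (cap substitution, available
  case) are implemented, and the evaluation metrics are invariant to the
  grand-mean recentering either way.
- The greedy CCR step re-scores all candidates each round; a rank-once
  variant would be faster on very large candidate sets but can diverge from
  the greedy optimum.
- NormFinder's Bayesian/common-variance variant is not implemented; the
  method-of-moments variant is, with its formulas pinned by oracle tests.
- The variance-PCA weighting follows the stated construction (eigenvalue
  weights over the first three PCs, univariate random-effects fits); other
  published variance-component PCA schemes differ in detail.
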