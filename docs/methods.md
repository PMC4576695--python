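# Methods

## Signal model

A 4C library reports, for one viewpoint, the ligation frequency of every
restriction fragment in the genome. The observed count k_ij for
fragment i in sample j is modelled as negative binomial with mean
s_j · μ(d_i) and dispersion α(μ) = a/μ + b, where d_i is the genomic
distance between the midpoints of fragment i and the viewpoint
fragment, s_j a library size factor, and μ(d) a smooth monotone
non-increasing function that flattens into a constant background far
from the viewpoint. Specific interactions are multiplicative
departures from μ(d); nothing in the inference assumes a parametric
form for the decay.

Distances are signed (negative left of the viewpoint); fragments on
other chromosomes ("trans") have no distance and are treated as
background. Coordinates are 0-based half-open throughout; BED exports
are 0-based half-open.

## Fragment reference and counting

The genome is cut in silico at every occurrence of the first enzyme's
recognition sequence on either strand (forward occurrence at p cuts at
p + cut_offset, reverse-complement occurrence at the mirrored offset;
identical for the palindromic 4-cutters typical of 4C). Overlapping
occurrences all count; N never matches. Terminal chromosome intervals
are kept as fragments; empty intervals are dropped. A fragment is
valid if it contains a second-enzyme site and at least one fragment
end (boundary to nearest interior second-enzyme cut) is ≥ 20 nt — one
short end does not invalidate a fragment whose other end passes.

Read counting keys each alignment on its 5′ terminus (alignment start
for + reads, half-open end for − reads) and strand. Under a
first-cutter sequencing primer, the left end accepts + reads starting
at the fragment start and the right end − reads ending at the fragment
end (both point inward); under a second-cutter primer the anchors are
the innermost second-enzyme cut coordinates with the opposite
orientations (reads point outward). The two ends are summed per
fragment. `slack` (default 0, i.e. the strict "starts directly at the
cut site" rule) widens the accepted window by ±slack nt for aligners
that shift soft-clipped termini. Secondary/supplementary/duplicate
records are skipped; every processed record is accounted for in the QC
tally (assigned to valid / assigned to invalid / rejected by reason),
and the fraction of aligned reads on valid fragments is reported
(warning below 0.5; healthy libraries sit around 0.7–0.95).

## Variance-stabilizing transformation

Size factors are median-of-ratios over fragments with all-positive
counts, rescaled to unit geometric mean (fallback: total-count ratios).
The dispersion trend α(μ) = a/μ + b is fitted to unclipped
method-of-moments dispersions (var − μ)/μ² of size-factor-normalized
counts by iteratively reweighted least squares on the design (1/μ, 1):
weights are inverse-variance (the sampling SD of a moment dispersion
estimate scales with the squared total CV, (1+a)/μ + α), and points
with |standardized residual| > 4 are excluded each iteration (≤ 10
iterations, tolerance 1e-6 on (a, b)). Two deliberate choices here:

* the moment estimates are **not** clipped at zero before fitting —
  clipping biases the intercept up by ~0.2 at the Poisson boundary,
  where half the per-fragment estimates are negative by sampling noise;
* outliers are excluded by a fixed standardized-residual threshold
  rather than by trimming a fixed quantile — the sampling noise of a
  variance estimate from few replicates is strongly right-skewed
  (χ²-like with n−1 degrees of freedom), so symmetric quantile trimming
  systematically biases the trend low by 25–30%, while a 4-SD threshold
  rejects genuine signal spikes and little else.

Measured recovery on 2000-fragment, 4-sample simulations with
α(μ) = 3/μ + 0.05: a within ~10%, b within ~5%, robust to 1% spiked
fragments; Poisson data drives b to its 1e-8 floor. Fit parameters are
clamped to a ≥ 0, b ≥ 1e-8.

With q = k/s_j the transform is

    v(k) = log2( (1 + a + 2bq + 2·sqrt(bq(1 + a + bq))) / (4b) ),

the antiderivative of 1/sqrt(Var(μ)) for Var(μ) = (1+a)μ + bμ², scaled
to be log2-like at large counts: v(2q) − v(q) → 1 and SD(v(K)) →
√b/ln 2 for all μ (delta method). v is strictly increasing, finite at
k = 0 (v(0) = log2((1+a)/4b)), and inverts algebraically:
q = (y − 1 − a)²/(4by) with y = 4b·2^v; round-trip error is at machine
precision. VST parameters are fitted per viewpoint on the fragments
that survive the count filter and the viewpoint mask.

## Decay fit

Per sample, v(k_ij) is regressed on x = log10|d_i| with a monotone
non-increasing smooth: f(x) = β₀ + Σ c_m I_m(x), c_m ≤ 0, where the
I_m are I-spline basis functions built as reversed cumulative sums of a
clamped cubic B-spline basis with interior knots at the deciles of x.
Coefficients solve a bounded least-squares problem with a
second-difference roughness penalty λ (default 1.0) on the spline
coefficients; the penalty is scaled by √n so that the data/penalty
balance is independent of the number of fragments (this also makes a
symmetric fit on mirrored data coincide exactly with the per-side
fits). Outside the fitted range the curve extrapolates as a constant;
the value at the largest fitted distance is the plateau used for trans
fragments. Symmetric mode pools both sides on |d| (so f(d) = f(−d)
exactly); per-side mode fits left and right independently and falls
back to symmetric with a warning when a side has fewer than 30
fragments.

## Interaction calling

Fragments with median count across samples below 40 are removed first.
The viewpoint-proximal zone is then masked: walking outward from the
viewpoint over the kept fragments (using the mean size-factor-normalized
count as the signal — the rule only compares neighbours, so any
monotone transform gives the same mask), the zone ends just before the
first fragment whose signal increases relative to its inward
neighbour; the viewpoint fragment is always masked and a cap of 20
fragments per side bounds the zone.

For the tested fragments, σ_j = 1.4826 · MAD of the residuals
r_ij = v(k_ij) − f_j(d_i) (MAD centred at the residual median; the
1.4826 factor makes σ consistent for normal residuals so that the
z → P conversion is calibrated), z_ij = r_ij/σ_j, one-sided
p_ij = 1 − Φ(z_ij), and Benjamini–Hochberg adjustment per sample over
the tested family of that viewpoint. The default call requires
z > 3 in all replicates of a condition and adjusted P < 0.01 in at
least one; with a single replicate the rule degenerates to that sample
(warned).

## Differential testing

Normalization factors n_ij = v⁻¹(f_j(d_i)), rescaled per fragment to
unit geometric mean across samples, carry both library size and each
sample's distance trend into the GLM as multiplicative offsets; the
renormalization makes the factors exactly invariant to a common
rescaling of all samples (the absolute scale of v⁻¹ is arbitrary).
Trans fragments use the per-sample plateau.

Per-fragment NB dispersions are estimated by profiling the condition
means and maximizing the Cox–Reid-adjusted likelihood (the adjustment
−½ log det XᵀWX removes the (J−p)/J downward bias of the plug-in
profile MLE, which would otherwise inflate the Wald test) on a
120-point log-spaced grid over [1e-8, 30] with parabolic refinement.
The trend a/μ̄ + b is fitted to the MLEs with the same robust IRLS as
the VST, and the final estimate is the mode of the likelihood times a
log-normal prior centred on the trend, with prior variance
max(MAD²-spread of log MLEs around the trend − trigamma((J−p)/2),
0.25²).

The Wald test fits μ_ij = exp(x_jᵀβ)·n_ij per fragment with design
[intercept, condition indicator] by Fisher-scoring IRLS (tolerance
1e-8, ≤ 100 iterations, batched across fragments); standard errors come
from the expected information (marginally smaller than observed-
information SEs for NB models), the statistic is β̂/SE with two-sided
normal P-values, BH-adjusted across the tested fragments of the
viewpoint. Non-converged fragments are flagged with NA P-values; no
fold-change shrinkage is applied. Fragments significant in the Wald
test are additionally labelled by whether they are also called as an
interaction. Measured on 2000-fragment 3-vs-3 simulations: null
fraction with p < 0.01 ≈ 0.02; mean estimated log2 fold change at
planted 4-fold changes ≈ 1.9 (the small shortfall arises because
planted changes lift that condition's fitted trend slightly, and the
normalization absorbs background-level changes by construction).

## Synthetic data generator

The generator defines the package's study conditions:

* mean model μ_ij = s_j (A·(|d_i|/1 kb)^−γ + B)·2^(spike_i + diff_ic(j))
  with defaults A = 5000 (the mean at 1 kb), γ = 1.2, B = 20; |d| is
  clamped at 0.5 kb so the viewpoint fragment gets a finite, very large
  mean; trans fragments sit at s_j·B;
* NB dispersion α(μ) = a/μ + b with defaults (3, 0.05); (0, 0) gives
  Poisson counts;
* size factors drawn log-uniform in [2^−0.5, 2^0.5] per simulation and
  normalized to unit geometric mean, unless supplied;
* toy fragments ~1 kb (jittered), 2000 cis fragments by default —
  under the median-40 filter the tested family is the ~200 fragments
  within ~100 kb of the viewpoint, which is what a single-viewpoint 4C
  analysis typically resolves;
* spikes and differential effects are log2-additive on the mean,
  matching the GLM parameterization; an 8-fold spike (3 log2 units)
  corresponds to ≥ 6 residual SDs on the transformed scale at any
  tested fragment;
* planted genomes are generated site-free by rejection scrubbing, with
  first-cutter sites at jittered spacing and one second-cutter site per
  fragment ≥ 25 nt from both boundaries, so every fragment is valid;
  alignment records carry exact 5′ termini and strands, so counting
  reproduces the simulated matrix exactly, and decoy records are
  rejection-sampled away from every legal anchor so they are rejected
  exactly.

What the generator does **not** emulate: mappability and GC biases,
PCR duplicates, sequencing errors, fragment-length effects, and
domain-level structure in the decay. Passing tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to these artefacts.

## Numerical choices and degenerate inputs

* lsq_linear (bounded least squares) with tolerance 1e-12 for the
  monotone fit; constant data fit exactly as the mean; strictly
  increasing data project to the constant mean.
* z-scores error on a degenerate (zero) residual scale unless a
  configured σ-floor is set.
* Dispersion grids are clamped to [1e-8, 30]; GLM means floored at
  1e-10 and linear predictors clipped at ±50 to survive separation
  (all-zero conditions), which is reported as a large fold change with
  a wide SE.
* All randomness flows through numpy Generators seeded explicitly;
  identical seeds give byte-identical outputs.

## Known limitations

* The z-score null is only approximately normal. The one-sided upper
  tail (which drives calling) is well calibrated, but the lower tail
  of VST-transformed NB counts is left-skewed, and fragments near the
  count-filter threshold are upward-selected — the trend fitted on
  them over-estimates the true decay beyond the distance where it
  crosses the filter floor, producing occasional z ≈ −4 residuals.
  Neither effect creates false positive calls (measured empirical FDR
  on nulls: 0 at the default rule), but two-sided use of the z-scores
  is discouraged.
* BH families are per sample within a viewpoint (calling) and per
  viewpoint (Wald); multi-viewpoint experiments that require
  genome-wide FDR control should pool P-values externally.
* Trans-chromosomal fragments are z-scored against the fitted plateau;
  with the default simulation conditions they rarely pass the count
  filter, so this path is exercised mainly by unit tests.
* Single-factor designs only (condition, optionally with replicates);
  no multi-factor ANOVA, no outlier refitting, no fold-change
  shrinkage.
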