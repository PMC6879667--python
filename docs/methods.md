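# Methods

## Setting

L tests of distinct hypotheses produce P-values P_1,…,P_L; the global null
says all are uniform (and, for the decorrelation module, that the
underlying statistics are jointly multivariate normal). The package
combines the *top-ranking* P-values into a single gene- or pathway-level
P-value. Truncation matters when real signals are expected to be few:
summing all L transformed P-values (Fisher) dilutes a handful of real
effects with noise, while the product of the k smallest order statistics
concentrates on the candidates.

## RTP: the rank truncated product

Statistic: W_k = Π_{i=1..k} P_(i), carried as −ln W_k (a sum of logs, so
products down to the underflow limit are safe). Ordered P-values are
dependent even after shuffling — the (k+1)-th order statistic confines the
k below it — but *conditionally* on P_(k+1) = t they are iid uniform on
(0, t). Hence −ln(W_k / t^k) | t ~ Gamma(k, 1) and, integrating t out
against its Beta(k+1, L−k) null law (substituting u for its CDF),

    Pr(W_k ≤ w) = 1 − ∫₀¹ G_k( ln( B⁻¹_{k+1,L−k}(u)^k / w ) ) du .

Special cases: k = L is Fisher's test (chi-square with 2L df at −2 ln w);
k = 1 is the Šidák minimum-P closed form 1 − (1 − P_(1))^L. The same
conditioning integral with exponent k+1 evaluates Pr(W_{k+1} ≤ w)
(`rtp_pvalue_next`) without re-deriving anything.

Numerics. The scalar path integrates the *survival* form
∫ Q_k(·) du (Q_k = Gamma(k,1) survival) adaptively with a breakpoint at
the kink where the gamma argument crosses zero; integrating Q rather than
1 − G keeps absolute accuracy when the combined P-value is tiny. The batch
path (`rtp_pvalue_batch`) shares fixed Gauss–Legendre nodes (default 512)
across all replicates: beta quantiles are computed once per (k, L) and the
only per-replicate cost is a vectorized `gammaincc`. Agreement between the
two paths is tested to 1e−6; the endpoints are clamped to [1e−12, 1−1e−12].

A second, independent evaluation of the same CDF (`rtp_pvalue_legacy`)
conditions on P_(k+1) directly in t-space and collapses the Poisson tail
sum into the gamma survival function, leaving a positive-integrand
one-dimensional integral evaluated in log space. Expanded term by term
through the alternating binomial coefficients — the classical presentation
of this distribution — the same expression cancels catastrophically for
moderate k, which is the historical motivation for the single-integral
form above; the reorganized evaluation stays accurate for k < L ≤ 200 and
serves as a cross-check oracle in the tests, verified against brute-force
Monte-Carlo (10⁷ sorted-uniform draws) at two (k, L, w) points.

## ART: augmented rank truncation

Conditionally on P_(k) the k−1 smallest P-values are iid uniform on
(0, P_(k)), so Σ_{i<k} −ln(P_(i)/P_(k)) = −ln W_{k−1} + (k−1) ln P_(k) is
exactly Gamma(k−1, 1) and independent of P_(k). P_(k) itself is
Beta(k, L−k+1); pushing it through its CDF and the Gamma(λ,1) quantile
yields a third independent gamma term, giving

    A_k = −ln W_{k−1} + (k−1) ln P_(k) + G⁻¹_λ(1 − B_k(P_(k)))
        ~ Gamma(k−1+λ, 1)   exactly under H₀,

with λ = (k−1)(ψ(L+1) − ψ(k)) chosen so the two P_(k) transforms share the
same expectation — a Lancaster-style weight: λ grows when P_(k) is more
informative (small k relative to L). The combined P-value is the gamma
upper tail at the observed a_k. The null law is exact, not asymptotic; the
tests verify it by Kolmogorov–Smirnov on 50,000 simulated replicates at
(k, L) = (2,5), (5,20), (10,100).

Edge cases: k = 1 degenerates (λ = 0); it is routed to the Šidák
minimum-P form, the k = 1 limit of RTP. 1 − B_k(P_(k)) is evaluated
through the inverse *survival* function `gammainccinv(λ, B_k)` so no
precision is lost when P_(k) is small. Ties among P-values need no special
handling — the product form is order-invariant.

## Adaptive truncation

Fixing k is arbitrary, so both adaptive methods scan a candidate set
(default 1..k_max), take m = min_k p_k of the per-k combined P-values, and
return Pr(min_k P_k ≤ m | H₀) — never smaller than m itself.

**ART-A.** The per-k ART P-values are computed exactly, so each normal
score z_k = Φ⁻¹(1 − p_k) is exactly standard normal; only the joint law
across candidates needs a reference. The candidate profile is a
deterministic function of the k_max smallest order statistics, and the
exponential-spacings representation of uniform order statistics
(P_(k) = P_(k+1) · V^(1/k), V uniform; P_(k_max) ~ Beta) simulates that
head in k_max dimensions *regardless of L* — the expensive B×L matrix of
the empirical method is never formed. The min-P reference is a cached,
fixed-seed sample (default 500,000 draws) of the exact profile maximum. A
multivariate-normal surrogate for the profile was evaluated during design:
fitting a Gaussian copula to the profile correlations (which
`partial_sum_model` still reports) understates the tail of max_k z_k —
the exact profile has weaker tail dependence than any Gaussian copula with
the same correlations — and inflates the far-tail type-I error beyond
Monte-Carlo error, so the exact-profile reference is used instead. The
adjustment is a binary search in the sorted reference (O(log n) per
dataset), floored at m, with the (r+1)/(n+1) estimator.

**Empirical aRTP.** The single-layer shortcut: one B×k_max matrix of null
partial sums (generated by the same head sampler), per-k P-values of the
observed data by rank against the matrix rows, per-k P-values of each null
row by descending midrank within its column, and the observed min-over-k
ranked against the null rows' minima, again with (r+1)/(B+1). A memory
guard refuses matrices beyond 2×10⁸ entries and suggests lowering B.

## Decorrelation (DOT) and LD reconstruction

If the statistics behind the P-values are y ~ MVN(0, Σ) under H₀, the
symmetric inverse root H = QΛ^(−1/2)Qᵀ of Σ = QΛQᵀ gives y_e = Hᵀy with
identity covariance; P-values are decorrelated as p → z = Φ⁻¹(1−p) →
1 − Φ(Hᵀz). The symmetric root is chosen for its order-invariance: in the
equicorrelation case a permutation of the inputs permutes the outputs.
The default convention is one-sided (the transform needs signed scores;
two-sided inputs lose the sign, so a `two_sided` back-transform squaring
y_e against chi-square(1) is provided but signed z-scores via
`decorrelate_zscores` are preferred). Eigenvalues below 1e−10 of the
largest are floored with a warning (LD matrices rebuilt from haplotype
frequencies are routinely near-singular); `strict=True` raises instead.
Σ is treated as known; propagating the uncertainty of an estimated Σ is
out of scope.

LD correlations from haplotype frequencies: p_i sums the frequencies of
haplotypes carrying the minor allele at locus i, P_ij those carrying both,
D_ij = P_ij − p_i p_j, r_ij = D_ij/√(p_i(1−p_i)p_j(1−p_j)). Monomorphic
loci raise an error naming the locus.

## Simulation harness

Replicate i of a design draws z ~ MVN(μ, Σ) from the counter-based stream
`default_rng([seed, tag, i])`, so any cell is reproducible in isolation.
P-values are two-sided, 2(1 − Φ(|z|)), by default — the convention under
which the constant-effect power grid reproduces — with a one-sided switch.
Effect models: null; constant μ; μ_i ~ U(lo, hi) redrawn per test per
replicate; sparse (a fixed rounded fraction of tests at a common μ, so a
zero fraction is bit-identical to the null stream). Correlation models:
identity; equicorrelation; random factor structure Σ ∝ WWᵀ + δI (W an
L×2 standard-normal loading matrix) rescaled to unit diagonal, with δ
bisected so the realized mean |ρ| off the diagonal hits the requested
target exactly for the returned draw.

Under a correlated design each method runs either as a *resampling*
comparator (the observed statistic ranked against MVN(0, Σ) null draws —
the surrogate for phenotype reshuffling with LD intact) or *decorrelated*
(DOT first, then the analytic combiner). Simes is applied unadjusted, as
a benchmark. `reproduce_table` re-estimates the published grids T1–T7 at
a chosen fraction of the original 100,000 replicates, reports binomial
standard errors, compares against the embedded reference values with a
3-combined-s.e. flag, and refuses scales so small that the standard error
would exceed 0.05.

Problem sizes in the shipped tests and acceptance script — chosen as the
package's own desk-scale defaults — are 20,000–50,000 replicates for null
calibration and 10,000–20,000 for power, which put Monte-Carlo standard
errors at 0.0005–0.005 depending on the level.

## What the generator does and does not emulate

The generator produces exchangeable normal statistics with exact control
of means and correlations. It does not emulate genotype data, estimation
noise in Σ, non-normal test statistics, or LD estimated from finite
reference panels — so passing calibration here demonstrates correctness of
the combining distributions, not robustness to misspecified Σ.

## Known limitations and open points

* **Random-effect power column.** Under the documented reading of the
  random-effects design (μ_i ~ U(0.05, 0.45) iid per test per replicate,
  two-sided), the harness reproduces every constant-effect power cell but
  estimates ~0.17 for the ART cell at (k=10, L=500) where the reference
  grid lists 0.43 — the reference column behaves like a *constant* effect
  of ≈0.4 and is not recoverable from its stated description (the original
  generator's details were not published in the main text). The harness
  keeps the stated reading; the corresponding acceptance check is expected
  to flag.
* One reference table mixes two stated effect sizes for the sparse design
  (1.4 in its caption, 0.5 in the text); the harness uses the caption
  value and that table is not a calibration surface.
* The second column block of the power tables is labeled k = 10 in print
  but corresponds to k = 100; the harness uses k = 100 there.
* The legacy RTP closed form is validated for k < L ≤ 200 and refuses
  beyond; the single-integral form is the production path at all sizes.
* ART-A's reference is exact in distribution but Monte-Carlo in nature;
  adjusted P-values below ~1/n_ref saturate at the (r+1)/(n+1) floor.
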