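# Methods

## Model

Phenotypes follow the linear mixed sparse-effects model

    y = X beta + W b + e,    e ~ N(0, sigma_e^2 I_n),

where `W` (n samples x N SNPs) is the standardized genotype matrix: raw
minor-allele counts x in {0,1,2} are mean-imputed (missing -> 2p) and
transformed column-wise to (x - 2p) / sqrt(2p(1-p)), with p the empirical
allele frequency of that SNP. The Hardy-Weinberg denominator 2p(1-p) is the
default (it matches the scaling used in the genomic-relationship
definition below); the observed column s.d. is available via
`standardize_genotypes(..., denominator="empirical")` and agrees
asymptotically under HWE.

Each SNP effect is spike-and-slab:

    b_j | I_j = 1 ~ N(0, sigma_b^2),     b_j | I_j = 0 = 0,
    I_j ~ Bernoulli(p) independently.

Hyperpriors: p ~ Beta(1,1); sigma_b^2 and sigma_e^2 ~ InvGamma(0.001,
0.001); independent N(0, sigma_a^2) on each fixed effect with sigma_a =
1e5 (we read sigma_a as the prior *standard deviation*; with 1e10 prior
variance the distinction is immaterial). An alternative continuous spike
N(0, sigma^2) with sigma = 0.01 replaces the point mass when
`HBMPriors(spike_sd=0.01)` is set; it exists for continuity experiments
and matches the point mass to PIP differences < 0.05 on test fixtures.

The genomic relationship matrix is A = W W'/N, equivalently A_jk =
(1/N) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i)) on mean-imputed
data. Allele frequencies are recomputed after every sample filter, since
they shift as individuals are removed.

Heritability is reported as PVE = sigma_g^2 / (sigma_g^2 + sigma_e^2).
For the spike-and-slab model sigma_g^2(t) = sigma_b^2(t) * k(t) per
retained draw t (k = number of active SNPs), the "slab-count" convention
under which standardized, weakly correlated SNPs each contribute
sigma_b^2 of variance; an empirical alternative sigma_g^2(t) =
Var(W b(t)) is exposed (`pve(method="empirical")`). For the mixed model,
PVE = sigma_g^2/(sigma_g^2 + sigma_e^2) at the REML optimum with a
delta-method standard error from the average-information matrix.

## Gibbs sampler

One sweep updates, in order: (I_j, b_j) for each SNP; beta; sigma_b^2 and
sigma_e^2; p. The indicator update is collapsed: with the partial residual
r_j (full residual with SNP j's contribution added back), s_j = w_j'w_j
and m_j = w_j'r_j,

    v1 = (s_j/sigma_e^2 + 1/sigma_b^2)^-1,   mu1 = v1 m_j / sigma_e^2,
    log BF_j = 0.5 log(v1/sigma_b^2) + mu1^2 / (2 v1),
    Pr(I_j=1 | rest) = logistic( log(p/(1-p)) + log BF_j ),

then b_j | I_j=1 ~ N(mu1, v1), else b_j = 0 (or the analogous spike
conditional when spike_sd > 0). All density ratios are computed in log
space. Because inactive SNPs contribute nothing, the per-sweep cost is
O(nN) independent of sparsity, which is the property that lets the sampler
reach ~1e5 SNPs. The remaining conditionals are standard conjugate forms:

    beta  ~ N( Q^-1 X'(y - Wb)/sigma_e^2, Q^-1 ),  Q = X'X/sigma_e^2 + I/sigma_a^2
    sigma_b^2 ~ IG(a1 + k/2, b1 + sum_active b_j^2 / 2)
    sigma_e^2 ~ IG(a2 + n/2, b2 + ||y - Xb - Wb||^2 / 2)
    p ~ Beta(1 + k, 1 + N - k).

When k = 0, sigma_b^2 is drawn from its prior (documented fallback; the
draw is clamped against gamma underflow). An optional joint redraw of the
active block (`ChainConfig(block_refresh=True)`, numpy engine) samples all
active effects from their multivariate normal conditional; when the active
set is wider than the sample count it uses the exact Woodbury/Matheron
construction so the only factorization has rank min(n, k).

Chain defaults follow the 5,000 burn-in / 2,000 retained schedule; the
desk-scale studies below use 2,000/1,000, which trace inspection shows is
ample at those sizes (the sampler activates true signals within the first
few sweeps). Initialization: I = 0, b = 0, beta = OLS on X alone,
sigma_e^2 = Var(y)/2, sigma_b^2 = 0.1, and p = 0.01 rather than the prior
mean 0.5 — GWAS-realistic sparsity shortens burn-in and the sampler is
ergodic regardless of the start. SNP scan order is sequential by default
(reproducibility); `scan_order="random"` is available.

Two engines implement the identical sweep law: a pure-numpy reference
assembled from the exposed full-conditional operations, and a numba kernel
(default) roughly two orders of magnitude faster. They consume different
RNG streams, so they agree in distribution — both are checked against the
exact 2^N enumeration posterior — while each is bit-reproducible for a
fixed seed. The residual cache is refreshed from its definition every 100
sweeps to stop floating-point drift (verified < 1e-8 in tests).

## Mixed-model baseline

The p = 1 special case is fit as y ~ N(X beta, A sigma_g^2 + I sigma_e^2)
by restricted maximum likelihood: average-information updates with an EM
fallback step whenever the AI step leaves the parameter space or would
decrease the restricted likelihood (the EM step guarantees ascent), and
variances clamped at a 1e-8 * Var(y) boundary. This is a from-scratch
implementation; its contract is agreement with the restricted-likelihood
optimum, verified against a dense grid search. The per-SNP variance is
reported as sigma_g^2 / N and per-SNP effects as the BLUP
b_hat = (sigma_g^2/N) W' V^-1 (y - X beta_hat).

## Quality control

Defaults mirror standard GWAS practice: samples with >= 5% missing
genotypes removed; SNPs with call rate <= 0.99 or MAF <= 0.01 removed
(all inclusive on the removal side); then greedy relatedness pruning —
while any pair's relationship exceeds 0.025, delete from the worst pair
the member with more above-threshold partners (ties: the smaller index).
The greedy degree rule keeps more samples than arbitrary pair deletion and
is deterministic; the survivor set is verified pair-clean by brute force
in tests. Missing genotypes are mean-imputed (to 2p) throughout; this is
the field's default and keeps W complete, but it shrinks real signal when
missingness is informative.

## Simulator

`simulate_dataset` draws, per SNP, a MAF ~ U(0.05, 0.5) and genotype
counts Binomial(2, MAF) i.i.d. across individuals — Hardy-Weinberg and
linkage equilibrium. Effects: exactly round(pN) SNPs (uniformly chosen)
get slab effects N(0, sigma_b^2); the rest are exactly zero (Case 1) or
N(0, 0.01^2) "noisy" effects (Case 2, applied to *all* non-associative
SNPs). The residual variance is calibrated from the realized slab genetic
values, sigma_e^2 = Var(W_slab b_slab) (1-PVE)/PVE, so the nominal PVE
refers to the point-mass model's genetic variance (sigma_b^2 x slab
count). In Case 2 the spike effects are deliberately *excess* signal on
top of that calibration: the all-causal mixed model absorbs them into
sigma_g^2 and overshoots, which is the phenomenon under study. Exact
signal counts (not Bernoulli thinning) keep truth manifests reproducible;
all randomness flows through one generator per dataset seed.

What the generator does **not** emulate: linkage disequilibrium (an AR(1)
allele-coupling mode exists for robustness probes but is no substitute for
real haplotype structure), population stratification or relatedness,
MAF-dependent effect-size architecture, and non-Gaussian phenotypes.
Passing tests therefore certify the estimation machinery under the
model's own assumptions plus HWE genotypes; they do not certify behavior
under real LD or structure.

## Study designs used by the test suite

Desk-scale stand-ins for the full-size simulation studies (the original
genotype panels are access-restricted; chains and cohorts are sized for
minutes, not hours, on one CPU):

* **Recovery** — Case 1, N=2000, n=500, p=0.01, sigma_b^2=0.1, PVE=0.5;
  posterior means of (p, sigma_b^2, PVE) within 2 posterior s.d. of truth
  in >= 8/10 seeds.
* **Mixed-model PVE inflation** — Case 2 with the sparser mixture
  p=0.003 at n=1000, N=2000. Design note: the expected inflation is
  Delta PVE ~ sigma^2/(p sigma_b^2) / (2 + sigma^2/(p sigma_b^2)) - 1/2,
  i.e. ~+0.14 at p=0.003 but only ~+0.02 at p=0.01, while the REML
  sampling error is roughly sqrt(2N)/n; the paired direction (MLM > HBM)
  is only resolvable in >= 8/10 replicates when the former exceeds the
  latter, which fixes this design rather than the p=0.01 one.
* **Detection** — Case 1, N=5000, n=1000, p=0.003: mean TPR >= 0.6 and
  mean FPR <= 0.2% at PIP >= 0.5 over 5 seeds.
* **Oracles** — chain PIPs vs exact enumeration over all 2^8 indicator
  configurations (hyperparameters frozen so the enumeration is exact);
  AI-REML vs dense restricted-likelihood grid; conjugate-update moments
  vs closed forms.
* **Multi-scale PVE** — Case 2 replicates: the mixed-model PVE at the
  loosest single-SNP p-value threshold (1e-1) is compared with the
  tightest estimable threshold, declining in >= 8/10 replicates. The
  intermediate rows are monotone only in expectation, not per replicate.

## Numerical choices and edge cases

* Log-space posterior odds; logistic of +/-inf saturates to {0,1} safely.
* Cholesky factorizations retry once with 1e-8 diagonal jitter.
* Inverse-gamma draws guard against gamma-variate underflow (1e-300).
* Monomorphic or all-missing SNPs are rejected at standardization and
  must be removed by QC first; `hbmix qc` also re-drops SNPs that become
  monomorphic after relatedness pruning.
* Constant SNP columns in the marginal scan get p-value 1 and a flag.
* REML at an unidentifiable design (e.g. A ~ I) returns a pinv-based
  information matrix with a warning; PVE is refused when both variance
  components sit on the boundary.
* Multi-scale rows with fewer than 2 surviving SNPs are marked not
  estimable rather than fitted.

## Known limitations

* Under a *null* phenotype the marginal posterior of p does not
  concentrate near zero: as sigma_b^2 -> 0 the slab becomes
  indistinguishable from the spike, and the near-improper IG(0.001,0.001)
  prior leaves appreciable posterior mass on that ridge, where p floats
  freely. Selection behavior is unaffected (all PIPs stay far below 0.5
  and the PVE posterior concentrates near 0), but p-hat from a null
  dataset should not be read as an estimate of "fraction of causal SNPs
  = 0". A weakly informative prior on sigma_b^2 would remove the ridge at
  the cost of departing from the stated hyperpriors.
* sigma_b^2 (and hence model-convention PVE) is upward-skewed in small
  active sets; the posterior s.d. honestly reflects this.
* Independence of indicators ignores LD: in real panels a causal signal
  spreads PIP mass over its LD block, and reported p-hat counts tagging
  SNPs, not distinct causal loci.
* The MLM comparison shares the GRM's equal-contribution assumption;
  MAF-weighted GRMs are out of scope.
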