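# Methods

## Model and procedure

`taucor` performs conditional gene-based association (GBA) analysis from
GWAS summary statistics in two steps per gene:

1. **Regional polygenicity.** The z statistics of the m_r SNPs surrounding
   the gene (window of +/-1 Mb by default) are modelled with a
   variance-component regression, `z_r = U_r b + e`, with random joint
   effects `b ~ N(0, tau I)` and residuals `e ~ N(0, U_r)`. Marginally
   `z_r ~ N(0, tau U_r^2 + U_r)`; `tau` is estimated by maximum likelihood.
   Because standardized joint effects relate to heritability, the parameter
   satisfies `tau = n h_r^2 / m_r`, giving the hard estimation bound
   `0 <= tau <= n / m_r` and a derived local SNP heritability
   `h_r^2 = tau m_r / n`.
2. **Covariance correction.** Under the gene-level null, the intragenic z
   vector conditional on the regional background is
   `z_g ~ N(0, tau U_gr U_gr' + U_g)`. The secondary analysis reruns the GBA
   test with this covariance; the z statistics themselves are never altered
   (the conditional mean stays zero). `Sigma - U_g` is PSD by construction,
   so each gene SNP's null variance can only grow, and for the kernel score
   tests (Burden/SKAT/SKAT-O) the conditional p-value is provably >= the
   initial one. PCA re-derives its components from `Sigma`, so its degrees of
   freedom can change and the guarantee is lost — the test suite exhibits a
   concrete counterexample by seeded random search.

Assumptions worth stating: SNPs in the summary file and the LD matrix match
by id and order (no allele harmonization is attempted — z signs are taken as
given); the LD matrix comes from a panel compatible with the GWAS; the
extragenic effects are exchangeable (a single variance `tau` for all m_r
SNPs). The method is deliberately tolerant of the latter being wrong: it is
fitted to whatever signal the region shows.

## Numerical choices

* **Likelihood in the eigenbasis.** `-2 ln L(tau) =
  sum_i [log(tau lam_i^2 + lam_i) + w_i^2/(tau lam_i^2 + lam_i)]` with
  `w = V' z_r`, summed over the retained eigenmodes of `U_r` only. This is
  the pseudo-inverse/pseudo-determinant of the low-rank approximation; each
  objective evaluation is O(rank) after one decomposition, so the bounded
  Brent minimizer (tolerance 1e-6 on tau) is essentially free. Boundary
  optima are detected within 10x the tolerance and flagged.
* **Truncation rule.** Eigenpairs are kept up to the smallest prefix holding
  f = 0.999 of the trace, and any mode below 1e-8 of the largest eigenvalue
  is dropped regardless. Both constants are configurable; they aim to keep
  near-full information while removing the numerically null space of dense
  LD. Indefinite input matrices are first clipped to PSD *without* rescaling
  the diagonal back to 1 (rescaling can reintroduce indefiniteness); the
  diagonal perturbation is logged, and repaired matrices are exempt from the
  unit-diagonal validation.
* **Chi-square mixtures.** SKAT-type null distributions
  `sum lam_j chi2_1` are evaluated by Imhof's integral, vectorized on a
  uniform grid with >= 16 points per oscillation period and truncated where
  the alternating-tail bound falls below 1e-10; the quadrature error is
  estimated by Richardson comparison of full- and half-resolution Simpson
  sums. When the error gate fails or p falls below 1e-8, a Lugannani-Rice
  saddlepoint approximation of the survival function takes over; it is
  accurate deep in the tail, and all tests report `log10p` computed through
  log-scale survival functions, so p-values far below the 1e-300 double
  floor never fail (p itself is clamped at 1e-300). The method used is
  recorded in each result's metadata.
* **SKAT-O.** Per-rho kernels `(1-rho) W^2 + rho w w'` on the default grid
  rho in {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; the per-rho p-values are
  combined with the equal-weight Cauchy combination rather than the original
  one-dimensional integration — simpler, well calibrated, and exact at the
  degenerate single-point grids (rho={1} is Burden, rho={0} is SKAT).
* **ACAT.** `T = sum w_j tan((0.5 - p_j) pi) / sum w_j`,
  `p = 0.5 - arctan(T)/pi`. Components below 1e-15 switch to the asymptote
  `1/(p pi)` carried in log10, so inputs given only as log10p combine
  correctly however extreme.
* **PCA test.** Components of `Sigma` are retained up to 85% of the trace by
  default (configurable); the statistic `sum_k (v_k'z)^2 / lam_k` is
  chi-square with k degrees of freedom. Eigenvalues below 1e-10 are never
  used.
* **Default weights** are all ones: the z-statistic inputs are already
  standardized effect measures. MAF-style weighting is exposed through
  `WeightScheme` but is not a default.

## Simulator

The generator draws summary statistics directly, without phenotypes:
causal status is Bernoulli per SNP with rates `rho K / m_g` inside the gene
and `(1-rho) K / m_r` outside (the realized causal count varies around K by
design); causal joint effects are `z_j ~ N(0, tau_sim)` with

```
tau_sim = (n / M) * (m_g + m_r) * h_gw2 / K
```

— the local heritability (panel fraction of the genome-wide h_gw2) split
equally over the K causal SNPs and scaled by sample size; and marginal
statistics are `z ~ N(U z_j, U)` via the eigen square root of U (valid for
rank-deficient LD). Scenario defaults mirror the study grid: K = 10,
rho in {0, 1}, h_gw2 in {0.3, 0.5, 0.7}, n/M = 0.05. Since the bound on the
estimated tau needs an explicit n, the scenario carries a genome SNP count
M (default 1e7, a sequencing-scale panel) from which n = n_over_M * M
(500,000 by default) follows unless given explicitly.

Synthetic LD is block-diagonal AR(1) (`corr = ar_rho^|i-j|` within a
block), PSD by construction. An optional `base_corr` adds a constant
correlation across the whole panel (`c J + (1-c) blockdiag(AR)`), a stylized
stand-in for the weak long-range LD of real reference panels. What the
generator does **not** emulate: allele-frequency structure, LD decay
heterogeneity, and the strong-but-patchy long-range LD of real chromosomes.
Consequences at desk scale: with pure AR blocks, causal SNPs outside the
gene essentially never push a gene below the 2.5e-6 threshold, so the
false-positive/conditional-specificity phenomenon is only demonstrable with
`base_corr > 0` (see `examples/03`) or with user-supplied real LD matrices;
passing tests on synthetic LD show the estimator, the correction and the
guarantees are implemented correctly, not that real-data operating
characteristics are reproduced.

## Evaluation

A gene is called positive when `p < threshold` strictly (gene-level default
2.5e-6). Sensitivity and specificity are computed on the truly-associated
and non-associated gene sets, accuracy is their prevalence-weighted
combination, and conditional-analysis metrics use as denominators only the
genes that entered conditional analysis (those initially significant) —
the convention under which all cells of the reference comparison table
follow from its printed counts. Rates are rounded half-up to two decimals
only at presentation.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
full suite completes in minutes on one CPU: tau recovery at m_r = 500 with
200 replicates per true tau; monotonicity over 1000 random instances with
m_g <= 10; calibration with 1e5 null replicates at m = 8; the two-step
simulation at m = 2000 (gene of 100 SNPs) with 150 replicates per arm. At
this panel size the heritability model implies tau = 5 (vs ~12.5 at the
full ~5000-SNP windows of the study design), so absolute selection rates
are smaller than at full scale; rates are reported with the number of
replicates they are based on.

## Known limitations

* No allele harmonization or reference-panel QC: inputs are trusted as
  aligned.
* Single variance component; no covariates, no multi-region joint fit.
* The conditional analysis corrects only the covariance; per-SNP conditional
  z statistics (COJO-style output) are out of scope.
* Imhof quadrature degrades for extremely imbalanced two-eigenvalue
  mixtures (grid would exceed 2^21 points); the saddlepoint fallback takes
  over with ~0.1% relative accuracy.
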