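# taucor

Conditional gene-based association analysis from GWAS summary statistics,
correcting for the **regional polygenic background**.

## The problem

Gene-based association (GBA) tests aggregate the GWAS z statistics of all
SNPs in a gene into one gene-level p-value. Because of linkage
disequilibrium (LD), causal variants *outside* a gene can induce an
association signal *inside* it, so a conditional analysis is needed before a
significant gene can be interpreted. Classical conditional analysis (e.g.
COJO-style) picks a few top outside SNPs and re-computes per-SNP statistics
against them. `taucor` instead treats the whole surrounding region as a
polygenic background and corrects the gene's LD matrix, leaving the z
statistics untouched.

## The model

Let `z_g` (m_g SNPs) and `z_r` (m_r SNPs) be the marginal z statistics of
the gene and its surrounding window, and `U_g`, `U_r`, `U_gr` the
corresponding blocks of the SNP-correlation (LD) matrix. The extragenic
effects are modelled as random:

```
z_r = U_r b + e,   b ~ N(0, tau I),   e ~ N(0, U_r)
  =>  z_r ~ N(0, tau U_r^2 + U_r)
```

The scalar `tau` measures the joint contribution of the m_r surrounding SNPs
to the trait; it is proportional to the local SNP heritability,
`tau = n h_r^2 / m_r`, and therefore bounded: `0 <= tau <= n / m_r`. It is
estimated by 1-D bounded maximum likelihood, evaluated in the truncated
eigenbasis of `U_r` (pseudo-inverse / pseudo-determinant), which is robust
to the multicollinearity of dense LD matrices.

Given `tau`, the null covariance of the intragenic z statistics conditional
on the regional background is

```
Sigma = tau U_gr U_gr' + U_g
```

and the secondary GBA analysis simply reruns any test on `(z_g, Sigma)`
instead of `(z_g, U_g)`. For the kernel score tests (Burden, SKAT, SKAT-O)
the conditional p-value is mathematically guaranteed to be greater than or
equal to the initial one (`Sigma - U_g` is positive semidefinite); the PCA
test does not share this guarantee.

Included: Burden, SKAT, SKAT-O, PCA and ACAT-O (Cauchy combination) tests
with an exact chi-square-mixture p-value engine (Imhof integration with a
saddlepoint tail fallback, reliable far below p = 1e-300 on the log10
scale), a direct summary-statistics simulator, and a
sensitivity/specificity/accuracy evaluation harness.

## Worked example

`examples/02_conditional_gene_test.py` builds a 250-SNP panel whose first 30
SNPs form a gene, injects a polygenic background into the whole region, and
runs the two-step pipeline:

```
gene DEMO1: m_g=30, m_r=220
tau_hat=1.2667  h_r2=0.00139
  burden  initial p = 7.617e-02   conditional p = 2.366e-01
  skat    initial p = 1.614e-08   conditional p = 8.232e-04
  skat-o  initial p = 1.247e-07   conditional p = 4.355e-03
  pca     initial p = 1.174e-13   conditional p = 1.980e-07
```

The gene looks strongly associated initially (SKAT p = 1.6e-08), but the
whole signal is induced by the background: the fitted `tau_hat = 1.27` and
the adjusted covariance raise every kernel-test p-value by several orders of
magnitude. The other examples cover tau/heritability estimation (`01`),
removal of induced false positives under a long-range-LD panel (`03`), and
the performance-metric arithmetic (`04`).

A thin CLI mirrors the library:

```
taucor pipeline --sumstats ss.tsv --ld ld.txt --genes genes.bed \
    --window 1000000 --tests burden,skat,skat-o,pca --out results.tsv
```

Summary statistics are TSV (`SNP`, `POS`, `Z` or `BETA`+`SE`, optional `N`);
LD matrices are plain square text or PLINK `--r square` files; genes are
BED-like TSV with 1-based half-open intervals.

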