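"""Two-step conditional gene-based analysis of a single gene.

Builds a 250-SNP panel whose first 30 SNPs form the gene, injects a strong
polygenic background into the surrounding region, and runs the full pipeline:
initial tests on (z_g, U_g), tau estimation from z_r, covariance adjustment,
and conditional tests on (z_g, tau U_gr U_gr' + U_g).
"""

import numpy as np

from taucor import (GeneInterval, PipelineConfig, SummaryStats, run_pipeline,
                    synth_ld)

m_g, m_r = 30, 220
m = m_g + m_r
U = synth_ld(m, [m], ar_rho=0.9)  # one AR block: gene and region share LD

rng = np.random.default_rng(11)
# regional background: every SNP carries a small random joint effect
z_joint = rng.normal(0.0, 1.2, m)
lam, V = np.linalg.eigh(U.values)
L = (V * np.sqrt(np.maximum(lam, 0.0))) @ V.T
z = U.values @ z_joint + L @ rng.standard_normal(m)

positions = 1_000 + 10 * np.arange(m)
stats = SummaryStats(U.snp_ids, z=z, positions=positions, n=200_000)
gene = GeneInterval("22", 1_000, 1_000 + 10 * m_g, "DEMO1")

cfg = PipelineConfig(tests=("burden", "skat", "skat-o", "pca"),
                     threshold=0.05, window=10_000)
res = run_pipeline(cfg, stats, U, [gene]).iloc[0]

print(f"gene {res['gene']}: m_g={res['m_g']}, m_r={res['m_r']}")
print(f"tau_hat={res['tau_hat']:.4f}  h_r2={res['h_r2']:.5f}")
for t in ("burden", "skat", "skat-o", "pca"):
    print(f"  {t:7s} initial p = {res[f'p_init_{t}']:.3e}   "
          f"conditional p = {res[f'p_cond_{t}']:.3e}")
# The conditional p-values are never smaller than the initial ones for the
# kernel tests: the gene's apparent signal is explained by the regional
# background, so the adjusted test is more conservative.
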