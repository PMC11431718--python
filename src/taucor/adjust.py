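"""Correction of the intragenic LD matrix for the regional polygenic background.

Under the fitted variance-component model the intragenic z statistics, with no
true gene effect, are distributed as

    z_g | background ~ N(0, tau * U_gr U_gr^T + U_g),

so the corrected covariance sigma = tau * U_gr U_gr^T + U_g replaces U_g in the
secondary gene-based analysis.  Only the covariance changes: the observed z_g
vector is passed through unchanged (the conditional mean stays zero), and sigma
is deliberately not re-standardized to a correlation matrix — the inflated
diagonal IS the correction, and rescaling would cancel it for single-SNP genes
and void the kernel-test p-value monotonicity guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ld import RegionPartition

__all__ = ["AdjustedGeneCov", "adjust_gene_cov"]


@dataclass
class AdjustedGeneCov:
    """Corrected intragenic covariance sigma = tau * U_gr U_gr^T + U_g."""

    sigma: np.ndarray
    tau_used: float
    source: RegionPartition | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.tau_used < 0:
            raise ValueError("tau_used must be >= 0")


def adjust_gene_cov(part: RegionPartition, tau: float) -> AdjustedGeneCov:
    """Build the background-adjusted covariance for the gene's z statistics.

    sigma = tau * U_gr U_gr^T + U_g, symmetrized; sigma - U_g is PSD by
    construction, so every gene-SNP variance can only grow.  A degenerate
    partition (no surrounding SNPs) returns U_g unchanged with tau_used = 0.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if part.degenerate:
        return AdjustedGeneCov(sigma=part.U_g.copy(), tau_used=0.0, source=part)
    sigma = tau * (part.U_gr @ part.U_gr.T) + part.U_g
    sigma = 0.5 * (sigma + sigma.T)
    return AdjustedGeneCov(sigma=sigma, tau_used=float(tau), source=part)
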