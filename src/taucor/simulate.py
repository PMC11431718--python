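"""Direct simulation of GWAS summary statistics over a gene and its region.

Instead of simulating phenotypes and genotypes, marginal z statistics are
drawn directly from their sampling distribution: causal SNPs get independent
joint effects z_j ~ N(0, tau_sim) (zero elsewhere), and the marginal vector is

    z ~ N(U z_j, U)

with U the LD matrix of the whole gene + region panel.  Causal status is
Bernoulli per SNP with rates rho*K/m_g inside the gene and (1-rho)*K/m_r
outside, so the realized causal count varies around K by design.  Assuming
every causal SNP explains the same heritability, the per-causal-SNP z variance
follows from the genome-wide heritability:

    tau_sim = (n / K) * ((m_r + m_g) / M) * h_gw2 = (n/M) * (m_r + m_g) * h_gw2 / K,

i.e. the local heritability (m/M fraction of h_gw2) split over K causal SNPs,
scaled by sample size.  A block-AR(1) synthetic LD generator stands in for
reference-panel LD matrices so the whole pipeline is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import adjust_gene_cov
from .gba import acat_test, burden_test, pca_test, skat_test, skato_test
from .ld import LDMatrix, RegionPartition, truncated_eigen
from .sumstats import SummaryStats
from .tau import estimate_tau

__all__ = [
    "SimScenario",
    "SimReplicate",
    "synth_ld",
    "draw_causal_status",
    "tau_sim",
    "simulate_replicate",
    "run_scenario",
]


@dataclass(frozen=True)
class SimScenario:
    """One simulation scenario for a gene of m_g SNPs in a region of m_r SNPs.

    Defaults mirror the study grid: K = 10 causal SNPs, causal fraction rho
    placed entirely inside (rho=1) or outside (rho=0) the gene, genome-wide
    heritability h_gw2 in {0.3, 0.5, 0.7}, and sample-to-genome-SNP ratio
    n/M = 0.05.
    """

    m_g: int
    m_r: int
    K: int = 10
    rho: float = 1.0
    h_gw2: float = 0.5
    n_over_M: float = 0.05
    M: int = 10_000_000
    n: int | None = None
    reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.M < self.m_g + self.m_r:
            raise ValueError("genome SNP count M smaller than the panel")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if not (0.0 <= self.h_gw2 <= 1.0):
            raise ValueError("h_gw2 must lie in [0, 1]")
        if self.n_over_M <= 0:
            raise ValueError("n_over_M must be positive")
        if self.rho * self.K > self.m_g:
            raise ValueError("expected causal count rho*K exceeds m_g")
        if (1.0 - self.rho) * self.K > self.m_r:
            raise ValueError("expected causal count (1-rho)*K exceeds m_r")

    @property
    def m(self) -> int:
        return self.m_g + self.m_r

    @property
    def sample_size(self) -> int:
        """Explicit n if given, else n = n_over_M * M (M defaults to 1e7)."""
        return self.n if self.n is not None else max(int(round(self.n_over_M * self.M)), 1)


@dataclass
class SimReplicate:
    """One simulated draw: causal mask, joint z effects, marginal z vector."""

    causal: np.ndarray
    z_joint: np.ndarray
    z_marginal: np.ndarray
    tau_sim: float

    def __post_init__(self) -> None:
        if np.any(self.z_joint[self.causal == 0] != 0.0):
            raise ValueError("non-causal SNPs must carry zero joint effect")


def synth_ld(
    m: int,
    block_sizes: list[int] | None = None,
    ar_rho: float = 0.9,
    seed: int | None = None,
    jitter: bool = False,
    base_corr: float = 0.0,
) -> LDMatrix:
    """Block-diagonal AR(1) correlation matrix emulating LD-block structure.

    Within a block, corr(i, j) = ar_rho^|i-j|; blocks are independent.  PSD by
    construction for ar_rho in [0, 1).  With ``jitter`` the block boundaries
    are perturbed reproducibly from ``seed`` (block count preserved).

    ``base_corr`` adds a constant correlation c across the whole panel
    (U = c J + (1-c) blockdiag(AR), still PSD with unit diagonal), a stylized
    stand-in for the weak long-range LD that links a gene to its wider region
    in real reference panels and that pure block structure cannot represent.
    """
    if not (0.0 <= ar_rho < 1.0):
        raise ValueError("ar_rho must lie in [0, 1)")
    if not (0.0 <= base_corr < 1.0):
        raise ValueError("base_corr must lie in [0, 1)")
    if block_sizes is None:
        block_sizes = [m]
    block_sizes = [int(b) for b in block_sizes]
    if sum(block_sizes) != m or any(b < 1 for b in block_sizes):
        raise ValueError(f"block sizes {block_sizes} inconsistent with m={m}")
    if jitter and seed is not None and len(block_sizes) > 1:
        rng = np.random.default_rng(seed)
        sizes = np.array(block_sizes)
        for _ in range(len(sizes)):
            i, j = rng.integers(0, len(sizes), size=2)
            if sizes[i] > 1:
                sizes[i] -= 1
                sizes[j] += 1
        block_sizes = sizes.tolist()
    U = np.zeros((m, m))
    off = 0
    for b in block_sizes:
        idx = np.arange(b)
        U[off:off + b, off:off + b] = ar_rho ** np.abs(idx[:, None] - idx[None, :])
        off += b
    if base_corr > 0.0:
        U = base_corr * np.ones((m, m)) + (1.0 - base_corr) * U
    return LDMatrix(values=U, snp_ids=[f"snp{i + 1}" for i in range(m)])


def draw_causal_status(scn: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli causal mask: rate rho*K/m_g in the gene, (1-rho)*K/m_r outside.

    Gene SNPs occupy indices [0, m_g); region SNPs [m_g, m_g + m_r).
    """
    p_g = scn.rho * scn.K / scn.m_g
    p_r = (1.0 - scn.rho) * scn.K / scn.m_r if scn.m_r else 0.0
    if p_g > 1.0 or p_r > 1.0:
        raise ValueError("causal probability exceeds 1")
    c = np.zeros(scn.m, dtype=np.int8)
    c[: scn.m_g] = rng.random(scn.m_g) < p_g
    c[scn.m_g:] = rng.random(scn.m_r) < p_r
    return c


def tau_sim(scn: SimScenario) -> float:
    """Per-causal-SNP z variance implied by the genome-wide heritability.

    tau = (n / M) * (m_r + m_g) * h_gw2 / K; with an explicit sample size the
    ratio n/M is taken from it, else from the scenario's n_over_M.
    """
    if scn.K < 1:
        raise ValueError("K must be >= 1")
    ratio = scn.sample_size / scn.M if scn.n is not None else scn.n_over_M
    return ratio * (scn.m_r + scn.m_g) * scn.h_gw2 / scn.K


def _psd_sqrt(U: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eigh(U)
    lam = np.maximum(lam, 0.0)
    return (V * np.sqrt(lam)) @ V.T


def simulate_replicate(
    scn: SimScenario,
    U: LDMatrix,
    rng: np.random.Generator | int,
    L: np.ndarray | None = None,
) -> SimReplicate:
    """Draw one replicate: causal mask, joint effects, marginal z vector.

    z_joint is N(0, tau_sim) at causal SNPs and 0 elsewhere; the marginal
    vector is U z_joint + L eps with L L' = U (eigen square root, valid for
    rank-deficient U).  Passing a precomputed ``L`` skips the decomposition;
    passing an integer seeds a fresh generator, so the same seed reproduces
    the replicate bit for bit.
    """
    if U.m != scn.m:
        raise ValueError(f"LD dimension {U.m} != scenario m {scn.m}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tau = tau_sim(scn)
    c = draw_causal_status(scn, rng)
    zj = np.zeros(scn.m)
    k = int(c.sum())
    if k and tau > 0:
        zj[c == 1] = rng.normal(0.0, np.sqrt(tau), size=k)
    if L is None:
        L = _psd_sqrt(U.values)
    z = U.values @ zj + L @ rng.standard_normal(scn.m)
    return SimReplicate(causal=c, z_joint=zj, z_marginal=z, tau_sim=tau)


_TEST_FUNCS = {
    "burden": lambda z, S: burden_test(z, S),
    "skat": lambda z, S: skat_test(z, S),
    "skat-o": lambda z, S: skato_test(z, S),
    "pca": lambda z, S: pca_test(z, S),
}


def run_scenario(
    scn: SimScenario,
    U: LDMatrix,
    tests: tuple[str, ...] = ("burden", "skat", "pca"),
    threshold: float = 2.5e-6,
    p_floor: float = 1e-30,
    acat: bool = False,
    rank_fraction: float = 0.999,
) -> pd.DataFrame:
    """Run a scenario end to end: initial GBA, selection, conditional GBA.

    The first ``scn.m_g`` SNPs are the gene.  Per replicate the table records
    each test's initial p-value; replicates whose minimum initial p falls in
    (p_floor, threshold) are selected for conditional analysis, where tau is
    estimated from the extragenic z's, the gene covariance adjusted and each
    test rerun.  Columns: rep, selected, tau_hat, h_r2, plus
    ``p_init_<test>`` / ``p_cond_<test>`` pairs.
    """
    unknown = set(tests) - set(_TEST_FUNCS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    mg = scn.m_g
    n = scn.sample_size
    U_g = U.values[:mg, :mg]
    U_r = U.values[mg:, mg:]
    U_gr = U.values[:mg, mg:]
    eig_r = truncated_eigen(U_r, f=rank_fraction) if scn.m_r else None
    L = _psd_sqrt(U.values)
    rng = np.random.default_rng(scn.seed)
    gene_ids = U.snp_ids[:mg]
    region_ids = U.snp_ids[mg:]
    rows = []
    for rep in range(scn.reps):
        sim = simulate_replicate(scn, U, rng, L=L)
        z_g, z_r = sim.z_marginal[:mg], sim.z_marginal[mg:]
        row: dict = {"rep": rep, "tau_sim": sim.tau_sim,
                     "n_causal_gene": int(sim.causal[:mg].sum()),
                     "n_causal_region": int(sim.causal[mg:].sum())}
        init = {}
        for t in tests:
            res = _TEST_FUNCS[t](z_g, U_g)
            init[t] = res
            row[f"p_init_{t}"] = res.p
            row[f"log10p_init_{t}"] = res.log10p
        if acat:
            comb = acat_test(list(init.values()))
            row["p_init_acat"] = comb.p
        # selection is per test (each test defines its own analysis track);
        # conditional quantities are computed once if any track selects
        selected = False
        for t in tests:
            sel = (init[t].p < threshold) and (init[t].p > p_floor)
            row[f"sel_{t}"] = sel
            selected = selected or sel
        row["selected"] = selected
        if selected and scn.m_r:
            est = estimate_tau(z_r, eig_r, n=n)
            part = RegionPartition(
                gene=SummaryStats(gene_ids, z_g),
                region=SummaryStats(region_ids, z_r),
                U_g=U_g, U_r=U_r, U_gr=U_gr,
            )
            sigma = adjust_gene_cov(part, est.tau_hat).sigma
            row["tau_hat"] = est.tau_hat
            row["h_r2"] = est.h_r2
            cond_results = []
            for t in tests:
                res = _TEST_FUNCS[t](z_g, sigma)
                cond_results.append(res)
                row[f"p_cond_{t}"] = res.p
                row[f"log10p_cond_{t}"] = res.log10p
            if acat:
                row["p_cond_acat"] = acat_test(cond_results).p
        rows.append(row)
    return pd.DataFrame(rows)
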