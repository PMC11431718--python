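"""LD (SNP-SNP correlation) matrices: I/O, validation, repair, spectral tools.

The LD matrix ``U`` is the genotype correlation matrix for an ordered SNP
panel.  For a gene and its surrounding region it is partitioned into blocks
``U_g`` (intragenic), ``U_r`` (extragenic) and the cross block ``U_gr``.
Reference-panel LD matrices are frequently slightly indefinite (sampling noise,
missing-data pairwise estimation), so a clip-to-PSD repair and a truncated
eigendecomposition with pseudo-inversion on the retained subspace are provided;
these are the machinery the tau likelihood runs on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import GeneInterval, SummaryStats

__all__ = [
    "LDMatrix",
    "EigenDecomp",
    "RegionPartition",
    "read_ld_matrix",
    "repair_psd",
    "truncated_eigen",
    "partition_region",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-6
_DIAG_TOL = 1e-4
_ENTRY_TOL = 1e-8


@dataclass
class LDMatrix:
    """Symmetric SNP-SNP correlation matrix with row/column labels.

    Full matrices must have unit diagonal (to 1e-6 at validation, 1e-4 at
    file-reading) and entries in [-1, 1]; off-diagonal blocks obtained by
    partitioning are stored as plain arrays, not as :class:`LDMatrix`.
    """

    values: np.ndarray
    snp_ids: list[str]
    strict: bool = True  # False for PSD-repaired matrices, whose clipped
    # reconstruction can push entries (incl. the diagonal) slightly past 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"LD matrix must be square, got {self.values.shape}")
        m = self.values.shape[0]
        if self.snp_ids is None:
            self.snp_ids = [f"snp{i + 1}" for i in range(m)]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match matrix dimension")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("LD matrix contains non-finite entries")
        asym = np.max(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-8:
            raise ValueError(f"LD matrix asymmetric beyond tolerance ({asym:.2e})")
        if self.strict and np.max(np.abs(self.values), initial=0.0) > 1 + _ENTRY_TOL:
            raise ValueError("LD entries outside [-1, 1]")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def require_unit_diagonal(self, tol: float = 1e-6) -> None:
        dev = np.max(np.abs(np.diag(self.values) - 1.0), initial=0.0)
        if dev > tol:
            raise ValueError(f"diagonal deviates from 1 by {dev:.2e} > {tol:.0e}")


@dataclass
class EigenDecomp:
    """Truncated spectral form ``U ~= V diag(lam) V^T`` of a PSD matrix.

    ``eigenvalues`` are the retained eigenvalues, sorted non-increasing and all
    strictly positive; ``eigenvectors`` the matching orthonormal columns;
    ``total_trace`` the trace of the source matrix (so the discarded mass is
    ``total_trace - eigenvalues.sum()``).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    rank: int
    total_trace: float

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.rank != self.eigenvalues.size or self.eigenvectors.shape[1] != self.rank:
            raise ValueError("rank inconsistent with retained eigenpairs")
        if self.rank < 1 or self.eigenvalues[self.rank - 1] <= 0:
            raise ValueError("retained eigenvalues must be strictly positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")


@dataclass
class RegionPartition:
    """The setG/setR split of a gene + region panel.

    ``gene``/``region`` are the intragenic and extragenic summary-statistic
    slices (z_g, z_r); ``U_g`` (m_g x m_g), ``U_r`` (m_r x m_r) and ``U_gr``
    (m_g x m_r) the corresponding LD blocks.  ``m_r == 0`` marks a degenerate
    partition: there is no regional background and the adjustment is a no-op.
    """

    gene: SummaryStats
    region: SummaryStats
    U_g: np.ndarray
    U_r: np.ndarray
    U_gr: np.ndarray

    def __post_init__(self) -> None:
        mg, mr = self.gene.m, self.region.m
        if self.U_g.shape != (mg, mg):
            raise ValueError("U_g shape mismatch")
        if self.U_r.shape != (mr, mr):
            raise ValueError("U_r shape mismatch")
        if self.U_gr.shape != (mg, mr):
            raise ValueError("U_gr shape mismatch")
        if set(self.gene.snp_ids) & set(self.region.snp_ids):
            raise ValueError("gene and region SNP sets overlap")

    @property
    def m_g(self) -> int:
        return self.gene.m

    @property
    def m_r(self) -> int:
        return self.region.m

    @property
    def degenerate(self) -> bool:
        return self.m_r == 0


def read_ld_matrix(path: str | Path, dialect: str = "square-text") -> LDMatrix:
    """Read a square LD matrix from plain text.

    ``square-text`` is a whitespace/tab-delimited m x m matrix with an optional
    single header line of SNP ids; ``plink-ld`` is PLINK ``--r square`` output
    (headerless whitespace matrix).  Near-symmetric input (asymmetry <= 1e-6)
    is symmetrized by averaging; larger asymmetry is an error, as are NaN
    entries, out-of-range values and a diagonal off 1 by more than 1e-4.
    """
    if dialect not in ("square-text", "plink-ld"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().split()
    snp_ids = None
    skiprows = 0
    if dialect == "square-text" and first:
        try:
            float(first[0])
        except ValueError:
            snp_ids = [str(t) for t in first]
            skiprows = 1
    vals = pd.read_csv(
        path, sep=r"\s+", header=None, skiprows=skiprows, na_values=["nan", "NaN", "NA"]
    ).to_numpy(dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError(f"LD file is not square: shape {vals.shape}")
    if np.any(~np.isfinite(vals)):
        raise ValueError("LD file contains NaN entries")
    asym = np.max(np.abs(vals - vals.T), initial=0.0)
    if asym > _SYM_TOL:
        raise ValueError(f"LD matrix asymmetry {asym:.2e} exceeds {_SYM_TOL:.0e}")
    vals = 0.5 * (vals + vals.T)
    diag_dev = np.max(np.abs(np.diag(vals) - 1.0), initial=0.0)
    if diag_dev > _DIAG_TOL:
        raise ValueError(f"diagonal deviates from 1 by {diag_dev:.2e}")
    if np.max(np.abs(vals), initial=0.0) > 1 + _ENTRY_TOL:
        raise ValueError("LD entries outside [-1, 1]")
    if snp_ids is not None and len(snp_ids) != vals.shape[0]:
        raise ValueError("header SNP-id count does not match matrix dimension")
    return LDMatrix(values=vals, snp_ids=snp_ids)


def repair_psd(ld: LDMatrix, floor: float = 0.0) -> LDMatrix:
    """Clip eigenvalues below ``floor`` and reassemble.

    The diagonal is deliberately NOT rescaled back to 1 after clipping:
    rescaling can reintroduce indefiniteness.  The maximal diagonal
    perturbation is logged.  If every eigenvalue is clipped the zero matrix is
    returned with a warning.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    vals = 0.5 * (ld.values + ld.values.T)
    lam, V = np.linalg.eigh(vals)
    if np.all(lam >= floor):
        return LDMatrix(values=vals, snp_ids=list(ld.snp_ids), strict=ld.strict)
    clipped = np.maximum(lam, floor)
    out = (V * clipped) @ V.T
    out = 0.5 * (out + out.T)
    if np.all(lam < floor) and floor == 0.0:
        warnings.warn("all eigenvalues clipped; repaired LD matrix is zero")
    diag_shift = np.max(np.abs(np.diag(out) - np.diag(vals)), initial=0.0)
    logger.info(
        "repair_psd: clipped %d/%d eigenvalues (min %.3e), max diagonal shift %.3e",
        int(np.sum(lam < floor)), lam.size, float(lam.min()), diag_shift,
    )
    return LDMatrix(values=out, snp_ids=list(ld.snp_ids), strict=False)


def truncated_eigen(
    ld: LDMatrix | np.ndarray, f: float = 0.999, eps: float = 1e-8
) -> EigenDecomp:
    """Truncated eigendecomposition of a PSD matrix.

    Eigenpairs are sorted descending; the retained set is the smallest prefix
    whose eigenvalue sum reaches ``f * trace`` with every member additionally
    exceeding ``eps * lambda_max`` (numerically null modes are dropped even if
    the mass rule would keep them).  At least one eigenpair is always retained;
    a zero matrix is an error.
    """
    vals = ld.values if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    lam, V = np.linalg.eigh(vals)
    lam, V = lam[::-1], V[:, ::-1]
    if lam[0] <= 0:
        raise ValueError("matrix has no positive eigenvalue (zero or negative definite)")
    total = float(np.trace(vals))
    # smallest prefix with cumulative mass >= f * trace
    csum = np.cumsum(lam)
    k_mass = int(np.searchsorted(csum, f * total) + 1)
    k_mass = min(k_mass, lam.size)
    keep = min(k_mass, int(np.sum(lam > eps * lam[0])))
    keep = max(keep, 1)
    return EigenDecomp(
        eigenvalues=lam[:keep].copy(),
        eigenvectors=V[:, :keep].copy(),
        rank=keep,
        total_trace=total,
    )


def partition_region(
    stats: SummaryStats,
    ld: LDMatrix,
    gene_interval: GeneInterval,
    window: int = 1_000_000,
) -> RegionPartition:
    """Split a panel into intragenic (setG) and extragenic (setR) parts.

    ``stats`` and ``ld`` must list the same SNPs in the same order.  The gene
    is the half-open 1-based interval [start, end); the region is
    [start - window, end + window) minus the gene.  SNPs outside the window are
    dropped.  A gene with no SNPs is an error; a gene with no surrounding SNPs
    yields a degenerate partition (m_r = 0).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if stats.positions is None:
        raise ValueError("summary statistics carry no positions; cannot partition")
    if stats.snp_ids != ld.snp_ids:
        raise ValueError("SNP ids/order differ between summary statistics and LD matrix")
    pos = stats.positions
    g = gene_interval
    in_gene = (pos >= g.start) & (pos < g.end)
    in_window = (pos >= g.start - window) & (pos < g.end + window)
    in_region = in_window & ~in_gene
    if not np.any(in_gene):
        raise ValueError(f"no intragenic SNPs in [{g.start}, {g.end})")
    gi = np.flatnonzero(in_gene)
    ri = np.flatnonzero(in_region)
    U = ld.values
    return RegionPartition(
        gene=stats.subset(gi),
        region=stats.subset(ri),
        U_g=U[np.ix_(gi, gi)].copy(),
        U_r=U[np.ix_(ri, ri)].copy(),
        U_gr=U[np.ix_(gi, ri)].copy(),
    )
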