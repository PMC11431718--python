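"""Per-SNP GWAS summary statistics and gene intervals.

A :class:`SummaryStats` object holds the marginal z statistics (``z = beta/se``)
for an ordered set of SNPs, optionally with the underlying effect sizes and
their standard errors, plus the GWAS sample size ``n``.  SNP order is the
contract with the LD matrix: rows/columns must match by id and position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SummaryStats", "GeneInterval", "read_sumstats", "read_genes"]

_Z_FROM_BETA_TOL = 1e-6


@dataclass
class SummaryStats:
    """Marginal summary statistics for an ordered SNP panel.

    Parameters
    ----------
    snp_ids
        SNP identifiers, unique, one per row.
    z
        Marginal z statistics (``beta/se``).
    positions
        1-based base-pair coordinates, or ``None`` if unknown.
    beta, se
        Optional effect sizes and standard errors; when both are given they
        must reproduce ``z`` to 1e-6 (``se`` strictly positive).
    n
        GWAS sample size (required for the tau upper bound ``n/m_r``).
    """

    snp_ids: list[str]
    z: np.ndarray
    positions: np.ndarray | None = None
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.z = np.asarray(self.z, dtype=float)
        m = len(self.snp_ids)
        if self.z.shape != (m,):
            raise ValueError(f"z has shape {self.z.shape}, expected ({m},)")
        if len(set(self.snp_ids)) != m:
            dupes = {s for s in self.snp_ids if self.snp_ids.count(s) > 1}
            raise ValueError(f"duplicated SNP ids: {sorted(dupes)[:5]}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (m,):
                raise ValueError("positions length mismatch")
        for name in ("beta", "se"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (m,):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.se is not None and np.any(self.se <= 0):
            raise ValueError("se must be strictly positive")
        if self.beta is not None and self.se is not None:
            if np.max(np.abs(self.z - self.beta / self.se), initial=0.0) > _Z_FROM_BETA_TOL:
                raise ValueError("z inconsistent with beta/se beyond 1e-6")
        if self.n is not None:
            self.n = int(self.n)
            if self.n < 1:
                raise ValueError("sample size n must be >= 1")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx: np.ndarray) -> "SummaryStats":
        """Row-subset preserving order of ``idx``."""
        idx = np.asarray(idx)
        return SummaryStats(
            snp_ids=[self.snp_ids[i] for i in idx],
            z=self.z[idx],
            positions=None if self.positions is None else self.positions[idx],
            beta=None if self.beta is None else self.beta[idx],
            se=None if self.se is None else self.se[idx],
            n=self.n,
        )


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a half-open 1-based interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


def read_sumstats(path: str | Path) -> SummaryStats:
    """Read a summary-statistics TSV.

    The file must have a header with column ``SNP`` and either ``Z`` or both
    ``BETA`` and ``SE`` (z is then computed as beta/se).  Optional columns:
    ``POS`` (1-based positions) and ``N`` (per-SNP sample size; the median is
    kept).  Column names are case-insensitive; row order is preserved.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).upper() for c in df.columns]
    if "SNP" not in df.columns:
        raise ValueError("missing mandatory column SNP")
    has_z = "Z" in df.columns
    has_bse = "BETA" in df.columns and "SE" in df.columns
    if not has_z and not has_bse:
        raise ValueError("need column Z or columns BETA and SE")
    beta = df["BETA"].to_numpy(float) if "BETA" in df.columns else None
    se = df["SE"].to_numpy(float) if "SE" in df.columns else None
    if se is not None and np.any(se <= 0):
        raise ValueError("se must be strictly positive")
    z = df["Z"].to_numpy(float) if has_z else beta / se
    n = int(np.median(df["N"].to_numpy(float))) if "N" in df.columns else None
    pos = df["POS"].to_numpy(np.int64) if "POS" in df.columns else None
    return SummaryStats(
        snp_ids=df["SNP"].astype(str).tolist(),
        z=z,
        positions=pos,
        beta=beta if has_bse else None,
        se=se if has_bse else None,
        n=n,
    )


def read_genes(path: str | Path) -> list[GeneInterval]:
    """Read a BED-like TSV of gene intervals: chrom, start, end[, name].

    Coordinates are taken as 1-based half-open ``[start, end)``; a header line
    is detected and skipped if the second column is non-numeric.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    first = df.iloc[0]
    try:
        int(first[1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    genes = []
    for _, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 and not pd.isna(row[3]) else ""
        genes.append(GeneInterval(str(row[0]), int(row[1]), int(row[2]), name))
    return genes
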