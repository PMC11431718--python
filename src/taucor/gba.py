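"""Gene-based association tests on a z vector and a null covariance matrix.

Every test here consumes (z_g, Sigma) where Sigma is either the raw intragenic
LD matrix U_g (initial analysis) or the background-adjusted covariance
tau * U_gr U_gr^T + U_g (conditional analysis):

* Burden       — T = (w'z)^2 / (w' Sigma w), 1-df chi-square.
* SKAT         — Q = sum w_i^2 z_i^2, null distribution a mixture
                 sum lambda_j chi2_1 with lambda_j = eig(W Sigma W).
* SKAT-O       — per-rho kernels K_rho = (1-rho) W^2 + rho w w' interpolating
                 SKAT (rho=0) and Burden (rho=1); per-rho p-values combined by
                 the Cauchy combination.
* PCA          — chi-square on the leading principal components of Sigma.
* ACAT         — Cauchy combination of arbitrary p-values (ACAT-O).

The chi-square-mixture survival function is evaluated exactly by Imhof's
integral representation, with a Lugannani-Rice saddlepoint approximation as
the fallback for far tails and non-convergence, so p-values far below 1e-30
are reported on the log10 scale without failing.  All results are
deterministic for fixed inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import chi2, norm

__all__ = [
    "GBAResult",
    "WeightScheme",
    "quadform_pvalue",
    "quadform_logsf",
    "burden_test",
    "skat_test",
    "skato_test",
    "pca_test",
    "acat_combine",
    "acat_test",
]

_LN10 = np.log(10.0)
_P_MIN = 1e-300
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class GBAResult:
    """One gene-level test result with an underflow-safe log10 p-value."""

    test: str
    statistic: float
    p: float
    log10p: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if self.log10p > 1e-12:
            raise ValueError("log10p must be <= 0")


@dataclass
class WeightScheme:
    """Per-SNP positive weights; default is unweighted (all ones)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or np.any(self.weights <= 0):
            raise ValueError("weights must be a 1-D vector of positive reals")

    @classmethod
    def ones(cls, m: int) -> "WeightScheme":
        return cls(np.ones(m))


# ---------------------------------------------------------------------------
# chi-square mixture survival function
# ---------------------------------------------------------------------------

def _imhof_integrand(u: np.ndarray, q: float, lam: np.ndarray) -> np.ndarray:
    theta = 0.5 * np.arctan(np.outer(lam, u)).sum(axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.log1p(np.outer(lam, u) ** 2).sum(axis=0)
    out = np.sin(theta) * np.exp(-log_rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(u > 0, out / np.where(u > 0, u, 1.0), 0.5 * (lam.sum() - q))
    return out


def _imhof_sf(q: float, lam: np.ndarray, eps_abs: float = 1e-10) -> tuple[float, float]:
    """P(sum lam_i chi2_1 > q) by Imhof's integral; returns (p, abserr).

    The integrand sin(theta(u)) / (u rho(u)) is sampled on a uniform grid fine
    enough for its fastest oscillation and truncated where one further
    oscillation lobe (the alternating-tail bound) is below ``eps_abs``; the
    quadrature error is estimated by comparing full- and half-resolution
    Simpson sums.  Returns (nan, inf) when the grid would be too large.
    """
    lam = np.asarray(lam, dtype=float)
    s = float(lam.sum())

    def amp(u: float) -> float:
        return float(np.exp(-0.25 * np.log1p((lam * u) ** 2).sum()) / u)

    # truncation point: residual tail bounded by amplitude * half-period
    target = eps_abs * 0.5 * q / np.pi
    T = 1.0
    while amp(T) > target:
        T *= 2.0
        if T > 2.0**48:
            return float("nan"), float("inf")
    # >= ~16 points per period of the fastest phase (s + q)/2
    h = 2.0 * np.pi / (16.0 * 0.5 * (s + q))
    n = int(np.ceil(T / h))
    if n > 2**21:
        return float("nan"), float("inf")
    n += n % 2  # Simpson needs an even interval count
    u = np.linspace(0.0, T, n + 1)
    y = _imhof_integrand(u, q, lam)
    val = integrate.simpson(y, dx=T / n)
    val_half = integrate.simpson(y[::2], dx=2 * T / n)
    # |full - half|/15 estimates the HALF-resolution error; the full-grid
    # Simpson error is ~16x smaller again
    err = abs(val - val_half) / 240.0 + eps_abs
    return 0.5 + val / np.pi, err / np.pi


def _saddlepoint_logsf(q: float, lam: np.ndarray) -> float:
    """log P(sum lam_i chi2_1 > q) by the Lugannani-Rice saddlepoint formula.

    Accurate deep in the upper tail where quadrature loses all digits; breaks
    down only at q == E[Q] where the saddlepoint is 0 (handled by the caller).
    """
    lmax = lam.max()
    zeta_hi = 1.0 / (2.0 * lmax) - 1e-12 / lmax

    def kprime(z: float) -> float:
        return float(np.sum(lam / (1.0 - 2.0 * z * lam)))

    mean = float(lam.sum())
    if abs(q - mean) < 1e-10 * max(mean, 1.0):
        return float(np.log(0.5))  # saddlepoint at 0; Q is near its mean
    zeta_lo = -1.0
    while kprime(zeta_lo) > q:
        zeta_lo *= 8.0
        if zeta_lo < -1e12:
            break
    zeta = brentq(lambda z: kprime(z) - q, zeta_lo, zeta_hi, xtol=1e-14, rtol=1e-14)
    K = -0.5 * float(np.sum(np.log1p(-2.0 * zeta * lam)))
    K2 = 2.0 * float(np.sum(lam**2 / (1.0 - 2.0 * zeta * lam) ** 2))
    w = np.sign(zeta) * np.sqrt(max(2.0 * (zeta * q - K), 0.0))
    v = zeta * np.sqrt(K2)
    if w == 0.0 or v == 0.0:
        return float(np.log(0.5))
    return float(norm.logsf(w + np.log(v / w) / w))


def quadform_logsf(q: float, lambdas: np.ndarray) -> tuple[float, dict]:
    """Natural-log survival probability of a weighted chi-square sum.

    Returns ``(log P(Q > q), meta)`` where meta records the method used:
    'imhof' (exact integral), 'saddlepoint' (tail fallback), or the degenerate
    single-lambda chi-square branch 'chi2'.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all mixture weights are zero")
    if q < 0:
        raise ValueError("quadratic form statistic must be >= 0")
    if q == 0.0:
        return 0.0, {"method": "exact-zero"}
    # single distinct weight: exact central chi-square
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(chi2.logsf(q / lam[0], df=lam.size)), {"method": "chi2"}
    p, err = _imhof_sf(q, lam)
    if np.isfinite(p) and err < max(1e-8, 5e-3 * p) and 1e-8 < p < 1.0:
        return float(np.log(p)), {"method": "imhof"}
    if np.isfinite(p) and err < 1e-8 and p >= 1.0:
        return 0.0, {"method": "imhof"}
    logp = _saddlepoint_logsf(q, lam)
    return min(logp, 0.0), {"method": "saddlepoint"}


def quadform_pvalue(q: float, lambdas: np.ndarray) -> float:
    """P(sum_i lambda_i chi2_{1,i} > q), clamped into (0, 1]."""
    logp, _ = quadform_logsf(q, lambdas)
    return float(np.clip(np.exp(logp), _P_MIN, 1.0))


def _result_from_logsf(test: str, stat: float, logp: float, meta: dict) -> GBAResult:
    p = float(np.clip(np.exp(logp), _P_MIN, 1.0))
    return GBAResult(test=test, statistic=float(stat), p=p,
                     log10p=min(logp / _LN10, 0.0), meta=meta)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _check_dims(z: np.ndarray, Sigma: np.ndarray, w: WeightScheme | None):
    z = np.asarray(z, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    m = z.shape[0]
    if Sigma.shape != (m, m):
        raise ValueError("Sigma dimension does not match z")
    if w is None:
        w = WeightScheme.ones(m)
    if w.weights.shape[0] != m:
        raise ValueError("weight vector dimension does not match z")
    return z, Sigma, w


def _psd_eigvals(S: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh(S)
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        warnings.warn(f"covariance not PSD (min eigenvalue {lam.min():.3e}); clipping")
    return np.maximum(lam, 0.0)


def burden_test(z: np.ndarray, Sigma: np.ndarray, w: WeightScheme | None = None) -> GBAResult:
    """Burden test: squared weighted sum of z against its null variance (1 df)."""
    z, Sigma, w = _check_dims(z, Sigma, w)
    denom = float(w.weights @ Sigma @ w.weights)
    if denom <= 0:
        raise ValueError("w' Sigma w must be positive")
    T = float(w.weights @ z) ** 2 / denom
    return _result_from_logsf("burden", T, float(chi2.logsf(T, df=1)), {"df": 1})


def skat_test(z: np.ndarray, Sigma: np.ndarray, w: WeightScheme | None = None) -> GBAResult:
    """SKAT: weighted sum of squared z with a chi-square-mixture null."""
    z, Sigma, w = _check_dims(z, Sigma, w)
    W = w.weights
    Q = float(np.sum(W**2 * z**2))
    lam = _psd_eigvals(Sigma * np.outer(W, W))  # eig(W Sigma W), W diagonal
    logp, meta = quadform_logsf(Q, lam)
    meta["n_lambda"] = int(np.sum(lam > 0))
    return _result_from_logsf("skat", Q, logp, meta)


def _kernel_sqrt(K: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    return (V * np.sqrt(lam)) @ V.T


def skato_test(
    z: np.ndarray,
    Sigma: np.ndarray,
    w: WeightScheme | None = None,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
) -> GBAResult:
    """SKAT-O: Burden/SKAT kernel interpolation over a rho grid.

    For each rho the statistic Q_rho = z' [(1-rho) W^2 + rho w w'] z has a
    chi-square-mixture null with weights eig(K^{1/2} Sigma K^{1/2}); the
    per-rho p-values are combined with the equal-weight Cauchy combination.
    The grid must contain 0 (pure SKAT) and 1 (pure Burden) unless it is a
    single point, in which case the result degenerates to that test exactly.
    """
    z, Sigma, w = _check_dims(z, Sigma, w)
    grid = tuple(float(r) for r in rho_grid)
    if any(r < 0 or r > 1 for r in grid):
        raise ValueError("rho values must lie in [0, 1]")
    if len(grid) == 0:
        raise ValueError("empty rho grid")
    if len(grid) > 1 and not (0.0 in grid and 1.0 in grid):
        raise ValueError("rho grid must contain 0 and 1")
    if grid == (1.0,):
        r = burden_test(z, Sigma, w)
        return GBAResult("skat-o", r.statistic, r.p, r.log10p,
                         {"rho_min": 1.0, "per_rho_log10p": [r.log10p]})
    if grid == (0.0,):
        r = skat_test(z, Sigma, w)
        return GBAResult("skat-o", r.statistic, r.p, r.log10p,
                         {"rho_min": 0.0, "per_rho_log10p": [r.log10p]})
    W = w.weights
    log10ps = []
    stats = []
    for rho in grid:
        if rho == 1.0:
            r = burden_test(z, Sigma, w)
            log10ps.append(r.log10p)
            stats.append(r.statistic)
            continue
        K = (1.0 - rho) * np.diag(W**2) + rho * np.outer(W, W)
        Q = float(z @ K @ z)
        A = _kernel_sqrt(K)
        lam = _psd_eigvals(A @ Sigma @ A)
        logp, _ = quadform_logsf(Q, lam)
        log10ps.append(min(logp / _LN10, 0.0))
        stats.append(Q)
    log10p = _acat_log10([10.0**lp for lp in log10ps], log10ps)
    i_min = int(np.argmin(log10ps))
    p = float(np.clip(10.0**log10p, _P_MIN, 1.0))
    return GBAResult("skat-o", stats[i_min], p, log10p,
                     {"rho_min": grid[i_min], "per_rho_log10p": log10ps})


def pca_test(z: np.ndarray, Sigma: np.ndarray, var_fraction: float = 0.85) -> GBAResult:
    """Principal-component chi-square test.

    Retains the smallest leading set of eigenvectors of Sigma explaining at
    least ``var_fraction`` of the trace and refers the sum of squared
    standardized scores to chi-square with that many degrees of freedom.
    """
    if not (0.0 < var_fraction <= 1.0):
        raise ValueError("var_fraction must be in (0, 1]")
    z, Sigma, _ = _check_dims(z, Sigma, None)
    lam, V = np.linalg.eigh(Sigma)
    lam, V = lam[::-1], V[:, ::-1]
    usable = lam > 1e-10
    if not np.any(usable):
        raise ValueError("no eigenvalue above 1e-10")
    lam, V = lam[usable], V[:, usable]
    csum = np.cumsum(lam)
    k = int(np.searchsorted(csum, var_fraction * float(np.trace(Sigma)) - 1e-12) + 1)
    k = min(k, lam.size)
    scores = V[:, :k].T @ z
    T = float(np.sum(scores**2 / lam[:k]))
    return _result_from_logsf("pca", T, float(chi2.logsf(T, df=k)), {"df": k})


# ---------------------------------------------------------------------------
# Cauchy combination (ACAT)
# ---------------------------------------------------------------------------

def _acat_log10(pvals: list[float], log10ps: list[float] | None = None,
                weights: np.ndarray | None = None) -> float:
    """log10 of the Cauchy-combination p-value, safe for p far below 1e-300.

    Small components (p < 1e-15) use the asymptote tan((0.5-p)pi) ~ 1/(p pi),
    carried in log10 so that log10p inputs beyond the double-precision floor
    still combine correctly.
    """
    p = np.clip(np.asarray(pvals, dtype=float), _P_MIN, 1.0 - 1e-16)
    wts = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    wts = wts / wts.sum()
    small = p < 1e-15
    # log10 magnitude of each small term w_j / (p_j pi)
    if log10ps is not None:
        lp_small = np.asarray(log10ps, dtype=float)[small]
    else:
        lp_small = np.log10(p[small])
    exps = -lp_small + np.log10(wts[small] / np.pi) if np.any(small) else np.array([])
    s_reg = float(np.sum(wts[~small] * np.tan((0.5 - p[~small]) * np.pi)))
    if exps.size and exps.max() > 250.0:
        # combined p ~ 1/(pi T); work on T in log10 (regular terms negligible)
        emax = float(exps.max())
        log10_T = emax + np.log10(np.sum(10.0 ** (exps - emax)))
        return float(-np.log10(np.pi) - log10_T)
    T = s_reg + float(np.sum(10.0**exps)) if exps.size else s_reg
    if T > 1e15:  # arctan saturates; use the Cauchy tail p ~ 1/(pi T)
        return float(-np.log10(np.pi * T))
    pc = 0.5 - np.arctan(T) / np.pi
    return float(np.log10(np.clip(pc, _P_MIN, 1.0)))


def acat_combine(pvals, weights=None) -> float:
    """Cauchy-combination (ACAT) aggregation of p-values into one p-value.

    T = sum_j w_j tan((0.5 - p_j) pi) / sum_j w_j;  p = 0.5 - arctan(T)/pi.
    Inputs are clipped to [1e-300, 1 - 1e-16]; weights default to equal and
    must be non-negative with a positive sum.
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if weights is not None:
        wts = np.asarray(weights, dtype=float)
        if wts.shape != p.shape or np.any(wts < 0) or wts.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    else:
        wts = None
    log10p = _acat_log10(list(p), None, wts)
    return float(np.clip(10.0**log10p, _P_MIN, 1.0))


def acat_test(results: list[GBAResult], weights=None) -> GBAResult:
    """ACAT-O over a list of test results, underflow-safe via their log10p."""
    if not results:
        raise ValueError("no results to combine")
    log10p = _acat_log10([r.p for r in results], [r.log10p for r in results],
                         None if weights is None else np.asarray(weights, float))
    p = float(np.clip(10.0**log10p, _P_MIN, 1.0))
    return GBAResult("acat-o", float("nan"), p, log10p,
                     {"combined": [r.test for r in results]})
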