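"""Autocovariance-corrected parametric Pearson test.

Under the independence null, the variance of the sample Pearson
correlation between two autocorrelated series is estimated as

    sigma2_rho = sum_{k=0..n-1} n_k * Cx(k) * Cy(k) / (n^2 * sx^2 * sy^2)

where Cx(k) is the lag-k autocovariance estimate (1/(n-k) normalization,
full-series mean), sx^2 = Cx(0), and n_k counts the entries of an n-by-n
matrix at |i - j| = k (n at k = 0, else 2(n-k)). A negative estimate --
possible in finite samples -- falls back to 1/n, the value the formula
takes in the absence of autocorrelation. The "effective sample size" is
m_hat = 1 + 1/sigma2_rho and a standard t test of the correlation is run
with m_hat in place of n:

    T = rho_hat * sqrt(m_hat - 2) / sqrt(1 - rho_hat^2),

two-tailed against a Student t with m_hat - 2 (possibly non-integer)
degrees of freedom. The quarter-truncated variant zeroes the
autocovariance products for k > n/4, whose estimates are dominated by
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateWindowError, InsufficientDataError, TTSError


def autocov_hat(x: np.ndarray, k: int) -> float:
    """Autocovariance estimate at lag k: (1/(n-k)) sum (x_t - xbar)(x_{t+k} - xbar)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if not 0 <= k < n:
        raise TTSError(f"lag k={k} outside [0, n)")
    xc = x - x.mean()
    return float(xc[: n - k] @ xc[k:]) / (n - k)


def _autocov_all(x: np.ndarray) -> np.ndarray:
    """Autocovariances at every lag 0..n-1 via one full correlation pass."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    xc = x - x.mean()
    raw = np.correlate(xc, xc, mode="full")[n - 1 :]
    return raw / (n - np.arange(n))


def n_k(n: int, k: int) -> int:
    """Count of n-by-n matrix entries with |i - j| = k: n at k=0, else 2(n-k)."""
    if not 0 <= k < n:
        raise TTSError(f"lag k={k} outside [0, n)")
    return n if k == 0 else 2 * (n - k)


@dataclass(frozen=True)
class ParametricResult:
    """Outcome of the corrected Pearson test."""

    rho_hat: float
    sigma2_rho: float
    fallback_used: bool
    m_hat: float
    T: float
    df: float
    p: float
    variant: str
    low_df_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "rho_hat": self.rho_hat,
            "sigma2_rho": self.sigma2_rho,
            "fallback_used": self.fallback_used,
            "m_hat": self.m_hat,
            "T": self.T,
            "df": self.df,
            "p": self.p,
            "variant": self.variant,
            "low_df_warning": self.low_df_warning,
        }


def corrected_pearson_test(
    x: np.ndarray, y: np.ndarray, variant: str = "full"
) -> ParametricResult:
    """Effective-sample-size t test of the Pearson correlation."""
    if variant not in ("full", "quarter_truncated"):
        raise TTSError(f"unknown variant {variant!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise TTSError("series must have equal length")
    if n < 8:
        raise InsufficientDataError("corrected Pearson test needs n >= 8")
    cx = _autocov_all(x)
    cy = _autocov_all(y)
    sx2, sy2 = cx[0], cy[0]
    if sx2 == 0.0 or sy2 == 0.0:
        raise DegenerateWindowError("zero-variance series")
    k = np.arange(n)
    nk = np.where(k == 0, n, 2 * (n - k))
    prod = cx * cy
    if variant == "quarter_truncated":
        prod = np.where(k > n / 4, 0.0, prod)
    sigma2 = float(np.sum(nk * prod) / (n * n * sx2 * sy2))
    fallback = bool(sigma2 <= 0.0)
    if fallback:
        sigma2 = 1.0 / n
    m_hat = 1.0 + 1.0 / sigma2
    xc = x - x.mean()
    yc = y - y.mean()
    rho = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    df = float(m_hat - 2.0)
    m_hat = float(m_hat)
    low_df = bool(df <= 0.0)
    if low_df:
        T = np.nan
        p = 1.0
    else:
        T = rho * np.sqrt(df) / np.sqrt(max(1.0 - rho * rho, np.finfo(float).tiny))
        p = float(2.0 * stats.t.sf(abs(T), df))
    return ParametricResult(
        rho_hat=rho,
        sigma2_rho=sigma2,
        fallback_used=fallback,
        m_hat=m_hat,
        T=float(T),
        df=df,
        p=p,
        variant=variant,
        low_df_warning=low_df,
    )
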