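"""The truncated time-shift (TTS) test engine.

Given two equal-length series x and y, the test deletes r points from each
end of x to form a truncated window, slides y across it by every shift
delta in [-r, r] (delta = 0 being the original alignment), and computes a
correlation statistic for each alignment. With

    B = number of shifts whose correlation is at least as strong as the
        unshifted one (so 1 <= B <= 2r + 1),

the test statistic is

    u = B / (r + 1).

Under the null hypothesis that x and y are independent, and assuming only
that the shifted series is strict-sense stationary, P(u <= alpha) <= alpha:
u is superuniform and can be thresholded like a p-value (it may exceed 1;
min(u, 1) is reported alongside). The naive alternative B/(2r+1) is not a
valid p-value -- the shifted surrogates are mutually dependent -- but its
false positive rate is inflated by less than a factor of 2, since
u / p_naive = (2r+1)/(r+1) < 2.

Power levers implemented here: the radius lattice r = j*m/alpha - 1 that
makes the significance threshold exactly attainable; lag pre-shifting for
hypothesized coupling delays; a Bonferroni multi-lag test; and a
detrend-retrend variant for trend-nonstationary surrogate sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigError,
    InsufficientDataError,
    InvalidLagError,
    InvalidRadiusError,
    InvalidShiftError,
    TTSError,
)
from .series import Series
from .statistics import HIGHER_STRONGER, StatisticSpec


class LargeRadiusWarning(UserWarning):
    """Truncation radius is a large fraction of the series length.

    The test then probes dependence between y and a short central x window
    only; dependence carried by the discarded ends would go undetected.
    """


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def truncate(x: Series, r: int) -> Series:
    """Delete r time points from each end: {x_{1+r}, ..., x_{n-r}}."""
    if r < 0:
        raise InvalidRadiusError(f"radius must be nonnegative, got {r}")
    if x.n <= 2 * r:
        raise InvalidRadiusError(f"need n > 2r, got n={x.n}, r={r}")
    return x.window(r, x.n - r)


def shifted_window(y: Series, r: int, delta: int) -> Series:
    """The length n-2r window {y_{1+r+delta}, ..., y_{n-r+delta}}.

    delta = 0 is the original alignment; |delta| <= r keeps the window
    inside the series.
    """
    if abs(delta) > r:
        raise InvalidShiftError(f"|delta|={abs(delta)} exceeds radius r={r}")
    if y.n <= 2 * r:
        raise InvalidRadiusError(f"need n > 2r, got n={y.n}, r={r}")
    return y.window(r + delta, y.n - r + delta)


def lag_preshift(x: Series, y: Series, l: int) -> tuple[Series, Series]:
    """Pre-shift for the lag-l test.

    l >= 0 pairs {x_{1+l}, ..., x_n} with {y_1, ..., y_{n-l}}; l < 0 is the
    mirror image. Both outputs have length n - |l|.
    """
    n = x.n
    if y.n != n:
        raise TTSError("series must have equal length")
    if abs(l) >= n:
        raise InvalidLagError(f"|l|={abs(l)} >= n={n} leaves no overlap")
    if l == 0:
        return x, y
    if l > 0:
        return x.window(l, n), y.window(0, n - l)
    return x.window(0, n + l), y.window(-l, n)


# ---------------------------------------------------------------------------
# Profile and counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftProfile:
    """Correlations theta(delta) for delta = -r..r.

    ``theta[r]`` (the centre) is the unshifted correlation theta_0.
    """

    r: int
    theta: np.ndarray
    orientation: str

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (2 * self.r + 1,):
            raise TTSError(
                f"profile needs 2r+1 = {2 * self.r + 1} values, got {theta.shape}"
            )
        object.__setattr__(self, "theta", theta)

    @property
    def shifts(self) -> np.ndarray:
        return np.arange(-self.r, self.r + 1)

    @property
    def theta0(self) -> float:
        return float(self.theta[self.r])


def _profile_pearson_fast(
    xw: np.ndarray, ysrc: np.ndarray, r: int
) -> np.ndarray:
    """Vectorized |Pearson| profile for a univariate pair.

    ``xw`` is the fixed truncated window (length L), ``ysrc`` the full
    shifted-series values (length L + 2r); row delta+r of the sliding-view
    matrix is the window at shift delta.
    """
    L = xw.size
    win = np.lib.stride_tricks.sliding_window_view(ysrc, L)  # (2r+1, L)
    xc = xw - xw.mean()
    wc = win - win.mean(axis=1, keepdims=True)
    vx = float(xc @ xc)
    vw = np.einsum("ij,ij->i", wc, wc)
    if vx == 0.0 or np.any(vw == 0.0):
        bad = int(np.nonzero(vw == 0.0)[0][0]) - r if vx != 0.0 else 0
        from .errors import DegenerateWindowError

        raise DegenerateWindowError(
            f"zero-variance window in Pearson profile (shift delta={bad})"
        )
    return np.abs(wc @ xc) / np.sqrt(vx * vw)


def shift_profile(
    x: Series, y: Series, r: int, stat: StatisticSpec, shift: str = "y"
) -> ShiftProfile:
    """Compute theta(delta) = stat(x_trunc, y_trunc(delta)) for delta in -r..r.

    ``shift`` selects which series is slid across the other ("y" by
    default); the statistic always receives its arguments in (x, y) order.
    A statistic failure is re-raised with the offending shift identified.
    """
    if x.n != y.n:
        raise TTSError("series must have equal length")
    if shift not in ("x", "y"):
        raise TTSError("shift must be 'x' or 'y'")
    if (
        stat.name == "pearson"
        and x.is_univariate
        and y.is_univariate
        and x.n - 2 * r >= 3
    ):
        if shift == "y":
            theta = _profile_pearson_fast(truncate(x, r).as_1d(), y.as_1d(), r)
        else:
            theta = _profile_pearson_fast(truncate(y, r).as_1d(), x.as_1d(), r)
        return ShiftProfile(r=r, theta=theta, orientation=stat.orientation)
    theta = np.empty(2 * r + 1)
    for i, delta in enumerate(range(-r, r + 1)):
        if shift == "y":
            args = (truncate(x, r), shifted_window(y, r, delta))
        else:
            args = (shifted_window(x, r, delta), truncate(y, r))
        try:
            theta[i] = stat(*args)
        except TTSError as exc:
            raise type(exc)(f"{exc} (shift delta={delta})") from exc
    return ShiftProfile(r=r, theta=theta, orientation=stat.orientation)


def count_B(profile: ShiftProfile) -> int:
    """Number of shifts at least as strong as the unshifted correlation.

    Comparison is exact (no tolerance): floating-point ties count as ties,
    which inflates B and is therefore conservative. delta = 0 always
    counts, so B >= 1.
    """
    t0 = profile.theta0
    if profile.orientation == HIGHER_STRONGER:
        return int(np.sum(profile.theta >= t0))
    return int(np.sum(profile.theta <= t0))


def _check_B(B: int, r: int) -> None:
    if not 1 <= B <= 2 * r + 1:
        raise TTSError(f"B={B} outside [1, 2r+1] for r={r}")


def u_statistic(B: int, r: int) -> float:
    """u = B/(r+1); superuniform under the null, may exceed 1."""
    _check_B(B, r)
    return B / (r + 1)


def naive_p(B: int, r: int) -> float:
    """The naive time-shift p-value B/(2r+1) (not valid; < 2x anticonservative)."""
    _check_B(B, r)
    return B / (2 * r + 1)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTSResult:
    """Outcome of one TTS test."""

    B: int
    r: int
    u: float
    p_reported: float
    lag: int
    alpha: float
    reject: bool
    statistic: str
    orientation: str
    surrogate_from: str
    profile: ShiftProfile

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "r": self.r,
            "u": self.u,
            "p": self.p_reported,
            "lag": self.lag,
            "alpha": self.alpha,
            "reject": self.reject,
            "statistic": self.statistic,
            "orientation": self.orientation,
            "surrogate_from": self.surrogate_from,
            "shifts": self.profile.shifts.tolist(),
            "theta": self.profile.theta.tolist(),
        }


def _finalize(
    profile: ShiftProfile,
    r: int,
    lag: int,
    alpha: float,
    stat: StatisticSpec,
    surrogate_from: str,
) -> TTSResult:
    B = count_B(profile)
    u = u_statistic(B, r)
    return TTSResult(
        B=B,
        r=r,
        u=u,
        p_reported=min(u, 1.0),
        lag=lag,
        alpha=alpha,
        reject=u <= alpha,
        statistic=stat.name,
        orientation=stat.orientation,
        surrogate_from=surrogate_from,
        profile=profile,
    )


def _validate_pair(x: Series, y: Series, r: int) -> None:
    x.require_complete()
    y.require_complete()
    if x.n != y.n:
        raise TTSError("series must have equal length")
    if x.n < 3:
        raise InsufficientDataError("need at least 3 time points")
    if x.n <= 2 * r:
        raise InvalidRadiusError(f"need n > 2r after lag pre-shift (n={x.n}, r={r})")
    if r > x.n / 3:
        warnings.warn(
            f"r={r} exceeds a third of the series length n={x.n}; only a short "
            "central x window is being tested",
            LargeRadiusWarning,
            stacklevel=3,
        )


def tts_test(
    x: Series,
    y: Series,
    r: int,
    stat: StatisticSpec,
    l: int = 0,
    alpha: float = 0.05,
    surrogate_from: str = "y",
) -> TTSResult:
    """Run the (lag-l) TTS test.

    The series named by ``surrogate_from`` is the one being shifted, and is
    the one whose stationarity underwrites validity. The lag ``l`` must be
    hypothesized a priori, never estimated from the tested data.
    """
    if surrogate_from not in ("x", "y"):
        raise TTSError("surrogate_from must be 'x' or 'y'")
    xl, yl = lag_preshift(x, y, l)
    _validate_pair(xl, yl, r)
    profile = shift_profile(xl, yl, r, stat, shift=surrogate_from)
    return _finalize(profile, r, l, alpha, stat, surrogate_from)


@dataclass(frozen=True)
class MultiLagResult:
    """Bonferroni multi-lag test: reject iff any per-lag u <= alpha/m."""

    lags: tuple[int, ...]
    per_lag: tuple[TTSResult, ...]
    alpha: float
    reject: bool

    @property
    def min_u(self) -> float:
        return min(res.u for res in self.per_lag)


def multi_lag_tts(
    x: Series,
    y: Series,
    r: int,
    stat: StatisticSpec,
    lags: Sequence[int],
    alpha: float = 0.05,
    surrogate_from: str = "y",
) -> MultiLagResult:
    """Lag-l TTS tests over a lag set with Bonferroni correction alpha/m."""
    lags = tuple(int(l) for l in lags)
    if len(set(lags)) != len(lags):
        raise ConfigError(f"duplicate lags in {lags}")
    if not lags:
        raise ConfigError("need at least one lag")
    m = len(lags)
    per = tuple(
        tts_test(x, y, r, stat, l=l, alpha=alpha / m, surrogate_from=surrogate_from)
        for l in lags
    )
    return MultiLagResult(
        lags=lags, per_lag=per, alpha=alpha, reject=any(res.reject for res in per)
    )


# ---------------------------------------------------------------------------
# Radius selection
# ---------------------------------------------------------------------------

def optimal_radius(alpha: float, m: int = 1, j: int = 1) -> int:
    """Power-maximizing radius lattice r = j*m/alpha - 1.

    At these radii the rejection region {u <= alpha} is exactly attainable;
    radii between lattice points waste data without easing the threshold.
    If j*m/alpha is not an integer the result is rounded to the nearest
    integer with a warning.
    """
    if not 0.0 < alpha < 1.0:
        raise TTSError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1 or j < 1:
        raise TTSError("m and j must be positive integers")
    raw = j * m / alpha - 1.0
    r = int(round(raw))
    if abs(raw - r) > 1e-9:
        warnings.warn(
            f"j*m/alpha = {j * m / alpha} is not an integer; rounding r to {r}",
            UserWarning,
            stacklevel=2,
        )
    return r


def default_radius(n: int, alpha: float, m: int = 1) -> int:
    """Largest lattice radius j*m/alpha - 1 at most n/5, but at least m/alpha - 1.

    Implements the small-radius guideline (r below ~20% of the series
    length performs well for short series) on the exact lattice. Raises
    when the series cannot even accommodate j = 1.
    """
    r_min = optimal_radius(alpha, m=m, j=1)
    if n <= 2 * r_min:
        raise InsufficientDataError(
            f"series of length {n} too short for m={m}, alpha={alpha}; "
            f"need at least {2 * r_min + 1} points"
        )
    step = m / alpha
    j = max(1, int((n // 5 + 1) // step))
    r = optimal_radius(alpha, m=m, j=j)
    if r > n // 5:
        r = r_min
    return r


# ---------------------------------------------------------------------------
# Detrend-retrend variant
# ---------------------------------------------------------------------------

def polynomial_trend(degree: int = 1) -> Callable[[Series], np.ndarray]:
    """OLS polynomial trend fitter, applied per feature row."""

    def fit(s: Series) -> np.ndarray:
        t = np.arange(s.n, dtype=float)
        out = np.empty_like(s.values)
        for i, row in enumerate(s.values):
            coeffs = np.polynomial.polynomial.polyfit(t, row, degree)
            out[i] = np.polynomial.polynomial.polyval(t, coeffs)
        return out

    return fit


def detrend_retrend_tts(
    x: Series,
    y: Series,
    r: int,
    stat: StatisticSpec,
    trend_fitter: Callable[[Series], np.ndarray] | None = None,
    alpha: float = 0.05,
) -> TTSResult:
    """TTS test with surrogates built from a detrended y.

    A deterministic trend T(t) is fit to y; surrogates are the shifted
    windows of the residual e = y - T with the truncated trend added back,
    so each surrogate inherits the original trend while the shifting acts
    on the (assumed stationary) residual. The delta = 0 surrogate is the
    original truncated y.
    """
    x.require_complete()
    y.require_complete()
    _validate_pair(x, y, r)
    fitter = trend_fitter or polynomial_trend(1)
    trend = np.asarray(fitter(y), dtype=float)
    if trend.shape != y.values.shape:
        raise TTSError(
            f"trend fitter returned shape {trend.shape}, expected {y.values.shape}"
        )
    resid = y.values - trend
    n = y.n
    trend_trunc = trend[:, r : n - r]
    xt = truncate(x, r)

    if stat.name == "pearson" and x.is_univariate and y.is_univariate:
        L = n - 2 * r
        win = (
            np.lib.stride_tricks.sliding_window_view(resid[0], L) + trend_trunc[0]
        ).copy()
        win[r] = y.values[0, r : n - r]  # exact original at delta = 0
        xw = xt.as_1d()
        xc = xw - xw.mean()
        wc = win - win.mean(axis=1, keepdims=True)
        vx = float(xc @ xc)
        vw = np.einsum("ij,ij->i", wc, wc)
        if vx == 0.0 or np.any(vw == 0.0):
            from .errors import DegenerateWindowError

            raise DegenerateWindowError("zero-variance window in detrend-retrend test")
        theta = np.abs(wc @ xc) / np.sqrt(vx * vw)
        profile = ShiftProfile(r=r, theta=theta, orientation=stat.orientation)
        return _finalize(profile, r, 0, alpha, stat, "y")

    theta = np.empty(2 * r + 1)
    for i, delta in enumerate(range(-r, r + 1)):
        if delta == 0:
            surr = truncate(y, r)
        else:
            surr = y.with_values(
                resid[:, r + delta : n - r + delta] + trend_trunc
            )
        try:
            theta[i] = stat(xt, surr)
        except TTSError as exc:
            raise type(exc)(f"{exc} (shift delta={delta})") from exc
    profile = ShiftProfile(r=r, theta=theta, orientation=stat.orientation)
    return _finalize(profile, r, 0, alpha, stat, "y")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    Accepts superuniform inputs (u statistics above 1), which are clipped
    at 1 before adjustment.
    """
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(arr < 0):
        raise TTSError("p-values must be nonnegative")
    clipped = np.minimum(arr, 1.0)
    return multipletests(clipped, method="fdr_bh")[1]
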