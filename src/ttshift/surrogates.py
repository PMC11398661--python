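"""Comparator surrogate-data procedures and the classical surrogate p-value.

These are the standard null models the truncated time-shift test is
benchmarked against: cyclic permutation, the stationary block bootstrap,
and iterative amplitude-adjusted Fourier transform (IAAFT) surrogates,
together with the circularization preprocessing that trims a series so its
ends match before wrap-around methods are applied. An iid shuffle is also
provided, mainly to demonstrate how badly a naive permutation test
miscalibrates on autocorrelated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CircularizationError, TTSError
from .series import Series
from .statistics import HIGHER_STRONGER, LOWER_STRONGER, StatisticSpec

_METHODS = ("cyclic", "block_bootstrap", "iaaft", "shuffle")


@dataclass(frozen=True)
class SurrogateSet:
    """A batch of surrogate series produced by one method."""

    method: str
    surrogates: tuple[Series, ...]
    params: dict = field(default_factory=dict)
    seed: int | None = None


def surrogate_pvalue(theta0: float, theta_surr, orientation: str = HIGHER_STRONGER) -> float:
    """Classical surrogate p-value (N_as_strong + 1) / (N_surrogates + 1).

    The +1 terms account for the original correlation; the result lies in
    [1/(N+1), 1] and is superuniform when the surrogates are exchangeable
    with the original.
    """
    arr = np.asarray(list(theta_surr), dtype=float)
    if arr.size == 0:
        raise TTSError("need at least one surrogate correlation")
    if orientation == HIGHER_STRONGER:
        n_ge = int(np.sum(arr >= theta0))
    elif orientation == LOWER_STRONGER:
        n_ge = int(np.sum(arr <= theta0))
    else:
        raise TTSError(f"unknown orientation {orientation!r}")
    return (n_ge + 1) / (arr.size + 1)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def cyclic_permutations(y: Series) -> SurrogateSet:
    """All n-1 nontrivial rotations of the series (deterministic).

    E.g. (1,2,3,4) -> (2,3,4,1), (3,4,1,2), (4,1,2,3).
    """
    n = y.n
    if n < 2:
        raise TTSError("need at least 2 points for cyclic permutation")
    surr = tuple(
        y.with_values(np.roll(y.values, -k, axis=1)) for k in range(1, n)
    )
    return SurrogateSet(method="cyclic", surrogates=surr)


def stationary_block_bootstrap(
    y: Series, p: float = 0.05, seed=None, return_indices: bool = False
):
    """One stationary-bootstrap surrogate (Politis-Romano).

    Starting from a uniform index, each step either restarts at a fresh
    uniform index (probability p) or continues to the next index with
    wrap-around, giving geometric blocks of mean length ~1/p. Output has
    the source length; values are a sub-multiset of the original's.
    """
    if not 0.0 < p <= 1.0:
        raise TTSError(f"restart probability must be in (0, 1], got {p}")
    n = y.n
    rng = np.random.default_rng(seed)
    restart = rng.random(n) < p
    restart[0] = True
    starts = rng.integers(0, n, size=n)
    # index = start of current block + steps since the block began
    block_id = np.cumsum(restart) - 1
    block_start_pos = np.nonzero(restart)[0]
    offsets = np.arange(n) - block_start_pos[block_id]
    idx = (starts[block_start_pos[block_id]] + offsets) % n
    surr = y.with_values(y.values[:, idx])
    if return_indices:
        return surr, idx
    return surr


def iaaft(
    y: Series,
    iterations: int = 200,
    output: str = "true_spectrum",
    seed=None,
) -> Series:
    """Iterative amplitude-adjusted Fourier transform surrogate.

    Starting from a random permutation of the series, alternately (i)
    impose the original Fourier amplitude spectrum while keeping the
    current phases and (ii) rank-remap the values onto the sorted original
    values. After the fixed iteration count, ``true_spectrum`` returns the
    spectrum-matched iterate and ``true_amplitudes`` the value-matched
    (exact permutation) iterate.
    """
    if not y.is_univariate:
        raise TTSError("IAAFT surrogates support univariate series only")
    if output not in ("true_spectrum", "true_amplitudes"):
        raise TTSError(f"unknown output {output!r}")
    vals = y.as_1d()
    n = vals.size
    if n < 4:
        raise TTSError("need at least 4 points for IAAFT")
    rng = np.random.default_rng(seed)
    sorted_vals = np.sort(vals)
    amplitudes = np.abs(np.fft.rfft(vals))
    s = rng.permutation(vals)
    s_spec = s
    for _ in range(iterations):
        phases = np.angle(np.fft.rfft(s))
        s_spec = np.fft.irfft(amplitudes * np.exp(1j * phases), n=n)
        ranks = np.argsort(np.argsort(s_spec, kind="stable"), kind="stable")
        s = sorted_vals[ranks]
    return y.with_values(s_spec if output == "true_spectrum" else s)


# ---------------------------------------------------------------------------
# Circularization
# ---------------------------------------------------------------------------

def circularize(
    x: Series,
    y: Series,
    L: int = 10,
    kmax: int = 40,
    select_on: str = "y",
) -> tuple[Series, Series]:
    """Trim both series so the retained segment's ends match.

    Finds (k_start, k_end), 1-based, minimizing

        sum_{i=0..L} (s_{k2+i} - s_{k1+i})^2

    on the ``select_on`` series s, subject to k1 <= kmax and
    n - L - k2 + 1 <= kmax (both cut points near the respective ends), with
    k2 > k1. Ties resolve to the lexicographically smallest (k1, k2). Both
    series are then truncated to the same 1-based index range
    [k_start, k_end - 1].
    """
    if x.n != y.n:
        raise TTSError("series must have equal length")
    if select_on not in ("x", "y"):
        raise TTSError("select_on must be 'x' or 'y'")
    s = (y if select_on == "y" else x)
    if not s.is_univariate:
        raise TTSError("circularization requires a univariate selection series")
    v = s.as_1d()
    n = s.n
    best = None
    best_pair = None
    # 1-based k with window k..k+L requires k + L <= n
    k2_lo = max(2, n - L - kmax + 1)
    for k1 in range(1, min(kmax, n - L) + 1):
        seg1 = v[k1 - 1 : k1 - 1 + L + 1]
        for k2 in range(max(k2_lo, k1 + 1), n - L + 1):
            seg2 = v[k2 - 1 : k2 - 1 + L + 1]
            mismatch = float(np.sum((seg2 - seg1) ** 2))
            if best is None or mismatch < best:
                best = mismatch
                best_pair = (k1, k2)
    if best_pair is None:
        raise CircularizationError(
            f"no feasible (k1, k2) pair for n={n}, L={L}, kmax={kmax}"
        )
    k_start, k_end = best_pair
    return x.window(k_start - 1, k_end - 1), y.window(k_start - 1, k_end - 1)


# ---------------------------------------------------------------------------
# Test driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateTestResult:
    """Outcome of one surrogate-data test."""

    p: float
    theta0: float
    theta_surr: np.ndarray
    method: str
    statistic: str
    orientation: str
    n_surrogates: int
    circularized: bool
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "theta0": self.theta0,
            "method": self.method,
            "statistic": self.statistic,
            "orientation": self.orientation,
            "n_surrogates": self.n_surrogates,
            "circularized": self.circularized,
            "seed": self.seed,
            "theta_surr": self.theta_surr.tolist(),
        }


def surrogate_test(
    x: Series,
    y: Series,
    method: str,
    stat: StatisticSpec,
    n_surrogates: int = 499,
    seed=None,
    circularize_first: bool = False,
) -> SurrogateTestResult:
    """Surrogate-data test: surrogates of y against the fixed x.

    ``method`` is one of cyclic, block_bootstrap, iaaft, shuffle. The
    cyclic method is exhaustive and ignores ``n_surrogates``. When
    ``circularize_first`` is set, both series are circularized (cut points
    selected on y, the surrogate source) before anything else, and both
    original and surrogate correlations use the circularized series.
    """
    if method not in _METHODS:
        raise TTSError(f"unknown method {method!r}; choose from {_METHODS}")
    x.require_complete()
    y.require_complete()
    if circularize_first:
        x, y = circularize(x, y, select_on="y")
    theta0 = stat(x, y)
    ss = np.random.SeedSequence(seed)
    if method == "cyclic":
        surrs = cyclic_permutations(y).surrogates
    elif method == "block_bootstrap":
        surrs = tuple(
            stationary_block_bootstrap(y, seed=child)
            for child in ss.spawn(n_surrogates)
        )
    elif method == "iaaft":
        surrs = tuple(iaaft(y, seed=child) for child in ss.spawn(n_surrogates))
    else:  # shuffle: iid permutation (invalid for autocorrelated data)
        surrs = tuple(
            y.with_values(
                y.values[:, np.random.default_rng(child).permutation(y.n)]
            )
            for child in ss.spawn(n_surrogates)
        )
    theta_surr = np.array([stat(x, s) for s in surrs])
    p = surrogate_pvalue(theta0, theta_surr, stat.orientation)
    return SurrogateTestResult(
        p=p,
        theta0=float(theta0),
        theta_surr=theta_surr,
        method=method,
        statistic=stat.name,
        orientation=stat.orientation,
        n_surrogates=len(surrs),
        circularized=circularize_first,
        seed=seed if isinstance(seed, int) else None,
    )
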