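"""Pluggable correlation statistics.

The time-shift engine is agnostic to the notion of "correlation": any pure
function of two equal-length windows can be used. This module provides the
statistics used throughout the benchmark and application suites:

* Pearson correlation strength (|r|), the linear workhorse;
* the Kraskov-Stoegbauer-Grassberger k-nearest-neighbour mutual information
  estimator (estimator I^(1)), with arbitrary marginal metrics, including a
  circular (angular) metric for directional data;
* local similarity (LSA), a dynamic-programming statistic for transient
  associations, popular in microbial ecology;
* cross-map skill, the delay-embedding prediction statistic from empirical
  dynamic modelling;
* median-over-shared-features aggregation for feature-by-time tables;
* small helpers: the |sin| transform for directional data, and gap filling.

Each statistic is wrapped in a :class:`StatisticSpec` carrying an
orientation flag: ``higher_stronger`` for similarity-like statistics and
``lower_stronger`` for error-like statistics (e.g. an MSE), so the engine
can invert comparisons instead of negating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.special import digamma
from scipy.stats import norm, rankdata

from .errors import (
    CannotFillError,
    DegenerateWindowError,
    InsufficientDataError,
    NoSharedFeaturesError,
    TTSError,
)
from .series import Series

HIGHER_STRONGER = "higher_stronger"
LOWER_STRONGER = "lower_stronger"


@dataclass(frozen=True)
class StatisticSpec:
    """A named correlation statistic with an orientation flag.

    ``func`` maps two :class:`Series` windows to a float and must be a pure
    function of its inputs (no hidden state); deterministic tie-breaking is
    by lowest index throughout.
    """

    name: str
    func: Callable[[Series, Series], float]
    orientation: str = HIGHER_STRONGER
    params: dict = field(default_factory=dict)
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER_STRONGER, LOWER_STRONGER):
            raise TTSError(f"unknown orientation {self.orientation!r}")

    def __call__(self, x: Series, y: Series) -> float:
        return float(self.func(x, y))


# ---------------------------------------------------------------------------
# Pearson correlation strength
# ---------------------------------------------------------------------------

def pearson_strength(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute value of the sample Pearson correlation coefficient.

    Raises :class:`DegenerateWindowError` when either window has zero
    variance (the coefficient is undefined there, and the shift engine
    reports which shift failed).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise TTSError("windows must have equal length")
    if a.size < 3:
        raise InsufficientDataError("Pearson correlation needs at least 3 points")
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(ac @ ac)
    vb = float(bc @ bc)
    if va == 0.0 or vb == 0.0:
        raise DegenerateWindowError("zero-variance window in Pearson correlation")
    return abs(float(ac @ bc) / np.sqrt(va * vb))


# ---------------------------------------------------------------------------
# k-nearest-neighbour mutual information (Kraskov estimator I^(1))
# ---------------------------------------------------------------------------

def _as_points(a: np.ndarray) -> np.ndarray:
    """Coerce input to an (N, d) sample-major array."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        return a[:, np.newaxis]
    if a.ndim != 2:
        raise TTSError("mutual-information input must be 1-D or 2-D")
    return a


def euclidean_pairwise(a: np.ndarray) -> np.ndarray:
    """Full Euclidean pairwise-distance matrix for (N, d) points."""
    return cdist(a, a)


def angular_distance(alpha, beta):
    """Distance between angles on the circle: arccos(cos(alpha - beta)).

    Maps any pair of real angles to [0, pi]; e.g. 0.1*pi and 1.9*pi are
    0.2*pi apart, not 1.8*pi.
    """
    d = np.cos(np.asarray(alpha, dtype=float) - np.asarray(beta, dtype=float))
    return np.arccos(np.clip(d, -1.0, 1.0))


def angular_pairwise(a: np.ndarray) -> np.ndarray:
    """Pairwise angular-distance matrix for a vector of angles (radians)."""
    v = np.asarray(a, dtype=float).ravel()
    return angular_distance(v[:, np.newaxis], v[np.newaxis, :])


def mi_knn(
    a: np.ndarray,
    b: np.ndarray,
    k: int = 3,
    metric_a: Callable[[np.ndarray], np.ndarray] | None = None,
    metric_b: Callable[[np.ndarray], np.ndarray] | None = None,
    jitter: float = 0.0,
    seed: int | None = None,
) -> float:
    """KSG mutual information estimator I^(1), in nats.

    The joint space uses the maximum of the two marginal distances. For
    each point the distance eps_i to its k-th joint neighbour is found, and
    n_a, n_b count marginal points strictly within eps_i; then

        I = psi(k) + psi(N) - < psi(n_a + 1) + psi(n_b + 1) >.

    ``metric_a`` / ``metric_b`` map an (N, d) array of points to an (N, N)
    pairwise-distance matrix; the default is Euclidean. ``jitter`` > 0 adds
    seeded uniform noise of that magnitude to break exact duplicates
    (off by default; the benchmark systems are continuous).
    """
    pa = _as_points(a)
    pb = _as_points(b)
    n = pa.shape[0]
    if pb.shape[0] != n:
        raise TTSError("mutual-information inputs must have equal sample counts")
    if n <= k:
        raise InsufficientDataError(f"need more than k={k} samples, got {n}")
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        pa = pa + rng.uniform(-jitter, jitter, size=pa.shape)
        pb = pb + rng.uniform(-jitter, jitter, size=pb.shape)
    da = (metric_a or euclidean_pairwise)(pa)
    db = (metric_b or euclidean_pairwise)(pb)
    dj = np.maximum(da, db)
    np.fill_diagonal(dj, np.inf)
    # k-th joint neighbour distance per point (self excluded via inf)
    eps = np.partition(dj, k - 1, axis=1)[:, k - 1]
    # marginal counts strictly within eps, excluding the point itself
    na = (da < eps[:, np.newaxis]).sum(axis=1) - 1
    nb = (db < eps[:, np.newaxis]).sum(axis=1) - 1
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(na + 1) + digamma(nb + 1))
    )


def mi_circular(speed: np.ndarray, direction: np.ndarray, k: int = 3) -> float:
    """MI between a linear variable and a circular one (angles in radians).

    Euclidean distance on the linear marginal, angular distance on the
    circular marginal.
    """
    return mi_knn(
        np.asarray(speed, dtype=float).ravel(),
        np.asarray(direction, dtype=float).ravel(),
        k=k,
        metric_a=euclidean_pairwise,
        metric_b=angular_pairwise,
    )


# ---------------------------------------------------------------------------
# Local similarity
# ---------------------------------------------------------------------------

def _normal_scores(v: np.ndarray) -> np.ndarray:
    """Rank -> Gaussian quantile transform, ties broken by average rank."""
    n = v.size
    return norm.ppf(rankdata(v, method="average") / (n + 1))


def local_similarity(a: np.ndarray, b: np.ndarray, D: int = 0) -> float:
    """Local similarity (LSA) score between two series.

    Both series are normal-score transformed; the score is

        (1/n) * max over |d| <= D, over contiguous intervals
                 | sum_t z_a[t] * z_b[t + d] |,

    computed by the standard dynamic program over maximal positive and
    negative partial sums. Symmetric under negating either input.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = a.size
    if b.size != n:
        raise TTSError("windows must have equal length")
    if n < 3:
        raise InsufficientDataError("local similarity needs at least 3 points")
    if D < 0 or D >= n:
        raise TTSError(f"delay bound D={D} outside [0, n)")
    za = _normal_scores(a)
    zb = _normal_scores(b)
    best = 0.0
    for d in range(-D, D + 1):
        if d >= 0:
            prod = za[: n - d] * zb[d:]
        else:
            prod = za[-d:] * zb[: n + d]
        pos = neg = 0.0
        for p in prod:
            pos = max(0.0, pos + p)
            neg = max(0.0, neg - p)
            best = max(best, pos, neg)
    return best / n


# ---------------------------------------------------------------------------
# Cross-map skill
# ---------------------------------------------------------------------------

def cross_map_skill(x: np.ndarray, y: np.ndarray, E: int = 2, tau: int = 1) -> float:
    """Simplex cross-map skill: predict y from the delay embedding of x.

    The embedding of x with dimension E and lag tau has n - (E-1)*tau
    points. Each point's E+1 nearest neighbours (self excluded) give
    exponential weights w_i = exp(-d_i/d_1) (indicator weights on
    zero-distance neighbours when d_1 = 0), and the contemporaneous y is
    predicted as their weighted mean. The skill is the Pearson correlation
    between predictions and observations. High skill when y drives x, by
    the usual cross-mapping logic.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise TTSError("windows must have equal length")
    if E < 1 or tau < 1:
        raise TTSError("need E >= 1 and tau >= 1")
    if n <= (E - 1) * tau + E + 2:
        raise InsufficientDataError(
            f"need n > (E-1)*tau + E + 2 = {(E - 1) * tau + E + 2}, got {n}"
        )
    offset = (E - 1) * tau
    m = n - offset
    # embedding: row i is (x[t], x[t-tau], ..., x[t-(E-1)tau]), t = offset + i
    emb = np.column_stack([x[offset - j * tau : n - j * tau] for j in range(E)])
    obs = y[offset:]
    k = E + 1
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=k + 1)
    preds = np.empty(m)
    for i in range(m):
        di, ii = dist[i], idx[i]
        # drop self: prefer the entry that is literally index i
        self_pos = np.nonzero(ii == i)[0]
        drop = self_pos[0] if self_pos.size else 0
        di = np.delete(di, drop)[:k]
        ii = np.delete(ii, drop)[:k]
        d1 = di[0]
        if d1 == 0.0:
            w = (di == 0.0).astype(float)
            if not w.any():  # unreachable, kept for safety
                w = np.ones(k)
        else:
            w = np.exp(-di / d1)
        preds[i] = float(w @ obs[ii] / w.sum())
    pc = preds - preds.mean()
    oc = obs - obs.mean()
    vp = float(pc @ pc)
    vo = float(oc @ oc)
    if vp == 0.0 or vo == 0.0:
        raise DegenerateWindowError("constant predictions or observations in cross map")
    return float(pc @ oc) / np.sqrt(vp * vo)


# ---------------------------------------------------------------------------
# Feature-table aggregation, transforms, gap filling
# ---------------------------------------------------------------------------

def median_feature_statistic(X: Series, Y: Series, base: StatisticSpec) -> float:
    """Median of the base statistic over features shared by ID between X and Y.

    With an even number of shared features the convention is the mean of
    the two central order statistics (numpy's median).
    """
    ids_x = X.feature_ids or ("f0",)
    ids_y = Y.feature_ids or ("f0",)
    shared = [i for i in ids_x if i in set(ids_y)]
    if not shared:
        raise NoSharedFeaturesError("no shared feature IDs between the two tables")
    lookup_x = {fid: row for fid, row in zip(ids_x, X.values)}
    lookup_y = {fid: row for fid, row in zip(ids_y, Y.values)}
    vals = [
        base(Series(lookup_x[fid], label=fid), Series(lookup_y[fid], label=fid))
        for fid in shared
    ]
    return float(np.median(vals))


def sin_mod_transform(phi: np.ndarray) -> np.ndarray:
    """Elementwise |sin(phi)| for angles in radians.

    Maps direction to [0, 1]: largest for motion at 90/270 degrees
    (tangential), smallest at 0/180 degrees (radial), making a linear
    correlation with e.g. speed meaningful.
    """
    return np.abs(np.sin(np.asarray(phi, dtype=float)))


def gap_fill(s: Series, method: str = "linear", seed: int | None = None) -> Series:
    """Fill internal NaN gaps by linear interpolation or seeded resampling.

    ``linear`` draws a straight line across each internal gap; ``resample``
    replaces each missing value with a uniform draw from that feature's
    observed values. Leading/trailing gaps must be trimmed beforehand.
    """
    if method not in ("linear", "resample"):
        raise TTSError(f"unknown gap-fill method {method!r}")
    vals = s.values.copy()
    rng = np.random.default_rng(seed)
    for i, row in enumerate(vals):
        mask = np.isnan(row)
        if not mask.any():
            continue
        if mask.all():
            raise CannotFillError(f"feature {i} has no observed values")
        if mask[0] or mask[-1]:
            raise CannotFillError(
                "leading/trailing gaps must be trimmed before gap filling"
            )
        obs_idx = np.nonzero(~mask)[0]
        if method == "linear":
            row[mask] = np.interp(np.nonzero(mask)[0], obs_idx, row[obs_idx])
        else:
            row[mask] = rng.choice(row[obs_idx], size=int(mask.sum()), replace=True)
    return s.with_values(vals)


# ---------------------------------------------------------------------------
# Named specs and registry (CLI / config addressing)
# ---------------------------------------------------------------------------

def _univariate(fn, **kw):
    def wrapped(xs: Series, ys: Series) -> float:
        return fn(xs.as_1d(), ys.as_1d(), **kw)

    return wrapped


def pearson_spec() -> StatisticSpec:
    return StatisticSpec(
        "pearson", _univariate(pearson_strength), HIGHER_STRONGER, {}, symmetric=True
    )


def mi_spec(k: int = 3) -> StatisticSpec:
    def fn(xs: Series, ys: Series) -> float:
        return mi_knn(xs.values.T, ys.values.T, k=k)

    return StatisticSpec("mi", fn, HIGHER_STRONGER, {"k": k}, symmetric=True)


def mi_circular_spec(k: int = 3) -> StatisticSpec:
    """MI where the first series is linear (speed) and the second circular."""
    return StatisticSpec(
        "mi-circular",
        _univariate(mi_circular, k=k),
        HIGHER_STRONGER,
        {"k": k},
        symmetric=False,
    )


def lsa_spec(D: int = 0) -> StatisticSpec:
    return StatisticSpec(
        "lsa", _univariate(local_similarity, D=D), HIGHER_STRONGER, {"D": D},
        symmetric=True,
    )


def ccm_spec(E: int = 2, tau: int = 1) -> StatisticSpec:
    """Cross-map skill, x used to estimate y (appropriate when y drives x)."""
    return StatisticSpec(
        "ccm", _univariate(cross_map_skill, E=E, tau=tau), HIGHER_STRONGER,
        {"E": E, "tau": tau}, symmetric=False,
    )


def median_pearson_spec() -> StatisticSpec:
    base = pearson_spec()

    def fn(xs: Series, ys: Series) -> float:
        return median_feature_statistic(xs, ys, base)

    return StatisticSpec("median-pearson", fn, HIGHER_STRONGER, {}, symmetric=True)


def median_lsa_spec(D: int = 0) -> StatisticSpec:
    base = lsa_spec(D=D)

    def fn(xs: Series, ys: Series) -> float:
        return median_feature_statistic(xs, ys, base)

    return StatisticSpec("median-lsa", fn, HIGHER_STRONGER, {"D": D}, symmetric=True)


_REGISTRY: dict[str, Callable[..., StatisticSpec]] = {
    "pearson": pearson_spec,
    "mi": mi_spec,
    "mi-circular": mi_circular_spec,
    "lsa": lsa_spec,
    "ccm": ccm_spec,
    "median-pearson": median_pearson_spec,
    "median-lsa": median_lsa_spec,
}


def make_statistic(name: str, **params) -> StatisticSpec:
    """Build a named statistic, e.g. ``make_statistic("mi", k=3)``."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise TTSError(
            f"unknown statistic {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    return factory(**params)
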