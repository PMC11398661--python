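"""Seeded generators for the benchmark systems.

These are the ground-truth processes used to measure calibration (false
positive rate on independent pairs) and power (rejection rate on coupled
pairs). The stationary set spans linear-Gaussian (AR(1)), deterministic
chaos (logistic map), periodic-plus-noise constructions with random phase
(the random phase is what makes them stationary), a latent-state binary
process, a growth/collapse population with a random observation offset,
and two nonlinear models (stochastic FitzHugh-Nagumo, chaotic 4-species
competitive Lotka-Volterra). Two nonstationary controls are included: a
Gaussian random walk and a trended AR(1).

All generators accept ``seed`` as anything ``numpy.random.default_rng``
takes (int, SeedSequence, Generator) and are exactly reproducible under a
fixed seed. Independent pairs are produced by two calls with independent
seeds; no state is shared.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .errors import SimulationError, TTSError
from .series import Series


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Univariate benchmark systems
# ---------------------------------------------------------------------------

def simulate_ar1(
    n: int,
    phi: float = 0.5,
    sigma: float = 1.0,
    trend_slope: float = 0.0,
    seed=None,
    allow_nonstationary: bool = False,
) -> Series:
    """AR(1): x_t = phi*x_{t-1} + eps_t + trend_slope*t, eps ~ N(0, sigma^2).

    With zero trend the chain is started from its stationary marginal
    N(0, sigma^2/(1-phi^2)), so the whole path is stationary. A nonzero
    ``trend_slope`` gives the trended (nonstationary) variant.
    """
    if abs(phi) >= 1 and not allow_nonstationary:
        raise TTSError(f"|phi|={abs(phi)} >= 1 is nonstationary; opt in explicitly")
    if sigma <= 0:
        raise TTSError("sigma must be positive")
    rng = _rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    if abs(phi) < 1:
        x0 = rng.normal(0.0, sigma / np.sqrt(1.0 - phi * phi))
    else:
        x0 = 0.0
    drive = eps.copy()
    drive[0] += phi * x0
    x = lfilter([1.0], [1.0, -phi], drive)
    if trend_slope != 0.0:
        # the trend term enters the recursion, like any other input
        t = np.arange(1, n + 1, dtype=float)
        x = x + lfilter([1.0], [1.0, -phi], trend_slope * t)
    return Series(x, label="ar1")


def simulate_logistic(
    n: int,
    growth: float = 3.8,
    x0: float | None = None,
    seed=None,
    burn_in: int | None = None,
) -> Series:
    """Logistic map x_{t+1} = growth * x_t * (1 - x_t) on [0, 1].

    Deterministic given x0 (the series then starts exactly at x0). When x0
    is unset it is drawn uniformly on (0, 1) and a short burn-in (default
    100) settles the orbit onto the attractor.
    """
    if not 0.0 < growth <= 4.0:
        raise TTSError(f"growth must be in (0, 4], got {growth}")
    if burn_in is None:
        burn_in = 100 if x0 is None else 0
    if x0 is None:
        x0 = float(_rng(seed).uniform(0.0, 1.0))
    elif not 0.0 <= x0 <= 1.0:
        raise TTSError(f"x0 must be in [0, 1], got {x0}")
    total = n + burn_in
    x = np.empty(total)
    v = x0
    for t in range(total):
        x[t] = v
        v = growth * v * (1.0 - v)
        if not 0.0 <= v <= 1.0:
            raise SimulationError(f"logistic orbit escaped [0,1] at step {t}")
    return Series(x[burn_in:], label="logistic")


def simulate_sine_sawtooth_noise(
    n: int,
    period: float = 20.0,
    noise_amp: float = 0.5,
    sawtooth_period: float = 200.0,
    seed=None,
) -> Series:
    """Random-phase sine with noise modulated by a random-phase sawtooth.

    x_t = sin(2 pi t / period + phase) + noise_amp * s_t * eps_t where s_t
    is a slow sawtooth in [0, 1) with its own random phase. The two random
    phases, drawn per realization, make the process stationary. With
    noise_amp = 0 this reduces to a pure random-phase sine.
    """
    rng = _rng(seed)
    t = np.arange(n, dtype=float)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    base = np.sin(2.0 * np.pi * t / period + phase)
    if noise_amp == 0.0:
        return Series(base, label="sine_sawtooth")
    saw_phase = rng.uniform(0.0, 1.0)
    saw = np.mod(t / sawtooth_period + saw_phase, 1.0)
    noise = noise_amp * saw * rng.normal(size=n)
    return Series(base + noise, label="sine_sawtooth")


def simulate_sine_threshold_noise(
    n: int,
    period: float = 20.0,
    threshold: float = 0.0,
    noise_sigma: float = 0.25,
    seed=None,
) -> Series:
    """Random-phase sine with a detection threshold and measurement noise.

    Values below ``threshold`` are clipped to it (a detector floor), then
    Gaussian measurement noise is added.
    """
    rng = _rng(seed)
    t = np.arange(n, dtype=float)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    base = np.maximum(np.sin(2.0 * np.pi * t / period + phase), threshold)
    return Series(base + noise_sigma * rng.normal(size=n), label="sine_threshold")


def simulate_autocorrelated_coin(
    n: int,
    phi: float = 0.9,
    latent_sigma: float = 0.5,
    noise_sigma: float = 0.1,
    q: float | None = None,
    seed=None,
) -> Series:
    """Coin flips whose heads probability varies in a stationary way.

    A latent stationary AR(1) is squashed through the logistic function to
    give q_t in (0, 1); the observation is Bernoulli(q_t) coded 1/0 plus
    Gaussian measurement noise. Passing a constant ``q`` overrides the
    latent process (q = 0.5, noise 0 gives an iid fair coin).
    """
    rng = _rng(seed)
    if q is not None:
        if not 0.0 <= q <= 1.0:
            raise TTSError("q must be in [0, 1]")
        qt = np.full(n, float(q))
    else:
        latent = simulate_ar1(n, phi=phi, sigma=latent_sigma, seed=rng).as_1d()
        qt = 1.0 / (1.0 + np.exp(-latent))
    flips = (rng.random(n) < qt).astype(float)
    if noise_sigma > 0:
        flips = flips + noise_sigma * rng.normal(size=n)
    return Series(flips, label="coin")


def simulate_growth_collapse(
    n: int,
    growth_rate: float = 1.2,
    period: int = 25,
    immigration: float = 1.0,
    seed=None,
) -> Series:
    """Exponential growth, periodic extinction, constant immigration.

    The deterministic orbit v_{k+1} = growth_rate * v_k + immigration is
    reset to 0 every ``period`` steps; the observed window starts at a
    uniformly random offset within one period, which makes the observed
    process stationary.
    """
    if growth_rate <= 0:
        raise TTSError("growth_rate must be positive")
    if period < 2:
        raise TTSError("period must be at least 2")
    if immigration < 0:
        raise TTSError("immigration must be nonnegative")
    offset = int(_rng(seed).integers(0, period))
    total = offset + n
    x = np.empty(total)
    v = 0.0
    for k in range(total):
        if k % period == 0:
            v = 0.0
        x[k] = v
        v = growth_rate * v + immigration
        if not np.isfinite(v):
            raise SimulationError("growth-collapse orbit overflowed")
    return Series(x[offset:], label="growth_collapse")


def simulate_fitzhugh_nagumo(
    n: int,
    a: float = 0.7,
    b: float = 0.8,
    tau: float = 12.5,
    current: float = 0.5,
    noise: float = 0.2,
    dt: float = 0.1,
    burn_in: int = 10_000,
    seed=None,
) -> Series:
    """Stochastic discrete-time FitzHugh-Nagumo oscillator (voltage trace).

    Euler-Maruyama steps of v' = v - v^3/3 - w + I + noise, w' =
    (v + a - b*w)/tau; the default drive I = 0.5 puts the deterministic
    skeleton on its limit cycle. The burn-in is discarded so sampling
    starts from the (approximately) stationary regime. The discrete-time
    map is the model itself, not an approximation target.
    """
    rng = _rng(seed)
    total = burn_in + n
    v, w = -1.0, -0.5
    sq = np.sqrt(dt) * noise
    eta = rng.normal(size=total) if noise > 0 else np.zeros(total)
    out = np.empty(total)
    for t in range(total):
        dv = v - v**3 / 3.0 - w + current
        dw = (v + a - b * w) / tau
        v = v + dt * dv + sq * eta[t]
        w = w + dt * dw
        if not (np.isfinite(v) and np.isfinite(w)):
            raise SimulationError(
                f"FitzHugh-Nagumo diverged at step {t} "
                f"(a={a}, b={b}, tau={tau}, I={current}, dt={dt})"
            )
        out[t] = v
    return Series(out[burn_in:], label="fitzhugh_nagumo")


# Chaotic 4-species competitive parameterization (Vano et al. 2006)
_LV_R = np.array([1.0, 0.72, 1.53, 1.27])
_LV_A = np.array(
    [
        [1.0, 1.09, 1.52, 0.0],
        [0.0, 1.0, 0.44, 1.36],
        [2.33, 0.0, 1.0, 0.47],
        [1.21, 0.51, 0.35, 1.0],
    ]
)


def simulate_lotka_volterra_chaotic(
    n: int,
    r: np.ndarray | None = None,
    A: np.ndarray | None = None,
    dt: float = 0.05,
    burn_in: int = 5_000,
    species: int = 0,
    seed=None,
) -> Series:
    """Discretized 4-species competitive Lotka-Volterra, chaotic regime.

    dx_i/dt = r_i x_i (1 - sum_j A_ij x_j), Euler steps of size dt,
    initial abundances drawn uniformly; burn-in discarded and one
    designated species returned. With all interspecies coefficients zero
    each species reduces to independent logistic growth toward carrying
    capacity 1/A_ii.
    """
    r = _LV_R if r is None else np.asarray(r, dtype=float)
    A = _LV_A if A is None else np.asarray(A, dtype=float)
    k = r.size
    if not 0 <= species < k:
        raise TTSError(f"species index {species} outside 0..{k - 1}")
    rng = _rng(seed)
    x = rng.uniform(0.1, 0.6, size=k)
    total = burn_in + n
    out = np.empty(total)
    for t in range(total):
        x = x + dt * r * x * (1.0 - A @ x)
        x = np.maximum(x, 0.0)
        if not np.all(np.isfinite(x)):
            raise SimulationError("Lotka-Volterra trajectory diverged")
        if np.all(x == 0.0):
            raise SimulationError("all species went extinct")
        out[t] = x[species]
    return Series(out[burn_in:], label="lotka_volterra")


def simulate_random_walk(n: int, sigma: float = 1.0, seed=None) -> Series:
    """Random walk: cumulative sum of N(0, sigma^2) increments from 0."""
    if sigma < 0:
        raise TTSError("sigma must be nonnegative")
    rng = _rng(seed)
    return Series(np.cumsum(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.zeros(n),
                  label="random_walk")


# ---------------------------------------------------------------------------
# Coupled systems
# ---------------------------------------------------------------------------

def _var_spectral_radius(phi_x, phi_y, beta_yx, lag_yx, beta_xy, lag_xy) -> float:
    """Spectral radius of the companion matrix of the joint VAR."""
    p = max(1, lag_yx if beta_yx else 1, lag_xy if beta_xy else 1)
    coef = [np.zeros((2, 2)) for _ in range(p)]
    coef[0][0, 0] = phi_x
    coef[0][1, 1] = phi_y
    if beta_yx:
        coef[max(lag_yx, 1) - 1][0, 1] += beta_yx
    if beta_xy:
        coef[max(lag_xy, 1) - 1][1, 0] += beta_xy
    comp = np.zeros((2 * p, 2 * p))
    comp[:2, :] = np.hstack(coef)
    if p > 1:
        comp[2:, :-2] = np.eye(2 * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_coupled_ar(
    n: int,
    phi_x: float = 0.5,
    phi_y: float = 0.5,
    beta: float = 0.5,
    coupling_lag: int = 2,
    direction: str = "y->x",
    sigma: float = 1.0,
    beta2: float = 0.0,
    coupling_lag2: int = 1,
    burn_in: int = 200,
    seed=None,
) -> tuple[Series, Series]:
    """Coupled AR(1) pair, e.g. y -> x: x_t = phi_x x_{t-1} + beta y_{t-lag} + eps.

    ``direction`` is one of "y->x", "x->y", "both"; the bidirectional mode
    adds the symmetric term with coefficient ``beta2`` at ``coupling_lag2``.
    With beta = 0 the two series are independent AR(1) processes. The
    joint parameterization must be stable (companion spectral radius < 1).
    """
    if direction not in ("y->x", "x->y", "both"):
        raise TTSError("direction must be 'y->x', 'x->y' or 'both'")
    if coupling_lag < 0 or coupling_lag2 < 0:
        raise TTSError("coupling lags must be nonnegative")
    b_yx = beta if direction in ("y->x", "both") else 0.0
    b_xy = beta if direction == "x->y" else (beta2 if direction == "both" else 0.0)
    l_yx = coupling_lag
    l_xy = coupling_lag if direction == "x->y" else coupling_lag2
    rad = _var_spectral_radius(phi_x, phi_y, b_yx, l_yx, b_xy, l_xy)
    if rad >= 1.0:
        raise TTSError(f"unstable parameterization (spectral radius {rad:.3f})")
    rng = _rng(seed)
    total = burn_in + n
    eps = rng.normal(0.0, sigma, size=total)
    eta = rng.normal(0.0, sigma, size=total)
    if b_xy == 0.0:
        # unidirectional fast path: y is a plain AR(1), x filters beta*y + eps
        y = lfilter([1.0], [1.0, -phi_y], eta)
        y_shift = np.zeros(total)
        if l_yx < total:
            y_shift[l_yx:] = y[: total - l_yx] if l_yx > 0 else y
        x = lfilter([1.0], [1.0, -phi_x], b_yx * y_shift + eps)
    else:
        if l_yx == 0 or l_xy == 0:
            raise TTSError("bidirectional coupling requires lags of at least 1")
        x = np.zeros(total)
        y = np.zeros(total)
        for t in range(1, total):
            xy = b_yx * y[t - l_yx] if t >= l_yx else 0.0
            yx = b_xy * x[t - l_xy] if t >= l_xy else 0.0
            x[t] = phi_x * x[t - 1] + xy + eps[t]
            y[t] = phi_y * y[t - 1] + yx + eta[t]
    return Series(x[burn_in:], label="x"), Series(y[burn_in:], label="y")


def simulate_coupled_logistic(
    n: int,
    r_x: float = 3.8,
    r_y: float = 3.5,
    beta_yx: float = 0.02,
    beta_xy: float = 0.1,
    lag_yx: int = 0,
    lag_xy: int = 0,
    burn_in: int = 300,
    seed=None,
) -> tuple[Series, Series]:
    """Coupled logistic maps (competition-inspired):

        x_{t+1} = x_t (r_x - r_x x_t - beta_yx y_{t - lag_yx})
        y_{t+1} = y_t (r_y - r_y y_t - beta_xy x_{t - lag_xy})

    ``beta_yx`` is the influence of y on x and vice versa. Initial
    conditions are uniform on (0.2, 0.8); a short burn-in is discarded.
    Orbits must remain in [0, 1].
    """
    rng = _rng(seed)
    total = burn_in + n
    maxlag = max(lag_yx, lag_xy, 1)
    x = np.empty(total + maxlag)
    y = np.empty(total + maxlag)
    x[: maxlag + 1] = rng.uniform(0.2, 0.8)
    y[: maxlag + 1] = rng.uniform(0.2, 0.8)
    for t in range(maxlag, total + maxlag - 1):
        x[t + 1] = x[t] * (r_x - r_x * x[t] - beta_yx * y[t - lag_yx])
        y[t + 1] = y[t] * (r_y - r_y * y[t] - beta_xy * x[t - lag_xy])
        if not (0.0 <= x[t + 1] <= 1.0 and 0.0 <= y[t + 1] <= 1.0):
            raise SimulationError(
                f"coupled logistic orbit escaped [0,1] at step {t - maxlag}"
            )
    return (
        Series(x[maxlag + burn_in :], label="x"),
        Series(y[maxlag + burn_in :], label="y"),
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

UNIVARIATE_SYSTEMS = {
    "ar1": simulate_ar1,
    "logistic": simulate_logistic,
    "sine_sawtooth_noise": simulate_sine_sawtooth_noise,
    "sine_threshold_noise": simulate_sine_threshold_noise,
    "autocorrelated_coin": simulate_autocorrelated_coin,
    "growth_collapse": simulate_growth_collapse,
    "fitzhugh_nagumo": simulate_fitzhugh_nagumo,
    "lotka_volterra_chaotic": simulate_lotka_volterra_chaotic,
    "random_walk": simulate_random_walk,
}

COUPLED_SYSTEMS = {
    "coupled_ar": simulate_coupled_ar,
    "coupled_logistic": simulate_coupled_logistic,
}

# the trended AR(1) is the ar1 generator with a nonzero slope
_TRENDED_AR1_DEFAULTS = {"trend_slope": 0.01}


def simulate(system_id: str, n: int, params: dict | None = None, seed=None) -> Series:
    """Dispatch a univariate system by name (``trended_ar1`` aliases ar1)."""
    params = dict(params or {})
    if system_id == "trended_ar1":
        merged = {**_TRENDED_AR1_DEFAULTS, **params}
        return simulate_ar1(n, seed=seed, **merged)
    try:
        fn = UNIVARIATE_SYSTEMS[system_id]
    except KeyError:
        raise TTSError(
            f"unknown system {system_id!r}; choose from "
            f"{sorted(UNIVARIATE_SYSTEMS) + ['trended_ar1'] + sorted(COUPLED_SYSTEMS)}"
        ) from None
    return fn(n, seed=seed, **params)


def simulate_pair(
    system_id: str,
    n: int,
    params: dict | None = None,
    seed=None,
    coupled: bool = False,
) -> tuple[Series, Series]:
    """An (x, y) pair: coupled from one generator, or two independent draws."""
    params = dict(params or {})
    if coupled:
        try:
            fn = COUPLED_SYSTEMS[system_id]
        except KeyError:
            raise TTSError(f"{system_id!r} is not a coupled system") from None
        return fn(n, seed=seed, **params)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    sx, sy = ss.spawn(2)
    return simulate(system_id, n, params, seed=sx), simulate(system_id, n, params, seed=sy)
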