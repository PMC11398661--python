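"""Experiment harness: false-positive-rate and power studies.

A cell of the study grid is one :class:`ExperimentConfig`: a generative
system (independent pair for calibration, coupled pair for power), one
test, one statistic, and a trial count. Per-trial seeds are derived from
the master seed by spawning a ``numpy.random.SeedSequence``, so results
are bit-for-bit reproducible and trials are independent.

Rates carry Wilson 95% confidence intervals. Trials whose statistic fails
on a degenerate window are excluded and counted; more than 1% failures
aborts the cell, guarding against silent bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import core, parametric, surrogates, systems
from .errors import ConfigError, TTSError
from .statistics import make_statistic

TESTS = (
    "tts",
    "naive_tts",
    "multi_lag_tts",
    "detrend_tts",
    "cyclic",
    "block_bootstrap",
    "iaaft",
    "shuffle",
    "parametric",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of a benchmark grid."""

    system: str
    n: int
    test: str = "tts"
    statistic: str = "pearson"
    n_trials: int = 2000
    alpha: float = 0.05
    master_seed: int = 0
    coupled: bool = False
    system_params: dict = field(default_factory=dict)
    stat_params: dict = field(default_factory=dict)
    test_params: dict = field(default_factory=dict)  # r, lag, lags, n_surrogates, ...

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ConfigError(f"unknown test {self.test!r}; choose from {TESTS}")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be positive")


@dataclass(frozen=True)
class RateResult:
    """A rejection rate with its Wilson 95% CI and cell metadata."""

    rate: float
    n_trials: int
    n_rejections: int
    n_failed: int
    ci_low: float
    ci_high: float
    config: ExperimentConfig

    def to_dict(self) -> dict:
        return {
            "system": self.config.system,
            "test": self.config.test,
            "statistic": self.config.statistic,
            "alpha": self.config.alpha,
            "n": self.config.n,
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_trials": self.n_trials,
            "n_rejections": self.n_rejections,
            "n_failed": self.n_failed,
            "master_seed": self.config.master_seed,
        }


def _run_one_test(cfg: ExperimentConfig, x, y, stat, trial_seed) -> bool:
    tp = cfg.test_params
    alpha = cfg.alpha
    if cfg.test in ("tts", "naive_tts"):
        res = core.tts_test(
            x, y, r=tp.get("r", 19), stat=stat, l=tp.get("lag", 0), alpha=alpha,
            surrogate_from=tp.get("surrogate_from", "y"),
        )
        if cfg.test == "naive_tts":
            return core.naive_p(res.B, res.r) <= alpha
        return res.reject
    if cfg.test == "multi_lag_tts":
        res = core.multi_lag_tts(
            x, y, r=tp.get("r", 99), stat=stat, lags=tp.get("lags", (0, 1, 2, 3, 4)),
            alpha=alpha,
        )
        return res.reject
    if cfg.test == "detrend_tts":
        res = core.detrend_retrend_tts(
            x, y, r=tp.get("r", 19), stat=stat,
            trend_fitter=core.polynomial_trend(tp.get("degree", 1)), alpha=alpha,
        )
        return res.reject
    if cfg.test == "parametric":
        res = parametric.corrected_pearson_test(
            x.as_1d(), y.as_1d(), variant=tp.get("variant", "full")
        )
        return res.p <= alpha
    res = surrogates.surrogate_test(
        x, y, method=cfg.test, stat=stat,
        n_surrogates=tp.get("n_surrogates", 499), seed=trial_seed,
        circularize_first=tp.get("circularize", False),
    )
    return res.p <= alpha


def run_experiment(cfg: ExperimentConfig) -> RateResult:
    """Run one grid cell and return its rejection rate with a Wilson CI."""
    stat = make_statistic(cfg.statistic, **cfg.stat_params)
    ss = np.random.SeedSequence(cfg.master_seed)
    children = ss.spawn(cfg.n_trials)
    rejections = 0
    failed = 0
    valid = 0
    max_failed = max(1, cfg.n_trials // 100)
    for child in children:
        pair_seed, test_seed = child.spawn(2)
        try:
            x, y = systems.simulate_pair(
                cfg.system, cfg.n, cfg.system_params, seed=pair_seed,
                coupled=cfg.coupled,
            )
            reject = _run_one_test(cfg, x, y, stat, test_seed)
        except TTSError:
            failed += 1
            if failed > max_failed:
                raise ConfigError(
                    f"more than 1% of trials failed in cell "
                    f"({cfg.system}, {cfg.test}, {cfg.statistic})"
                )
            continue
        valid += 1
        rejections += int(reject)
    rate = rejections / valid if valid else float("nan")
    lo, hi = proportion_confint(rejections, valid, alpha=0.05, method="wilson")
    return RateResult(
        rate=rate,
        n_trials=valid,
        n_rejections=rejections,
        n_failed=failed,
        ci_low=float(lo),
        ci_high=float(hi),
        config=cfg,
    )


def run_fpr_experiment(cfg: ExperimentConfig) -> RateResult:
    """False-positive-rate study: requires an independent (uncoupled) pair."""
    if cfg.coupled:
        raise ConfigError("FPR experiments use independent pairs (coupled=False)")
    return run_experiment(cfg)


def run_power_experiment(cfg: ExperimentConfig) -> RateResult:
    """Power study: requires a coupled system pair."""
    if not cfg.coupled:
        raise ConfigError("power experiments use coupled pairs (coupled=True)")
    return run_experiment(cfg)


def binomial_margin(alpha: float, n_trials: int, k: float = 3.0) -> float:
    """k binomial standard errors around a nominal rate alpha."""
    return k * float(np.sqrt(alpha * (1.0 - alpha) / n_trials))
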