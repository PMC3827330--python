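"""Delayed-Rejection Adaptive Metropolis (DRAM) sampling utilities.

A small, generic random-walk Metropolis sampler with two features layered on
top: the proposal covariance is adapted from the chain history after an
initial non-adaptive phase (Adaptive Metropolis), and a rejected proposal is
given a second chance from a shrunken proposal with the delayed-rejection
acceptance correction (one DR stage).  Point estimates and uncertainty are
read off the final segment of the chain: the mean is the estimate, the SD is
the standard error, and the 2.5th/97.5th percentiles give the 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["McmcConfig", "ChainResult", "run_chain", "summarize_trace", "stability_check"]


@dataclass
class McmcConfig:
    """Chain conventions for latent-correlation estimation.

    chain_length
        Total number of Metropolis steps (default 5000; 10000 for hard
        problems).
    estimate_window
        Number of final draws summarised into the estimate/SE/CI
        (default 2000).  Burn-in is implicit: everything before the window
        is discarded from the summary.
    adapt_start_frac
        Fraction of the chain run with the fixed initial proposal before
        covariance adaptation begins.
    delayed_rejection
        Enable the one-stage delayed-rejection fallback proposal.
    dr_shrink
        Linear shrink factor applied to the proposal Cholesky at the DR
        stage.
    """

    chain_length: int = 5000
    estimate_window: int = 2000
    seed: int = 0
    adapt_start_frac: float = 0.1
    adapt_interval: int = 10
    initial_scale: float = 0.1
    delayed_rejection: bool = True
    dr_shrink: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.estimate_window < self.chain_length:
            raise ValueError(
                f"estimate_window ({self.estimate_window}) must be positive and "
                f"smaller than chain_length ({self.chain_length})"
            )


@dataclass
class ChainResult:
    """Raw output of :func:`run_chain`: one row per step, unconstrained scale."""

    params: np.ndarray          # (chain_length, d)
    logpost: np.ndarray         # (chain_length,)
    accept_rate: float
    config: McmcConfig = field(repr=False)


def _logq_ratio(chol: np.ndarray, y1: np.ndarray, y2: np.ndarray, x: np.ndarray) -> float:
    """log q1(y2,y1) - log q1(x,y1) for the stage-1 Gaussian proposal."""
    za = solve_triangular(chol, y1 - y2, lower=True)
    zb = solve_triangular(chol, y1 - x, lower=True)
    return -0.5 * (float(za @ za) - float(zb @ zb))


def run_chain(logpost, init: np.ndarray, config: McmcConfig) -> ChainResult:
    """Sample ``logpost`` with DRAM starting from ``init``.

    ``logpost`` maps an unconstrained parameter vector to a log posterior
    density (up to a constant); it may return ``-inf`` but must be finite at
    ``init``.  The run is fully reproducible from ``config.seed``.
    """
    theta = np.asarray(init, dtype=float).copy()
    d = theta.size
    lp = float(logpost(theta))
    if not math.isfinite(lp):
        raise ValueError(
            "log-posterior is not finite at the initial point; "
            "re-initialize (e.g. from moment estimates) before sampling"
        )

    rng = np.random.default_rng(config.seed)
    n = config.chain_length
    chain = np.empty((n, d))
    lps = np.empty(n)

    scale0 = config.initial_scale / math.sqrt(d)
    chol = np.eye(d) * scale0
    sd = 2.38**2 / d
    eps = 1e-10

    # running moments of the chain for covariance adaptation
    mean = theta.copy()
    cov_acc = np.zeros((d, d))
    n_seen = 1
    adapt_start = max(10, int(config.adapt_start_frac * n))
    accepted = 0

    for i in range(n):
        z = rng.standard_normal(d)
        prop = theta + chol @ z
        lp_prop = float(logpost(prop))
        log_a1 = lp_prop - lp
        if math.log(rng.uniform()) < log_a1:
            theta, lp = prop, lp_prop
            accepted += 1
        elif config.delayed_rejection:
            # one-stage delayed rejection with a shrunken proposal
            z2 = rng.standard_normal(d)
            prop2 = theta + config.dr_shrink * (chol @ z2)
            lp2 = float(logpost(prop2))
            if math.isfinite(lp2):
                log_a1_rev = lp_prop - lp2  # alpha1(prop2 -> prop)
                if log_a1_rev >= 0.0:
                    pass  # numerator vanishes: reject
                else:
                    lq = _logq_ratio(chol, prop, prop2, theta)
                    log_num_1m = math.log1p(-math.exp(min(log_a1_rev, -1e-12)))
                    log_den_1m = math.log1p(-math.exp(min(log_a1, -1e-12)))
                    log_a2 = lp2 - lp + lq + log_num_1m - log_den_1m
                    if math.log(rng.uniform()) < log_a2:
                        theta, lp = prop2, lp2
                        accepted += 1

        chain[i] = theta
        lps[i] = lp

        # adaptive covariance bookkeeping (Welford-style accumulation)
        n_seen += 1
        delta = theta - mean
        mean += delta / n_seen
        cov_acc += np.outer(delta, theta - mean)
        if i >= adapt_start and (i - adapt_start) % config.adapt_interval == 0:
            cov = sd * (cov_acc / (n_seen - 1) + eps * np.eye(d))
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass  # keep the previous proposal

    return ChainResult(
        params=chain, logpost=lps, accept_rate=accepted / n, config=config
    )


def summarize_trace(trace: np.ndarray, window: int) -> tuple[float, float, tuple[float, float]]:
    """Mean, SD and (2.5th, 97.5th) percentiles of the final ``window`` draws."""
    trace = np.asarray(trace, dtype=float)
    if window > trace.size:
        raise ValueError(
            f"estimate window ({window}) longer than chain ({trace.size})"
        )
    seg = trace[-window:]
    est = float(np.mean(seg))
    se = float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0
    lo, hi = np.percentile(seg, [2.5, 97.5])
    return est, se, (float(lo), float(hi))


def stability_check(
    trace: np.ndarray, window: int, frac: float = 0.25, z_limit: float = 3.0
) -> tuple[float, bool]:
    """Geweke-style drift diagnostic on the estimate window.

    Compares the mean of the first ``frac`` of the window with the mean of
    the last ``frac`` via a two-sample z statistic.  The variance of each
    segment mean is estimated by batch means, which remains honest for
    autocorrelated MCMC draws.  A constant chain has zero drift by
    convention.  Returns ``(z, passed)``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2 * window // 2 or trace.size < window:
        raise ValueError("chain too short for the requested window")
    seg = trace[-window:]
    m = max(2, int(frac * window))
    a, b = seg[:m], seg[-m:]

    def var_of_mean(x: np.ndarray) -> float:
        nb = max(2, int(math.sqrt(x.size)))
        usable = (x.size // nb) * nb
        batches = x[:usable].reshape(nb, -1).mean(axis=1)
        return float(np.var(batches, ddof=1) / nb)

    denom = math.sqrt(var_of_mean(a) + var_of_mean(b))
    if denom == 0.0:
        z = 0.0
    else:
        z = float((np.mean(a) - np.mean(b)) / denom)
    return z, abs(z) < z_limit
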