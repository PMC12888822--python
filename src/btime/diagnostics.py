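"""MCMC convergence diagnostics and predictive model comparison.

Convergence is judged by the Gelman–Rubin potential scale reduction factor
(PSRF), computed from the between-chain variance ``B`` and the mean
within-chain variance ``W`` of ``J`` retained draws per chain as

    sqrt(R_hat) = sqrt( ( ((J - 1) / J) * W + (1 / J) * B ) / W ),

with convergence declared when every monitored parameter has
``sqrt(R_hat) < 1.1``.  A stricter split-chain variant (each chain halved
before the same computation) is reported alongside.

Out-of-sample fit is compared by the expected log pointwise predictive
density (ELPD) estimated with Pareto-smoothed importance-sampling
leave-one-out cross-validation (PSIS-LOO): raw importance ratios per held-out
observation, a generalized Pareto fit to the upper tail of the ratios,
replacement of the tail by its expected order statistics, truncation at the
raw maximum, and a weighted log-mean.  WAIC is computed from the pointwise
posterior variance as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ConvergenceReport",
    "ModelComparison",
    "psrf",
    "split_psrf",
    "compute_convergence",
    "psis_loo",
    "waic",
    "elpd_rank",
]

PSRF_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# PSRF
# ---------------------------------------------------------------------------

def psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor sqrt(R_hat) for one parameter.

    ``chains`` is (n_chains, J).  Returns ``inf`` when the within-chain
    variance is zero but the chains disagree (a degenerate, non-converged
    state); returns the B=0 limit ``sqrt((J-1)/J)`` when all chains are
    identical and constant-free.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    n_chains, J = chains.shape
    if J < 2:
        raise ValueError("need at least two draws per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B = J * chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    return float(np.sqrt(((J - 1) / J * W + B / J) / W))


def split_psrf(chains: np.ndarray) -> float:
    """PSRF after splitting each chain into halves (detects within-chain
    drift that the plain diagnostic misses)."""
    chains = np.asarray(chains, dtype=float)
    J = chains.shape[1]
    half = J // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    return psrf(split)


@dataclass
class ConvergenceReport:
    """Per-parameter PSRF values plus the overall convergence flag."""

    psrf: dict[str, float]
    split: dict[str, float]
    B: dict[str, float]
    W: dict[str, float]
    J: int
    threshold: float = PSRF_THRESHOLD

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values()) if self.psrf else np.nan

    @property
    def converged(self) -> bool:
        return bool(self.psrf) and all(r < self.threshold for r in self.psrf.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.psrf),
                "psrf": list(self.psrf.values()),
                "split_psrf": [self.split[k] for k in self.psrf],
                "B": [self.B[k] for k in self.psrf],
                "W": [self.W[k] for k in self.psrf],
            }
        )


def compute_convergence(monitor: dict[str, np.ndarray]) -> ConvergenceReport:
    """Build a :class:`ConvergenceReport` from named (n_chains, J) arrays."""
    rhat, split, Bs, Ws = {}, {}, {}, {}
    J = 0
    for name, chains in monitor.items():
        chains = np.asarray(chains, dtype=float)
        J = chains.shape[1]
        rhat[name] = psrf(chains)
        split[name] = split_psrf(chains)
        Ws[name] = float(chains.var(axis=1, ddof=1).mean())
        Bs[name] = float(J * chains.mean(axis=1).var(ddof=1))
    return ConvergenceReport(psrf=rhat, split=split, B=Bs, W=Ws, J=J)


# ---------------------------------------------------------------------------
# generalized Pareto tail fit (Zhang & Stephens 2009 profile posterior)
# ---------------------------------------------------------------------------

def _gpdfit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto distribution to sorted exceedances ``x``.

    Returns (k, sigma).  Empirical-Bayes profile estimate with the standard
    weak prior pulling k toward 0.5 for small tails.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    M = 30 + int(np.sqrt(n))
    bs = 1.0 - np.sqrt(M / (np.arange(1, M + 1) - 0.5))
    bs /= prior_bs * x[int(n / 4 + 0.5) - 1]
    bs += 1.0 / x[-1]
    ks = np.mean(np.log1p(-bs[:, None] * x), axis=1)
    L = n * (np.log(-bs / ks) - ks - 1.0)
    w = 1.0 / np.exp(L - L[:, None]).sum(axis=1)
    b_post = np.sum(bs * w)
    k_post = np.mean(np.log1p(-b_post * x))
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return float(k_post), float(sigma)


def _psis_smooth_tail(lw: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth the upper tail of one observation's log importance weights.

    The tail size follows the standard recipe: the larger of 20% of the
    draws and ceil(3 * sqrt(draws)) is capped at 20% of the draws.
    Returns the smoothed log-weights (truncated at the raw maximum) and
    the Pareto shape diagnostic k.
    """
    S = lw.size
    tail_len = int(min(0.2 * S, 3.0 * np.sqrt(S)))
    if tail_len < 5:
        return lw, -np.inf
    order = np.argsort(lw)
    tail_idx = order[-tail_len:]
    cutoff = lw[order[-tail_len - 1]]
    exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
    if np.allclose(exceed, 0.0):
        return lw, -np.inf
    k, sigma = _gpdfit(exceed)
    if np.isfinite(k):
        # replace tail by expected order statistics of the fitted GPD
        p = (np.arange(1, tail_len + 1) - 0.5) / tail_len
        if abs(k) < 1e-12:
            q = -sigma * np.log1p(-p)
        else:
            q = sigma * np.expm1(-k * np.log1p(-p)) / k  # sigma/k * ((1-p)^-k - 1)
        smoothed = np.log(q + np.exp(cutoff))
        lw = lw.copy()
        lw[tail_idx[np.argsort(lw[tail_idx])]] = np.sort(smoothed)
        np.minimum(lw, lw.max(), out=lw)
    return lw, k


@dataclass
class ModelComparison:
    """PSIS-LOO / WAIC summary for one fitted model."""

    name: str
    elpd_loo: float
    se_elpd: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    waic: float
    p_waic: float
    n_obs: int
    warnings: list[str] = field(default_factory=list)


def psis_loo(loglik: np.ndarray, name: str = "model") -> ModelComparison:
    """PSIS-LOO ELPD from a (draws, observations) log-likelihood matrix.

    Observations with a Pareto shape diagnostic k > 0.7 are recorded as
    warnings (the importance-sampling estimate is unreliable for them).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be (draws, observations)")
    S, n = loglik.shape
    if S < 100:
        raise ValueError("need at least 100 draws for PSIS-LOO")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("log-likelihood matrix contains non-finite entries")
    pointwise = np.empty(n)
    ks = np.empty(n)
    for i in range(n):
        ll = loglik[:, i]
        lw = -ll
        lw = lw - lw.max()
        lw, k = _psis_smooth_tail(lw)
        ks[i] = k
        pointwise[i] = logsumexp(lw + ll) - logsumexp(lw)
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=1))) if n > 1 else 0.0
    warns = []
    n_bad = int((ks > 0.7).sum())
    if n_bad:
        msg = f"{n_bad}/{n} observations with Pareto k > 0.7"
        warns.append(msg)
        warnings.warn(f"PSIS-LOO: {msg}", stacklevel=2)
    w_elpd, p_w = waic(loglik)
    return ModelComparison(
        name=name,
        elpd_loo=elpd,
        se_elpd=se,
        pointwise=pointwise,
        pareto_k=ks,
        waic=w_elpd,
        p_waic=p_w,
        n_obs=n,
        warnings=warns,
    )


def waic(loglik: np.ndarray) -> tuple[float, float]:
    """WAIC on the ELPD scale: lppd minus the pointwise-variance penalty.

    Returns ``(elpd_waic, p_waic)``."""
    loglik = np.asarray(loglik, dtype=float)
    S = loglik.shape[0]
    lppd = logsumexp(loglik, axis=0) - np.log(S)
    p = loglik.var(axis=0, ddof=1)
    return float((lppd - p).sum()), float(p.sum())


def elpd_rank(models: list[ModelComparison]) -> pd.DataFrame:
    """Rank models by PSIS-LOO ELPD; the best model has difference 0.

    Ties are ordered by name for stability.  All models must score the same
    observations.
    """
    if not models:
        raise ValueError("no models to rank")
    n_obs = {mc.n_obs for mc in models}
    if len(n_obs) != 1:
        raise ValueError(f"models score different observation counts: {sorted(n_obs)}")
    ordered = sorted(models, key=lambda mc: (-mc.elpd_loo, mc.name))
    best = ordered[0]
    rows = []
    for mc in ordered:
        d = mc.pointwise - best.pointwise
        se_d = float(np.sqrt(mc.n_obs * d.var(ddof=1))) if mc.n_obs > 1 else 0.0
        rows.append(
            {
                "model": mc.name,
                "elpd_loo": mc.elpd_loo,
                "se": mc.se_elpd,
                "delta_elpd": mc.elpd_loo - best.elpd_loo,
                "se_delta": se_d,
                "p_waic": mc.p_waic,
            }
        )
    return pd.DataFrame(rows)
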