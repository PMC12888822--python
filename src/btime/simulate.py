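"""Gaussian-copula simulator for correlated multivariate beta-binomial counts.

The generator emulates a two-group multiplex-immunofluorescence experiment:
``n_samples`` tissue samples split between a control (X=0) and a case (X=1)
group, ``m`` cell types counted out of ``total_cells`` cells each.  Marginally
each cell-type count is beta-binomial: a per-sample positivity probability is
drawn from ``Beta(mu_j * kappa, (1 - mu_j) * kappa)`` with ``kappa = 1/rho - 1``
set by the intra-class correlation ``rho``, and the count is binomial given
that probability.  Cross-cell-type dependence is imposed through a Gaussian
copula with correlation ``R_cop = (1 - s) I + s R_target``.

Group effects are *local*: a configurable fraction of samples in each group
is perturbed, shifting all cell-type means by +25% (affected X=1 samples)
or -25% (affected X=0 samples).  The null scenario is ``perturb_fraction=0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_TARGET_CORRELATION",
    "DEFAULT_BASELINE_MEANS",
    "SimConfig",
    "SimulatedDataset",
    "beta_shapes",
    "nearest_pd",
    "shrink_correlation",
    "perturbed_means",
    "generate_dataset",
    "generate_replicates",
]

#: default cross-cell-type target correlation for the four simulated types
DEFAULT_TARGET_CORRELATION = np.array(
    [
        [1.00, 0.80, 0.85, 0.70],
        [0.80, 1.00, 0.60, 0.50],
        [0.85, 0.60, 1.00, 0.75],
        [0.70, 0.50, 0.75, 1.00],
    ]
)

#: default control-group mean proportions for M1..M4
DEFAULT_BASELINE_MEANS = (0.25, 0.10, 0.01, 0.005)


def beta_shapes(mu: float, rho: float) -> tuple[float, float]:
    """Beta shape parameters under the mean–dispersion reparameterization.

    ``alpha = mu * kappa``, ``beta = (1 - mu) * kappa`` with
    ``kappa = 1/rho - 1``, so that the beta-binomial intra-class
    correlation equals ``rho``.
    """
    if not 0 < mu < 1:
        raise ValueError("mean proportion mu must be in (0, 1)")
    if not 0 < rho < 1:
        raise ValueError("intra-class correlation rho must be in (0, 1)")
    kappa = 1.0 / rho - 1.0
    return mu * kappa, (1.0 - mu) * kappa


def nearest_pd(R: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite
    correlation matrix (Higham-style alternating projections).

    Alternates projection onto the PSD cone (eigenvalue clipping, with
    Dykstra correction) and onto the unit-diagonal affine set, then
    renormalizes to a correlation matrix.  A matrix that is already PD
    with unit diagonal is returned unchanged.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("input must be symmetric")
    eig = np.linalg.eigvalsh(R)
    if eig[0] > tol and np.allclose(np.diag(R), 1.0, atol=1e-12):
        return R.copy()

    Y = R.copy()
    dS = np.zeros_like(R)
    for _ in range(max_iter):
        Rk = Y - dS
        w, V = np.linalg.eigh(Rk)
        Xk = (V * np.clip(w, 0.0, None)) @ V.T
        dS = Xk - Rk
        Y_new = Xk.copy()
        np.fill_diagonal(Y_new, 1.0)
        if np.linalg.norm(Y_new - Y, ord="fro") < tol:
            Y = Y_new
            break
        Y = Y_new
    # renormalize and nudge off the PSD boundary
    w, V = np.linalg.eigh(Y)
    w = np.clip(w, 10 * tol, None)
    Y = (V * w) @ V.T
    d = np.sqrt(np.diag(Y))
    Y = Y / np.outer(d, d)
    Y = (Y + Y.T) / 2.0
    np.fill_diagonal(Y, 1.0)
    return Y


def shrink_correlation(R_target: np.ndarray, s: float) -> np.ndarray:
    """Convex shrinkage toward independence: ``(1 - s) I + s R_target``."""
    if not 0 <= s <= 1:
        raise ValueError("shrinkage s must be in [0, 1]")
    R_target = np.asarray(R_target, dtype=float)
    return (1.0 - s) * np.eye(R_target.shape[0]) + s * R_target


@dataclass
class SimConfig:
    """Configuration of one simulation scenario.

    Defaults are the reference study conditions: 50 samples split evenly
    between two groups, four cell types of 500 cells each, baseline means
    (0.25, 0.10, 0.01, 0.005), intra-class correlation 0.05, and the default
    4x4 target correlation with no copula shrinkage (``shrink=1`` keeps the
    full target).
    """

    n_samples: int = 50
    group1_fraction: float = 0.5
    total_cells: int = 500
    baseline_means: tuple[float, ...] = DEFAULT_BASELINE_MEANS
    icc: float = 0.05
    perturb_fraction: float = 0.0
    perturb_effect: float = 0.25
    R_target: np.ndarray = field(default_factory=lambda: DEFAULT_TARGET_CORRELATION.copy())
    shrink: float = 1.0
    seed: int = 0
    marker_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.R_target = np.asarray(self.R_target, dtype=float)
        mus = np.asarray(self.baseline_means, dtype=float)
        if np.any(mus <= 0) or np.any(mus >= 1):
            raise ValueError("baseline means must lie in (0, 1)")
        if not 0 < self.icc < 1:
            raise ValueError("icc must be in (0, 1)")
        if not 0 <= self.perturb_fraction <= 1:
            raise ValueError("perturb_fraction must be in [0, 1]")
        if not 0 <= self.shrink <= 1:
            raise ValueError("shrink must be in [0, 1]")
        m = len(mus)
        if self.R_target.shape != (m, m):
            raise ValueError("R_target shape must match the number of cell types")
        if not np.allclose(self.R_target, self.R_target.T):
            raise ValueError("R_target must be symmetric")
        if not np.allclose(np.diag(self.R_target), 1.0):
            raise ValueError("R_target must have unit diagonal")
        if self.marker_names is None:
            self.marker_names = tuple(f"M{j + 1}" for j in range(m))

    @property
    def m(self) -> int:
        return len(self.baseline_means)

    def copula_correlation(self) -> np.ndarray:
        """The correlation actually used by the copula: the target projected
        to the nearest PD correlation matrix, then shrunk by ``s``."""
        return shrink_correlation(nearest_pd(self.R_target), self.shrink)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["R_target"] = self.R_target.tolist()
        d["baseline_means"] = list(self.baseline_means)
        d["marker_names"] = list(self.marker_names)
        return d


@dataclass
class SimulatedDataset:
    """One simulated two-group experiment.

    ``counts`` is ``n_samples x m``; ``group`` is the binary predictor X;
    ``affected``/``direction`` record the local perturbation; ``probs`` keeps
    the realized per-sample Beta probabilities for debugging and moment
    checks.
    """

    counts: np.ndarray
    totals: np.ndarray
    group: np.ndarray
    affected: np.ndarray
    direction: np.ndarray
    probs: np.ndarray
    config: SimConfig
    replicate: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts table (one row per sample, one column per
        cell type) in the layout the model fitters read."""
        n = len(self.totals)
        df = pd.DataFrame(
            {
                "core_id": [f"core{i + 1}" for i in range(n)],
                "subject_id": [f"subj{i + 1}" for i in range(n)],
                "group": self.group.astype(int),
                "affected": self.affected.astype(int),
                "direction": self.direction,
                "total_cells": self.totals.astype(int),
            }
        )
        for j, name in enumerate(self.config.marker_names):
            df[name] = self.counts[:, j].astype(int)
        return df


def perturbed_means(config: SimConfig, group: np.ndarray, affected: np.ndarray) -> np.ndarray:
    """Per-sample, per-cell-type mean proportions after local perturbation.

    Affected X=1 samples have every mean shifted by ``+perturb_effect``
    (relative), affected X=0 samples by ``-perturb_effect``; unaffected
    samples keep the baseline means.
    """
    mus = np.asarray(config.baseline_means, dtype=float)
    shift = np.where(group == 1, 1.0 + config.perturb_effect, 1.0 - config.perturb_effect)
    factor = np.where(affected, shift, 1.0)
    out = factor[:, None] * mus[None, :]
    if np.any(out >= 1.0) or np.any(out <= 0.0):
        raise ValueError("perturbed means must stay inside (0, 1)")
    return out


def _assign_groups_and_affected(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_samples
    n1 = int(round(config.group1_fraction * n))
    group = np.zeros(n, dtype=int)
    group[:n1] = 1
    affected = np.zeros(n, dtype=bool)
    for g in (0, 1):
        idx = np.flatnonzero(group == g)
        k = int(round(config.perturb_fraction * idx.size))
        if k > 0:
            affected[rng.choice(idx, size=k, replace=False)] = True
    return group, affected


def generate_dataset(config: SimConfig, seed: int | None = None, replicate: int = 0) -> SimulatedDataset:
    """Draw one dataset from the copula beta-binomial generator.

    For each sample a latent Gaussian vector ``Z ~ N_m(0, R_cop)`` is
    transformed to uniforms ``U = Phi(Z)`` and mapped through the inverse
    Beta CDF with shape parameters derived from that sample's (possibly
    perturbed) means; counts are then binomial given the probabilities.
    Deterministic given the seed.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    group, affected = _assign_groups_and_affected(config, rng)
    mus = perturbed_means(config, group, affected)
    kappa = 1.0 / config.icc - 1.0
    alpha, beta = mus * kappa, (1.0 - mus) * kappa

    R_cop = config.copula_correlation()
    L = np.linalg.cholesky(R_cop)
    Z = rng.standard_normal((config.n_samples, config.m)) @ L.T
    U = stats.norm.cdf(Z)
    probs = stats.beta.ppf(U, alpha, beta)
    counts = rng.binomial(config.total_cells, probs)

    direction = np.where(affected, np.where(group == 1, "up", "down"), "none")
    totals = np.full(config.n_samples, config.total_cells)
    return SimulatedDataset(
        counts=counts,
        totals=totals,
        group=group,
        affected=affected,
        direction=direction,
        probs=probs,
        config=config,
        replicate=replicate,
        seed=seed,
    )


def generate_replicates(config: SimConfig, n_reps: int) -> list[SimulatedDataset]:
    """Independent replicate datasets with seeds derived counter-style from
    the master seed: replicate ``r`` uses ``default_rng([seed, r])``-compatible
    seeding via ``seed * 10_000 + r`` kept below 2**31."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [
        generate_dataset(config, seed=replicate_seed(config.seed, r), replicate=r)
        for r in range(n_reps)
    ]


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Reproducible per-replicate seed derived from the master seed."""
    return int((master_seed * 100_003 + replicate) % (2**31 - 1))


def save_replicates(datasets: list[SimulatedDataset], outdir: str | Path) -> None:
    """Write one CSV per replicate plus a JSON metadata file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.to_frame().to_csv(outdir / f"replicate_{ds.replicate:03d}.csv", index=False)
    meta = {
        "config": datasets[0].config.to_dict(),
        "n_reps": len(datasets),
        "seeds": [ds.seed for ds in datasets],
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1))
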