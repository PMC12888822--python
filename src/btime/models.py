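"""Bayesian hierarchical beta-binomial models for multi-cell-type abundance.

The observation model: for cell type ``i`` measured in core ``k`` of subject
``j`` (in covariate group ``g``),

    Y_igjk ~ Binomial(N_gjk, p_igj),
    p_igj  ~ Beta(gamma_i * pi_igj, gamma_i * (1 - pi_igj)),
    logit(pi_igj) = beta0_i + sum_v beta_vi * X_vgj + S_igj,

with a per-subject random effect ``S_igj ~ Normal(0, sigma_Si^2)`` shared by
all cores of a subject.  The cell-type coefficient vectors carry multivariate
normal priors ``beta0 ~ MVN(v0, T0)`` and ``beta_v ~ MVN(v1, T1)`` whose
covariances encode the immune differentiation tree through one of five
structures (see :mod:`btime.celltree`): unstructured (inverse-Wishart),
exponential decay, tree (LCA), scaled tree, and multi-level tree.

By default the latent ``p`` is integrated out analytically, giving a
beta-binomial likelihood per core; ``latent_p=True`` instead samples the
per-subject probabilities explicitly (the two parameterizations coincide
when each subject contributes a single core).  Posterior sampling uses an
adaptive Metropolis-within-Gibbs scheme with conditionally independent
vectorized updates for the random effects, plus a conjugate inverse-Wishart
Gibbs step for the unstructured covariances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit, gammaln

from .celltree import CovarianceStructure, DifferentiationTree
from .diagnostics import ConvergenceReport, compute_convergence

logger = logging.getLogger(__name__)

__all__ = [
    "CountDataset",
    "MultiCellModelSpec",
    "ChainSchedule",
    "PosteriorSamples",
    "fit_multicell",
    "fit_singlecell",
    "significance_call",
    "log_posterior",
    "SIMULATION_SCHEDULE",
    "COHORT_SCHEDULE",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
#: diagonal jitter keeping prior covariances Cholesky-safe at extreme proposals
PSD_JITTER = 1e-9


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class CountDataset:
    """Per-core totals and positive counts with subject/covariate annotations.

    Cores are stored sorted by subject so that per-subject reductions are
    contiguous.  ``X`` holds the covariates expanded to core level (constant
    within subject).
    """

    counts: np.ndarray          # (n_cores, m) int
    totals: np.ndarray          # (n_cores,) int
    X: np.ndarray               # (n_cores, q) float
    subject_idx: np.ndarray     # (n_cores,) int in 0..n_subjects-1
    cell_types: tuple[str, ...]
    covariate_names: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()
    n_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.counts.shape[0]:
            self.X = self.X.T
        if np.any(self.counts < 0) or np.any(self.counts > self.totals[:, None]):
            raise ValueError("counts must satisfy 0 <= Y <= N for every core")

    @property
    def n_cores(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    @property
    def n_subjects(self) -> int:
        return int(self.subject_idx.max()) + 1 if self.n_cores else 0

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        cell_types: list[str] | tuple[str, ...],
        covariates: list[str] | tuple[str, ...],
        subject_col: str = "subject_id",
        total_col: str = "total_cells",
        min_total: int = 10,
        standardize: bool = True,
    ) -> "CountDataset":
        """Build a dataset from a long-format counts table.

        Cores whose total cell count is below ``min_total`` are excluded
        (tissue cores with a nearly empty tumor compartment carry no
        abundance information); the number dropped is recorded and logged.
        Continuous covariates (more than two distinct values) are
        standardized to mean 0 / SD 1 when ``standardize`` is set.
        """
        missing = [c for c in list(cell_types) + list(covariates) + [subject_col, total_col]
                   if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns in counts table: {missing}")
        keep = df[total_col] >= min_total
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.info("excluded %d cores with total cells < %d", n_excluded, min_total)
        df = df.loc[keep].copy()
        # cores with an unknown covariate value (e.g. missing debulking
        # status) carry no usable contrast and are dropped
        known = df[list(covariates)].notna().all(axis=1)
        if (~known).any():
            logger.info("excluded %d cores with missing covariate values",
                        int((~known).sum()))
            df = df.loc[known]
        if df.empty:
            raise ValueError("no cores left after exclusion filter")
        # stable sort by subject for contiguous per-subject reductions
        df = df.sort_values(subject_col, kind="stable").reset_index(drop=True)
        subj_codes, subj_uniques = pd.factorize(df[subject_col])
        X = df[list(covariates)].to_numpy(dtype=float)
        for q, name in enumerate(covariates):
            vals = np.unique(X[:, q])
            if vals.size < 2:
                raise ValueError(f"covariate {name!r} is constant; no contrast to estimate")
            if standardize and vals.size > 2:
                X[:, q] = (X[:, q] - X[:, q].mean()) / X[:, q].std()
        return cls(
            counts=df[list(cell_types)].to_numpy(),
            totals=df[total_col].to_numpy(),
            X=X,
            subject_idx=np.asarray(subj_codes, dtype=np.int64),
            cell_types=tuple(cell_types),
            covariate_names=tuple(covariates),
            subject_ids=tuple(str(s) for s in subj_uniques),
            n_excluded=n_excluded,
        )

    def select(self, cell_type: str) -> "CountDataset":
        """Single-cell-type view of the dataset (m = 1)."""
        i = self.cell_types.index(cell_type)
        return CountDataset(
            counts=self.counts[:, [i]],
            totals=self.totals,
            X=self.X,
            subject_idx=self.subject_idx,
            cell_types=(cell_type,),
            covariate_names=self.covariate_names,
            subject_ids=self.subject_ids,
            n_excluded=self.n_excluded,
        )


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSchedule:
    """MCMC chain schedule: number of chains, adaptation sweeps (proposal
    tuning), burn-in sweeps (discarded), and retained draws per chain."""

    n_chains: int = 4
    adapt: int = 1000
    burn: int = 1000
    draws: int = 2000

    def __post_init__(self):
        if self.n_chains < 1 or self.draws < 1:
            raise ValueError("need at least one chain and one retained draw")


#: scaled-down default schedule for simulation-study fits
SIMULATION_SCHEDULE = ChainSchedule(n_chains=4, adapt=1000, burn=1000, draws=2000)
#: heavy schedule appropriate for cohort analyses
COHORT_SCHEDULE = ChainSchedule(n_chains=4, adapt=2000, burn=100_000, draws=100_000)


@dataclass(frozen=True)
class MultiCellModelSpec:
    """Priors and covariance structure for the multi-cell-type model.

    Default hyperpriors (all overridable): coefficient prior means 0;
    ``gamma_i ~ Gamma(0.01, 0.01)``; structure scales ``zeta, lambda,
    omega_l ~ Gamma(2, 1)``; ``sigma0m^2, sigma1m^2 ~ InvGamma(2, 1)``;
    unstructured ``T ~ InvWishart(m + 2, I)``; random-effect SDs
    ``sigma_S ~ half-Student-t(3, 0, 2.5)``.
    """

    structure: CovarianceStructure = field(
        default_factory=lambda: CovarianceStructure("unstructured")
    )
    tree: DifferentiationTree | None = None
    #: True, False, or "auto" (include the random subject effect exactly when
    #: some subject contributes more than one core; with one core per subject
    #: it is unidentifiable against the beta-binomial dispersion)
    subject_effects: bool | str = "auto"
    latent_p: bool = False
    gamma_prior: tuple[float, float] = (0.01, 0.01)      # Gamma(shape, rate)
    struct_gamma_prior: tuple[float, float] = (2.0, 1.0)  # zeta/lambda/omega
    scale_invgamma_prior: tuple[float, float] = (2.0, 1.0)  # sigma^2 (expdecay)
    sd_halft_scale: float = 2.5                           # random-effect SD
    sd_halft_df: float = 3.0

    def __post_init__(self):
        if self.structure.kind != "unstructured" and self.tree is None:
            raise ValueError(f"structure {self.structure.kind!r} requires a tree")

    def resolve_subject_effects(self, dataset: CountDataset) -> bool:
        if self.subject_effects == "auto":
            return bool(np.bincount(dataset.subject_idx).max() > 1)
        return bool(self.subject_effects)

    def validate_against(self, dataset: CountDataset) -> None:
        if self.tree is not None:
            if tuple(self.tree.nodes) != tuple(dataset.cell_types):
                missing = set(dataset.cell_types) - set(self.tree.nodes)
                if missing:
                    raise ValueError(
                        f"cell types absent from the tree: {sorted(missing)}"
                    )
                raise ValueError(
                    "tree nodes must match dataset cell types in order: "
                    f"{self.tree.nodes} vs {dataset.cell_types}"
                )


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """MCMC draws, shaped ``(n_chains, n_draws, ...)`` per parameter."""

    draws: dict[str, np.ndarray]
    cell_types: tuple[str, ...]
    covariate_names: tuple[str, ...]
    loglik: np.ndarray | None = None    # (n_chains, n_draws, n_cores, m)
    convergence: ConvergenceReport | None = None
    seed: int | None = None

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled: shape (n_chains * n_draws, ...)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def slope(self, cell_type: str, covariate: str | None = None) -> np.ndarray:
        """Pooled draws of the slope for one cell type (first covariate by
        default)."""
        q = 0 if covariate is None else self.covariate_names.index(covariate)
        i = self.cell_types.index(cell_type)
        return self.flat("beta")[:, q, i]

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-(covariate, cell type) posterior summary of the slopes."""
        rows = []
        for q, cov in enumerate(self.covariate_names):
            for i, ct in enumerate(self.cell_types):
                d = self.flat("beta")[:, q, i]
                call = significance_call_from_draws(d, level=level)
                psrf_val = None
                if self.convergence is not None:
                    psrf_val = self.convergence.psrf.get(f"beta[{cov}][{ct}]")
                rows.append(
                    {
                        "covariate": cov,
                        "cell_type": ct,
                        "mean": d.mean(),
                        "median": np.median(d),
                        "lower": call["lower"],
                        "upper": call["upper"],
                        "width": call["width"],
                        "significant": call["significant"],
                        "psrf": psrf_val,
                    }
                )
        return pd.DataFrame(rows)

    def pointwise_loglik(self, cell_type: str | None = None) -> np.ndarray:
        """Pooled pointwise log-likelihood matrix (draws x observations);
        optionally restricted to one cell type's core-level counts."""
        if self.loglik is None:
            raise ValueError("fit was run without loglik storage")
        ll = self.loglik.reshape(-1, *self.loglik.shape[2:])
        if cell_type is not None:
            ll = ll[:, :, self.cell_types.index(cell_type)]
            return ll
        return ll.reshape(ll.shape[0], -1)


def significance_call_from_draws(draws: np.ndarray, level: float = 0.95) -> dict:
    if draws.size < 1000:
        raise ValueError("need at least 1000 retained draws for a stable CI")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(draws, [alpha, 1.0 - alpha])
    return {
        "significant": bool(lower > 0 or upper < 0),
        "lower": float(lower),
        "upper": float(upper),
        "width": float(upper - lower),
    }


def significance_call(
    samples: PosteriorSamples,
    cell_type: str,
    covariate: str | None = None,
    level: float = 0.95,
) -> dict:
    """Equal-tailed credible interval call for one slope: significant iff
    the interval excludes zero."""
    return significance_call_from_draws(samples.slope(cell_type, covariate), level=level)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (small m)."""
    m = scale.shape[0]
    if m == 1:
        return scale / rng.chisquare(df)
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((m, m))
    A[np.diag_indices(m)] = np.sqrt(rng.chisquare(df - np.arange(m)))
    A[np.tril_indices(m, -1)] = rng.standard_normal(m * (m - 1) // 2)
    W = L @ A
    return np.linalg.inv(W @ W.T)


def betabinom_loglik(y, n, a, b, include_binom_coef: bool = True):
    """Beta-binomial log pmf, broadcastable.

    Parameter points outside the support (for example a shape driven to 0 or
    infinity by an extreme proposal) evaluate to ``-inf`` rather than NaN so
    that a Metropolis step rejects them cleanly.
    """
    with np.errstate(invalid="ignore"):
        out = (
            gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
            + gammaln(a + b) - gammaln(a) - gammaln(b)
        )
        if include_binom_coef:
            out = out + gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    if np.ndim(out):
        out[np.isnan(out)] = -np.inf
    elif np.isnan(out):
        out = -np.inf
    return out


def _halft_logpdf(x, df, scale):
    """Half-Student-t log density on x > 0 (unnormalized constants kept)."""
    return -0.5 * (df + 1.0) * np.log1p((x / scale) ** 2 / df)


def _gamma_logpdf(x, shape, rate):
    return (shape - 1.0) * np.log(x) - rate * x


def _invgamma_logpdf(x, shape, scale):
    return -(shape + 1.0) * np.log(x) - scale / x


def log_posterior(
    spec: MultiCellModelSpec,
    dataset: CountDataset,
    point: dict,
) -> float:
    """Unnormalized log posterior density at a parameter point.

    ``point`` maps parameter names to arrays: ``beta0`` (m,), ``beta``
    (q, m), ``gamma`` (m,), optionally ``S`` (m, n_subjects) and
    ``sigma_S`` (m,), plus structure parameters (``T`` list of explicit
    covariance matrices, or ``lam``/``omega``/``zeta``+``sigma`` per the
    structure kind).  Used for oracle checks and initialization; the
    sampler itself evaluates the same terms incrementally.
    """
    spec.validate_against(dataset)
    m, q = dataset.m, dataset.X.shape[1]
    beta0 = np.asarray(point["beta0"], dtype=float)
    beta = np.asarray(point["beta"], dtype=float).reshape(q, m)
    gamma = np.asarray(point["gamma"], dtype=float)
    if np.any(gamma <= 0):
        return -np.inf
    use_S = spec.resolve_subject_effects(dataset)
    eta = beta0[None, :] + dataset.X @ beta
    if use_S:
        S = np.asarray(point["S"], dtype=float)
        sigma_S = np.asarray(point["sigma_S"], dtype=float)
        eta = eta + S[:, dataset.subject_idx].T
    pi = expit(eta)
    a, b = gamma[None, :] * pi, gamma[None, :] * (1.0 - pi)
    lp = float(
        betabinom_loglik(dataset.counts, dataset.totals[:, None], a, b).sum()
    )
    # coefficient priors
    covs = _coef_covariances(spec, dataset, point)
    vecs = [beta0] + [beta[v] for v in range(q)]
    for vec, T in zip(vecs, covs):
        L = cholesky(T, lower=True)
        z = solve_triangular(L, vec, lower=True)
        lp += -0.5 * z @ z - np.log(np.diag(L)).sum() - 0.5 * m * _LOG_2PI
    lp += _structure_logprior(spec, dataset, point)
    g_shape, g_rate = spec.gamma_prior
    lp += float(_gamma_logpdf(gamma, g_shape, g_rate).sum())
    if use_S:
        lp += float(
            (-0.5 * (S / sigma_S[:, None]) ** 2 - np.log(sigma_S[:, None])).sum()
        )
        lp += float(_halft_logpdf(sigma_S, spec.sd_halft_df, spec.sd_halft_scale).sum())
    return lp


def _coef_covariances(spec, dataset, point) -> list[np.ndarray]:
    n_coef = 1 + dataset.X.shape[1]
    kind = spec.structure.kind
    if kind == "unstructured":
        return [np.asarray(T, dtype=float) for T in point["T"]]
    if kind == "tree":
        T = spec.structure.build(spec.tree)
        return [T] * n_coef
    if kind == "scaled_tree":
        return [spec.structure.build(spec.tree, [lam]) for lam in point["lam"]]
    if kind == "multilevel_tree":
        return [spec.structure.build(spec.tree, w) for w in point["omega"]]
    if kind == "expdecay":
        zeta = float(point["zeta"])
        return [
            spec.structure.build(spec.tree, np.concatenate([[zeta], sig]))
            for sig in point["sigma"]
        ]
    raise ValueError(kind)


def _structure_logprior(spec, dataset, point) -> float:
    kind = spec.structure.kind
    a, r = spec.struct_gamma_prior
    lp = 0.0
    if kind == "scaled_tree":
        lp += float(_gamma_logpdf(np.asarray(point["lam"]), a, r).sum())
    elif kind == "multilevel_tree":
        lp += float(_gamma_logpdf(np.asarray(point["omega"]), a, r).sum())
    elif kind == "expdecay":
        lp += float(_gamma_logpdf(float(point["zeta"]), a, r))
        ia, ib = spec.scale_invgamma_prior
        sig2 = np.asarray(point["sigma"], dtype=float) ** 2
        lp += float(_invgamma_logpdf(sig2, ia, ib).sum())
    elif kind == "unstructured":
        m = dataset.m
        nu = m + 2
        for T in point["T"]:
            T = np.asarray(T, dtype=float)
            sign, logdet = np.linalg.slogdet(T)
            if sign <= 0:
                return -np.inf
            lp += -0.5 * (nu + m + 1) * logdet - 0.5 * np.trace(np.linalg.inv(T))
    return lp


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _RMAdapt:
    """Robbins–Monro scale adaptation for (vectors of) proposal scales."""

    def __init__(self, shape, init=0.25, target=0.44):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.t = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        self.t += 1
        rate = min(0.25, 2.0 / (self.t + 20.0) ** 0.6)
        self.log_s += rate * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, -12.0, 6.0, out=self.log_s)


class _MultiCellSampler:
    """Adaptive Metropolis-within-Gibbs sampler for one chain."""

    def __init__(self, spec: MultiCellModelSpec, dataset: CountDataset, rng):
        self.spec = spec
        self.d = dataset
        self.rng = rng
        self.m = dataset.m
        self.q = dataset.X.shape[1]
        self.n_coef = 1 + self.q
        self.n_subj = dataset.n_subjects
        self.subject_effects = spec.resolve_subject_effects(dataset)

        # contiguous per-subject segments (dataset is sorted by subject)
        si = dataset.subject_idx
        if np.any(np.diff(si) < 0):
            raise ValueError("dataset cores must be sorted by subject")
        self.seg_starts = np.searchsorted(si, np.arange(self.n_subj))

        self.Y = dataset.counts.astype(float)
        self.N = dataset.totals.astype(float)[:, None]
        self._init_state()
        self._refresh_gamma_cache()
        self._init_structure()
        self._refresh_loglik()

    # ---- state ----------------------------------------------------------
    def _init_state(self):
        d, rng = self.d, self.rng
        pooled = (d.counts.sum(axis=0) + 0.5) / (d.totals.sum() + 1.0)
        self.beta0 = np.log(pooled / (1 - pooled)) + 0.1 * rng.standard_normal(self.m)
        self.beta = 0.1 * rng.standard_normal((self.q, self.m))
        self.log_gamma = np.log(20.0) + 0.2 * rng.standard_normal(self.m)
        if self.subject_effects:
            self.S = 0.01 * rng.standard_normal((self.m, self.n_subj))
            self.log_sigma_S = np.log(0.3) + 0.1 * rng.standard_normal(self.m)
        self.Xeta = self.d.X  # design matrix aligned with the eta rows
        self.eta = self._compute_eta()

        self.ad_beta0 = _RMAdapt(self.m, init=0.2)
        self.ad_beta = _RMAdapt((self.q, self.m), init=0.2)
        self.ad_gamma = _RMAdapt(self.m, init=0.4)
        if self.subject_effects:
            self.ad_S = _RMAdapt((self.m, self.n_subj), init=0.5)
            self.ad_sigS = _RMAdapt(self.m, init=0.4)
            self.ad_ridge = _RMAdapt(self.m, init=0.4)
            self.ad_rescale = _RMAdapt(self.m, init=0.3)

    def _compute_eta(self):
        eta = self.beta0[None, :] + self.d.X @ self.beta
        if self.subject_effects:
            eta = eta + self.S[:, self.d.subject_idx].T
        return eta

    def _init_structure(self):
        spec, m = self.spec, self.m
        kind = spec.structure.kind
        self.kind = kind
        if kind == "unstructured":
            self.T = [np.eye(m) for _ in range(self.n_coef)]
        elif kind == "tree":
            self.T_base = spec.structure.build(spec.tree)
        elif kind == "scaled_tree":
            self.T_base = CovarianceStructure("tree", block=spec.structure.block).build(spec.tree)
            self.log_lam = np.zeros(self.n_coef)
            self.ad_lam = _RMAdapt(self.n_coef, init=0.5)
        elif kind == "multilevel_tree":
            self.n_levels = spec.tree.max_level
            self.log_omega = np.zeros((self.n_coef, self.n_levels))
            self.ad_omega = _RMAdapt(self.n_coef, init=0.3, target=0.234)
            from .celltree import block_mask, level_indicator
            B = np.stack([level_indicator(spec.tree, l + 1) for l in range(self.n_levels)])
            if spec.structure.block:
                B = B * block_mask(spec.tree)[None, :, :]
            self.B_stack = B
        elif kind == "expdecay":
            from .celltree import path_distance
            nodes = spec.tree.nodes
            self.dist = np.array(
                [[path_distance(spec.tree, s, t) for t in nodes] for s in nodes]
            )
            self.log_zeta = np.log(2.0)
            self.log_sig = np.zeros((self.n_coef, m))
            self.ad_zeta = _RMAdapt((), init=0.4)
            self.ad_sig = _RMAdapt(self.n_coef, init=0.3, target=0.234)
        self._refresh_chols()

    def _multilevel_T(self, omega):
        return np.tensordot(omega, self.B_stack, axes=1) + PSD_JITTER * np.eye(self.m)

    def _expdecay_delta(self, zeta):
        return np.exp(-self.dist / zeta) + PSD_JITTER * np.eye(self.m)

    def _refresh_chols(self):
        """Cholesky factors of the current T for each coefficient vector."""
        kind, m = self.kind, self.m
        if kind == "unstructured":
            self.chols = [np.linalg.cholesky(T) for T in self.T]
        elif kind == "tree":
            L = np.linalg.cholesky(self.T_base)
            self.chols = [L] * self.n_coef
        elif kind == "scaled_tree":
            L = np.linalg.cholesky(self.T_base)
            self.chols = [np.sqrt(np.exp(ll)) * L for ll in self.log_lam]
        elif kind == "multilevel_tree":
            self.chols = [
                np.linalg.cholesky(self._multilevel_T(np.exp(w))) for w in self.log_omega
            ]
        elif kind == "expdecay":
            self.L_delta = np.linalg.cholesky(self._expdecay_delta(np.exp(self.log_zeta)))
            self.L_delta_inv = solve_triangular(
                self.L_delta, np.eye(m), lower=True, check_finite=False
            )
            self.L_delta_logdet = float(np.log(np.diag(self.L_delta)).sum())
            self.chols = [np.exp(ls)[:, None] * self.L_delta for ls in self.log_sig]
        self._refresh_derived()

    def _refresh_derived(self):
        """Cached triangular inverses and log-determinants of the prior
        Cholesky factors (the MVN prior is evaluated many times per sweep)."""
        self.chol_invs = [solve_triangular(L, np.eye(self.m), lower=True,
                                           check_finite=False) for L in self.chols]
        self.chol_logdets = [float(np.log(np.diag(L)).sum()) for L in self.chols]

    # ---- densities ------------------------------------------------------
    # The beta-binomial shapes satisfy a + b = gamma, so gammaln(a + b) and
    # gammaln(N + a + b) depend on gamma alone and are cached between
    # dispersion updates.
    def _refresh_gamma_cache(self):
        g = np.exp(self.log_gamma)
        with np.errstate(invalid="ignore"):
            self._lgam_g = gammaln(g)                      # (m,)
            self._lgam_ng = gammaln(self.N + g[None, :])   # (n_cores, m)

    def _obs_loglik(self, eta):
        """Core-level observation log-likelihood matrix (n_cores, m),
        binomial coefficient omitted (constant in the parameters)."""
        pi = expit(eta)
        g = np.exp(self.log_gamma)[None, :]
        a, b = g * pi, g * (1.0 - pi)
        with np.errstate(invalid="ignore"):
            out = (
                gammaln(self.Y + a) + gammaln(self.N - self.Y + b)
                - gammaln(a) - gammaln(b)
                + self._lgam_g[None, :] - self._lgam_ng
            )
        out[np.isnan(out)] = -np.inf
        return out

    def _obs_loglik_col(self, i, eta_col):
        pi = expit(eta_col)
        g = np.exp(self.log_gamma[i])
        a, b = g * pi, g * (1.0 - pi)
        with np.errstate(invalid="ignore"):
            out = (
                gammaln(self.Y[:, i] + a) + gammaln(self.N[:, 0] - self.Y[:, i] + b)
                - gammaln(a) - gammaln(b)
                + self._lgam_g[i] - self._lgam_ng[:, i]
            )
        out[np.isnan(out)] = -np.inf
        return out

    def _refresh_loglik(self):
        self.ll = self._obs_loglik(self.eta)

    def _coef_logprior(self, c, vec):
        z = self.chol_invs[c] @ vec
        return -0.5 * z @ z - self.chol_logdets[c]

    def _obs_loglik_gamma(self, log_gamma):
        """Observation log-likelihood matrix at the current linear predictor
        but an alternative dispersion vector (same term grouping as the
        cached path so accepted values are bit-identical)."""
        pi = expit(self.eta)
        g = np.exp(log_gamma)[None, :]
        a, b = g * pi, g * (1.0 - pi)
        with np.errstate(invalid="ignore"):
            out = (
                gammaln(self.Y + a) + gammaln(self.N - self.Y + b)
                - gammaln(a) - gammaln(b)
                + gammaln(g) - gammaln(self.N + g)
            )
        out[np.isnan(out)] = -np.inf
        return out

    # ---- sweep ----------------------------------------------------------
    def sweep(self, adapt: bool):
        self._update_coefs(adapt)
        self._update_gamma(adapt)
        if self.subject_effects:
            self._update_random_effects(adapt)
            self._update_sigma_S(adapt)
            self._update_dispersion_ridge(adapt)
            self._update_effect_rescale(adapt)
        self._update_structure(adapt)

    def _update_coefs(self, adapt):
        rng = self.rng
        # intercepts
        acc0 = np.zeros(self.m)
        for i in range(self.m):
            step = self.ad_beta0.scale[i] * rng.standard_normal()
            prop = self.beta0.copy()
            prop[i] += step
            new_col = self.eta[:, i] + step
            new_ll = self._obs_loglik_col(i, new_col)
            delta = (
                new_ll.sum() - self.ll[:, i].sum()
                + self._coef_logprior(0, prop) - self._coef_logprior(0, self.beta0)
            )
            if np.log(rng.random()) < delta:
                self.beta0 = prop
                self.eta[:, i] = new_col
                self.ll[:, i] = new_ll
                acc0[i] = 1.0
        if adapt:
            self.ad_beta0.update(acc0)
        # slopes
        accb = np.zeros((self.q, self.m))
        for v in range(self.q):
            xv = self.Xeta[:, v]
            for i in range(self.m):
                step = self.ad_beta.scale[v, i] * rng.standard_normal()
                prop = self.beta[v].copy()
                prop[i] += step
                new_col = self.eta[:, i] + step * xv
                new_ll = self._obs_loglik_col(i, new_col)
                delta = (
                    new_ll.sum() - self.ll[:, i].sum()
                    + self._coef_logprior(1 + v, prop)
                    - self._coef_logprior(1 + v, self.beta[v])
                )
                if np.log(rng.random()) < delta:
                    self.beta[v] = prop
                    self.eta[:, i] = new_col
                    self.ll[:, i] = new_ll
                    accb[v, i] = 1.0
        if adapt:
            self.ad_beta.update(accb)

    def _update_gamma(self, adapt):
        rng = self.rng
        prop = self.log_gamma + self.ad_gamma.scale * rng.standard_normal(self.m)
        old_lg = self.log_gamma
        new_ll = self._obs_loglik_gamma(prop)
        shape, rate = self.spec.gamma_prior
        # Gamma prior + log-scale Jacobian: shape * log(gamma) - rate * gamma
        prior_new = shape * prop - rate * np.exp(prop)
        prior_old = shape * old_lg - rate * np.exp(old_lg)
        delta = new_ll.sum(axis=0) - self.ll.sum(axis=0) + prior_new - prior_old
        accept = np.log(rng.random(self.m)) < delta
        self.log_gamma = np.where(accept, prop, old_lg)
        self.ll[:, accept] = new_ll[:, accept]
        if np.any(accept):
            self._refresh_gamma_cache()
        if adapt:
            self.ad_gamma.update(accept)

    def _segsum(self, mat):
        """Sum a (n_cores, m) matrix over the contiguous cores of each
        subject -> (m, n_subjects)."""
        return np.add.reduceat(mat, self.seg_starts, axis=0).T

    def _update_random_effects(self, adapt):
        rng = self.rng
        step = self.ad_S.scale * rng.standard_normal((self.m, self.n_subj))
        new_eta = self.eta + self._rescale_eta_delta(step)
        new_ll = self._obs_loglik(new_eta)
        d_lik = self._segsum(new_ll) - self._segsum(self.ll)     # (m, n_subj)
        sig = np.exp(self.log_sigma_S)[:, None]
        Sp = self.S + step
        d_prior = -0.5 * (Sp / sig) ** 2 + 0.5 * (self.S / sig) ** 2
        accept = np.log(rng.random((self.m, self.n_subj))) < d_lik + d_prior
        self.S = np.where(accept, Sp, self.S)
        row_accept = self._rescale_eta_delta(accept)             # (rows, m) bool
        self.eta = np.where(row_accept, new_eta, self.eta)
        self.ll = np.where(row_accept, new_ll, self.ll)
        if adapt:
            self.ad_S.update(accept)

    def _update_sigma_S(self, adapt):
        rng = self.rng
        prop = self.log_sigma_S + self.ad_sigS.scale * rng.standard_normal(self.m)
        sse = (self.S**2).sum(axis=1)

        def logpost(log_sig):
            sig = np.exp(log_sig)
            return (
                -self.n_subj * log_sig - 0.5 * sse / sig**2
                + _halft_logpdf(sig, self.spec.sd_halft_df, self.spec.sd_halft_scale)
                + log_sig  # Jacobian of log transform
            )

        delta = logpost(prop) - logpost(self.log_sigma_S)
        accept = np.log(rng.random(self.m)) < delta
        self.log_sigma_S = np.where(accept, prop, self.log_sigma_S)
        if adapt:
            self.ad_sigS.update(accept)

    def _sigma_S_logpost(self, log_sig, sse):
        """Log density terms involving sigma_S (normal prior of S, half-t
        hyperprior, log-scale Jacobian)."""
        sig = np.exp(log_sig)
        return (
            -self.n_subj * log_sig - 0.5 * sse / sig**2
            + _halft_logpdf(sig, self.spec.sd_halft_df, self.spec.sd_halft_scale)
            + log_sig
        )

    def _update_dispersion_ridge(self, adapt):
        """Joint move along the gamma / sigma_S ridge: with one or few cores
        per subject the beta-binomial dispersion and the subject-effect SD
        trade off; moving both log-parameters together mixes across the
        ridge that coordinatewise updates crawl along."""
        rng = self.rng
        eps = self.ad_ridge.scale * rng.standard_normal(self.m)
        lg_new = self.log_gamma + eps
        ls_new = self.log_sigma_S + eps
        new_ll = self._obs_loglik_gamma(lg_new)
        shape, rate = self.spec.gamma_prior
        sse = (self.S**2).sum(axis=1)
        delta = (
            new_ll.sum(axis=0) - self.ll.sum(axis=0)
            + shape * lg_new - rate * np.exp(lg_new)
            - (shape * self.log_gamma - rate * np.exp(self.log_gamma))
            + self._sigma_S_logpost(ls_new, sse)
            - self._sigma_S_logpost(self.log_sigma_S, sse)
        )
        accept = np.log(rng.random(self.m)) < delta
        self.log_gamma = np.where(accept, lg_new, self.log_gamma)
        self.log_sigma_S = np.where(accept, ls_new, self.log_sigma_S)
        self.ll[:, accept] = new_ll[:, accept]
        if np.any(accept):
            self._refresh_gamma_cache()
        if adapt:
            self.ad_ridge.update(accept)

    def _rescale_eta_delta(self, shift):
        """Row-level linear-predictor increments for per-subject shifts
        (m, n_subjects) -> (rows, m)."""
        return shift[:, self.d.subject_idx].T

    def _update_effect_rescale(self, adapt):
        """Ancillarity move: scale a cell type's random effects and their SD
        by a common factor c, leaving S/sigma_S fixed.  The acceptance ratio
        carries the Jacobian c^{n_subjects} of the scaling."""
        rng = self.rng
        eps = self.ad_rescale.scale * rng.standard_normal(self.m)
        c = np.exp(eps)
        shift = (c[:, None] - 1.0) * self.S
        new_eta = self.eta + self._rescale_eta_delta(shift)
        new_ll = self._obs_loglik(new_eta)
        sig = np.exp(self.log_sigma_S)
        # S-prior ratio cancels (S/sigma fixed) except the -n*eps normalizer,
        # which the S-scaling Jacobian +n*eps exactly offsets; remaining terms:
        delta = (
            (new_ll - self.ll).sum(axis=0)
            + _halft_logpdf(c * sig, self.spec.sd_halft_df, self.spec.sd_halft_scale)
            - _halft_logpdf(sig, self.spec.sd_halft_df, self.spec.sd_halft_scale)
            + eps  # log-sigma Jacobian
        )
        accept = np.log(rng.random(self.m)) < delta
        self.S = np.where(accept[:, None], c[:, None] * self.S, self.S)
        self.log_sigma_S = np.where(accept, self.log_sigma_S + eps, self.log_sigma_S)
        row_accept = np.broadcast_to(accept[None, :], new_eta.shape)
        self.eta = np.where(row_accept, new_eta, self.eta)
        self.ll = np.where(row_accept, new_ll, self.ll)
        if adapt:
            self.ad_rescale.update(accept)

    # ---- structure parameters ------------------------------------------
    def _coef_vectors(self):
        return [self.beta0] + [self.beta[v] for v in range(self.q)]

    def _update_structure(self, adapt):
        rng = self.rng
        a_pr, r_pr = self.spec.struct_gamma_prior
        if self.kind == "unstructured":
            nu = self.m + 2
            for c, vec in enumerate(self._coef_vectors()):
                scale = np.eye(self.m) + np.outer(vec, vec)
                self.T[c] = _invwishart_rvs(nu + 1, scale, rng)
            self._refresh_chols()
        elif self.kind == "scaled_tree":
            acc = np.zeros(self.n_coef)
            vecs = self._coef_vectors()
            L = cholesky(self.T_base, lower=True)
            logdet_base = np.log(np.diag(L)).sum()
            for c, vec in enumerate(vecs):
                z = solve_triangular(L, vec, lower=True, check_finite=False)
                quad = z @ z
                cur = self.log_lam[c]
                prop = cur + self.ad_lam.scale[c] * rng.standard_normal()

                def lp(ll):
                    lam = np.exp(ll)
                    return (
                        -0.5 * quad / lam - 0.5 * self.m * ll - logdet_base
                        + a_pr * ll - r_pr * lam  # Gamma prior + Jacobian
                    )

                if np.log(rng.random()) < lp(prop) - lp(cur):
                    self.log_lam[c] = prop
                    acc[c] = 1.0
            if adapt:
                self.ad_lam.update(acc)
            self._refresh_chols()
        elif self.kind == "multilevel_tree":
            acc = np.zeros(self.n_coef)
            for c, vec in enumerate(self._coef_vectors()):
                cur = self.log_omega[c]
                prop = cur + self.ad_omega.scale[c] * rng.standard_normal(self.n_levels)

                def lp(lw, L):
                    z = solve_triangular(L, vec, lower=True, check_finite=False)
                    return (
                        -0.5 * z @ z - np.log(np.diag(L)).sum()
                        + (a_pr * lw - r_pr * np.exp(lw)).sum()
                    )

                L_prop = np.linalg.cholesky(self._multilevel_T(np.exp(prop)))
                if np.log(rng.random()) < lp(prop, L_prop) - lp(cur, self.chols[c]):
                    self.log_omega[c] = prop
                    self.chols[c] = L_prop
                    acc[c] = 1.0
            if adapt:
                self.ad_omega.update(acc)
            self._refresh_derived()
        elif self.kind == "expdecay":
            self._update_expdecay(adapt, a_pr, r_pr)

    def _update_expdecay(self, adapt, a_pr, r_pr):
        rng = self.rng
        vecs = self._coef_vectors()

        scaled_vecs = np.stack(
            [vec / np.exp(self.log_sig[c]) for c, vec in enumerate(vecs)]
        )  # (n_coef, m)

        def zeta_logprior(log_zeta, Linv, logdet):
            z = scaled_vecs @ Linv.T
            return (
                a_pr * log_zeta - r_pr * np.exp(log_zeta)
                - 0.5 * (z * z).sum() - self.n_coef * logdet
            )

        # zeta (shared across coefficient vectors); the current state's
        # Cholesky of Delta and its inverse are cached
        prop_z = self.log_zeta + self.ad_zeta.scale * rng.standard_normal()
        L_new = np.linalg.cholesky(self._expdecay_delta(np.exp(prop_z)))
        Linv_new = solve_triangular(L_new, np.eye(self.m), lower=True, check_finite=False)
        logdet_new = float(np.log(np.diag(L_new)).sum())
        acc_z = np.log(rng.random()) < (
            zeta_logprior(prop_z, Linv_new, logdet_new)
            - zeta_logprior(self.log_zeta, self.L_delta_inv, self.L_delta_logdet)
        )
        if acc_z:
            self.log_zeta = prop_z
            self.L_delta, self.L_delta_inv, self.L_delta_logdet = L_new, Linv_new, logdet_new
        if adapt:
            self.ad_zeta.update(1.0 if acc_z else 0.0)
        # per-vector scale blocks
        ia, ib = self.spec.scale_invgamma_prior
        acc = np.zeros(self.n_coef)
        for c, vec in enumerate(vecs):
            cur = self.log_sig[c]
            prop = cur + self.ad_sig.scale[c] * rng.standard_normal(self.m)

            def lp(ls):
                sig = np.exp(ls)
                z = self.L_delta_inv @ (vec / sig)
                # InvGamma(ia, ib) on sigma^2 with Jacobian d sigma^2 / d log sigma
                return (
                    -0.5 * z @ z - ls.sum()
                    + (_invgamma_logpdf(sig**2, ia, ib) + 2.0 * ls).sum()
                )

            if np.log(rng.random()) < lp(prop) - lp(cur):
                self.log_sig[c] = prop
                acc[c] = 1.0
        if adapt:
            self.ad_sig.update(acc)
        self._refresh_chols()

    # ---- structure draw snapshot ---------------------------------------
    def structure_state(self) -> dict[str, np.ndarray]:
        if self.kind == "unstructured":
            return {"T": np.stack(self.T)}
        if self.kind == "scaled_tree":
            return {"lam": np.exp(self.log_lam)}
        if self.kind == "multilevel_tree":
            return {"omega": np.exp(self.log_omega)}
        if self.kind == "expdecay":
            return {"zeta": np.asarray(np.exp(self.log_zeta)),
                    "sigma": np.exp(self.log_sig)}
        return {}


# ---------------------------------------------------------------------------
# latent-p sampler variant
# ---------------------------------------------------------------------------

class _LatentPSampler(_MultiCellSampler):
    """Variant that samples the per-subject latent probabilities p_igj
    explicitly instead of integrating them out.  The linear-predictor and
    dispersion updates then act on the Beta density of p, while the
    binomial counts enter only through the p update."""

    def _init_state(self):
        d = self.d
        # per-subject aggregates and subject-level covariates (needed by
        # _compute_eta, which the base initializer calls)
        self.Y_subj = np.add.reduceat(d.counts.astype(float), self.seg_starts, axis=0)
        self.N_subj = np.add.reduceat(
            d.totals.astype(float), self.seg_starts
        )[:, None]                                                   # (n_subj, 1)
        self.X_subj = d.X[self.seg_starts]
        p0 = (self.Y_subj + 0.5) / (self.N_subj + 1.0)
        self.logit_p = np.log(p0 / (1 - p0))
        self.ad_p = _RMAdapt((self.n_subj, self.m), init=0.5)
        super()._init_state()
        self.Xeta = self.X_subj

    def _compute_eta(self):
        # in this variant the linear predictor lives at subject level
        eta = self.beta0[None, :] + self.X_subj @ self.beta
        if self.subject_effects and hasattr(self, "S"):
            eta = eta + self.S.T
        return eta

    # "observation" loglik for coefficient/gamma/S updates = Beta density of p
    def _beta_density(self, logit_p, eta, log_gamma):
        pi = expit(eta)
        g = np.exp(log_gamma)[None, :]
        a, b = g * pi, g * (1 - pi)
        p = expit(logit_p)
        return (
            (a - 1) * np.log(p) + (b - 1) * np.log1p(-p)
            + gammaln(a + b) - gammaln(a) - gammaln(b)
        )

    def _obs_loglik(self, eta):
        return self._beta_density(self.logit_p, eta, self.log_gamma)

    def _obs_loglik_col(self, i, eta_col):
        pi = expit(eta_col)
        g = np.exp(self.log_gamma[i])
        a, b = g * pi, g * (1 - pi)
        p = expit(self.logit_p[:, i])
        return (
            (a - 1) * np.log(p) + (b - 1) * np.log1p(-p)
            + gammaln(a + b) - gammaln(a) - gammaln(b)
        )

    def _obs_loglik_gamma(self, log_gamma):
        return self._beta_density(self.logit_p, self.eta, log_gamma)

    def _segsum(self, mat):
        # eta rows are already one-per-subject here
        return mat.T

    def _rescale_eta_delta(self, shift):
        return shift.T

    def sweep(self, adapt):
        self._update_p(adapt)
        super().sweep(adapt)

    def _update_p(self, adapt):
        rng = self.rng
        prop = self.logit_p + self.ad_p.scale * rng.standard_normal((self.n_subj, self.m))
        p_new, p_old = expit(prop), expit(self.logit_p)
        binom_new = self.Y_subj * np.log(p_new) + (self.N_subj - self.Y_subj) * np.log1p(-p_new)
        binom_old = self.Y_subj * np.log(p_old) + (self.N_subj - self.Y_subj) * np.log1p(-p_old)
        beta_new = self._beta_density(prop, self.eta, self.log_gamma)
        # Jacobian of the logit transform: log p + log(1 - p)
        jac_new = np.log(p_new) + np.log1p(-p_new)
        jac_old = np.log(p_old) + np.log1p(-p_old)
        delta = binom_new - binom_old + beta_new - self.ll + jac_new - jac_old
        accept = np.log(rng.random((self.n_subj, self.m))) < delta
        self.logit_p = np.where(accept, prop, self.logit_p)
        self.ll = np.where(accept, beta_new, self.ll)
        if adapt:
            self.ad_p.update(accept)

    def core_loglik(self):
        """Core-level binomial log-likelihood at the current latent p."""
        p = expit(self.logit_p)[self.d.subject_idx]
        return (
            gammaln(self.N + 1) - gammaln(self.Y + 1) - gammaln(self.N - self.Y + 1)
            + self.Y * np.log(p) + (self.N - self.Y) * np.log1p(-p)
        )


# ---------------------------------------------------------------------------
# fitting front ends
# ---------------------------------------------------------------------------

def fit_multicell(
    spec: MultiCellModelSpec,
    dataset: CountDataset,
    schedule: ChainSchedule = SIMULATION_SCHEDULE,
    seed: int = 0,
    store_loglik: bool = True,
    thin: int = 1,
) -> PosteriorSamples:
    """Fit the multi-cell-type beta-binomial model by MCMC.

    Runs ``schedule.n_chains`` independent chains (proposal adaptation during
    the first ``adapt`` sweeps, ``burn`` discarded sweeps, ``draws`` retained
    draws per chain), computes the PSRF convergence report over the stored
    parameters, and optionally stores the pointwise core-level log-likelihood
    for PSIS-LOO model comparison.
    """
    spec.validate_against(dataset)
    m, q = dataset.m, dataset.X.shape[1]
    ndraw = schedule.draws
    cls = _LatentPSampler if spec.latent_p else _MultiCellSampler

    logC = (
        gammaln(dataset.totals[:, None] + 1)
        - gammaln(dataset.counts + 1)
        - gammaln(dataset.totals[:, None] - dataset.counts + 1)
    )

    chains: dict[str, list[np.ndarray]] = {}
    ll_store = [] if store_loglik else None
    for c in range(schedule.n_chains):
        rng = np.random.default_rng([int(seed) % (2**31 - 1), c])
        smp = cls(spec, dataset, rng)
        store: dict[str, list] = {}
        lls = []
        for it in range(schedule.adapt + schedule.burn + ndraw * thin):
            smp.sweep(adapt=it < schedule.adapt)
            k = it - schedule.adapt - schedule.burn
            if k >= 0 and k % thin == 0:
                store.setdefault("beta0", []).append(smp.beta0.copy())
                store.setdefault("beta", []).append(smp.beta.copy())
                store.setdefault("gamma", []).append(np.exp(smp.log_gamma))
                if smp.subject_effects:
                    store.setdefault("sigma_S", []).append(np.exp(smp.log_sigma_S))
                for name, val in smp.structure_state().items():
                    store.setdefault(name, []).append(np.array(val, copy=True))
                if store_loglik:
                    if spec.latent_p:
                        lls.append(smp.core_loglik().astype(np.float32))
                    else:
                        lls.append((smp.ll + logC).astype(np.float32))
        for name, vals in store.items():
            chains.setdefault(name, []).append(np.stack(vals))
        if store_loglik:
            ll_store.append(np.stack(lls))

    draws = {name: np.stack(vals) for name, vals in chains.items()}
    loglik = np.stack(ll_store) if store_loglik else None

    monitor = _monitored_params(draws, dataset)
    convergence = compute_convergence(monitor)
    if not convergence.converged:
        logger.warning(
            "fit flagged non-converged: max PSRF %.3f", convergence.max_psrf
        )
    return PosteriorSamples(
        draws=draws,
        cell_types=dataset.cell_types,
        covariate_names=dataset.covariate_names,
        loglik=loglik,
        convergence=convergence,
        seed=seed,
    )


def _monitored_params(draws: dict[str, np.ndarray], dataset: CountDataset) -> dict:
    """Flatten stored draws into named scalar chains for PSRF monitoring."""
    out = {}
    cts, covs = dataset.cell_types, dataset.covariate_names
    for i, ct in enumerate(cts):
        out[f"beta0[{ct}]"] = draws["beta0"][:, :, i]
        out[f"gamma[{ct}]"] = np.log(draws["gamma"][:, :, i])
        for v, cov in enumerate(covs):
            out[f"beta[{cov}][{ct}]"] = draws["beta"][:, :, v, i]
        if "sigma_S" in draws:
            out[f"sigma_S[{ct}]"] = np.log(draws["sigma_S"][:, :, i])
    if "lam" in draws:
        for c in range(draws["lam"].shape[2]):
            out[f"lambda[{c}]"] = np.log(draws["lam"][:, :, c])
    if "zeta" in draws:
        out["zeta"] = np.log(draws["zeta"])
    return out


def fit_singlecell(
    dataset: CountDataset,
    cell_type: str,
    schedule: ChainSchedule = SIMULATION_SCHEDULE,
    seed: int = 0,
    subject_effects: bool | str = "auto",
    latent_p: bool = False,
    store_loglik: bool = True,
) -> PosteriorSamples:
    """Single-cell-type comparator: the same beta-binomial hierarchy fit to
    one cell type with scalar (inverse-Wishart, here inverse-gamma) priors
    on the coefficient variances."""
    sub = dataset.select(cell_type)
    spec = MultiCellModelSpec(
        structure=CovarianceStructure("unstructured"),
        subject_effects=subject_effects,
        latent_p=latent_p,
    )
    return fit_multicell(
        spec, sub, schedule=schedule, seed=seed, store_loglik=store_loglik
    )
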