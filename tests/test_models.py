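"""Tests for the hierarchical beta-binomial models and their sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from btime.celltree import CovarianceStructure, DifferentiationTree
from btime.models import (
    ChainSchedule,
    CountDataset,
    MultiCellModelSpec,
    betabinom_loglik,
    fit_multicell,
    fit_singlecell,
    log_posterior,
    significance_call,
    significance_call_from_draws,
)
from btime.simulate import SimConfig, generate_dataset

QUICK = ChainSchedule(n_chains=2, adapt=400, burn=300, draws=1000)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

def _toy_frame():
    return pd.DataFrame(
        {
            "core_id": ["c1", "c2", "c3", "c4", "c5"],
            "subject_id": ["s1", "s1", "s2", "s2", "s3"],
            "stage": [0, 0, 1, 1, 1],
            "age": [52.0, 52.0, 64.0, 64.0, 71.0],
            "total_cells": [100, 80, 5, 120, 90],
            "A": [10, 8, 1, 30, 9],
            "B": [2, 1, 0, 4, 3],
        }
    )


class TestCountDataset:
    def test_low_count_cores_excluded(self):
        cd = CountDataset.from_frame(_toy_frame(), ["A", "B"], ["stage"])
        assert cd.n_cores == 4
        assert cd.n_excluded == 1

    def test_exclusion_threshold_configurable(self):
        cd = CountDataset.from_frame(_toy_frame(), ["A", "B"], ["stage"], min_total=1)
        assert cd.n_cores == 5 and cd.n_excluded == 0

    def test_subjects_contiguous(self):
        cd = CountDataset.from_frame(_toy_frame(), ["A", "B"], ["stage"])
        assert np.all(np.diff(cd.subject_idx) >= 0)
        assert cd.n_subjects == 3

    def test_continuous_covariate_standardized(self):
        cd = CountDataset.from_frame(_toy_frame(), ["A"], ["age"])
        assert cd.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert cd.X[:, 0].std() == pytest.approx(1.0)

    def test_binary_covariate_untouched(self):
        cd = CountDataset.from_frame(_toy_frame(), ["A"], ["stage"])
        assert set(np.unique(cd.X[:, 0])) == {0.0, 1.0}

    def test_constant_covariate_rejected(self):
        df = _toy_frame()
        df["flat"] = 1
        with pytest.raises(ValueError, match="flat"):
            CountDataset.from_frame(df, ["A"], ["flat"])

    def test_counts_above_totals_rejected(self):
        df = _toy_frame()
        df.loc[0, "A"] = 999
        with pytest.raises(ValueError):
            CountDataset.from_frame(df, ["A"], ["stage"])

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="Z"):
            CountDataset.from_frame(_toy_frame(), ["A", "Z"], ["stage"])

    def test_select_single_cell_type(self):
        cd = CountDataset.from_frame(_toy_frame(), ["A", "B"], ["stage"])
        sub = cd.select("B")
        assert sub.m == 1 and sub.cell_types == ("B",)
        np.testing.assert_array_equal(sub.counts[:, 0], cd.counts[:, 1])


# ---------------------------------------------------------------------------
# log posterior vs an independent term-by-term oracle
# ---------------------------------------------------------------------------

def _oracle_log_posterior(spec, cd, point, tree):
    """Brute-force summation with scipy.stats densities (up to the same
    additive constants as the implementation drops)."""
    beta0 = point["beta0"]
    beta = point["beta"]
    gamma = point["gamma"]
    S = point["S"]
    sigma_S = point["sigma_S"]
    lam = point["lam"]
    lp = 0.0
    for c in range(cd.n_cores):
        for i in range(cd.m):
            eta = beta0[i] + beta[0, i] * cd.X[c, 0] + S[i, cd.subject_idx[c]]
            pi = 1.0 / (1.0 + np.exp(-eta))
            lp += stats.betabinom.logpmf(
                cd.counts[c, i], cd.totals[c], gamma[i] * pi, gamma[i] * (1 - pi)
            )
    from btime.celltree import build_tree_covariance

    T = build_tree_covariance(tree)
    lp += stats.multivariate_normal.logpdf(beta0, mean=np.zeros(2), cov=lam[0] * T)
    lp += stats.multivariate_normal.logpdf(beta[0], mean=np.zeros(2), cov=lam[1] * T)
    # unnormalized pieces, matching the implementation's dropped constants
    lp += np.sum((0.01 - 1) * np.log(gamma) - 0.01 * gamma)
    lp += np.sum((2 - 1) * np.log(lam) - 1.0 * lam)
    for i in range(cd.m):
        lp += np.sum(stats.norm.logpdf(S[i], 0, sigma_S[i]))
    lp += np.sum(-2.0 * np.log1p((sigma_S / 2.5) ** 2 / 3.0))
    return lp


def test_log_posterior_matches_bruteforce_oracle():
    tree = DifferentiationTree(
        ["A", "B"], {"A": None, "B": "A"}, {"A": 0, "B": 1}, {"A": 1, "B": 2}
    )
    cd = CountDataset.from_frame(_toy_frame(), ["A", "B"], ["stage"], min_total=1)
    spec = MultiCellModelSpec(structure=CovarianceStructure("scaled_tree"), tree=tree)
    rng = np.random.default_rng(0)

    def random_point():
        return {
            "beta0": rng.normal(-2, 0.5, 2),
            "beta": rng.normal(0, 0.3, (1, 2)),
            "gamma": rng.uniform(5, 30, 2),
            "S": rng.normal(0, 0.2, (2, 3)),
            "sigma_S": rng.uniform(0.1, 0.6, 2),
            "lam": rng.uniform(0.5, 3.0, 2),
        }

    p1, p2 = random_point(), random_point()
    mine = log_posterior(spec, cd, p1) - log_posterior(spec, cd, p2)
    oracle = _oracle_log_posterior(spec, cd, p1, tree) - _oracle_log_posterior(
        spec, cd, p2, tree
    )
    assert abs(mine - oracle) < 1e-8


def test_log_posterior_rejects_invalid_gamma():
    tree = DifferentiationTree(
        ["A", "B"], {"A": None, "B": "A"}, {"A": 0, "B": 1}, {"A": 1, "B": 2}
    )
    cd = CountDataset.from_frame(_toy_frame(), ["A", "B"], ["stage"], min_total=1)
    spec = MultiCellModelSpec(structure=CovarianceStructure("scaled_tree"), tree=tree)
    point = {
        "beta0": np.zeros(2),
        "beta": np.zeros((1, 2)),
        "gamma": np.array([-1.0, 5.0]),
        "S": np.zeros((2, 3)),
        "sigma_S": np.ones(2),
        "lam": np.ones(2),
    }
    assert log_posterior(spec, cd, point) == -np.inf


def test_marginal_count_distribution_approaches_binomial():
    """With gamma large the beta-binomial marginal collapses to the binomial:
    total-variation distance below 1e-2."""
    N, mu = 30, 0.2
    y = np.arange(N + 1)
    big_gamma = 1e6
    bb = np.exp(
        betabinom_loglik(y, N, big_gamma * mu, big_gamma * (1 - mu))
    )
    binom = stats.binom.pmf(y, N, mu)
    assert 0.5 * np.abs(bb - binom).sum() < 0.01


def test_binomial_term_is_zero_at_saturation():
    # Y = N with p -> 1: the count term contributes log(1) = 0
    val = betabinom_loglik(10, 10, 1e8 * (1 - 1e-10), 1e8 * 1e-10)
    assert val == pytest.approx(0.0, abs=1e-3)


# ---------------------------------------------------------------------------
# significance calls
# ---------------------------------------------------------------------------

class TestSignificanceCall:
    def test_constant_draws(self):
        call = significance_call_from_draws(np.full(2000, 0.5))
        assert call["significant"]
        assert call["lower"] == call["upper"] == 0.5
        assert call["width"] == 0.0

    def test_symmetric_draws_not_significant(self):
        rng = np.random.default_rng(0)
        call = significance_call_from_draws(rng.standard_normal(5000))
        assert not call["significant"]

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(1)
        call = significance_call_from_draws(rng.standard_normal(100_000))
        assert call["lower"] == pytest.approx(-1.96, abs=0.03)
        assert call["upper"] == pytest.approx(1.96, abs=0.03)
        assert call["width"] == pytest.approx(3.92, abs=0.05)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            significance_call_from_draws(np.zeros(100))


# ---------------------------------------------------------------------------
# sampler behavior
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def m1_dataset(sim_dataset_60):
    return sim_dataset_60.select("M1")


def test_deterministic_given_seed(m1_dataset):
    sched = ChainSchedule(n_chains=2, adapt=100, burn=50, draws=200)
    a = fit_multicell(MultiCellModelSpec(), m1_dataset, schedule=sched, seed=9)
    b = fit_multicell(MultiCellModelSpec(), m1_dataset, schedule=sched, seed=9)
    np.testing.assert_array_equal(a.draws["beta0"], b.draws["beta0"])
    np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])
    c = fit_multicell(MultiCellModelSpec(), m1_dataset, schedule=sched, seed=10)
    assert not np.array_equal(a.draws["beta"], c.draws["beta"])


def test_single_cell_is_multicell_at_m1(m1_dataset):
    """Structural nesting: the single-cell comparator is exactly the joint
    model restricted to one cell type."""
    single = fit_singlecell(
        m1_dataset, "M1", schedule=QUICK, seed=4, store_loglik=False
    )
    joint = fit_multicell(
        MultiCellModelSpec(), m1_dataset, schedule=QUICK, seed=4, store_loglik=False
    )
    np.testing.assert_array_equal(single.draws["beta"], joint.draws["beta"])


def test_marginalized_and_latent_p_agree(m1_dataset):
    """Integrating p out analytically and sampling it explicitly target the
    same posterior when each subject has one core."""
    marg = fit_singlecell(m1_dataset, "M1", schedule=QUICK, seed=2, store_loglik=False)
    lat = fit_singlecell(
        m1_dataset, "M1", schedule=QUICK, seed=3, latent_p=True, store_loglik=False
    )
    m_d, l_d = marg.slope("M1"), lat.slope("M1")
    pooled_sd = np.sqrt((m_d.var() + l_d.var()) / 2)
    assert abs(m_d.mean() - l_d.mean()) < 0.5 * pooled_sd + 0.05
    w_m = significance_call(marg, "M1")["width"]
    w_l = significance_call(lat, "M1")["width"]
    assert 0.7 < w_m / w_l < 1.4


def test_all_zero_counts_concentrate_near_zero():
    df = pd.DataFrame(
        {
            "core_id": [f"c{i}" for i in range(20)],
            "subject_id": [f"s{i}" for i in range(20)],
            "group": [0, 1] * 10,
            "total_cells": [200] * 20,
            "Z": [0] * 20,
        }
    )
    cd = CountDataset.from_frame(df, ["Z"], ["group"])
    fit = fit_singlecell(cd, "Z", schedule=QUICK, seed=5, store_loglik=False)
    pi_post = 1.0 / (1.0 + np.exp(-fit.flat("beta0")[:, 0]))
    assert np.median(pi_post) < 0.1
    call = significance_call(fit, "Z")
    assert not call["significant"]
    assert call["width"] > 1.0  # no information about the contrast


def test_cell_type_label_equivariance(sim_dataset_60):
    """Permuting the cell-type columns permutes the slope posteriors."""
    perm = ["M2", "M1", "M4", "M3"]
    df = generate_dataset(SimConfig(perturb_fraction=0.6, seed=5), seed=1234).to_frame()
    cd_perm = CountDataset.from_frame(df, cell_types=perm, covariates=["group"])
    sched = ChainSchedule(n_chains=2, adapt=500, burn=300, draws=1200)
    base = fit_multicell(MultiCellModelSpec(), sim_dataset_60, schedule=sched, seed=6,
                         store_loglik=False)
    swapped = fit_multicell(MultiCellModelSpec(), cd_perm, schedule=sched, seed=7,
                            store_loglik=False)
    for ct in ("M1", "M2"):
        a, b = base.slope(ct), swapped.slope(ct)
        tol = 3 * np.sqrt(a.var() / 200 + b.var() / 200) + 0.05
        assert abs(a.mean() - b.mean()) < tol


def test_prior_predictive_moments_match_beta_binomial():
    """Simulating from the model's generative story reproduces the
    beta-binomial mean and variance implied by (pi, gamma)."""
    rng = np.random.default_rng(8)
    N, pi, gamma = 500, 0.1, 19.0
    n_draws = 40_000
    p = rng.beta(gamma * pi, gamma * (1 - pi), size=n_draws)
    y = rng.binomial(N, p)
    rho = 1.0 / (gamma + 1.0)
    expected_var = N * pi * (1 - pi) * (1 + (N - 1) * rho)
    assert y.mean() == pytest.approx(N * pi, rel=0.02)
    assert y.var() == pytest.approx(expected_var, rel=0.06)


def test_tree_mismatch_rejected(sim_dataset_60, nhs):
    spec = MultiCellModelSpec(structure=CovarianceStructure("tree"), tree=nhs)
    with pytest.raises(ValueError, match="tree"):
        fit_multicell(spec, sim_dataset_60, schedule=QUICK, seed=0)


def test_structure_requires_tree():
    with pytest.raises(ValueError):
        MultiCellModelSpec(structure=CovarianceStructure("scaled_tree"), tree=None)
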