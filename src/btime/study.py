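"""Experiment orchestration: the simulation study grid and cohort workflows.

`run_simulation_study` reproduces the two-group copula simulation design at a
configurable scale: for each perturbation level and replicate it generates a
dataset, fits the requested models (the single-cell-type comparator plus any
of the five multi-cell covariance structures), and records per-cell-type
significance calls (95% equal-tailed credible interval for the group slope
excluding zero), credible-interval widths, and per-cell-type PSIS-LOO ELPD.
Aggregation produces the capture-proportion table and the
highest-ELPD / narrowest-CI tally tables.

`run_cohort_analysis` is the corresponding workflow for a real counts table:
per-model credible intervals and widths for every cell type, with the
narrowest-width model identified per cell type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .celltree import CovarianceStructure, DifferentiationTree, simulation_tree
from .diagnostics import psis_loo
from .models import (
    ChainSchedule,
    CountDataset,
    MultiCellModelSpec,
    PosteriorSamples,
    SIMULATION_SCHEDULE,
    fit_multicell,
    fit_singlecell,
    significance_call,
)
from .simulate import SimConfig, generate_dataset, replicate_seed

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "ExperimentGrid",
    "ResultTable",
    "fit_model_by_name",
    "run_simulation_study",
    "run_cohort_analysis",
]

#: canonical model names, ordered simplest to most structured (tie-break order)
MODEL_NAMES = (
    "single",
    "unstructured",
    "expdecay",
    "tree",
    "scaled_tree",
    "multilevel_tree",
)


def _make_spec(model: str, tree: DifferentiationTree | None, block: bool = False) -> MultiCellModelSpec | None:
    if model == "single":
        return None
    kind = model
    return MultiCellModelSpec(structure=CovarianceStructure(kind, block=block), tree=tree)


def fit_model_by_name(
    model: str,
    dataset: CountDataset,
    tree: DifferentiationTree | None,
    schedule: ChainSchedule,
    seed: int,
    block: bool = False,
    store_loglik: bool = True,
) -> dict[str, PosteriorSamples]:
    """Fit one named model; the single-cell comparator returns one fit per
    cell type, joint models a single fit, keyed by cell type either way."""
    if model == "single":
        return {
            ct: fit_singlecell(
                dataset, ct, schedule=schedule, seed=seed, store_loglik=store_loglik
            )
            for ct in dataset.cell_types
        }
    spec = _make_spec(model, tree, block=block)
    fit = fit_multicell(
        spec, dataset, schedule=schedule, seed=seed, store_loglik=store_loglik
    )
    return {ct: fit for ct in dataset.cell_types}


@dataclass
class ExperimentGrid:
    """The simulation experiment: perturbation levels x models x replicates."""

    levels: tuple[float, ...] = (0.0, 0.2, 0.6)
    models: tuple[str, ...] = MODEL_NAMES
    n_reps: int = 100
    config: SimConfig = field(default_factory=SimConfig)
    tree: DifferentiationTree = field(default_factory=simulation_tree)
    schedule: ChainSchedule = SIMULATION_SCHEDULE
    master_seed: int = 0
    compute_elpd: bool = True

    def __post_init__(self):
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")


@dataclass
class ResultTable:
    """Aggregated simulation-study results.

    ``records`` holds one row per (level, model, replicate, cell type) with
    significance, CI width, ELPD and convergence; the ``capture``,
    ``elpd_counts`` and ``ci_counts`` frames are the aggregated views.
    """

    records: pd.DataFrame
    capture: pd.DataFrame
    elpd_counts: pd.DataFrame | None
    ci_counts: pd.DataFrame
    n_nonconverged: int


def _replicate_rows(
    level: float,
    rep: int,
    dataset_frame: pd.DataFrame,
    models: tuple[str, ...],
    tree: DifferentiationTree,
    schedule: ChainSchedule,
    seed: int,
    cell_types: tuple[str, ...],
    compute_elpd: bool,
) -> list[dict]:
    cd = CountDataset.from_frame(
        dataset_frame, cell_types=list(cell_types), covariates=["group"]
    )
    rows = []
    for model in models:
        fits = fit_model_by_name(
            model, cd, tree, schedule, seed=seed, store_loglik=compute_elpd
        )
        for ct in cell_types:
            fit = fits[ct]
            call = significance_call(fit, ct)
            elpd = np.nan
            if compute_elpd:
                ll = fit.pointwise_loglik(cell_type=ct)
                elpd = psis_loo(ll, name=f"{model}:{ct}").elpd_loo
            rows.append(
                {
                    "level": level,
                    "replicate": rep,
                    "model": model,
                    "cell_type": ct,
                    "significant": call["significant"],
                    "lower": call["lower"],
                    "upper": call["upper"],
                    "width": call["width"],
                    "elpd": elpd,
                    "converged": bool(fit.convergence.converged),
                }
            )
    return rows


def aggregate_results(records: pd.DataFrame, compute_elpd: bool = True) -> ResultTable:
    """Aggregate per-replicate rows into the study's summary tables.

    Non-converged fits are excluded from every tally (their count is
    reported); ELPD and narrowest-CI ties are broken in favor of the
    simpler model in the :data:`MODEL_NAMES` ordering.
    """
    n_nonconv = int((~records["converged"]).sum())
    if n_nonconv:
        logger.warning("excluding %d non-converged fit rows from aggregation", n_nonconv)
    ok = records[records["converged"]].copy()
    order = {m: i for i, m in enumerate(MODEL_NAMES)}
    ok["model_order"] = ok["model"].map(order)

    capture = (
        ok.groupby(["level", "model", "cell_type"])["significant"]
        .mean()
        .rename("capture")
        .reset_index()
    )

    def _winner_counts(frame: pd.DataFrame, col: str, best_high: bool) -> pd.DataFrame:
        rows = []
        for (level, ct), grp in frame.groupby(["level", "cell_type"]):
            counts = dict.fromkeys(frame["model"].unique(), 0)
            for _, rep_grp in grp.groupby("replicate"):
                g = rep_grp.dropna(subset=[col])
                if g.empty:
                    continue
                g = g.sort_values([col, "model_order"], ascending=[not best_high, True])
                counts[g.iloc[0]["model"]] += 1
            for model, cnt in counts.items():
                rows.append({"level": level, "cell_type": ct, "model": model, col + "_wins": cnt})
        return pd.DataFrame(rows)

    elpd_counts = None
    if compute_elpd and ok["elpd"].notna().any():
        elpd_counts = _winner_counts(ok, "elpd", best_high=True)
    ci_counts = _winner_counts(ok, "width", best_high=False)
    return ResultTable(
        records=records,
        capture=capture,
        elpd_counts=elpd_counts,
        ci_counts=ci_counts,
        n_nonconverged=n_nonconv,
    )


def run_simulation_study(
    grid: ExperimentGrid,
    cache_dir: str | Path | None = None,
) -> ResultTable:
    """Run the full (level, model, replicate) grid and aggregate.

    With ``cache_dir`` set, per-replicate result rows are written to disk as
    they complete and reloaded on rerun, making the study resumable.
    """
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    all_rows: list[dict] = []
    cell_types = grid.config.marker_names
    for level in grid.levels:
        cfg = replace(grid.config, perturb_fraction=level, seed=grid.master_seed)
        for rep in range(grid.n_reps):
            tag = f"level{level:g}_rep{rep:03d}"
            cache_file = cache / f"{tag}.json" if cache else None
            if cache_file and cache_file.exists():
                all_rows.extend(json.loads(cache_file.read_text()))
                continue
            seed = replicate_seed(grid.master_seed + int(1000 * level), rep)
            ds = generate_dataset(cfg, seed=seed, replicate=rep)
            rows = _replicate_rows(
                level,
                rep,
                ds.to_frame(),
                grid.models,
                grid.tree,
                grid.schedule,
                seed=seed,
                cell_types=cell_types,
                compute_elpd=grid.compute_elpd,
            )
            if cache_file:
                cache_file.write_text(json.dumps(rows))
            all_rows.extend(rows)
            logger.info("finished %s", tag)
    records = pd.DataFrame(all_rows)
    return aggregate_results(records, compute_elpd=grid.compute_elpd)


def plot_ci_forest(table: pd.DataFrame, covariate: str | None = None, ax=None):
    """Minimal forest plot of per-model slope credible intervals.

    ``table`` is the output of :func:`run_cohort_analysis` (or any frame
    with model / cell_type / lower / upper / mean columns).  One horizontal
    interval per (cell type, model); a dashed line marks zero.
    """
    import matplotlib.pyplot as plt

    if covariate is not None:
        table = table[table["covariate"] == covariate]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1))
    labels, y = [], 0
    for ct, grp in table.groupby("cell_type", sort=False):
        for _, row in grp.iterrows():
            ax.plot([row["lower"], row["upper"]], [y, y], "-", color="C0")
            ax.plot(row["mean"], y, "o", color="C0", ms=4)
            labels.append(f"{ct} | {row['model']}")
            y += 1
    ax.axvline(0.0, ls="--", color="red", lw=1)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("95% credible interval for the slope")
    return ax


def run_cohort_analysis(
    counts: pd.DataFrame | str | Path,
    tree: DifferentiationTree,
    covariates: list[str],
    models: tuple[str, ...] = MODEL_NAMES,
    block_variants: bool = False,
    schedule: ChainSchedule = SIMULATION_SCHEDULE,
    seed: int = 0,
    min_total: int = 10,
) -> pd.DataFrame:
    """Cohort-style analysis: per-model credible intervals for every cell
    type, plus identification of the narrowest-CI model per cell type.

    The counts table must contain one column per tree node; cell types in
    the tree order define the model dimension.  Returns a tidy frame with
    one row per (model, covariate, cell type).
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts)
    missing = [ct for ct in tree.nodes if ct not in counts.columns]
    if missing:
        raise ValueError(f"cell types missing from counts table: {missing}")
    cd = CountDataset.from_frame(
        counts, cell_types=list(tree.nodes), covariates=covariates, min_total=min_total
    )
    model_list: list[tuple[str, bool]] = [(model, False) for model in models]
    if block_variants:
        model_list += [(model, True) for model in models if model in ("tree", "scaled_tree")]
    rows = []
    for model, block in model_list:
        label = model + ("_block" if block else "")
        fits = fit_model_by_name(
            model, cd, tree, schedule, seed=seed, block=block, store_loglik=False
        )
        done = set()
        for ct in tree.nodes:
            fit = fits[ct]
            key = id(fit)
            summ = fit.summary()
            for _, r in summ.iterrows():
                if (key, r["covariate"], r["cell_type"]) in done:
                    continue
                done.add((key, r["covariate"], r["cell_type"]))
                if model == "single" and r["cell_type"] != ct:
                    continue
                rows.append({"model": label, **r.to_dict()})
    out = pd.DataFrame(rows).drop_duplicates(subset=["model", "covariate", "cell_type"])
    # flag the narrowest CI per (covariate, cell type)
    out["narrowest"] = False
    for (_, _), grp in out.groupby(["covariate", "cell_type"]):
        out.loc[grp["width"].idxmin(), "narrowest"] = True
    return out.reset_index(drop=True)
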