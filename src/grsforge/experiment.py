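"""Orchestration: cyclic train/validation/test evaluation, joint
hyperparameter tuning, scenario sweeps, and the repeated-split scheme.

The cyclic scheme turns R independent replicate datasets into R
train/validation/test triples: replicate i trains, its predecessor
(wrapping) validates, its successor (wrapping) tests.  Hyperparameters
are tuned once per setting by averaging validation AUC over the first
``tuning_reps`` iterations and then frozen for all replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .base import GRSModel
from .elastic_net_grs import ElasticNetConfig, fit_elastic_net
from .evaluation import auc, estimate_power, evaluate_grs, logit_transform_grs
from .forest_grs import ForestConfig, fit_probability_forest, fit_rf_vim
from .logic_regression import SearchConfig, fit_logic_bagging, fit_logic_regression
from .snp_simulator import SimulatedDataset, SimulationDesign, generate_replicates

__all__ = [
    "METHODS",
    "MethodScale",
    "ExperimentConfig",
    "cyclic_scheme_indices",
    "default_grids",
    "fit_method",
    "tune_hyperparameters",
    "run_simulation_study",
    "repeated_split_scheme",
]

METHODS = ("rf", "rfvim", "logicreg", "logicbag", "enet", "true_model")


@dataclass(frozen=True)
class MethodScale:
    """Ensemble/search sizes that trade runtime for fidelity.

    ``paper_scale()`` restores the full published sizes; the defaults are
    desk-scale so a sweep finishes on one workstation core.
    """

    num_trees: int = 500
    n_bags: int = 100
    boruta_iterations: int = 50
    annealing_iterations: int = 50_000

    @staticmethod
    def paper_scale() -> "MethodScale":
        return MethodScale(num_trees=2000, n_bags=500, boruta_iterations=100,
                           annealing_iterations=500_000)


@dataclass
class ExperimentConfig:
    """One simulation-study run: a design, methods, grids, and scales."""

    design: SimulationDesign
    methods: tuple[str, ...] = ("rf", "enet")
    grids: Optional[dict] = None          # method -> list of param dicts; None = defaults
    tuning_reps: int = 10
    level: float = 0.05
    n_replicates: Optional[int] = None    # overrides design.n_replicates
    scale: MethodScale = field(default_factory=MethodScale)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def cyclic_scheme_indices(i: int, R: int = 100) -> tuple[int, int, int]:
    """1-based (train, validation, test): predecessor validates, successor tests."""
    if not 1 <= i <= R:
        raise ValueError(f"replicate index {i} outside 1..{R}")
    validation = i - 1 if i != 1 else R
    test = i + 1 if i != R else 1
    return i, validation, test


def default_grids(p: int, N: int) -> dict:
    """Materialize the per-method tuning grids for p SNPs and N samples."""
    root = int(np.floor(np.sqrt(p)))
    mtry_grid = sorted({max(1, int(np.floor(f * root))) for f in (0.5, 1.0, 2.0)})
    mns_grid = sorted({max(1, int(np.floor(f * N))) for f in (0.01, 0.05, 0.1)})
    forest = [{"mtry": m, "min_node_size": s} for m in mtry_grid for s in mns_grid]
    logic = [{"ntrees": t, "nleaves": l} for t in range(1, 7) for l in range(1, 11) if l >= t]
    enet = [{"alpha": a} for a in (0.5, 0.75, 0.9, 0.99)]
    return {"rf": forest, "rfvim": forest, "logicreg": logic, "logicbag": logic,
            "enet": enet, "true_model": [{}]}


@dataclass
class _TrueModelGRS:
    dataset: SimulatedDataset

    def predict_risk(self, genotypes) -> np.ndarray:
        return self.dataset.true_model.predict_risk(genotypes)


def fit_method(method: str, train: SimulatedDataset, params: dict,
               scale: MethodScale = MethodScale(),
               rng: Optional[np.random.Generator] = None) -> GRSModel:
    """Fit one GRS construction method on a training replicate.

    GRS are always constructed from the genetic data only; environmental
    covariables never enter the score (they may enter the association
    analysis afterwards).
    """
    rng = np.random.default_rng() if rng is None else rng
    g, y = train.genotypes, train.outcome
    if method == "rf":
        cfg = ForestConfig(num_trees=scale.num_trees, mtry=params.get("mtry"),
                           min_node_size=params.get("min_node_size", 1))
        return fit_probability_forest(g, y, cfg, rng=rng)
    if method == "rfvim":
        cfg = ForestConfig(num_trees=scale.num_trees, mtry=params.get("mtry"),
                           min_node_size=params.get("min_node_size", 1))
        return fit_rf_vim(g, y, cfg, n_iterations=scale.boruta_iterations, rng=rng)
    if method == "logicreg":
        cfg = SearchConfig(max_trees=params.get("ntrees", 2),
                           max_total_leaves=params.get("nleaves", 8),
                           search=params.get("search", "annealing"),
                           iterations=scale.annealing_iterations)
        return fit_logic_regression(g, y, cfg, rng=rng)
    if method == "logicbag":
        cfg = SearchConfig(max_trees=params.get("ntrees", 2),
                           max_total_leaves=params.get("nleaves", 8), search="greedy")
        return fit_logic_bagging(g, y, cfg, n_bags=scale.n_bags, rng=rng)
    if method == "enet":
        cfg = ElasticNetConfig(seed=int(rng.integers(2 ** 31)))
        return fit_elastic_net(g, y, cfg, alpha=params.get("alpha"))
    if method == "true_model":
        if train.true_model.needs_environment:
            raise ValueError("the gxe scenario has no genetics-only true GRS")
        return _TrueModelGRS(train)
    raise ValueError(f"unknown method {method!r}")


def _rng_for(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def tune_hyperparameters(method: str, replicates: Sequence[SimulatedDataset],
                         grid: Sequence[dict], scale: MethodScale = MethodScale(),
                         tuning_reps: int = 10, seed: int = 0) -> dict:
    """Pick the grid point with the highest mean validation AUC.

    For tuning iteration i (1-based), replicate i trains and its cyclic
    predecessor validates.  Ties keep the first grid point in grid order.
    """
    if len(grid) == 1:
        return dict(grid[0])
    R = len(replicates)
    tuning_reps = min(tuning_reps, R)
    midx = METHODS.index(method)
    best_params, best_auc = None, -np.inf
    for params in grid:
        aucs = []
        for i in range(1, tuning_reps + 1):
            tr_i, val_i, _ = cyclic_scheme_indices(i, R)
            train, val = replicates[tr_i - 1], replicates[val_i - 1]
            # common random numbers across grid points: identical points tie exactly
            model = fit_method(method, train, params, scale,
                               rng=_rng_for(seed, midx, i))
            aucs.append(auc(model.predict_risk(val.genotypes), val.outcome.values))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:
            best_params, best_auc = dict(params), mean_auc
    return best_params


def run_simulation_study(config: ExperimentConfig) -> dict:
    """Generate replicates, tune each method, run the cyclic scheme, aggregate.

    Returns a dict with the per-replicate tidy ``results`` table, the
    per-method ``summary`` (mean test/train AUC with MC standard errors and
    the estimated power at ``level``), and the ``chosen_params``.
    """
    design = dataclasses.replace(config.design, seed=config.seed)
    R = config.n_replicates or design.n_replicates
    replicates = generate_replicates(design, n_replicates=R)
    grids = config.grids or default_grids(design.n_snps, design.sample_size)
    rows = []
    chosen: dict[str, dict] = {}
    for method in config.methods:
        params = tune_hyperparameters(method, replicates, grids.get(method, [{}]),
                                      config.scale, config.tuning_reps, seed=config.seed)
        chosen[method] = params
        midx = METHODS.index(method)
        for i in range(1, R + 1):
            tr_i, _, te_i = cyclic_scheme_indices(i, R)
            train, test = replicates[tr_i - 1], replicates[te_i - 1]
            try:
                model = fit_method(method, train, params, config.scale,
                                   rng=_rng_for(config.seed, midx, 10_000 + i))
                res = evaluate_grs(model.predict_risk(test.genotypes), test.outcome.values)
                train_auc = auc(logit_transform_grs(model.predict_risk(train.genotypes)),
                                train.outcome.values)
                rows.append({"method": method, "replicate": i, "ok": True,
                             "test_auc": res.auc, "train_auc": train_auc,
                             "wald_p": res.wald_p, "accuracy": res.accuracy,
                             "sensitivity": res.sensitivity, "specificity": res.specificity,
                             "degenerate": res.degenerate})
            except Exception as exc:  # record and continue
                rows.append({"method": method, "replicate": i, "ok": False,
                             "error": str(exc)})
    results = pd.DataFrame(rows)
    summary_rows = []
    for method in config.methods:
        sub = results[(results["method"] == method) & results["ok"]]
        if sub.empty:
            continue
        power, power_se = estimate_power(sub["wald_p"].tolist(), config.level)
        n = len(sub)
        summary_rows.append({
            "method": method, "n_replicates": n,
            "mean_test_auc": sub["test_auc"].mean(),
            "se_test_auc": sub["test_auc"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "mean_train_auc": sub["train_auc"].mean(),
            "power": power, "power_se": power_se,
            "mean_accuracy": sub["accuracy"].mean(),
            "mean_sensitivity": sub["sensitivity"].mean(),
            "mean_specificity": sub["specificity"].mean(),
        })
    return {"results": results, "summary": pd.DataFrame(summary_rows), "chosen_params": chosen}


def repeated_split_scheme(labels: Sequence[int], n_splits: int = 100,
                          test_fraction: float = 0.5, tune_fraction: float = 0.25,
                          rng: Optional[np.random.Generator] = None) -> list[dict]:
    """Repeated stratified train/test splits with a tuning sub-split.

    Each split divides the samples into test/train by ``test_fraction``
    (stratified by outcome), then carves ``tune_fraction`` of the training
    half into a validation part (floor per class).  Index sets are returned
    for audit.
    """
    y = np.asarray(labels)
    if len(y) < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng() if rng is None else rng
    splits = []
    classes = np.unique(y)
    for _ in range(n_splits):
        test_idx, tune_val_idx, tune_train_idx = [], [], []
        for c in classes:
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(len(idx))]
            n_test = int(round(len(idx) * test_fraction))
            test_c, train_c = idx[:n_test], idx[n_test:]
            n_val = int(np.floor(len(train_c) * tune_fraction))
            tune_val_idx.append(train_c[:n_val])
            tune_train_idx.append(train_c[n_val:])
            test_idx.append(test_c)
        train_all = np.sort(np.concatenate(tune_val_idx + tune_train_idx))
        splits.append({
            "train": train_all,
            "test": np.sort(np.concatenate(test_idx)),
            "tune_train": np.sort(np.concatenate(tune_train_idx)),
            "tune_validation": np.sort(np.concatenate(tune_val_idx)),
        })
    return splits
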