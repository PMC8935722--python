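"""Probability-estimation random forests for {0,1,2}-coded SNPs, with
permutation variable importance and shadow-variable (Boruta-style) selection.

Trees here differ from plain classification trees in that leaves hold the
empirical in-bag case fraction rather than a hard class, and the forest
prediction is the arithmetic mean of leaf probabilities over trees.  This
matters for risk estimation: if the true stratum risk is 0.8 and every
tree recognizes it, vote averaging would report 1.0 while probability
averaging reports ~0.8.

Genotypes coded 0/1/2 admit exactly two ordered cut points per SNP,
({0} | {1,2}) and ({0,1} | {2}), so a split search covers dominant and
recessive inheritance without recoding.  Each tree is grown on a
bootstrap sample; out-of-bag (OOB) indices are recorded for the
permutation importance, defined per feature as the mean over trees of the
increase in OOB misclassification (threshold 0.5) after permuting that
feature among the tree's OOB rows.

The Boruta-style selection augments the data with one independently
permuted shadow copy of every feature per iteration, fits a forest, and
marks a hit for each original feature whose importance exceeds the
maximum shadow importance; exact binomial tests on the hit counts against
p = 0.5 (default threshold 1%) confirm or reject features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binomtest

from .base import ConstantGRS, genotype_values

__all__ = [
    "ForestConfig",
    "ProbabilityTree",
    "ProbabilityForest",
    "ForestGRS",
    "RfVimGRS",
    "VimReport",
    "gini_impurity",
    "best_split",
    "fit_probability_forest",
    "permutation_vim",
    "boruta_select",
    "fit_rf_vim",
]


def gini_impurity(p1: float) -> float:
    """Binary Gini impurity 2 * p1 * (1 - p1)."""
    return 2.0 * p1 * (1.0 - p1)


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``mtry`` is the number of candidate features sampled (without
    replacement) at each node; ``None`` means floor(sqrt(p)).
    ``min_node_size`` is the minimum in-bag sample count per leaf.
    """

    num_trees: int = 2000
    mtry: Optional[int] = None
    min_node_size: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        m = int(np.floor(np.sqrt(p))) if self.mtry is None else self.mtry
        return max(1, min(m, p))


def best_split(X_node: np.ndarray, y_node: np.ndarray,
               candidate_features: np.ndarray, min_node_size: int):
    """Best (feature, cut) among candidates by weighted child Gini.

    ``cut`` c means the left child takes rows with genotype <= c, so
    c = 0 is the ({0},{1,2}) dominant split and c = 1 the ({0,1},{2})
    recessive split.  Returns ``(feature, cut, weighted_impurity)`` or
    ``None`` if no candidate reduces impurity while leaving at least
    ``min_node_size`` samples in both children.  Ties break toward the
    lowest feature index, then the lowest cut.
    """
    feats = np.sort(np.asarray(candidate_features))
    sub = X_node[:, feats]
    y = np.asarray(y_node, dtype=np.float64)
    m = sub.shape[0]
    ctot = y.sum()
    parent = 2.0 * ctot * (m - ctot) / m  # m * gini(parent)

    is0 = sub == 0
    is2 = sub == 2
    n0 = is0.sum(axis=0).astype(np.float64)
    n2 = is2.sum(axis=0).astype(np.float64)
    c0 = y @ is0
    c2 = y @ is2

    # columns: cut 0 -> left (n0, c0); cut 1 -> left (m - n2, ctot - c2)
    nl = np.stack([n0, m - n2], axis=1)
    cl = np.stack([c0, ctot - c2], axis=1)
    nr = m - nl
    cr = ctot - cl
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(nl > 0, 2.0 * cl * (nl - cl) / np.where(nl > 0, nl, 1), 0.0) + \
                np.where(nr > 0, 2.0 * cr * (nr - cr) / np.where(nr > 0, nr, 1), 0.0)
    valid = (nl >= min_node_size) & (nr >= min_node_size) & (score < parent - 1e-12)
    if not valid.any():
        return None
    score = np.where(valid, score, np.inf)
    flat = int(np.argmin(score))  # row-major: lowest feature first, then lowest cut
    fi, cut = divmod(flat, 2)
    return int(feats[fi]), int(cut), float(score[fi, cut] / m)


@dataclass
class ProbabilityTree:
    """Flat-array binary tree; leaves hold empirical in-bag case fractions."""

    feature: np.ndarray   # split feature per node; -1 for leaves
    cut: np.ndarray       # split cut per node (genotype <= cut goes left)
    left: np.ndarray
    right: np.ndarray
    prob: np.ndarray      # leaf probability (case fraction); NaN for inner nodes

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=float)
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] < 0:
                out[idx] = self.prob[node]
                continue
            go_left = X[idx, self.feature[node]] <= self.cut[node]
            stack.append((int(self.left[node]), idx[go_left]))
            stack.append((int(self.right[node]), idx[~go_left]))
        return out

    def features_used(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])


def _grow_tree(X: np.ndarray, y: np.ndarray, in_bag: np.ndarray,
               mtry: int, min_node_size: int, rng: np.random.Generator) -> ProbabilityTree:
    p = X.shape[1]
    feature: list[int] = []
    cut: list[int] = []
    left: list[int] = []
    right: list[int] = []
    prob: list[float] = []

    def new_node() -> int:
        feature.append(-1)
        cut.append(-1)
        left.append(-1)
        right.append(-1)
        prob.append(np.nan)
        return len(feature) - 1

    root = new_node()
    stack: list[tuple[int, np.ndarray]] = [(root, in_bag)]
    while stack:
        node, idx = stack.pop()
        y_node = y[idx]
        m = len(idx)
        ctot = int(y_node.sum())
        if m < 2 * min_node_size or ctot == 0 or ctot == m:
            prob[node] = ctot / m
            continue
        feats = rng.choice(p, size=mtry, replace=False) if mtry < p else np.arange(p)
        split = best_split(X[idx], y_node, feats, min_node_size)
        if split is None:
            prob[node] = ctot / m
            continue
        f, c, _ = split
        go_left = X[idx, f] <= c
        feature[node], cut[node] = f, c
        left[node] = new_node()
        right[node] = new_node()
        stack.append((left[node], idx[go_left]))
        stack.append((right[node], idx[~go_left]))
    return ProbabilityTree(feature=np.array(feature), cut=np.array(cut),
                           left=np.array(left), right=np.array(right),
                           prob=np.array(prob))


@dataclass
class ProbabilityForest:
    """Bootstrap ensemble of probability estimation trees with recorded OOB rows."""

    trees: list[ProbabilityTree]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    n_features: int
    config: ForestConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        acc = np.zeros(X.shape[0], dtype=float)
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)


@dataclass
class ForestGRS:
    """GRS model backed by a probability forest on additively coded SNPs."""

    forest: ProbabilityForest

    def predict_risk(self, genotypes) -> np.ndarray:
        return self.forest.predict(genotype_values(genotypes))


def fit_probability_forest(genotypes, outcome, config: ForestConfig = ForestConfig(),
                           rng: Optional[np.random.Generator] = None) -> ForestGRS:
    """Grow ``num_trees`` probability trees on independent bootstrap samples."""
    X = np.asarray(genotype_values(genotypes))
    y = np.asarray(outcome.values if hasattr(outcome, "values") else outcome).astype(np.int64)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    n, p = X.shape
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mtry = config.resolve_mtry(p)
    all_rows = np.arange(n)
    trees, boots, oobs = [], [], []
    for _ in range(config.num_trees):
        bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_rows, bag, assume_unique=False)
        trees.append(_grow_tree(X, y, bag, mtry, config.min_node_size, rng))
        boots.append(bag)
        oobs.append(oob)
    forest = ProbabilityForest(trees=trees, bootstrap_indices=boots, oob_indices=oobs,
                               n_features=p, config=config)
    return ForestGRS(forest=forest)


def permutation_vim(forest: ProbabilityForest, genotypes, outcome,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-feature OOB permutation importance of a fitted forest.

    For each tree: classify its OOB rows at threshold 0.5, then re-classify
    after permuting one feature among those rows; the importance is the mean
    misclassification increase over trees.  Features unused by a tree
    contribute exactly zero for that tree; trees without OOB rows are skipped.
    """
    X = np.asarray(genotype_values(genotypes))
    y = np.asarray(outcome.values if hasattr(outcome, "values") else outcome).astype(np.int64)
    rng = np.random.default_rng() if rng is None else rng
    p = forest.n_features
    imp = np.zeros(p, dtype=float)
    n_used = 0
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X[oob].copy()
        yo = y[oob]
        base_err = np.mean((tree.predict(Xo) > 0.5).astype(int) != yo)
        for f in tree.features_used():
            original = Xo[:, f].copy()
            Xo[:, f] = original[rng.permutation(len(oob))]
            perm_err = np.mean((tree.predict(Xo) > 0.5).astype(int) != yo)
            Xo[:, f] = original
            imp[f] += perm_err - base_err
    if n_used == 0:
        raise ValueError("no tree has out-of-bag observations")
    return imp / n_used


@dataclass
class VimReport:
    """Outcome of the shadow-variable selection."""

    importance: np.ndarray          # mean original-feature VIM over iterations
    hits: np.ndarray                # iterations where VIM > max shadow VIM
    n_iterations: int
    decisions: list[str]            # per feature: confirmed / rejected / tentative
    alpha: float
    feature_ids: list[str] = field(default_factory=list)

    @property
    def confirmed(self) -> np.ndarray:
        return np.array([i for i, d in enumerate(self.decisions) if d == "confirmed"], dtype=int)

    def to_frame(self):
        import pandas as pd

        ids = self.feature_ids or [f"SNP{i + 1}" for i in range(len(self.hits))]
        return pd.DataFrame({"feature": ids, "importance": self.importance,
                             "hits": self.hits, "decision": self.decisions})


def decide_from_hits(hits: int, n_iterations: int, alpha: float = 0.01) -> str:
    """Exact binomial decision for one feature's hit count against p = 0.5."""
    if binomtest(hits, n_iterations, 0.5, alternative="greater").pvalue < alpha:
        return "confirmed"
    if binomtest(hits, n_iterations, 0.5, alternative="less").pvalue < alpha:
        return "rejected"
    return "tentative"


def boruta_select(genotypes, outcome, config: ForestConfig = ForestConfig(),
                  n_iterations: int = 100, alpha: float = 0.01,
                  rng: Optional[np.random.Generator] = None,
                  feature_ids: Optional[list[str]] = None) -> VimReport:
    """Shadow-variable selection: hit counting against the max shadow importance."""
    X = np.asarray(genotype_values(genotypes))
    y = np.asarray(outcome.values if hasattr(outcome, "values") else outcome).astype(np.int64)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    imp_sum = np.zeros(p, dtype=float)
    for _ in range(n_iterations):
        shadow = np.column_stack([X[rng.permutation(n), j] for j in range(p)])
        X_ext = np.concatenate([X, shadow], axis=1)
        forest = fit_probability_forest(X_ext, y, config=config, rng=rng).forest
        vim = permutation_vim(forest, X_ext, y, rng=rng)
        hits += vim[:p] > vim[p:].max()
        imp_sum += vim[:p]
    decisions = [decide_from_hits(int(h), n_iterations, alpha) for h in hits]
    if feature_ids is None and hasattr(genotypes, "snp_ids"):
        feature_ids = list(genotypes.snp_ids)
    return VimReport(importance=imp_sum / n_iterations, hits=hits,
                     n_iterations=n_iterations, decisions=decisions, alpha=alpha,
                     feature_ids=feature_ids or [])


@dataclass
class RfVimGRS:
    """Forest fitted on the confirmed-feature subset (or a constant fallback)."""

    selected: np.ndarray
    model: object  # ForestGRS on the selected columns, or ConstantGRS
    report: VimReport

    def predict_risk(self, genotypes) -> np.ndarray:
        X = genotype_values(genotypes)
        if isinstance(self.model, ConstantGRS):
            return self.model.predict_risk(X)
        return self.model.predict_risk(X[:, self.selected])


def fit_rf_vim(genotypes, outcome, config: ForestConfig = ForestConfig(),
               n_iterations: int = 100, alpha: float = 0.01,
               rng: Optional[np.random.Generator] = None) -> RfVimGRS:
    """Boruta-style selection followed by a forest restricted to confirmed features.

    Tentative features are not selected.  With no confirmed feature the
    model degenerates to the constant training prevalence.
    """
    X = np.asarray(genotype_values(genotypes))
    y = np.asarray(outcome.values if hasattr(outcome, "values") else outcome).astype(np.int64)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    report = boruta_select(genotypes, outcome, config=config, n_iterations=n_iterations,
                           alpha=alpha, rng=rng)
    sel = report.confirmed
    if len(sel) == 0:
        return RfVimGRS(selected=sel, model=ConstantGRS(float(y.mean())), report=report)
    sub_config = ForestConfig(num_trees=config.num_trees,
                              mtry=min(config.resolve_mtry(X.shape[1]), len(sel)),
                              min_node_size=config.min_node_size)
    model = fit_probability_forest(X[:, sel], y, config=sub_config, rng=rng)
    return RfVimGRS(selected=sel, model=model, report=report)
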