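"""Logic regression over binarized SNPs: Boolean logic trees embedded in a
logistic model, searched greedily or by simulated annealing, plus bagged
ensembles ("logic bagging").

A logic tree is a binary tree with AND/OR in the inner nodes and (possibly
negated) binary features in the leaves; it evaluates to 0/1.  A model
combines M trees in a GLM,

    logit(P(Y = 1)) = b0 + b1 * L1(x) + ... + bM * LM(x),

scored by the deviance of the logistic fit.  The search moves are:
alternating a leaf's literal, alternating an operator, splitting a leaf
into an operator node with a fresh literal, pruning an operator node to
one of its children, and adding or deleting a (single-literal) tree; this
move set connects the whole state space under the tree/leaf budgets.

SNPs are binarized into dominant and recessive indicators before the
search, so a single literal already expresses a mode of inheritance and
conjunctions express epistasis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit

from .base import genotype_values

__all__ = [
    "Literal",
    "Op",
    "LogicTree",
    "LogicModel",
    "SearchConfig",
    "evaluate_tree",
    "count_leaves",
    "tree_to_expression",
    "parse_expression",
    "enumerate_neighbors",
    "score_model",
    "greedy_search",
    "anneal_search",
    "acceptance_probability",
    "fit_logic_regression",
    "fit_logic_bagging",
    "LogicRegressionGRS",
    "LogicBaggingGRS",
]

COEF_CLIP = 15.0


@dataclass(frozen=True)
class Literal:
    """A binary feature or its negation."""

    feature_index: int
    negated: bool = False


@dataclass(frozen=True)
class Op:
    """Inner node: AND/OR over exactly two children."""

    operator: str  # "and" | "or"
    left: "NodeT"
    right: "NodeT"

    def __post_init__(self) -> None:
        if self.operator not in ("and", "or"):
            raise ValueError("operator must be 'and' or 'or'")


NodeT = Union[Literal, Op]


@dataclass(frozen=True)
class LogicTree:
    """A rooted logic tree; thin wrapper over the node structure."""

    root: NodeT

    def evaluate(self, x) -> np.ndarray:
        return evaluate_tree(self.root, x)

    @property
    def n_leaves(self) -> int:
        return count_leaves(self.root)

    def __str__(self) -> str:
        return tree_to_expression(self.root)


def _eval_node(node: NodeT, X: np.ndarray) -> np.ndarray:
    if isinstance(node, Literal):
        if node.feature_index < 0 or node.feature_index >= X.shape[1]:
            raise IndexError(f"feature index {node.feature_index} out of range for {X.shape[1]} features")
        col = X[:, node.feature_index].astype(bool)
        return ~col if node.negated else col
    left = _eval_node(node.left, X)
    right = _eval_node(node.right, X)
    return (left & right) if node.operator == "and" else (left | right)


def evaluate_tree(tree: Union[LogicTree, NodeT], x) -> np.ndarray:
    """Evaluate a logic tree on a binary vector (-> scalar 0/1) or matrix (-> 0/1 array)."""
    node = tree.root if isinstance(tree, LogicTree) else tree
    X = np.atleast_2d(np.asarray(x))
    out = _eval_node(node, X).astype(np.int8)
    return out[0] if np.asarray(x).ndim == 1 else out


def count_leaves(node: NodeT) -> int:
    if isinstance(node, Literal):
        return 1
    return count_leaves(node.left) + count_leaves(node.right)


# ---------------------------------------------------------------------------
# expression printing / parsing

_OP_SYMBOL = {"and": "∧", "or": "∨"}


def _expr(node: NodeT, feature_ids: Optional[Sequence[str]], top: bool) -> str:
    if isinstance(node, Literal):
        name = feature_ids[node.feature_index] if feature_ids else f"X{node.feature_index + 1}"
        return f"{name}^c" if node.negated else name
    body = (f"{_expr(node.left, feature_ids, False)} {_OP_SYMBOL[node.operator]} "
            f"{_expr(node.right, feature_ids, False)}")
    return body if top else f"({body})"


def tree_to_expression(tree: Union[LogicTree, NodeT],
                       feature_ids: Optional[Sequence[str]] = None) -> str:
    """Render a tree as a Boolean expression, e.g. ``(X1^c ∧ X2) ∨ (X1 ∧ X3^c)``."""
    node = tree.root if isinstance(tree, LogicTree) else tree
    return _expr(node, feature_ids, top=True)


_TOKEN_RE = re.compile(r"\s*(\(|\)|∧|∨|&|\||X\d+(\^c)?|[A-Za-z_][\w.]*(_[DR])?(\^c)?)")


class ExpressionParseError(ValueError):
    pass


def parse_expression(text: str, feature_ids: Optional[Sequence[str]] = None) -> NodeT:
    """Parse a parenthesized Boolean expression back into a tree.

    Leaves are ``X<k>`` (1-based feature index) or, when ``feature_ids``
    is given, any of those names; ``^c`` marks negation.  Same-operator
    chains associate to the left.
    """
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionParseError(f"unexpected character at position {pos}: {text[pos]!r}")
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    i = 0

    def peek():
        return tokens[i][0] if i < len(tokens) else None

    def leaf(tok: str, at: int) -> Literal:
        negated = tok.endswith("^c")
        name = tok[:-2] if negated else tok
        if feature_ids is not None and name in feature_ids:
            return Literal(list(feature_ids).index(name), negated)
        m = re.fullmatch(r"X(\d+)", name)
        if not m:
            raise ExpressionParseError(f"unknown feature {name!r} at position {at}")
        return Literal(int(m.group(1)) - 1, negated)

    def operand() -> NodeT:
        nonlocal i
        tok, at = tokens[i] if i < len(tokens) else (None, len(text))
        if tok is None:
            raise ExpressionParseError(f"unexpected end of expression at position {at}")
        if tok == "(":
            i += 1
            node = expression()
            if peek() != ")":
                raise ExpressionParseError(f"missing ')' near position {tokens[i - 1][1]}")
            i += 1
            return node
        if tok in (")", "∧", "∨", "&", "|"):
            raise ExpressionParseError(f"unexpected token {tok!r} at position {at}")
        i += 1
        return leaf(tok, at)

    def expression() -> NodeT:
        nonlocal i
        node = operand()
        while peek() in ("∧", "∨", "&", "|"):
            op = "and" if peek() in ("∧", "&") else "or"
            i += 1
            node = Op(op, node, operand())
        return node

    node = expression()
    if i != len(tokens):
        raise ExpressionParseError(f"trailing input at position {tokens[i][1]}")
    return node


# ---------------------------------------------------------------------------
# models and scoring

@dataclass
class LogicModel:
    """Intercept plus coefficients over M logic trees (M = 0 is intercept-only)."""

    intercept: float
    trees: tuple[NodeT, ...]
    coefficients: np.ndarray
    deviance: float = np.nan
    converged: bool = True

    def linear_predictor(self, X_bin: np.ndarray) -> np.ndarray:
        eta = np.full(X_bin.shape[0], self.intercept, dtype=float)
        for coef, tree in zip(self.coefficients, self.trees):
            if coef != 0.0:
                eta += coef * _eval_node(tree, X_bin)
        return eta

    def predict(self, X_bin: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X_bin))

    def expressions(self, feature_ids: Optional[Sequence[str]] = None) -> list[str]:
        return [tree_to_expression(t, feature_ids) for t in self.trees]


@dataclass(frozen=True)
class SearchConfig:
    """Budgets and search settings for the logic-model search.

    ``max_total_leaves`` is the leaf budget summed over all trees.  The
    annealing temperatures are tuned automatically from a pilot sample of
    random moves when not given explicitly (initial acceptance ~90%,
    final acceptance ~0).
    """

    max_trees: int = 2
    max_total_leaves: int = 8
    search: str = "greedy"  # "greedy" | "annealing"
    iterations: int = 50_000
    start_temperature: Optional[float] = None
    end_temperature: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.max_trees <= self.max_total_leaves):
            raise ValueError("need 1 <= max_trees <= max_total_leaves")
        if self.search not in ("greedy", "annealing"):
            raise ValueError("search must be 'greedy' or 'annealing'")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.start_temperature is not None and self.end_temperature is not None:
            if not (self.start_temperature > self.end_temperature > 0):
                raise ValueError("need start_temperature > end_temperature > 0")


def _deviance_at(A: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    mu = expit(np.clip(A @ beta, -30, 30))
    return -2.0 * float(y @ np.log(np.clip(mu, 1e-12, None))
                        + (1 - y) @ np.log(np.clip(1 - mu, 1e-12, None)))


def _irls(A: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50):
    """Logistic IRLS on a small design matrix; returns (beta, deviance, converged).

    Under complete separation the coefficients diverge; once any exceeds
    the clip bound the whole vector is rescaled onto the bound.  Scaling
    (rather than per-coordinate clipping) preserves the separating
    direction, so separated fits still saturate their predictions.
    """
    n, k = A.shape
    beta = np.zeros(k)
    dev_old = _deviance_at(A, y, beta)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Aw = A * w[:, None]
        beta_new = np.linalg.solve(A.T @ Aw + 1e-10 * np.eye(k), Aw.T @ z)
        top = np.max(np.abs(beta_new))
        if top > COEF_CLIP:
            beta_new = beta_new * (COEF_CLIP / top)
            dev_new = _deviance_at(A, y, beta_new)
            if dev_new <= dev_old:  # separation: keep the rescaled iterate
                beta, dev_old = beta_new, dev_new
            break
        dev = _deviance_at(A, y, beta_new)
        beta = beta_new
        if abs(dev_old - dev) < tol:
            dev_old = dev
            converged = True
            break
        dev_old = dev
    return beta, dev_old, converged


def score_model(structure: tuple[NodeT, ...], X_bin: np.ndarray, y: np.ndarray
                ) -> tuple[LogicModel, float]:
    """Fit the logistic coefficients of a fixed tree set; return model and deviance.

    Constant tree columns are absorbed into the intercept (coefficient 0);
    duplicated columns are collapsed onto the first occurrence.
    """
    y = np.asarray(y, dtype=float)
    M = len(structure)
    cols = [_eval_node(t, X_bin).astype(float) for t in structure]
    keep: list[int] = []
    dup_of: dict[int, int] = {}
    for j, c in enumerate(cols):
        if c.min() == c.max():
            continue  # constant: absorbed into the intercept
        for k in keep:
            if np.array_equal(c, cols[k]):
                dup_of[j] = k
                break
        else:
            keep.append(j)
    A = np.column_stack([np.ones(len(y))] + [cols[k] for k in keep])
    beta, dev, converged = _irls(A, y)
    coefs = np.zeros(M)
    for pos, j in enumerate(keep):
        coefs[j] = beta[pos + 1]
    model = LogicModel(intercept=float(beta[0]), trees=tuple(structure),
                       coefficients=coefs, deviance=dev, converged=converged)
    return model, dev


# ---------------------------------------------------------------------------
# the move set

def _replace(node: NodeT, path: tuple[int, ...], new: NodeT) -> NodeT:
    if not path:
        return new
    assert isinstance(node, Op)
    if path[0] == 0:
        return Op(node.operator, _replace(node.left, path[1:], new), node.right)
    return Op(node.operator, node.left, _replace(node.right, path[1:], new))


def _walk(node: NodeT, path: tuple[int, ...] = ()):
    """Yield (path, node) in preorder."""
    yield path, node
    if isinstance(node, Op):
        yield from _walk(node.left, path + (0,))
        yield from _walk(node.right, path + (1,))


def _literals(n_features: int):
    for f in range(n_features):
        for neg in (False, True):
            yield Literal(f, neg)


def enumerate_neighbors(structure: tuple[NodeT, ...], n_features: int,
                        config: SearchConfig) -> list[tuple[NodeT, ...]]:
    """All structures one move away, in a fixed deterministic order.

    Move order: leaf alternation, operator alternation, leaf splitting
    (budget permitting), branch pruning, tree addition, tree deletion.
    """
    total_leaves = sum(count_leaves(t) for t in structure)
    out: list[tuple[NodeT, ...]] = []

    def with_tree(ti: int, new_root: NodeT) -> tuple[NodeT, ...]:
        return structure[:ti] + (new_root,) + structure[ti + 1:]

    # 1) alternate a leaf's literal
    for ti, tree in enumerate(structure):
        for path, node in _walk(tree):
            if isinstance(node, Literal):
                for lit in _literals(n_features):
                    if lit != node:
                        out.append(with_tree(ti, _replace(tree, path, lit)))
    # 2) alternate an operator
    for ti, tree in enumerate(structure):
        for path, node in _walk(tree):
            if isinstance(node, Op):
                flipped = Op("or" if node.operator == "and" else "and", node.left, node.right)
                out.append(with_tree(ti, _replace(tree, path, flipped)))
    # 3) split a leaf (grow a branch)
    if total_leaves < config.max_total_leaves:
        for ti, tree in enumerate(structure):
            for path, node in _walk(tree):
                if isinstance(node, Literal):
                    for op in ("and", "or"):
                        for lit in _literals(n_features):
                            out.append(with_tree(ti, _replace(tree, path, Op(op, node, lit))))
    # 4) prune a branch (replace an operator node by one of its children)
    for ti, tree in enumerate(structure):
        for path, node in _walk(tree):
            if isinstance(node, Op):
                out.append(with_tree(ti, _replace(tree, path, node.left)))
                out.append(with_tree(ti, _replace(tree, path, node.right)))
    # 5) add a single-literal tree
    if len(structure) < config.max_trees and total_leaves < config.max_total_leaves:
        for lit in _literals(n_features):
            out.append(structure + (lit,))
    # 6) delete a tree
    for ti in range(len(structure)):
        out.append(structure[:ti] + structure[ti + 1:])
    return out


# ---------------------------------------------------------------------------
# searches

def greedy_search(X_bin: np.ndarray, y: np.ndarray, config: SearchConfig,
                  max_steps: int = 200) -> LogicModel:
    """Steepest-descent search: move to the best neighbor while the deviance improves."""
    structure: tuple[NodeT, ...] = ()
    model, dev = score_model(structure, X_bin, y)
    n_features = X_bin.shape[1]
    for _ in range(max_steps):
        best_model, best_dev, best_structure = None, dev, None
        for cand in enumerate_neighbors(structure, n_features, config):
            cand_model, cand_dev = score_model(cand, X_bin, y)
            if cand_dev < best_dev - 1e-10:
                best_model, best_dev, best_structure = cand_model, cand_dev, cand
        if best_structure is None:
            break
        structure, model, dev = best_structure, best_model, best_dev
    return model


def acceptance_probability(delta: float, temperature: float) -> float:
    """Metropolis rule: 1 for improving moves, exp(-delta/T) otherwise."""
    if delta <= 0:
        return 1.0
    return float(np.exp(-delta / temperature))


def _auto_temperatures(X_bin: np.ndarray, y: np.ndarray, config: SearchConfig,
                       rng: np.random.Generator, n_pilot: int = 200) -> tuple[float, float]:
    """Pilot random walk to pick a cooling range.

    The start temperature targets ~90% acceptance of typical worsening
    moves; the end temperature makes even the smallest observed worsening
    essentially never accepted.
    """
    structure: tuple[NodeT, ...] = ()
    _, dev = score_model(structure, X_bin, y)
    n_features = X_bin.shape[1]
    deltas: list[float] = []
    for _ in range(n_pilot):
        nbrs = enumerate_neighbors(structure, n_features, config)
        cand = nbrs[rng.integers(len(nbrs))]
        _, cand_dev = score_model(cand, X_bin, y)
        if cand_dev > dev:
            deltas.append(cand_dev - dev)
        structure, dev = cand, cand_dev  # accept everything during the pilot
    if not deltas:
        return 10.0, 1e-3
    hi = float(np.quantile(deltas, 0.9))
    lo = float(np.quantile(deltas, 0.1))
    t_start = max(hi / (-np.log(0.9)), 1e-6)
    t_end = max(lo / (-np.log(1e-4)), 1e-9)
    if t_end >= t_start:
        t_end = t_start / 1000.0
    return t_start, t_end


def anneal_search(X_bin: np.ndarray, y: np.ndarray, config: SearchConfig,
                  rng: Optional[np.random.Generator] = None) -> LogicModel:
    """Simulated annealing: one uniformly random neighbor per iteration,
    Metropolis acceptance under geometric cooling; returns the best model visited."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.start_temperature is None or config.end_temperature is None:
        t_start, t_end = _auto_temperatures(X_bin, y, config, rng)
    else:
        t_start, t_end = config.start_temperature, config.end_temperature
    n_features = X_bin.shape[1]
    structure: tuple[NodeT, ...] = ()
    model, dev = score_model(structure, X_bin, y)
    best_model, best_dev = model, dev
    K = config.iterations
    ratio = t_end / t_start
    for k in range(K):
        T = t_start * ratio ** (k / max(K - 1, 1))
        nbrs = enumerate_neighbors(structure, n_features, config)
        cand = nbrs[rng.integers(len(nbrs))]
        cand_model, cand_dev = score_model(cand, X_bin, y)
        if rng.random() < acceptance_probability(cand_dev - dev, T):
            structure, model, dev = cand, cand_model, cand_dev
            if dev < best_dev:
                best_model, best_dev = model, dev
    return best_model


# ---------------------------------------------------------------------------
# GRS wrappers

def _binarize(vals: np.ndarray) -> np.ndarray:
    out = np.empty((vals.shape[0], 2 * vals.shape[1]), dtype=np.int8)
    out[:, 0::2] = (vals != 0)
    out[:, 1::2] = (vals == 2)
    return out


@dataclass
class LogicRegressionGRS:
    """A single fitted logic-regression model over dominant/recessive indicators."""

    model: LogicModel
    feature_ids: list[str] = field(default_factory=list)

    def predict_risk(self, genotypes) -> np.ndarray:
        return self.model.predict(_binarize(genotype_values(genotypes)))


@dataclass
class LogicBaggingGRS:
    """Bagged ensemble of logic-regression models; predictions are averaged."""

    members: list[LogicModel]
    feature_ids: list[str] = field(default_factory=list)

    def predict_risk(self, genotypes) -> np.ndarray:
        X_bin = _binarize(genotype_values(genotypes))
        acc = np.zeros(X_bin.shape[0], dtype=float)
        for m in self.members:
            acc += m.predict(X_bin)
        return acc / len(self.members)


def _feature_ids(genotypes) -> list[str]:
    if hasattr(genotypes, "snp_ids"):
        ids = []
        for sid in genotypes.snp_ids:
            ids.extend([f"{sid}_D", f"{sid}_R"])
        return ids
    return []


def fit_logic_regression(genotypes, outcome, config: SearchConfig = SearchConfig(),
                         rng: Optional[np.random.Generator] = None) -> LogicRegressionGRS:
    """Binarize genotypes and run the configured search (greedy or annealing)."""
    X_bin = _binarize(genotype_values(genotypes))
    y = np.asarray(outcome.values if hasattr(outcome, "values") else outcome).astype(float)
    if config.search == "greedy":
        model = greedy_search(X_bin, y, config)
    else:
        model = anneal_search(X_bin, y, config, rng=rng)
    return LogicRegressionGRS(model=model, feature_ids=_feature_ids(genotypes))


def fit_logic_bagging(genotypes, outcome, config: SearchConfig = SearchConfig(),
                      n_bags: int = 500,
                      rng: Optional[np.random.Generator] = None) -> LogicBaggingGRS:
    """Bootstrap-aggregated logic regression; members are fitted greedily."""
    X_bin = _binarize(genotype_values(genotypes))
    y = np.asarray(outcome.values if hasattr(outcome, "values") else outcome).astype(float)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = len(y)
    members: list[LogicModel] = []
    for _ in range(n_bags):
        bag = rng.integers(0, n, size=n)
        yb = y[bag]
        if yb.min() == yb.max():  # degenerate bootstrap: intercept-only member
            members.append(score_model((), X_bin[bag], yb)[0])
            continue
        members.append(greedy_search(X_bin[bag], yb, config))
    return LogicBaggingGRS(members=members, feature_ids=_feature_ids(genotypes))
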