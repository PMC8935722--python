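import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from grsforge.logic_regression import (
    ExpressionParseError,
    Literal,
    LogicModel,
    Op,
    SearchConfig,
    acceptance_probability,
    anneal_search,
    count_leaves,
    enumerate_neighbors,
    evaluate_tree,
    fit_logic_bagging,
    fit_logic_regression,
    greedy_search,
    parse_expression,
    score_model,
    tree_to_expression,
)

# (X1^c AND X2) OR (X1 AND X3^c): the classic example of a logic tree that
# is prediction-equivalent to a three-variable classification tree
EXAMPLE_TREE = Op("or",
                  Op("and", Literal(0, True), Literal(1)),
                  Op("and", Literal(0), Literal(2, True)))


def classification_tree_reference(x1, x2, x3):
    """The equivalent classification tree: split on X1, then X2 (left) or X3 (right)."""
    if x1 == 0:
        return x2
    return 1 - x3


@st.composite
def random_trees(draw, n_features=5, max_leaves=10):
    """Random logic trees with at most max_leaves leaves."""
    n_leaves = draw(st.integers(1, max_leaves))
    nodes = [Literal(draw(st.integers(0, n_features - 1)), draw(st.booleans()))
             for _ in range(n_leaves)]
    while len(nodes) > 1:
        i = draw(st.integers(0, len(nodes) - 2))
        op = draw(st.sampled_from(["and", "or"]))
        nodes[i] = Op(op, nodes.pop(i + 1), nodes[i])
    return nodes[0]


class TestTreeEvaluation:
    def test_example_tree_truth_table_matches_classification_tree(self):
        for bits in itertools.product((0, 1), repeat=3):
            expected = classification_tree_reference(*bits)
            assert evaluate_tree(EXAMPLE_TREE, np.array(bits)) == expected

    def test_example_tree_single_vectors(self):
        assert evaluate_tree(EXAMPLE_TREE, np.array([1, 1, 0])) == 1
        assert evaluate_tree(EXAMPLE_TREE, np.array([0, 0, 0])) == 0

    def test_out_of_range_feature_errors(self):
        with pytest.raises(IndexError):
            evaluate_tree(Literal(5), np.array([1, 0]))

    @given(random_trees())
    def test_matrix_evaluation_matches_rowwise(self, tree):
        X = np.array(list(itertools.product((0, 1), repeat=5)))
        vec = evaluate_tree(tree, X)
        rows = [evaluate_tree(tree, x) for x in X]
        assert np.array_equal(vec, rows)


class TestExpressions:
    def test_single_leaf(self):
        assert tree_to_expression(Literal(0)) == "X1"
        assert tree_to_expression(Literal(2, True)) == "X3^c"

    def test_example_tree_rendering(self):
        assert tree_to_expression(EXAMPLE_TREE) == "(X1^c ∧ X2) ∨ (X1 ∧ X3^c)"

    def test_parse_errors_report_position(self):
        with pytest.raises(ExpressionParseError, match="position"):
            parse_expression("X1 ∧ )")

    @given(random_trees())
    def test_print_parse_roundtrip_is_evaluation_identity(self, tree):
        back = parse_expression(tree_to_expression(tree))
        X = np.array(list(itertools.product((0, 1), repeat=5)))
        assert np.array_equal(evaluate_tree(tree, X), evaluate_tree(back, X))


class TestMoves:
    CONFIG = SearchConfig(max_trees=2, max_total_leaves=3)

    def test_leaf_alternation_count_for_single_literal(self):
        # any of 2p features x 2 negations minus the current literal
        n_features = 6
        structure = (Literal(0, False),)
        nbrs = enumerate_neighbors(structure, n_features, self.CONFIG)
        alternations = [s for s in nbrs if len(s) == 1 and isinstance(s[0], Literal)]
        assert len(alternations) == 2 * n_features - 1

    def test_no_growth_at_leaf_budget(self):
        cfg = SearchConfig(max_trees=1, max_total_leaves=2)
        full = (Op("and", Literal(0), Literal(1)),)
        nbrs = enumerate_neighbors(full, 4, cfg)
        assert all(sum(count_leaves(t) for t in s) <= 2 for s in nbrs)

    def test_intercept_only_can_only_add_trees(self):
        nbrs = enumerate_neighbors((), 3, self.CONFIG)
        assert len(nbrs) == 6  # 2p single-literal additions
        assert all(len(s) == 1 and isinstance(s[0], Literal) for s in nbrs)

    def test_tree_budget_respected(self):
        cfg = SearchConfig(max_trees=1, max_total_leaves=4)
        nbrs = enumerate_neighbors((Literal(0),), 3, cfg)
        assert all(len(s) <= 1 for s in nbrs)


class TestScoring:
    def test_intercept_only_deviance_closed_form(self):
        y = np.array([0, 1] * 50)
        X = np.zeros((100, 2), dtype=np.int8)
        _, dev = score_model((), X, y)
        assert dev == pytest.approx(2 * 100 * np.log(2), abs=1e-6)

    def test_perfect_separator_drives_deviance_to_clip_floor(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(80, 3)).astype(np.int8)
        y = X[:, 1].astype(float)
        model, dev = score_model((Literal(1),), X, y)
        assert dev < 1.0  # near zero, bounded below by the coefficient clip
        risks = model.predict(X)
        assert (np.abs(risks - y) < 1e-3).all()  # saturated but finite predictions

    def test_deviance_matches_reference_glm(self, rng):
        X = rng.integers(0, 2, size=(120, 4)).astype(np.int8)
        eta = -0.3 + 1.1 * X[:, 0] - 0.8 * (X[:, 1] & X[:, 2])
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        structure = (Literal(0), Op("and", Literal(1), Literal(2)))
        model, dev = score_model(structure, X, y)
        Z = np.column_stack([np.ones(120), X[:, 0], X[:, 1] & X[:, 2]])
        ref = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
        assert dev == pytest.approx(ref.deviance, abs=1e-6)
        assert np.allclose([model.intercept, *model.coefficients], ref.params, atol=1e-5)

    def test_duplicate_trees_collapse_to_first(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(60, 2)).astype(np.int8)
        y = rng.integers(0, 2, size=60).astype(float)
        model, dev = score_model((Literal(0), Literal(0)), X, y)
        single, dev_single = score_model((Literal(0),), X, y)
        assert dev == pytest.approx(dev_single, abs=1e-8)
        assert model.coefficients[1] == 0.0
        assert model.coefficients[0] == pytest.approx(single.coefficients[0], abs=1e-8)

    def test_constant_tree_absorbed_into_intercept(self):
        X = np.ones((40, 2), dtype=np.int8)
        y = np.array([0, 1] * 20, dtype=float)
        model, dev = score_model((Literal(0),), X, y)
        assert model.coefficients[0] == 0.0
        assert dev == pytest.approx(2 * 40 * np.log(2), abs=1e-6)


class TestGreedySearch:
    def test_recovers_single_informative_literal(self, rng):
        X = rng.integers(0, 2, size=(200, 6)).astype(np.int8)
        y = X[:, 3].astype(float)  # noise-free Y = X4
        model = greedy_search(X, y, SearchConfig(max_trees=2, max_total_leaves=4))
        preds = evaluate_tree(model.trees[0], X) if model.trees else None
        assert model.trees and np.array_equal(preds, y.astype(np.int8))

    def test_pure_noise_with_one_leaf_barely_improves(self, rng):
        X = rng.integers(0, 2, size=(300, 8)).astype(np.int8)
        y = rng.integers(0, 2, size=300).astype(float)
        model = greedy_search(X, y, SearchConfig(max_trees=1, max_total_leaves=1))
        _, dev0 = score_model((), X, y)
        # best of 16 correlated chi2(1)-scale improvements stays modest
        assert dev0 - model.deviance < 25.0

    def test_accepted_moves_strictly_decrease_deviance(self, small_marginal_data):
        _, train, _ = small_marginal_data
        from grsforge.logic_regression import _binarize

        X = _binarize(train.genotypes.values)[:150]
        y = train.outcome.values[:150].astype(float)
        cfg = SearchConfig(max_trees=2, max_total_leaves=3)
        devs = [score_model((), X, y)[1]]
        structure = ()
        while True:
            best = None
            for cand in enumerate_neighbors(structure, X.shape[1], cfg):
                _, d = score_model(cand, X, y)
                if best is None or d < best[1]:
                    best = (cand, d)
            if best is None or best[1] >= devs[-1] - 1e-10:
                break
            structure = best[0]
            devs.append(best[1])
        assert all(b < a for a, b in zip(devs, devs[1:]))
        final = greedy_search(X, y, cfg)
        assert final.deviance == pytest.approx(devs[-1], abs=1e-8)


class TestAnnealing:
    def test_acceptance_probability_closed_forms(self):
        assert acceptance_probability(0.0, 1.0) == 1.0
        assert acceptance_probability(-3.0, 0.5) == 1.0
        assert acceptance_probability(1.0, 1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_best_visited_never_worse_than_intercept_only(self, rng):
        X = rng.integers(0, 2, size=(100, 5)).astype(np.int8)
        y = rng.integers(0, 2, size=100).astype(float)
        _, dev0 = score_model((), X, y)
        cfg = SearchConfig(max_trees=2, max_total_leaves=3, search="annealing",
                           iterations=300, seed=4)
        model = anneal_search(X, y, cfg, rng=rng)
        assert model.deviance <= dev0 + 1e-9

    def test_cold_annealing_never_accepts_worse(self, rng):
        X = rng.integers(0, 2, size=(80, 4)).astype(np.int8)
        y = (X[:, 0] | X[:, 1]).astype(float)
        cfg = SearchConfig(max_trees=1, max_total_leaves=2, search="annealing",
                           iterations=400, start_temperature=1e-9, end_temperature=1e-10)
        model = anneal_search(X, y, cfg, rng=rng)
        # stochastic hill-climbing: end state is a local optimum no worse than start
        _, dev0 = score_model((), X, y)
        assert model.deviance <= dev0


class TestFittedGRS:
    def test_predictions_strictly_inside_unit_interval(self, small_marginal_data):
        _, train, test = small_marginal_data
        cfg = SearchConfig(max_trees=2, max_total_leaves=3)
        m = fit_logic_regression(train.genotypes, train.outcome, cfg)
        risks = m.predict_risk(test.genotypes)
        assert (risks > 0).all() and (risks < 1).all()

    def test_same_seed_gives_identical_model(self, small_marginal_data):
        _, train, _ = small_marginal_data
        cfg = SearchConfig(max_trees=2, max_total_leaves=3, search="annealing",
                           iterations=200, seed=9)
        a = fit_logic_regression(train.genotypes, train.outcome, cfg)
        b = fit_logic_regression(train.genotypes, train.outcome, cfg)
        assert a.model.expressions() == b.model.expressions()
        assert np.allclose(a.model.coefficients, b.model.coefficients)

    def test_interaction_signal_detected(self):
        import grsforge as gf

        design = gf.scenario2_design(2.4, 5, (4, 5), sample_size=600, seed=21, n_replicates=2)
        train, test = gf.generate_replicates(design)
        cfg = SearchConfig(max_trees=2, max_total_leaves=4)
        m = fit_logic_regression(train.genotypes, train.outcome, cfg)
        test_auc = gf.auc(m.predict_risk(test.genotypes), test.outcome.values)
        # 3 s.e. above chance for n=600 balanced (se ~ 0.024 under H0)
        assert test_auc > 0.57


class TestLogicBagging:
    def _tiny_members(self):
        t = Literal(0)
        m1 = LogicModel(intercept=np.log(0.2 / 0.8), trees=(), coefficients=np.array([]))
        m2 = LogicModel(intercept=np.log(0.4 / 0.6), trees=(), coefficients=np.array([]))
        return m1, m2

    def test_ensemble_mean_of_two_members(self):
        from grsforge.logic_regression import LogicBaggingGRS

        m1, m2 = self._tiny_members()
        ens = LogicBaggingGRS(members=[m1, m2])
        g = np.zeros((3, 2), dtype=int)
        assert np.allclose(ens.predict_risk(g), 0.3)
        # member-order permutation invariance and min/max bounds
        ens_rev = LogicBaggingGRS(members=[m2, m1])
        assert np.allclose(ens.predict_risk(g), ens_rev.predict_risk(g))
        assert (ens.predict_risk(g) >= 0.2 - 1e-12).all()
        assert (ens.predict_risk(g) <= 0.4 + 1e-12).all()

    def test_identical_members_collapse_to_member_prediction(self):
        from grsforge.logic_regression import LogicBaggingGRS

        m1, _ = self._tiny_members()
        ens = LogicBaggingGRS(members=[m1, m1, m1])
        g = np.zeros((2, 2), dtype=int)
        assert np.allclose(ens.predict_risk(g), 0.2)

    def test_bagging_reduces_prediction_variance(self):
        import grsforge as gf

        design = gf.scenario1_design(1.5, 4, 250, seed=33, n_replicates=5)
        reps = gf.generate_replicates(design)
        probe = reps[-1].genotypes
        cfg = SearchConfig(max_trees=2, max_total_leaves=3)
        singles, bags = [], []
        for r in reps[:4]:
            rng = np.random.default_rng(r.replicate_index)
            singles.append(fit_logic_regression(r.genotypes, r.outcome, cfg).predict_risk(probe))
            bags.append(fit_logic_bagging(r.genotypes, r.outcome, cfg, n_bags=8,
                                          rng=rng).predict_risk(probe))
        var_single = np.var(np.stack(singles), axis=0).mean()
        var_bag = np.var(np.stack(bags), axis=0).mean()
        assert var_bag <= var_single
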