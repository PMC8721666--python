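import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abbrevkit.evalkit import (
    GiniDecisionTree,
    categorize,
    conditional_table,
    fit_tree,
    level_coverages,
    rank_histogram,
    score_pairs,
)
from abbrevkit.textio import GoldPair


def pairs(*triples):
    return [GoldPair(d, s, l) for d, s, l in triples]


class TestScorePairs:
    def test_perfect_agreement(self):
        g = pairs(("d1", "AB", "alpha beta"), ("d1", "CD", "ceta delta"),
                  ("d2", "EF", "epsilon phi"))
        r = score_pairs(g, g)
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_half_right(self):
        pred = pairs(("d1", "AB", "alpha beta"), ("d1", "CD", "wrong lf"))
        gold = pairs(("d1", "AB", "alpha beta"), ("d1", "CD", "ceta delta"))
        r = score_pairs(pred, gold)
        assert (r.precision, r.recall, r.f1) == (0.5, 0.5, 0.5)

    def test_empty_predictions(self):
        r = score_pairs([], pairs(("d1", "AB", "alpha beta")))
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)

    def test_lf_match_is_whitespace_and_case_insensitive(self):
        pred = pairs(("d1", "AB", "Alpha  Beta"))
        gold = pairs(("d1", "AB", "alpha beta"))
        assert score_pairs(pred, gold).f1 == 1.0

    def test_duplicates_collapse(self):
        pred = pairs(("d1", "AB", "alpha beta"), ("d1", "AB", "alpha beta"))
        gold = pairs(("d1", "AB", "alpha beta"))
        assert score_pairs(pred, gold).precision == 1.0


class TestCategorize:
    @pytest.mark.parametrize(
        "cand,gold,category,edge",
        [
            ("controls", "healthy controls", "off_by_one", "left"),
            ("Latent herpes simplex virus", "herpes simplex virus", "off_by_one", "left"),
            ("bedside percutaneous dilational tracheostomy",
             "percutaneous dilational tracheostomy", "off_by_one", "left"),
            ("alpha beta gamma", "alpha beta", "off_by_one", "right"),
            ("perceived muscle soreness", "rating of perceived muscle soreness",
             "otherwise", "none"),
            ("herpes simplex virus", "herpes simplex virus", "correct", "none"),
            ("completely unrelated span", "herpes simplex virus", "otherwise", "none"),
        ],
    )
    def test_one_token_edge_rule(self, cand, gold, category, edge):
        got = categorize(cand, gold)
        assert (got.category, got.edge) == (category, edge)

    def test_delta_sign_tracks_direction(self):
        assert categorize("Latent herpes virus", "herpes virus").delta == +1
        assert categorize("virus", "herpes virus").delta == -1

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from("alpha beta gamma delta".split()), min_size=1, max_size=4),
           st.lists(st.sampled_from("alpha beta gamma delta".split()), min_size=1, max_size=4))
    def test_detection_symmetric(self, a, b):
        ca = categorize(" ".join(a), " ".join(b))
        cb = categorize(" ".join(b), " ".join(a))
        assert (ca.category == "off_by_one") == (cb.category == "off_by_one")
        assert (ca.category == "correct") == (cb.category == "correct")


class TestConditionalTable:
    def test_arithmetic(self):
        rows = [(1, 1)] * 4 + [(1, 0)] + [(0, 1)] + [(0, 0)] * 4
        table = conditional_table(rows)
        assert table[0] == (0.2, 5)
        assert table[1] == (0.8, 5)

    def test_empty_stratum_is_undefined_not_zero(self):
        table = conditional_table([(1, 1), (1, 0)])
        assert table[0] is None
        assert table[1] == (0.5, 2)

    def test_synthetic_data_prefers_charmatch(self, synth_bundle):
        df = synth_bundle["table"]
        table = conditional_table(zip(df["charmatch"], df["gold"]))
        assert table[1][0] > table[0][0]


class TestRankHistogram:
    def test_all_correct_at_zero(self):
        assert rank_histogram([(0, 1)] * 5) == {0: 5}

    def test_correct_at_lower_rank_counted_there(self):
        hist = rank_histogram([(0, 0), (1, 0), (2, 0), (3, 1), (4, 0)])
        assert hist[3] == 1 and hist[0] == 0

    def test_total_conserved(self, synth_bundle):
        df = synth_bundle["table"]
        hist = rank_histogram(zip(df["rank"], df["gold"]))
        assert sum(hist.values()) == int(df["gold"].sum())
        # most correct candidates sit at the top rank
        assert hist[0] > sum(v for k, v in hist.items() if k > 0)


class TestGiniTree:
    def test_pure_data_yields_single_leaf(self):
        df = pd.DataFrame({"charmatch": [0, 1] * 20, "gold": [0] * 40})
        root = fit_tree(df, ["charmatch"])
        assert root.is_leaf
        assert (root.best_label, root.accuracy, root.coverage) == (0, 1.0, 1.0)

    def test_root_coverage_is_total(self, synth_bundle):
        df = synth_bundle["table"]
        root = fit_tree(df, ["rank", "charmatch"])
        assert root.coverage == 1.0

    def test_five_candidate_groups_give_80_20_mass(self, synth_bundle):
        """With 5 candidates per SF and usually one correct, gold is ~20% ones."""
        df = synth_bundle["table"]
        frac_ones = df["gold"].mean()
        assert 0.12 <= frac_ones <= 0.25
        root = fit_tree(df, ["rank", "charmatch"])
        assert root.best_label == 0
        assert root.accuracy == pytest.approx(1 - frac_ones, abs=1e-9)

    def test_agreement_then_charmatch_structure(self, synth_bundle):
        df = synth_bundle["table"]
        root = fit_tree(df, ["rank", "charmatch", "agreement"], max_depth=3)
        assert root.feature == "agreement"
        children = [root.left, root.right]
        split_children = [c for c in children if not c.is_leaf]
        assert split_children
        assert all(c.feature == "charmatch" for c in split_children)

    def test_level_coverages_sum_to_one(self, synth_bundle):
        df = synth_bundle["table"]
        root = fit_tree(df, ["rank", "charmatch", "agreement"], max_depth=4)
        for total in level_coverages(root):
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_split_agrees_with_sklearn_on_fixture(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(0)
        n = 2000
        strong = rng.integers(0, 2, n)
        weak = rng.integers(0, 2, n)
        y = np.where(rng.random(n) < 0.9, strong, weak)
        df = pd.DataFrame({"strong": strong, "weak": weak})
        ours = GiniDecisionTree(features=["strong", "weak"], max_depth=1).fit(df, y)
        theirs = DecisionTreeClassifier(criterion="gini", max_depth=1).fit(df, y)
        assert ours.tree_.feature == df.columns[theirs.tree_.feature[0]]
        agree = (ours.predict(df) == theirs.predict(df)).mean()
        assert agree == 1.0

    def test_empty_feature_subset_rejected(self):
        df = pd.DataFrame({"gold": [0, 1]})
        with pytest.raises(ValueError):
            fit_tree(df, [])

    def test_split_never_increases_gini(self, synth_bundle):
        df = synth_bundle["table"]
        root = fit_tree(df, ["rank", "charmatch", "agreement"], max_depth=4)

        def gini(node):
            p = node.accuracy if node.best_label == 1 else 1 - node.accuracy
            return 2 * p * (1 - p)

        def walk(node):
            if node.is_leaf:
                return
            parent = gini(node)
            wl = node.left.coverage / node.coverage
            child = wl * gini(node.left) + (1 - wl) * gini(node.right)
            assert child <= parent + 1e-12
            walk(node.left)
            walk(node.right)

        walk(root)
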