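import math

import numpy as np
import pandas as pd
import pytest

from abbrevkit.extract import Candidate
from abbrevkit.features import FeatureVector
from abbrevkit.rerank import (
    PRESETS,
    FEATURE_NAMES,
    LogisticReranker,
    SeparationError,
    fit,
    median_confidence,
    preset,
    rerank,
    score,
    sigmoid,
)


def fv(rank=0, cm=0, l1f=0.0):
    return FeatureVector(rank=rank, charmatch=cm, freq=round(math.expm1(l1f)),
                         log1p_freq=math.log1p(round(math.expm1(l1f))))


def simulate(beta, n, rng):
    """Draw (X, y) from a known logistic model over the three features."""
    rank = rng.integers(0, 5, size=n)
    cm = rng.integers(0, 2, size=n)
    l1f = np.log1p(rng.poisson(3.0, size=n))
    z = beta[0] + beta[1] * rank + beta[2] * cm + beta[3] * l1f
    y = (rng.random(n) < sigmoid(z)).astype(int)
    X = pd.DataFrame({"rank": rank, "charmatch": cm, "log1p_freq": l1f})
    return X, y


class TestPresets:
    def test_full_coefficient_grid(self):
        # three nested formula blocks of four benchmark fits each
        grid = np.array([PRESETS[k] for k in range(1, 13)])
        assert np.all(grid[:4, 2:] == 0.0)
        assert np.all(grid[4:8, 3] == 0.0)
        assert np.all(grid[4:, 2] > 0)
        assert np.all(grid[:, 1] < 0)  # less is more for rank, in all 12
        for k in range(1, 13):
            assert tuple(preset(k).beta_) == PRESETS[k]

    def test_out_of_range_id(self):
        with pytest.raises(ValueError):
            preset(13)

    def test_score_closed_form(self):
        m = preset(5)  # (-1.2, -3.2, 3.5, 0)
        assert score(m, fv(rank=0, cm=1)) == pytest.approx(1 / (1 + math.exp(-2.3)), abs=1e-12)
        assert score(m, fv(rank=0, cm=0)) == pytest.approx(1 / (1 + math.exp(1.2)), abs=1e-12)

    def test_z_zero_scores_half(self):
        m = LogisticReranker(active=("rank",))
        m.beta_ = np.zeros(4)
        assert score(m, fv(rank=3, cm=1)) == 0.5


class TestFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        beta = (-2.0, -3.0, 3.5, 0.4)
        X, y = simulate(beta, 50_000, rng)
        m = LogisticReranker().fit(X, y)
        assert np.allclose(m.beta_, beta, atol=0.15)
        assert m.report_.converged

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X, y = simulate((-1.0, -2.0, 2.0, 0.3), 5_000, rng)
        ours = LogisticReranker().fit(X, y)
        theirs = sm.Logit(y, sm.add_constant(X[list(FEATURE_NAMES)])).fit(disp=0)
        assert np.allclose(ours.beta_, theirs.params.to_numpy(), atol=1e-6)
        se_ours = [ours.report_.standard_errors[k]
                   for k in ("intercept",) + FEATURE_NAMES]
        assert np.allclose(se_ours, theirs.bse.to_numpy(), rtol=1e-4)

    def test_null_feature_coefficient_near_zero(self):
        rng = np.random.default_rng(3)
        n = 20_000
        X = pd.DataFrame({
            "rank": rng.integers(0, 5, n),
            "charmatch": rng.integers(0, 2, n),
            "log1p_freq": np.zeros(n),
        })
        y = (rng.random(n) < 0.5).astype(int)  # independent of everything
        m = LogisticReranker(active=("rank",)).fit(X, y)
        b1 = m.report_.coefficients["rank"]
        se = m.report_.standard_errors["rank"]
        assert abs(b1) < 3 * se

    def test_single_class_rejected(self):
        X = pd.DataFrame({"rank": [0, 1], "charmatch": [0, 1], "log1p_freq": [0, 0]})
        with pytest.raises(ValueError, match="class"):
            LogisticReranker().fit(X, [1, 1])

    def test_perfect_separation_detected_and_ridge_recovers(self):
        X = pd.DataFrame({"rank": [0, 0, 0, 0], "charmatch": [1, 1, 0, 0],
                          "log1p_freq": [0.0] * 4})
        y = [1, 1, 0, 0]  # gold == charmatch exactly
        with pytest.raises(SeparationError, match="ridge"):
            LogisticReranker(active=("charmatch",)).fit(X, y)
        m = LogisticReranker(active=("charmatch",), ridge=1.0).fit(X, y)
        assert np.isfinite(m.beta_).all()

    def test_nested_log_likelihoods_monotone(self, synth_bundle):
        df = synth_bundle["table"]
        X, y = df[["rank", "charmatch", "log1p_freq"]], df["gold"]
        lls = [
            LogisticReranker(active=a).fit(X, y).report_.log_likelihood
            for a in (("rank",), ("rank", "charmatch"),
                      ("rank", "charmatch", "log1p_freq"))
        ]
        assert lls[0] <= lls[1] <= lls[2]

    def test_functional_wrapper(self):
        rng = np.random.default_rng(9)
        X, y = simulate((-1.0, -2.0, 2.0, 0.0), 3_000, rng)
        data = [(fv(rank=int(r), cm=int(c), l1f=float(f)), int(g))
                for r, c, f, g in zip(X["rank"], X["charmatch"], X["log1p_freq"], y)]
        model, report = fit(data, active=("rank", "charmatch"))
        assert report.converged
        assert model.beta_[3] == 0.0  # inactive pinned


class TestSklearnProtocol:
    def test_clone_and_cross_val(self):
        from sklearn.base import clone
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(21)
        X, y = simulate((-1.0, -2.0, 2.5, 0.3), 4_000, rng)
        est = LogisticReranker(active=("rank", "charmatch"))
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        scores = cross_val_score(est, X[list(FEATURE_NAMES)].to_numpy(), y,
                                 cv=3, scoring="accuracy")
        assert scores.min() > 0.6


class TestRerank:
    def test_charmatch_can_overturn_rank(self):
        m = preset(5)
        cands = [
            (Candidate("d1", "HC", "controls", 0), fv(rank=0, cm=0)),
            (Candidate("d1", "HC", "healthy controls", 1), fv(rank=1, cm=1)),
        ]
        ordered = rerank(cands, m)
        assert ordered[0][0].lf_candidate == "healthy controls"
        # z values from the printed coefficients: -0.9 beats -1.2
        assert ordered[0][2] == pytest.approx(sigmoid(-0.9), abs=1e-12)

    def test_stable_tie_break_keeps_original_order(self):
        m = preset(5)
        cands = [(Candidate("d1", "AB", f"c{r}", r), fv(rank=0, cm=0)) for r in range(3)]
        assert [c.rank for c, _, _ in rerank(cands, m)] == [0, 1, 2]

    def test_rank_only_model_never_reorders(self):
        m = preset(1)
        cands = [(Candidate("d1", "AB", f"c{r}", r), fv(rank=r, cm=r % 2)) for r in range(5)]
        assert [c.rank for c, _, _ in rerank(cands, m)] == [0, 1, 2, 3, 4]

    def test_mixed_group_rejected(self):
        m = preset(1)
        cands = [(Candidate("d1", "AB", "x y", 0), fv()),
                 (Candidate("d2", "AB", "x y", 0), fv())]
        with pytest.raises(ValueError, match="mixed"):
            rerank(cands, m)

    def test_monotonicity_in_each_feature(self):
        m = preset(9)  # all three features active
        base = score(m, fv(rank=2, cm=0, l1f=0.0))
        assert score(m, fv(rank=3, cm=0)) < base          # beta1 < 0
        assert score(m, fv(rank=2, cm=1)) > base          # beta2 > 0
        assert score(m, fv(rank=2, cm=0, l1f=2.0)) > base  # beta3 > 0


class TestMedianConfidence:
    def test_single_correct_candidate_at_z_zero(self):
        m = LogisticReranker(active=("rank",))
        m.beta_ = np.zeros(4)
        assert median_confidence(m, [(fv(), 1), (fv(rank=1), 0)]) == 0.5

    def test_no_correct_candidates_rejected(self):
        with pytest.raises(ValueError):
            median_confidence(preset(1), [(fv(), 0)])

    def test_permutation_invariant(self):
        data = [(fv(rank=r, cm=r % 2), 1) for r in range(5)]
        m = preset(5)
        assert median_confidence(m, data) == median_confidence(m, data[::-1])

    def test_more_features_more_confident(self, synth_bundle):
        """Nested fitted models are increasingly confident on correct candidates."""
        df = synth_bundle["table"]
        X, y = df[["rank", "charmatch", "log1p_freq"]], df["gold"]
        meds = []
        for active in (("rank",), ("rank", "charmatch"),
                       ("rank", "charmatch", "log1p_freq")):
            m = LogisticReranker(active=active).fit(X, y)
            correct = m.predict_proba(X[y == 1])[:, 1]
            meds.append(float(np.median(correct)))
        assert meds[0] <= meds[1] <= meds[2]
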