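"""LASSO selection, logistic fit, Youden thresholding, metrics, protocol."""

import numpy as np
import pandas as pd
import pytest

from oracles import auc_pair_counting
from slnrad.modeling import (ModelConfig, evaluate, fit_logistic,
                             fit_single_seed, lasso_select, predict_scores,
                             run_seed_protocol, youden_threshold)


def _planted(n=200, p=20, seed=0, strength=2.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    eta = strength * X["f3"] - strength * X["f6"]
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
    return X, y


def test_lasso_recovers_planted_features_and_respects_cap():
    X, y = _planted()
    sel = lasso_select(X, y, ModelConfig(), seed=1)
    assert {"f3", "f6"} <= set(sel)
    assert len(sel) <= 10


def test_lasso_near_empty_on_pure_noise():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(80, 15)))
    X.columns = [f"n{i}" for i in range(15)]
    y = pd.Series(rng.integers(0, 2, size=80))
    sizes = [len(lasso_select(X, y, ModelConfig(), seed=s)) for s in range(1, 6)]
    assert np.mean(sizes) <= 2  # 1-SD rule keeps noise selections tiny


def test_lasso_cap_enforced_with_many_informative_features():
    rng = np.random.default_rng(7)
    n = 150
    X = pd.DataFrame(rng.normal(size=(n, 30)), columns=[f"f{i}" for i in range(30)])
    eta = X.iloc[:, :20].sum(axis=1)  # 20 weakly informative features
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
    for seed in (1, 2, 3):
        assert len(lasso_select(X, y, ModelConfig(), seed=seed)) <= 10


def test_lasso_rejects_one_class_labels():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
    X.columns = list("abc")
    with pytest.raises(ValueError, match="degenerate"):
        lasso_select(X, pd.Series(np.ones(10, dtype=int)), ModelConfig(), 1)


def test_logistic_matches_grid_search_likelihood_oracle():
    """Coefficients on a 3-point problem agree with brute-force ML."""
    # not linearly separable, so the ML optimum is finite
    X = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
    y = pd.Series([1, 0, 1])
    intercept, coef = fit_logistic(X, y, ["x"])

    def nll(b0, b1):
        eta = b0 + b1 * X["x"].to_numpy()
        p = 1 / (1 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        yy = y.to_numpy()
        return -np.sum(yy * np.log(p) + (1 - yy) * np.log(1 - p))

    b0g, b1g = np.meshgrid(np.linspace(-6, 6, 241), np.linspace(-6, 6, 241))
    vals = np.vectorize(nll)(b0g, b1g)
    i = np.unravel_index(vals.argmin(), vals.shape)
    assert intercept == pytest.approx(b0g[i], abs=0.1)
    assert coef["x"] == pytest.approx(b1g[i], abs=0.1)


def test_logistic_monotone_in_label_like_feature():
    rng = np.random.default_rng(1)
    y = pd.Series(rng.integers(0, 2, size=40))
    X = pd.DataFrame({"f": y + 0.01 * rng.normal(size=40)})
    intercept, coef = fit_logistic(X, y, ["f"])
    scores = 1 / (1 + np.exp(-(intercept + coef["f"] * X["f"])))
    assert scores[y == 1].min() > scores[y == 0].max()


def test_logistic_intercept_only_fallback():
    y = pd.Series([0, 0, 1, 0])
    intercept, coef = fit_logistic(pd.DataFrame(index=y.index), y, [])
    assert len(coef) == 0
    assert 1 / (1 + np.exp(-intercept)) == pytest.approx(0.25)


def test_youden_separable_and_tie_cases():
    t = youden_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
    assert t == pytest.approx(0.5)
    # interleaved labels: enumerating the three cut-points gives YI
    # 0.5 / 0.0 / 0.5, so the optimum is 0.5 at the lowest threshold 0.15
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 0, 1, 0])
    t2 = youden_threshold(scores, labels)
    assert t2 == pytest.approx(0.15)
    pred = scores >= t2
    sens = (pred & (labels == 1)).sum() / 2
    spec = (~pred & (labels == 0)).sum() / 2
    assert sens + spec - 1 == pytest.approx(0.5)
    with pytest.raises(ValueError, match="constant"):
        youden_threshold(np.full(4, 0.5), np.array([0, 1, 0, 1]))


def test_youden_equals_exhaustive_cutpoint_scan(rng):
    scores = rng.random(30)
    labels = (rng.random(30) < 0.4).astype(int)
    t = youden_threshold(scores, labels)
    uniq = np.unique(scores)
    best = -np.inf
    best_t = None
    for c in (uniq[:-1] + uniq[1:]) / 2:
        pred = scores >= c
        yi = (pred[labels == 1].mean()) + ((~pred)[labels == 0].mean()) - 1
        if yi > best:
            best, best_t = yi, c
    assert t == pytest.approx(best_t)


def test_evaluate_reproduces_published_training_row():
    """37 positives / 33 called, 72 negatives / 59 called -> 0.89/0.82/0.71."""
    labels = np.array([1] * 37 + [0] * 72)
    scores = np.concatenate([
        np.linspace(0.6, 0.9, 33), np.linspace(0.1, 0.4, 4),     # positives
        np.linspace(0.1, 0.4, 59), np.linspace(0.6, 0.9, 13),    # negatives
    ])
    rep = evaluate(scores, labels, threshold=0.5)
    assert round(rep.sensitivity, 2) == 0.89
    assert round(rep.specificity, 2) == 0.82
    assert round(rep.yi, 2) == 0.71
    assert rep.yi == pytest.approx(rep.sensitivity + rep.specificity - 1)


def test_evaluate_perfect_and_random():
    labels = np.array([0, 0, 1, 1])
    rep = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), labels, 0.5)
    for v in rep.as_dict().values():
        assert v == pytest.approx(1.0)
    with pytest.raises(ValueError, match="single class"):
        evaluate(np.array([0.5, 0.6]), np.array([1, 1]), 0.5)


def test_auc_equals_pair_counting(rng):
    scores = rng.random(40).round(1)  # coarse grid forces ties
    labels = (rng.random(40) < 0.5).astype(int)
    rep = evaluate(scores, labels, 0.5)
    assert rep.auc == pytest.approx(auc_pair_counting(scores, labels))


def _protocol_data(seed=0):
    X, y = _planted(n=90, p=8, seed=seed)
    Xv, yv = _planted(n=40, p=8, seed=seed + 1)
    Xt, yt = _planted(n=30, p=8, seed=seed + 2)
    return X, y, Xv, yv, Xt, yt


def test_seed_protocol_winner_and_determinism():
    X, y, Xv, yv, Xt, yt = _protocol_data()
    cfg = ModelConfig(n_seeds=4)
    best, reports = run_seed_protocol(X, y, X, y, Xv, yv, Xt, yt, cfg)
    accs = [fit_single_seed(X, y, cfg, s).training_accuracy for s in range(1, 5)]
    assert best.training_accuracy == pytest.approx(max(accs))
    best2, reports2 = run_seed_protocol(X, y, X, y, Xv, yv, Xt, yt, cfg)
    assert best2.selected_features == best.selected_features
    assert best2.threshold == best.threshold
    assert reports2["testing"].as_dict() == reports["testing"].as_dict()
    # threshold frozen from training and applied to every split
    assert best.threshold_from_training
    for rep in reports.values():
        assert rep.yi == pytest.approx(rep.sensitivity + rep.specificity - 1)


def test_seed_protocol_single_seed_reduces_to_single_run():
    X, y, Xv, yv, Xt, yt = _protocol_data(3)
    cfg = ModelConfig(n_seeds=1)
    best, _ = run_seed_protocol(X, y, X, y, Xv, yv, Xt, yt, cfg)
    single = fit_single_seed(X, y, cfg, 1)
    assert best.selected_features == single.selected_features
    assert best.seed == 1
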