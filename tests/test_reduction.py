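"""Normalization, ADASYN, Mann-Whitney filter, Spearman pruning, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slnrad.reduction import (ReductionGrid, ReductionParams, correlation_prune,
                              fit_apply_zscore, mannwhitney_filter,
                              mannwhitney_p, pca_reduce, rebalance_adasyn,
                              run_reduction, select_reduction_params)


# -- z-score -----------------------------------------------------------------

def test_zscore_hand_arithmetic():
    train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    val = pd.DataFrame({"f": [2.0, 4.0]})
    (ztr, zval), state = fit_apply_zscore(train, val)
    np.testing.assert_allclose(ztr["f"], [-1.0, 0.0, 1.0])  # SD convention n-1
    assert zval["f"].iloc[0] == 0.0  # value equal to the training mean
    assert zval["f"].iloc[1] == pytest.approx(2.0)
    assert state.fitted_on_training


def test_zscore_drops_constant_columns_everywhere():
    train = pd.DataFrame({"c": [5.0, 5.0, 5.0], "f": [0.0, 1.0, 2.0]})
    val = pd.DataFrame({"c": [7.0], "f": [1.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        (ztr, zval), state = fit_apply_zscore(train, val)
    assert list(ztr.columns) == ["f"] and list(zval.columns) == ["f"]
    assert state.dropped_columns == ["c"]


def test_zscore_training_columns_standardized(rng):
    train = pd.DataFrame(rng.normal(3, 7, size=(50, 4)),
                         columns=list("abcd"))
    (ztr,), _ = fit_apply_zscore(train)
    np.testing.assert_allclose(ztr.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(ztr.std(ddof=1), 1.0, atol=1e-12)


# -- ADASYN ------------------------------------------------------------------

def _toy(n_min=10, n_maj=30, seed=0):
    rng = np.random.default_rng(seed)
    X_min = rng.normal(0, 1, size=(n_min, 3))
    X_maj = rng.normal(1.5, 1, size=(n_maj, 3))
    X = pd.DataFrame(np.vstack([X_min, X_maj]), columns=list("xyz"),
                     index=[f"s{i}" for i in range(n_min + n_maj)])
    y = pd.Series([1] * n_min + [0] * n_maj, index=X.index)
    return X, y


def test_adasyn_balanced_input_unchanged():
    X, y = _toy(15, 15)
    Xa, ya = rebalance_adasyn(X, y, seed=1)
    assert len(Xa) == len(X) and (ya == y).all()


def test_adasyn_budget_balances_10_30():
    X, y = _toy(10, 30)
    Xa, ya = rebalance_adasyn(X, y, seed=2)
    counts = ya.value_counts()
    assert counts[1] == 30 and counts[0] == 30  # budget (30-10)*1 = 20 synthetics
    # originals unchanged, first
    pd.testing.assert_frame_equal(Xa.iloc[: len(X)], X)


def test_adasyn_synthetics_lie_on_minority_segments():
    X, y = _toy(12, 36, seed=3)
    Xa, ya = rebalance_adasyn(X, y, seed=3)
    X_min = X[y == 1].to_numpy()
    synth = Xa.iloc[len(X):].to_numpy()
    assert len(synth) == 24
    for s in synth:
        on_segment = False
        for i in range(len(X_min)):
            for j in range(len(X_min)):
                if i == j:
                    continue
                d = X_min[j] - X_min[i]
                denom = d @ d
                if denom == 0:
                    continue
                lam = (s - X_min[i]) @ d / denom
                proj = X_min[i] + lam * d
                if 0 <= lam <= 1 and np.linalg.norm(s - proj) < 1e-9:
                    on_segment = True
                    break
            if on_segment:
                break
        assert on_segment


def test_adasyn_rejects_degenerate_inputs():
    X, y = _toy(10, 30)
    with pytest.raises(ValueError, match="two classes"):
        rebalance_adasyn(X, pd.Series(1, index=X.index), seed=0)
    X2, y2 = _toy(3, 30)
    with pytest.raises(ValueError, match="minority"):
        rebalance_adasyn(X2, y2, seed=0)


def test_adasyn_deterministic_under_seed():
    X, y = _toy(10, 30)
    a, _ = rebalance_adasyn(X, y, seed=7)
    b, _ = rebalance_adasyn(X, y, seed=7)
    pd.testing.assert_frame_equal(a, b)


# -- Mann-Whitney ------------------------------------------------------------

def test_exact_p_for_fully_separated_quartets():
    p = mannwhitney_p(np.array([1, 2, 3, 4.0]), np.array([5, 6, 7, 8.0]))
    assert p == pytest.approx(2.0 / 70.0)
    table = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6, 7, 8.0]})
    labels = pd.Series([1, 1, 1, 1, 0, 0, 0, 0])
    kept05, pvals = mannwhitney_filter(table, labels, 0.05)
    kept01, _ = mannwhitney_filter(table, labels, 0.01)
    assert kept05 == ["f"] and kept01 == []
    assert pvals["f"] == pytest.approx(2.0 / 70.0)


def test_identical_groups_removed_at_any_threshold():
    table = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]})
    labels = pd.Series([1, 1, 0, 0])
    kept, pvals = mannwhitney_filter(table, labels, 0.05)
    assert kept == [] and pvals["f"] == pytest.approx(1.0)


def test_label_like_feature_attains_minimal_p():
    x = np.array([1, 2, 3, 4, 5.0])
    y = np.array([6, 7, 8, 9, 10.0])
    # smallest achievable two-sided p at n=m=5 is 2/binom(10,5)
    assert mannwhitney_p(x, y) == pytest.approx(2.0 / 252.0)


# -- Spearman pruning --------------------------------------------------------

def test_duplicate_column_pruned_keeping_lower_p():
    rng = np.random.default_rng(0)
    base = rng.normal(size=40)
    table = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=40)})
    prio = pd.Series({"a": 0.5, "b": 0.001, "c": 0.2})
    kept = correlation_prune(table, 0.95, priority=prio)
    assert "b" in kept and "a" not in kept and "c" in kept


@pytest.mark.parametrize("threshold", [0.75, 0.95])
def test_post_prune_pair_scan_clean(threshold, rng):
    base = rng.normal(size=(60, 3))
    mix = np.column_stack([
        base[:, 0], base[:, 0] + 0.05 * rng.normal(size=60),
        base[:, 1], base[:, 1] * 2 + 0.3 * rng.normal(size=60),
        base[:, 2], rng.normal(size=60),
    ])
    table = pd.DataFrame(mix, columns=list("abcdef"))
    kept = correlation_prune(table, threshold)
    rho = np.abs(sps.spearmanr(table[kept].to_numpy()).statistic)
    rho = np.atleast_2d(rho)
    off = rho[~np.eye(len(kept), dtype=bool)]
    assert (off < threshold).all()


def test_independent_noise_survives_at_095(rng):
    table = pd.DataFrame(rng.normal(size=(50, 8)),
                         columns=[f"n{i}" for i in range(8)])
    kept = correlation_prune(table, 0.95)
    assert kept == list(table.columns)


# -- PCA ---------------------------------------------------------------------

def test_pca_planar_data_exact_and_variance_ordered(rng):
    basis = rng.normal(size=(2, 6))
    coords = rng.normal(size=(30, 2))
    X = pd.DataFrame(coords @ basis)
    (ztr, zo), pca = pca_reduce(X, [X.iloc[:5]], k=2)
    recon = pca.inverse_transform(ztr.to_numpy())
    np.testing.assert_allclose(recon, X.to_numpy(), atol=1e-9)
    var = ztr.var(ddof=1).to_numpy()
    assert np.all(np.diff(var) <= 1e-12)
    # k = n_features preserves total variance
    Xf = pd.DataFrame(rng.normal(size=(20, 4)))
    (zf,), _ = pca_reduce(Xf, [], k=4)
    assert zf.to_numpy().var(axis=0, ddof=1).sum() == pytest.approx(
        Xf.to_numpy().var(axis=0, ddof=1).sum())
    with pytest.raises(ValueError, match="exceeds"):
        pca_reduce(Xf, [], k=25)


# -- grid machinery ----------------------------------------------------------

def test_reduction_params_restricted_to_printed_grids():
    ReductionParams(0.05, 0.95, None)
    with pytest.raises(ValueError):
        ReductionParams(0.02, 0.95, None)
    with pytest.raises(ValueError):
        ReductionParams(0.05, 0.5, None)
    with pytest.raises(ValueError):
        ReductionParams(0.05, 0.95, 30)
    assert len(ReductionGrid().cells()) == 4 * 5 * 6
    published_cr_optimum = ReductionParams(0.05, 0.95, None)
    assert published_cr_optimum in ReductionGrid().cells()


def _signal_tables(seed=0, n=60, p_noise=6):
    rng = np.random.default_rng(seed)
    y = pd.Series(rng.random(n) < 0.34, dtype=int,
                  index=[f"s{i}" for i in range(n)]).astype(int)
    X = pd.DataFrame(rng.normal(size=(n, p_noise)),
                     columns=[f"noise{i}" for i in range(p_noise)],
                     index=y.index)
    X["signal"] = y * 2.0 + rng.normal(size=n) * 0.5
    return X, y


def test_run_reduction_order_and_separation():
    Xtr, ytr = _signal_tables(0)
    Xva, _ = _signal_tables(1, n=20)
    Xte, _ = _signal_tables(2, n=10)
    red = run_reduction(Xtr, ytr, Xva, Xte, ReductionParams(0.05, 0.95, None),
                        seed=0)
    assert "signal" in red["state"].retained_features
    assert red["state"].fitted_on_training
    # validation transformed with training statistics, not its own
    assert abs(red["val"].mean().mean()) > 1e-6 or len(red["val"]) == 0
    # rebalanced training has ~equal classes
    counts = red["train_labels"].value_counts()
    assert abs(counts[0] - counts[1]) <= 2


def test_grid_cell_keeping_signal_beats_cell_discarding_it():
    Xtr, ytr = _signal_tables(3, n=80)
    Xva, yva = _signal_tables(4, n=40)
    # recompute validation labels consistent with its signal column
    yva = (Xva["signal"] > 1.0).astype(int)
    from slnrad.modeling import ModelConfig

    grid = ReductionGrid(p_values=(0.001, 0.05), rho_values=(0.95,),
                         pca_values=(None,))
    winner, scores = select_reduction_params(
        grid, Xtr, ytr, Xva, yva, n_seeds=3,
        model_config=ModelConfig(n_seeds=3),
    )
    assert len(scores) == 2
    single = ReductionGrid(p_values=(0.05,), rho_values=(0.95,),
                           pca_values=(None,))
    w2, s2 = select_reduction_params(single, Xtr, ytr, Xva, yva, n_seeds=2,
                                     model_config=ModelConfig(n_seeds=2))
    assert w2 == ReductionParams(0.05, 0.95, None) and len(s2) == 1
    # determinism
    w3, _ = select_reduction_params(single, Xtr, ytr, Xva, yva, n_seeds=2,
                                    model_config=ModelConfig(n_seeds=2))
    assert w2 == w3
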