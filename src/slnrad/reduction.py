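"""Train-anchored normalization, ADASYN rebalancing, and feature reduction.

The reduction protocol, in order, all statistics fitted on the training
split only and reused verbatim on validation/test:

1. z-score each feature with the training mean and SD (n−1 convention;
   zero-SD columns are dropped everywhere with a warning);
2. rebalance the training split — and only the training split — with
   adaptive synthetic oversampling (ADASYN: density-weighted per-sample
   allocation, linear interpolation toward minority-class neighbors);
3. keep image features that differ between classes by a two-sided
   Mann-Whitney U test at a grid-searched p threshold;
4. prune correlated groups (Spearman |rho| >= a grid-searched threshold),
   keeping per group the member with the smallest Mann-Whitney p;
5. optionally project onto the leading principal components (basis fitted
   on training only).

Steps 3-5 see only image-derived (CR or DLB) features; the clinical block
is appended unreduced afterwards.  The hyperparameter grid is the published
one: p in {0.001, 0.005, 0.01, 0.05}, rho in {0.75, 0.80, 0.85, 0.90,
0.95}, PCA components in {none, 20, 40, 60, 80, 100}, selected by mean
validation accuracy over repeated modeling seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "P_GRID",
    "RHO_GRID",
    "PCA_GRID",
    "ReductionParams",
    "ReductionGrid",
    "ReductionState",
    "fit_apply_zscore",
    "rebalance_adasyn",
    "mannwhitney_p",
    "mannwhitney_filter",
    "correlation_prune",
    "pca_reduce",
    "run_reduction",
    "select_reduction_params",
]

P_GRID = (0.001, 0.005, 0.01, 0.05)
RHO_GRID = (0.75, 0.80, 0.85, 0.90, 0.95)
PCA_GRID = (None, 20, 40, 60, 80, 100)


@dataclass(frozen=True)
class ReductionParams:
    p_threshold: float = 0.05
    rho_threshold: float = 0.95
    pca_components: int | None = None

    def __post_init__(self) -> None:
        if self.p_threshold not in P_GRID:
            raise ValueError(f"p_threshold must be one of {P_GRID}")
        if self.rho_threshold not in RHO_GRID:
            raise ValueError(f"rho_threshold must be one of {RHO_GRID}")
        if self.pca_components not in PCA_GRID:
            raise ValueError(f"pca_components must be one of {PCA_GRID}")


@dataclass(frozen=True)
class ReductionGrid:
    p_values: tuple = P_GRID
    rho_values: tuple = RHO_GRID
    pca_values: tuple = PCA_GRID

    def cells(self) -> list[ReductionParams]:
        return [
            ReductionParams(p, r, k)
            for p, r, k in product(self.p_values, self.rho_values, self.pca_values)
        ]


@dataclass
class ReductionState:
    """Frozen training-set statistics needed to transform new data."""

    means: pd.Series
    stds: pd.Series
    dropped_columns: list[str]
    mw_pvalues: pd.Series | None = None
    retained_features: list[str] | None = None
    pca: PCA | None = None
    params: ReductionParams | None = None
    fitted_on_training: bool = True


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

def fit_apply_zscore(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[list[pd.DataFrame], ReductionState]:
    """Standardize with training mean/SD; apply the same affine map everywhere.

    Zero-SD (constant) training columns carry no information and are dropped
    from every table with a warning.
    """
    if train.empty:
        raise ValueError("empty training table")
    means = train.mean(axis=0)
    stds = train.std(axis=0, ddof=1)
    dropped = list(stds.index[(stds == 0) | stds.isna()])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance training columns",
                      stacklevel=2)
    keep = [c for c in train.columns if c not in set(dropped)]
    state = ReductionState(means=means[keep], stds=stds[keep], dropped_columns=dropped)
    out = [(t[keep] - state.means) / state.stds for t in (train, *others)]
    return out, state


# ---------------------------------------------------------------------------
# ADASYN
# ---------------------------------------------------------------------------

def rebalance_adasyn(
    train: pd.DataFrame,
    labels: pd.Series,
    seed: int,
    k: int = 5,
    beta: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Adaptive synthetic oversampling of the minority class.

    The synthesis budget is ``G = (n_maj - n_min) * beta``, allocated across
    minority samples proportionally to the fraction of majority neighbors
    among their ``k`` nearest neighbors in the full training set (harder
    samples get more synthetics).  Each synthetic point lies on the segment
    between a minority sample and one of its ``k`` nearest minority-class
    neighbors.  Original rows are returned unchanged, first.
    """
    y = labels.astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("ADASYN needs exactly two classes in the training labels")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    G = int(round((n_maj - n_min) * beta))
    if G <= 0:
        return train.copy(), labels.copy()
    if n_min < k + 1:
        raise ValueError(f"minority class needs >= {k + 1} samples for k={k}")

    rng = np.random.default_rng(seed)
    X = train.to_numpy(dtype=np.float64)
    X_min = X[y.to_numpy() == minority]

    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx_all = nn_all.kneighbors(X_min)
    is_maj = (y.to_numpy() != minority)[idx_all[:, 1:]]  # drop self
    r = is_maj.mean(axis=1)
    if r.sum() == 0:
        r = np.ones_like(r)  # minority nowhere near majority: uniform allocation
    r_hat = r / r.sum()
    g = np.floor(r_hat * G).astype(int)
    # distribute the flooring remainder to the hardest samples
    short = G - g.sum()
    if short > 0:
        order = np.argsort(-(r_hat * G - g))
        g[order[:short]] += 1

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(X_min))).fit(X_min)
    _, idx_min = nn_min.kneighbors(X_min)

    synth = []
    for i, gi in enumerate(g):
        nbrs = idx_min[i, 1:]
        for _ in range(gi):
            z = int(rng.choice(nbrs))
            lam = rng.random()
            synth.append(X_min[i] + lam * (X_min[z] - X_min[i]))
    synth_df = pd.DataFrame(
        np.asarray(synth), columns=train.columns,
        index=[f"synth-{j:04d}" for j in range(len(synth))],
    )
    aug = pd.concat([train, synth_df])
    aug_labels = pd.concat([
        labels,
        pd.Series([minority] * len(synth_df), index=synth_df.index, dtype=labels.dtype),
    ])
    return aug, aug_labels


# ---------------------------------------------------------------------------
# Mann-Whitney filter
# ---------------------------------------------------------------------------

def mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both groups have < 8 samples and the
    pooled values are tie-free; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(x), len(y)) < 8 and tie_free) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def mannwhitney_filter(
    table: pd.DataFrame,
    labels: pd.Series,
    p_threshold: float,
) -> tuple[list[str], pd.Series]:
    """Features whose distributions differ between classes at p < threshold.

    Returns ``(retained_names, pvalues_for_all_columns)``.  An empty result
    is allowed (and logged by the caller).
    """
    y = labels.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pvals = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=np.float64)
        pvals[col] = mannwhitney_p(v[y == 1], v[y == 0])
    pser = pd.Series(pvals)
    retained = list(pser.index[pser < p_threshold])
    return retained, pser


# ---------------------------------------------------------------------------
# Spearman pruning
# ---------------------------------------------------------------------------

def correlation_prune(
    table: pd.DataFrame,
    rho_threshold: float,
    priority: pd.Series | None = None,
) -> list[str]:
    """Greedy decorrelation: keep one representative per correlated group.

    Candidates are visited in ascending ``priority`` (Mann-Whitney p; column
    order if absent) and kept unless |Spearman rho| with an already-kept
    feature reaches the threshold — so each correlated group is represented
    by its most class-informative member.
    """
    cols = list(table.columns)
    if not cols:
        return []
    if len(cols) == 1:
        return cols
    rho = sps.spearmanr(table.to_numpy(dtype=np.float64)).statistic
    rho = np.atleast_2d(np.abs(np.nan_to_num(rho, nan=0.0)))
    order = (
        list(priority.loc[cols].sort_values(kind="stable").index)
        if priority is not None
        else cols
    )
    col_pos = {c: i for i, c in enumerate(cols)}
    kept: list[str] = []
    for c in order:
        i = col_pos[c]
        if all(rho[i, col_pos[kc]] < rho_threshold for kc in kept):
            kept.append(c)
    return [c for c in cols if c in set(kept)]  # restore column order


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_reduce(
    train: pd.DataFrame,
    others: list[pd.DataFrame],
    k: int,
) -> tuple[list[pd.DataFrame], PCA]:
    """Project onto the top-k principal components of the training table."""
    if k > min(len(train) - 1, train.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(n_train-1={len(train) - 1}, "
            f"n_features={train.shape[1]})"
        )
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(train.to_numpy(dtype=np.float64))
    names = [f"PC{i + 1:03d}" for i in range(k)]
    out = [
        pd.DataFrame(pca.transform(t.to_numpy(dtype=np.float64)),
                     index=t.index, columns=names)
        for t in (train, *others)
    ]
    return out, pca


# ---------------------------------------------------------------------------
# full reduction pass
# ---------------------------------------------------------------------------

def run_reduction(
    train: pd.DataFrame,
    train_labels: pd.Series,
    val: pd.DataFrame,
    test: pd.DataFrame,
    params: ReductionParams,
    seed: int,
    clinical_columns: list[str] | None = None,
    filter_on_rebalanced: bool = True,
    adasyn_k: int = 5,
) -> dict:
    """Run the full ordered reduction on one feature arm.

    Returns a dict with the reduced tables (clinical block appended
    unreduced): ``train`` (rebalanced) / ``train_labels`` / ``train_orig`` /
    ``val`` / ``test`` / ``state``.
    """
    clinical_columns = clinical_columns or []
    image_cols = [c for c in train.columns if c not in set(clinical_columns)]

    (z_train, z_val, z_test), state = fit_apply_zscore(train, val, test)
    image_cols = [c for c in image_cols if c in z_train.columns]
    clin_cols = [c for c in clinical_columns if c in z_train.columns]

    # shrink the neighbor count when the minority class is very small so the
    # pipeline still runs on tiny training splits; below 2 minority samples
    # no interpolation is possible and rebalancing is skipped with a warning
    n_min = int(train_labels.value_counts().min())
    k_eff = min(adasyn_k, n_min - 1)
    if k_eff >= 1:
        bal_train, bal_labels = rebalance_adasyn(z_train, train_labels,
                                                 seed=seed, k=k_eff)
    else:
        warnings.warn("minority class too small to rebalance; skipping ADASYN",
                      stacklevel=2)
        bal_train, bal_labels = z_train, train_labels

    filt_table = bal_train if filter_on_rebalanced else z_train
    filt_labels = bal_labels if filter_on_rebalanced else train_labels
    retained, pvals = mannwhitney_filter(filt_table[image_cols], filt_labels,
                                         params.p_threshold)
    if retained:
        retained = correlation_prune(filt_table[retained], params.rho_threshold,
                                     priority=pvals[retained])

    state.mw_pvalues = pvals
    state.retained_features = list(retained)
    state.params = params

    tables = {
        "train": bal_train, "train_orig": z_train, "val": z_val, "test": z_test,
    }
    if params.pca_components is not None and retained:
        k = min(params.pca_components, len(retained))
        if k > min(len(filt_table) - 1, len(retained)):
            k = min(len(filt_table) - 1, len(retained))
        keys = list(tables)
        (pc_first, *pc_rest), pca = pca_reduce(
            tables[keys[0]][retained], [tables[kk][retained] for kk in keys[1:]], k
        )
        pcs = dict(zip(keys, [pc_first, *pc_rest]))
        state.pca = pca
        reduced = {kk: pd.concat([pcs[kk], tables[kk][clin_cols]], axis=1)
                   for kk in keys}
    else:
        reduced = {kk: tables[kk][retained + clin_cols] for kk in tables}

    return {
        "train": reduced["train"],
        "train_labels": bal_labels,
        "train_orig": reduced["train_orig"],
        "train_orig_labels": train_labels,
        "val": reduced["val"],
        "test": reduced["test"],
        "state": state,
    }


def select_reduction_params(
    grid: ReductionGrid,
    train: pd.DataFrame,
    train_labels: pd.Series,
    val: pd.DataFrame,
    val_labels: pd.Series,
    n_seeds: int = 100,
    clinical_columns: list[str] | None = None,
    model_config=None,
) -> tuple[ReductionParams, pd.DataFrame]:
    """Grid-search the reduction hyperparameters.

    For every grid cell the reduction plus LASSO/logistic protocol is run
    for ``n_seeds`` modeling seeds and the cell with the highest mean
    validation accuracy wins (ties: first cell in grid order).  Returns the
    winning cell and the per-cell score table.
    """
    from . import modeling  # local import: modeling depends on this module

    cfg = model_config or modeling.ModelConfig(n_seeds=n_seeds)
    dummy_test = val.iloc[:0]
    rows = []
    failures = []
    for cell in grid.cells():
        try:
            red = run_reduction(train, train_labels, val, dummy_test, cell,
                                seed=0, clinical_columns=clinical_columns)
            accs = []
            for seed in range(1, n_seeds + 1):
                fit = modeling.fit_single_seed(
                    red["train"], red["train_labels"], cfg, seed
                )
                scores = modeling.predict_scores(red["val"], fit)
                accs.append(float(np.mean(
                    (scores >= fit.threshold).astype(int) == val_labels.to_numpy()
                )))
            rows.append({
                "p_threshold": cell.p_threshold,
                "rho_threshold": cell.rho_threshold,
                "pca_components": cell.pca_components,
                "mean_val_accuracy": float(np.mean(accs)),
            })
        except ValueError as exc:
            failures.append((cell, str(exc)))
    if not rows:
        raise ValueError(f"every grid cell failed; diagnostics: {failures}")
    scores_df = pd.DataFrame(rows)
    best = scores_df.iloc[int(scores_df["mean_val_accuracy"].to_numpy().argmax())]
    winner = ReductionParams(
        float(best["p_threshold"]), float(best["rho_threshold"]),
        None if pd.isna(best["pca_components"]) else int(best["pca_components"]),
    )
    return winner, scores_df
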