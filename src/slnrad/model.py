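"""Model / Results objects tying reduction and modeling together.

:class:`SLNPredictionModel` is built from a subject-by-feature table with
train/validation/test row assignments; :meth:`SLNPredictionModel.fit` runs
the full protocol — train-anchored z-scoring, ADASYN rebalancing, the
Mann-Whitney/Spearman/PCA reduction, the repeated-seed LASSO + logistic +
Youden-threshold cycle — and returns an :class:`SLNPredictionResults`
carrying the winning model's coefficients, frozen threshold, per-split
performance and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modeling, reduction
from .features import build_feature_table, clinical_columns_of
from .modeling import ModelConfig, PerformanceReport
from .phantom import DCEStudy, PhantomConfig, split_cohort
from .reduction import ReductionGrid, ReductionParams

__all__ = ["SLNPredictionModel", "SLNPredictionResults"]


class SLNPredictionModel:
    """Sentinel-lymph-node metastasis prediction from one feature arm.

    Parameters
    ----------
    features : DataFrame
        Subjects x named features (image arm plus ``clinical:`` block).
    labels : Series
        Binary SLN status aligned with ``features``.
    splits : dict
        ``{"train": [...], "validation": [...], "testing": [...]}`` row
        labels; disjoint, exhaustive over the index.
    reduction_params : ReductionParams, optional
        Fixed reduction hyperparameters (default: the p=0.05 / rho=0.95 /
        no-PCA cell).  Use :meth:`search_reduction_params` to grid-search.
    config : ModelConfig, optional
        CV folds, feature cap, number of protocol seeds.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: pd.Series,
        splits: dict[str, list],
        reduction_params: ReductionParams | None = None,
        config: ModelConfig | None = None,
        arm: str = "CR",
    ):
        self.features = features
        self.labels = labels.loc[features.index]
        ids = [i for part in splits.values() for i in part]
        if sorted(ids) != sorted(features.index):
            raise ValueError("splits must partition the feature-table index")
        self.splits = splits
        self.reduction_params = reduction_params or ReductionParams()
        self.config = config or ModelConfig()
        self.arm = arm
        self.clinical_columns = clinical_columns_of(features)

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_cohort(
        cls,
        studies: list[DCEStudy],
        phantom_config: PhantomConfig,
        arm: str = "CR",
        analysis: str = "intra_peri",
        backbone=None,
        catalog=None,
        **kwargs,
    ) -> "SLNPredictionModel":
        """Extract features from a phantom cohort and split it."""
        table, labels = build_feature_table(studies, arm, analysis,
                                            catalog=catalog, backbone=backbone)
        train, val, test = split_cohort(studies, phantom_config)
        splits = {
            "train": [s.subject_id for s in train],
            "validation": [s.subject_id for s in val],
            "testing": [s.subject_id for s in test],
        }
        return cls(table, labels, splits, arm=arm, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        label_column: str = "label",
        split_column: str = "split",
        **kwargs,
    ) -> "SLNPredictionModel":
        """Build from one flat table with label and split columns."""
        labels = table[label_column]
        splits = {
            name: list(table.index[table[split_column] == key])
            for name, key in (("train", "train"), ("validation", "validation"),
                              ("testing", "testing"))
        }
        feats = table.drop(columns=[label_column, split_column])
        return cls(feats, labels, splits, **kwargs)

    # -- split views ---------------------------------------------------------
    def _part(self, name: str) -> tuple[pd.DataFrame, pd.Series]:
        idx = self.splits[name]
        return self.features.loc[idx], self.labels.loc[idx]

    # -- hyperparameter search ----------------------------------------------
    def search_reduction_params(
        self, grid: ReductionGrid | None = None, n_seeds: int = 100,
    ) -> tuple[ReductionParams, pd.DataFrame]:
        """Grid-search reduction hyperparameters by mean validation accuracy
        and adopt the winner."""
        tr, ytr = self._part("train")
        va, yva = self._part("validation")
        winner, scores = reduction.select_reduction_params(
            grid or ReductionGrid(), tr, ytr, va, yva, n_seeds=n_seeds,
            clinical_columns=self.clinical_columns, model_config=self.config,
        )
        self.reduction_params = winner
        return winner, scores

    # -- fitting -------------------------------------------------------------
    def fit(self, seed: int = 0) -> "SLNPredictionResults":
        """Run reduction and the repeated-seed protocol; return results.

        ``seed`` drives the ADASYN sampler; the protocol's internal LASSO
        seeds run 1..n_seeds as configured.
        """
        tr, ytr = self._part("train")
        va, yva = self._part("validation")
        te, yte = self._part("testing")
        red = reduction.run_reduction(
            tr, ytr, va, te, self.reduction_params, seed=seed,
            clinical_columns=self.clinical_columns,
        )
        pipeline, reports = modeling.run_seed_protocol(
            red["train"], red["train_labels"],
            red["train_orig"], red["train_orig_labels"],
            red["val"], yva, red["test"], yte, self.config,
        )
        return SLNPredictionResults(
            model=self, pipeline=pipeline, reduction_state=red["state"],
            reports=reports, fit_seed=seed,
        )


@dataclass
class SLNPredictionResults:
    """Fitted pipeline, per-split performance and diagnostics."""

    model: SLNPredictionModel
    pipeline: modeling.FittedPipeline
    reduction_state: reduction.ReductionState
    reports: dict[str, PerformanceReport]
    fit_seed: int = 0

    # -- accessors -----------------------------------------------------------
    @property
    def selected_features(self) -> list[str]:
        return self.pipeline.selected_features

    @property
    def threshold(self) -> float:
        return self.pipeline.threshold

    @property
    def params(self) -> pd.Series:
        """Logistic coefficients including the intercept."""
        out = pd.Series({"(intercept)": self.pipeline.intercept})
        return pd.concat([out, self.pipeline.coefficients])

    def metrics(self, split: str) -> PerformanceReport:
        return self.reports[split]

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.as_dict() for k, v in self.reports.items()}).T

    # -- prediction ----------------------------------------------------------
    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Scores for new subjects on the original feature scale.

        Applies the frozen training z-score (and PCA basis if used) before
        the logistic model.
        """
        st = self.reduction_state
        z = (features[st.means.index] - st.means) / st.stds
        if st.pca is not None:
            pcs = st.pca.transform(z[st.retained_features].to_numpy())
            cols = [f"PC{i + 1:03d}" for i in range(pcs.shape[1])]
            z = pd.concat(
                [pd.DataFrame(pcs, index=z.index, columns=cols),
                 z[self.model.clinical_columns]], axis=1,
            )
        scores = modeling.predict_scores(z, self.pipeline)
        return pd.Series(scores, index=features.index, name="score")

    def predict_label(self, features: pd.DataFrame) -> pd.Series:
        return (self.predict(features) >= self.threshold).astype(int)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        p = self.model.reduction_params
        lines = [
            "SLN metastasis prediction — repeated-seed LASSO/logistic pipeline",
            "=" * 68,
            f"arm: {self.model.arm}    winning seed: {self.pipeline.seed} "
            f"of {self.model.config.n_seeds}",
            f"reduction: p<{p.p_threshold}, |rho|<{p.rho_threshold}, "
            f"PCA={p.pca_components or 'none'}",
            f"decision threshold (Youden, training): {self.threshold:.4f}",
            "",
            "selected features and logistic coefficients:",
        ]
        for name, val in self.params.items():
            lines.append(f"  {name:<48s} {val:+10.4f}")
        lines += ["", "performance (rows: splits):",
                  self.metrics_frame().round(3).to_string()]
        return "\n".join(lines)

    def plot_roc(self, split: str = "validation", ax=None):
        """ROC curve of one split (matplotlib axes returned)."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        idx = self.model.splits[split]
        scores = self.predict(self.model.features.loc[idx])
        y = self.model.labels.loc[idx].to_numpy()
        fpr, tpr, _ = roc_curve(y, scores)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"{split} (AUC={self.reports[split].auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
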