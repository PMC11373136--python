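"""Top-level modelling interface: build from data, fit, inspect results.

:class:`HepatotoxicityClassifier` wraps the full pipeline — curation,
featurization, scaling, sequential feature selection, heterogeneous
ensemble — behind a statsmodels-style surface: construct the model from
data (or a compound DataFrame via :meth:`from_dataframe`), call
:meth:`fit`, and read estimates and diagnostics off the returned
:class:`HepatotoxicityResults`, whose :meth:`~HepatotoxicityResults.summary`
prints a member-by-metric table.

>>> model = HepatotoxicityClassifier.from_dataframe(df, seed=0)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation
from .base_models import ModelConfig
from .dataset import CuratedDataset, curate_dataset
from .ensembles import (
    EnsembleConfig,
    FittedEnsemble,
    named_ensemble_members,
    train_ensemble,
)
from .errors import SchemaError
from .evaluation import CVReport, MetricsReport, evaluate_predictions, metrics_frame
from .featurization import (
    FeatureMatrix,
    ScalerState,
    apply_minmax,
    clean_feature_matrix,
    compute_descriptors,
    compute_morgan_fingerprints,
    fit_minmax,
)
from .feature_selection import (
    EliminationTrace,
    rank_features,
    select_optimal_subset,
    sequential_elimination,
)


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the sequential feature-selection stage."""

    enabled: bool = True
    ranker: str = "embedded_forest"
    step_size: int | None = None  # None -> 5% of features
    evaluator: ModelConfig | None = None  # None -> 100-tree random forest


class EnsemblePipeline:
    """Fit-time pipeline: clean -> scale -> select -> ensemble.

    Everything (scaler, ranking, subset, members) is refitted on whatever
    training rows ``fit`` receives, so the same object factory drives
    holdout fits, repeated holdouts and cross-validation without leakage.
    """

    def __init__(
        self,
        ensemble_config: EnsembleConfig,
        selection: SelectionConfig | None = None,
        scale: bool | None = None,
        seed: int = 0,
    ):
        self.ensemble_config = ensemble_config
        self.selection = selection or SelectionConfig(enabled=False)
        self.scale = scale
        self.seed = seed
        self.scaler_: ScalerState | None = None
        self.selected_features_: list[str] | None = None
        self.trace_: EliminationTrace | None = None
        self.ensemble_: FittedEnsemble | None = None

    def fit(self, X: FeatureMatrix, y) -> "EnsemblePipeline":
        if not isinstance(X, FeatureMatrix):
            raise SchemaError("EnsemblePipeline requires a FeatureMatrix")
        X = clean_feature_matrix(X)
        scale = self.scale
        if scale is None:  # bits are already in [0, 1]
            scale = X.kind != "circular_fingerprints"
        if scale:
            self.scaler_ = fit_minmax(X)
            X = apply_minmax(self.scaler_, X)
        if self.selection.enabled:
            ranking = rank_features(X, y, ranker=self.selection.ranker, seed=self.seed)
            self.trace_ = sequential_elimination(
                X,
                y,
                ranking,
                step_size=self.selection.step_size,
                evaluator=self.selection.evaluator,
                seed=self.seed,
            )
            subset = select_optimal_subset(self.trace_)
            # keep ranking order for a deterministic column layout
            self.selected_features_ = [n for n in ranking.names if n in subset]
            X = X.select(self.selected_features_)
        else:
            self.selected_features_ = list(X.feature_names)
        self.ensemble_ = train_ensemble(self.ensemble_config, X, y)
        return self

    def _transform(self, X: FeatureMatrix) -> FeatureMatrix:
        if self.ensemble_ is None:
            raise RuntimeError("pipeline is not fitted")
        if self.scaler_ is not None:
            X = X.select(self.scaler_.feature_names)
            X = apply_minmax(self.scaler_, X)
        return X.select(self.selected_features_)

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        return self.ensemble_.predict_proba(self._transform(X))

    def predict_label(self, X: FeatureMatrix, threshold: float = 0.5) -> np.ndarray:
        return self.ensemble_.predict_label(self._transform(X), threshold)


class HepatotoxicityClassifier:
    """Hepatotoxicity ensemble model bound to a featurized dataset.

    Parameters
    ----------
    X : FeatureMatrix
        Compound features (any of the three representation kinds).
    y : array-like of {0, 1}
        1 = hepatotoxic, 0 = non-hepatotoxic.
    ensemble_config : EnsembleConfig, optional
        Defaults to the five-member soft-voting line-up (knn, svc, rf, et,
        rnn) — the configuration that pairs with circular fingerprints.
    selection : SelectionConfig, optional
        Sequential feature selection settings; disabled by default.
    dataset : CuratedDataset, optional
        Kept for provenance when built via :meth:`from_dataframe`.
    """

    def __init__(
        self,
        X: FeatureMatrix,
        y,
        ensemble_config: EnsembleConfig | None = None,
        selection: SelectionConfig | None = None,
        scale: bool | None = None,
        dataset: CuratedDataset | None = None,
        seed: int = 0,
    ):
        self.X = X
        self.y = np.asarray(y, dtype=int).ravel()
        if self.X.n_samples != self.y.shape[0]:
            raise SchemaError("X rows and y length differ")
        self.seed = seed
        self.ensemble_config = ensemble_config or EnsembleConfig(
            "voting", named_ensemble_members("IV", seed=seed), seed=seed
        )
        self.selection = selection or SelectionConfig(enabled=False)
        self.scale = scale
        self.dataset = dataset

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        smiles_col: str = "smiles",
        label_col: str = "label",
        feature_kind: str = "circular_fingerprints",
        radius: int = 2,
        n_bits: int = 2048,
        **kwargs,
    ) -> "HepatotoxicityClassifier":
        """Curate a raw compound table and featurize it in one step."""
        renamed = df.rename(columns={smiles_col: "smiles", label_col: "label"})
        if "source_id" not in renamed:
            renamed["source_id"] = ""
        dataset = curate_dataset(renamed[["smiles", "label", "source_id"]])
        if feature_kind == "circular_fingerprints":
            X = compute_morgan_fingerprints(dataset, radius=radius, n_bits=n_bits)
        else:
            X = compute_descriptors(dataset, kind=feature_kind)
        return cls(X, np.asarray(dataset.labels), dataset=dataset, **kwargs)

    def _pipeline(self, seed: int) -> EnsemblePipeline:
        cfg = self.ensemble_config
        members = tuple(ModelConfig(m.algorithm, m.hyperparameters, seed=seed) for m in cfg.members)
        reseeded = EnsembleConfig(
            strategy=cfg.strategy,
            members=members,
            voting_mode=cfg.voting_mode,
            n_bootstrap=cfg.n_bootstrap,
            resample=cfg.resample,
            meta=cfg.meta,
            k_oof=cfg.k_oof,
            seed=seed,
        )
        return EnsemblePipeline(reseeded, selection=self.selection, scale=self.scale, seed=seed)

    def fit(self, test_fraction: float = 0.2, seed: int | None = None) -> "HepatotoxicityResults":
        """Stratified holdout fit: train the pipeline, evaluate on the rest."""
        seed = self.seed if seed is None else seed
        labels = [int(v) for v in self.y]
        from sklearn.model_selection import train_test_split

        tr, te = train_test_split(
            np.arange(len(labels)),
            test_size=test_fraction,
            random_state=seed,
            stratify=labels,
        )
        pipe = self._pipeline(seed)
        pipe.fit(self.X.take_rows(tr), self.y[tr])
        scores = pipe.predict_proba(self.X.take_rows(te))
        report = evaluate_predictions(self.y[te], scores)
        from .base_models import predict_proba as _member_proba

        Xt = pipe._transform(self.X.take_rows(te))
        member_reports = {
            m.config.algorithm: evaluate_predictions(self.y[te], _member_proba(m, Xt))
            for m in pipe.ensemble_.members
        }
        return HepatotoxicityResults(
            model=self,
            pipeline=pipe,
            train_idx=np.sort(tr),
            test_idx=np.sort(te),
            report=report,
            member_reports=member_reports,
            test_scores=scores,
            seed=seed,
        )

    def cross_validate(self, k: int = 10, seed: int | None = None) -> CVReport:
        """Stratified k-fold CV re-running the entire pipeline per fold."""
        seed = self.seed if seed is None else seed
        return evaluation.kfold_cross_validate(self._pipeline, self.X, self.y, k=k, seed=seed)

    def repeated_holdout(self, n_repeats: int = 5, seeds=None, test_fraction: float = 0.2):
        """Mean +/- SD metrics over fresh seeded 80/20 holdouts."""
        return evaluation.repeated_holdout_summary(
            self._pipeline, self.X, self.y, n_repeats=n_repeats, seeds=seeds,
            test_fraction=test_fraction,
        )


@dataclass
class HepatotoxicityResults:
    """Holdout-fit results: the fitted pipeline plus evaluation reports."""

    model: HepatotoxicityClassifier
    pipeline: EnsemblePipeline
    train_idx: np.ndarray
    test_idx: np.ndarray
    report: MetricsReport
    member_reports: dict[str, MetricsReport]
    test_scores: np.ndarray
    seed: int

    @property
    def selected_features(self) -> list[str]:
        return list(self.pipeline.selected_features_)

    @property
    def ensemble(self) -> FittedEnsemble:
        return self.pipeline.ensemble_

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        return self.pipeline.predict_proba(X)

    def metrics_table(self) -> pd.DataFrame:
        named = dict(self.member_reports)
        named["ensemble"] = self.report
        return metrics_frame(named)

    def roc_frame(self) -> pd.DataFrame:
        return evaluation.roc_points(self.model.y[self.test_idx], self.test_scores)

    def summary(self) -> str:
        cfg = self.model.ensemble_config
        lines = [
            "Hepatotoxicity ensemble classifier",
            "=" * 70,
            f"strategy: {cfg.strategy} ({cfg.voting_mode} vote)"
            if cfg.strategy == "voting"
            else f"strategy: {cfg.strategy}",
            f"members:  {', '.join(m.algorithm for m in cfg.members)}",
            f"features: {self.model.X.kind} "
            f"({len(self.selected_features)}/{self.model.X.n_features} retained)",
            f"samples:  {len(self.train_idx)} train / {len(self.test_idx)} test "
            f"(seed {self.seed})",
            "-" * 70,
            self.metrics_table().round(4).to_string(),
            "=" * 70,
        ]
        return "\n".join(lines)
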