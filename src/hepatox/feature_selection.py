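"""Feature ranking and sequential elimination scored by AUC contribution.

The search ranks features once (by default with impurity importances of a
seeded random forest — the "embedded" route; a univariate-AUC ranker is the
tractable alternative to refitting one model per left-out feature), then
repeatedly removes the lowest-ranked block of features and rescores a fixed
evaluator on an internal stratified validation split of the *training* rows
only. Each removal step is scored by its relative AUC contribution

    contribution = (AUC_w - AUC_i) / AUC_w

where AUC_w is the all-features baseline and AUC_i the AUC without the
removed block: positive means the removed content was informative. The
optimal subset is the step (baseline included) with maximal AUC, ties
broken toward fewer features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .base_models import ModelConfig, build_and_fit, predict_proba
from .errors import DegenerateLabels, DomainError, SchemaError
from .featurization import FeatureMatrix

RANKERS = ("embedded_forest", "univariate_auc")

#: AUC assigned to a model with no features left (chance).
EMPTY_FEATURE_AUC = 0.5


@dataclass
class FeatureRanking:
    """Features ordered most-to-least important with their scores."""

    names: list[str]
    scores: list[float]
    ranker_id: str

    def __post_init__(self):
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked names must be unique")
        if not all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class EliminationStep:
    """One recorded state of the elimination search."""

    n_retained: int
    features: frozenset[str]
    auc: float
    contribution: float


@dataclass
class EliminationTrace:
    """AUC trajectory of sequential removal, baseline first."""

    steps: list[EliminationStep]
    auc_w: float
    step_size: int
    baseline_features: frozenset[str]

    def to_records(self) -> list[dict]:
        rows = [
            {
                "step": 0,
                "n_retained": len(self.baseline_features),
                "auc": self.auc_w,
                "contribution": 0.0,
            }
        ]
        for k, s in enumerate(self.steps, 1):
            rows.append(
                {"step": k, "n_retained": s.n_retained, "auc": s.auc, "contribution": s.contribution}
            )
        return rows


def contribution_score(auc_w: float, auc_i: float) -> float:
    """Relative AUC contribution of removed content: (AUC_w - AUC_i)/AUC_w.

    Positive when removal hurt (the removed features were informative),
    negative when removal helped.

    Raises
    ------
    DomainError
        If ``auc_w`` is not strictly positive.
    """
    if auc_w <= 0:
        raise DomainError("auc_w must be strictly positive")
    return (auc_w - auc_i) / auc_w


def rank_features(
    X_train: FeatureMatrix,
    y,
    ranker: str = "embedded_forest",
    seed: int = 0,
) -> FeatureRanking:
    """Rank all features most-to-least important.

    ``embedded_forest`` uses impurity-based importances of a seeded random
    forest; ``univariate_auc`` scores each feature by |per-feature AUC - 0.5|.
    Ties break lexicographically by feature name, so all-constant inputs
    yield a deterministic alphabetical order.

    Raises
    ------
    DegenerateLabels
        If ``y`` contains a single class.
    """
    if ranker not in RANKERS:
        raise ValueError(f"unknown ranker {ranker!r}")
    ya = np.asarray(y, dtype=int).ravel()
    if X_train.n_samples != ya.shape[0]:
        raise SchemaError("X_train rows and y length differ")
    if len(np.unique(ya)) < 2:
        raise DegenerateLabels("ranking requires both classes")

    if ranker == "embedded_forest":
        forest = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        forest.fit(X_train.values, ya)
        scores = forest.feature_importances_
    else:
        pos = X_train.values[ya == 1]
        neg = X_train.values[ya == 0]
        # per-column rank AUC via the Mann-Whitney identity, ties counted 1/2
        scores = np.empty(X_train.n_features)
        for j in range(X_train.n_features):
            col = X_train.values[:, j]
            if np.ptp(col) == 0:
                scores[j] = 0.0
                continue
            auc = roc_auc_score(ya, col)
            scores[j] = abs(auc - 0.5)

    order = sorted(range(len(scores)), key=lambda j: (-scores[j], X_train.feature_names[j]))
    return FeatureRanking(
        names=[X_train.feature_names[j] for j in order],
        scores=[float(scores[j]) for j in order],
        ranker_id=ranker,
    )


def _evaluator_auc(
    evaluator: ModelConfig,
    X_tr: FeatureMatrix,
    y_tr,
    X_va: FeatureMatrix,
    y_va,
) -> float:
    model = build_and_fit(evaluator, X_tr, y_tr)
    return float(roc_auc_score(y_va, predict_proba(model, X_va)))


def sequential_elimination(
    X_train: FeatureMatrix,
    y,
    ranking: FeatureRanking,
    step_size: int | None = None,
    evaluator: ModelConfig | None = None,
    seed: int = 0,
) -> EliminationTrace:
    """Remove the lowest-ranked ``step_size`` features per step, rescoring.

    Step AUCs come from refitting ``evaluator`` on a fixed internal
    stratified 80/20 split of the training rows (the held-out test set is
    never touched). Default step size is 5% of the features (minimum 1);
    default evaluator is a 100-tree random forest. The search stops once
    ``step_size`` or fewer features remain; a step that removes everything
    scores the chance AUC 0.5.
    """
    ya = np.asarray(y, dtype=int).ravel()
    if set(ranking.names) != set(X_train.feature_names):
        raise SchemaError("ranking must cover exactly the matrix's features")
    n_feat = X_train.n_features
    if step_size is None:
        step_size = max(1, int(round(0.05 * n_feat)))
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    if evaluator is None:
        evaluator = ModelConfig("rf", {"n_estimators": 100}, seed=seed)

    tr, va = train_test_split(
        np.arange(len(ya)), test_size=0.2, random_state=seed, stratify=ya
    )
    ordered = X_train.select(ranking.names)  # most -> least important
    X_tr, X_va = ordered.take_rows(tr), ordered.take_rows(va)
    y_tr, y_va = ya[tr], ya[va]

    auc_w = _evaluator_auc(evaluator, X_tr, y_tr, X_va, y_va)
    steps: list[EliminationStep] = []
    retained = list(ranking.names)
    while len(retained) > 0:
        retained = retained[: max(0, len(retained) - step_size)]
        if retained:
            auc_i = _evaluator_auc(
                evaluator, X_tr.select(retained), y_tr, X_va.select(retained), y_va
            )
        else:
            auc_i = EMPTY_FEATURE_AUC
        steps.append(
            EliminationStep(
                n_retained=len(retained),
                features=frozenset(retained),
                auc=auc_i,
                contribution=contribution_score(auc_w, auc_i),
            )
        )
        if len(retained) <= step_size:
            break
    return EliminationTrace(
        steps=steps,
        auc_w=auc_w,
        step_size=step_size,
        baseline_features=frozenset(ranking.names),
    )


def select_optimal_subset(trace: EliminationTrace) -> frozenset[str]:
    """The feature set (baseline included) with maximal AUC.

    Ties break toward fewer features.
    """
    candidates = [(trace.auc_w, len(trace.baseline_features), trace.baseline_features)]
    candidates += [(s.auc, s.n_retained, s.features) for s in trace.steps if s.n_retained > 0]
    best = max(candidates, key=lambda t: (t[0], -t[1]))
    return best[2]
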