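"""Voting, bagging and stacking combiners over heterogeneous base models.

The named ensembles of the study design are expressible through
:func:`named_ensemble_members`:

=========  =====================================  =======================
 name       members                                feature representation
=========  =====================================  =======================
 I          knn, svc, rf, et, rnn                  physchem descriptors
 II         knn, svc, rf, et, rnn                  extended descriptors
 III        knn, svc, rf, et, rnn                  combined descriptors
 IV         knn, svc, rf, et, rnn                  circular fingerprints
 IV(A)      knn, svc, rf, et, mlp                  circular fingerprints
 IV(B)      knn, svc, rf, et, rnn, mlp             circular fingerprints
=========  =====================================  =======================

All members receive equal weight. Soft voting averages member
probabilities; hard voting takes the majority label with exact ties
resolved toward the toxic class (screening favors sensitivity). Bagging
refits every member on bootstrap resamples and soft-votes all
member x replicate streams. Stacking feeds out-of-fold member
probabilities to a logistic meta-learner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .base_models import FittedModel, ModelConfig, build_and_fit, predict_label, predict_proba
from .errors import ConfigError, HepatoxError
from .featurization import FeatureMatrix

STRATEGIES = ("voting", "bagging", "stacking")

#: Base-learner line-ups of the named ensembles (I-III differ only in the
#: feature matrix they are trained on, which the caller supplies).
NAMED_MEMBER_SETS = {
    "I": ("knn", "svc", "rf", "et", "rnn"),
    "II": ("knn", "svc", "rf", "et", "rnn"),
    "III": ("knn", "svc", "rf", "et", "rnn"),
    "IV": ("knn", "svc", "rf", "et", "rnn"),
    "IV(A)": ("knn", "svc", "rf", "et", "mlp"),
    "IV(B)": ("knn", "svc", "rf", "et", "rnn", "mlp"),
}


@dataclass(frozen=True)
class EnsembleConfig:
    """Declarative ensemble spec: strategy, members, combiner settings."""

    strategy: str
    members: tuple[ModelConfig, ...]
    voting_mode: str = "soft"
    n_bootstrap: int = 5
    resample: bool = True  # test hook: False makes bagging degenerate to voting
    meta: str = "logistic"
    k_oof: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if not self.members:
            raise ConfigError("ensemble needs at least one member")
        if self.voting_mode not in ("soft", "hard"):
            raise ConfigError(f"voting_mode must be soft or hard, got {self.voting_mode!r}")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.strategy == "stacking" and self.k_oof < 2:
            raise ConfigError("stacking requires k_oof >= 2")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "members": [m.to_dict() for m in self.members],
            "voting_mode": self.voting_mode,
            "n_bootstrap": self.n_bootstrap,
            "resample": self.resample,
            "meta": self.meta,
            "k_oof": self.k_oof,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleConfig":
        return cls(
            strategy=d["strategy"],
            members=tuple(ModelConfig.from_dict(m) for m in d["members"]),
            voting_mode=d.get("voting_mode", "soft"),
            n_bootstrap=d.get("n_bootstrap", 5),
            resample=d.get("resample", True),
            meta=d.get("meta", "logistic"),
            k_oof=d.get("k_oof", 5),
            seed=d.get("seed", 0),
        )


def named_ensemble_members(name: str, seed: int = 0) -> tuple[ModelConfig, ...]:
    """Default member configs for one of the named ensembles (I..IV(B))."""
    if name not in NAMED_MEMBER_SETS:
        raise ConfigError(f"unknown ensemble name {name!r}; expected one of {list(NAMED_MEMBER_SETS)}")
    return tuple(ModelConfig(alg, seed=seed) for alg in NAMED_MEMBER_SETS[name])


# ------------------------------------------------------------------- combiners
def soft_vote(member_probs: Sequence[float]) -> float:
    """Equal-weight arithmetic mean of member probabilities for one sample."""
    if len(member_probs) == 0:
        raise ConfigError("soft_vote needs at least one member probability")
    arr = np.asarray(member_probs, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(arr.mean())


def hard_vote(member_labels: Sequence[int]) -> int:
    """Majority label over members; an exact tie resolves to 1 (toxic)."""
    if len(member_labels) == 0:
        raise ConfigError("hard_vote needs at least one member label")
    votes_1 = int(np.sum(np.asarray(member_labels) == 1))
    votes_0 = len(member_labels) - votes_1
    return 1 if votes_1 >= votes_0 else 0


# --------------------------------------------------------------- fitted object
@dataclass
class FittedEnsemble:
    """A trained combiner: fitted members plus strategy-specific state."""

    config: EnsembleConfig
    members: list[FittedModel]            # one per config member (voting/stacking)
    replicates: list[list[FittedModel]] = field(default_factory=list)  # bagging
    meta_model: object = None             # stacking
    feature_names: list[str] = field(default_factory=list)

    def member_proba(self, X) -> np.ndarray:
        """(n_samples, n_members) probability streams of the base models."""
        if self.config.strategy == "bagging":
            streams = [predict_proba(m, X) for reps in self.replicates for m in reps]
        else:
            streams = [predict_proba(m, X) for m in self.members]
        return np.column_stack(streams)

    def predict_proba(self, X) -> np.ndarray:
        """Combined probability of the positive class per row."""
        probs = self.member_proba(X)
        if self.config.strategy == "stacking":
            return self.meta_model.predict_proba(probs)[:, 1]
        if self.config.voting_mode == "hard":
            labels = (probs >= 0.5).astype(int)
            return np.array([float(hard_vote(row)) for row in labels])
        return probs.mean(axis=1)

    def predict_label(self, X, threshold: float = 0.5) -> np.ndarray:
        return predict_label(self.predict_proba(X), threshold)


def _fit_members(
    members: Sequence[ModelConfig], X_train, y
) -> list[FittedModel]:
    fitted = []
    for k, cfg in enumerate(members):
        try:
            fitted.append(build_and_fit(cfg, X_train, y))
        except Exception as exc:
            raise HepatoxError(f"member {k} ({cfg.algorithm}) failed to fit: {exc}") from exc
    return fitted


def _feature_names(X_train) -> list[str]:
    if isinstance(X_train, FeatureMatrix):
        return list(X_train.feature_names)
    return [f"f{i}" for i in range(np.asarray(X_train).shape[1])]


def train_voting_ensemble(cfg: EnsembleConfig, X_train, y) -> FittedEnsemble:
    """Fit every member on the full training matrix; combine by voting."""
    if cfg.strategy != "voting":
        raise ConfigError("config strategy must be 'voting'")
    return FittedEnsemble(
        config=cfg,
        members=_fit_members(cfg.members, X_train, y),
        feature_names=_feature_names(X_train),
    )


def train_bagging_ensemble(cfg: EnsembleConfig, X_train, y) -> FittedEnsemble:
    """Fit each member on ``n_bootstrap`` bootstrap resamples; soft-vote all.

    Resamples are drawn with replacement at full training size, seeded from
    ``cfg.seed``. With ``resample=False`` and ``n_bootstrap=1`` the result is
    identical to plain voting (degenerate-case hook used in tests).
    """
    if cfg.strategy != "bagging":
        raise ConfigError("config strategy must be 'bagging'")
    Xa = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, dtype=float)
    ya = np.asarray(y, dtype=int).ravel()
    rng = np.random.default_rng(cfg.seed)
    replicates: list[list[FittedModel]] = []
    for k, mcfg in enumerate(cfg.members):
        reps = []
        for r in range(cfg.n_bootstrap):
            if cfg.resample:
                idx = bootstrap_indices(len(ya), rng)
                # guard: a resample missing a class cannot train a classifier
                while len(np.unique(ya[idx])) < 2:
                    idx = bootstrap_indices(len(ya), rng)
            else:
                idx = np.arange(len(ya))
            Xb = X_train.take_rows(idx) if isinstance(X_train, FeatureMatrix) else Xa[idx]
            try:
                reps.append(build_and_fit(replace_seed(mcfg, mcfg.seed + r), Xb, ya[idx]))
            except Exception as exc:
                raise HepatoxError(f"member {k} ({mcfg.algorithm}) replicate {r} failed: {exc}") from exc
        replicates.append(reps)
    return FittedEnsemble(
        config=cfg,
        members=[reps[0] for reps in replicates],
        replicates=replicates,
        feature_names=_feature_names(X_train),
    )


def bootstrap_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """A with-replacement resample of size n (on average ~63.2% unique rows)."""
    return rng.integers(0, n, size=n)


def replace_seed(cfg: ModelConfig, seed: int) -> ModelConfig:
    return ModelConfig(cfg.algorithm, cfg.hyperparameters, seed=seed)


def train_stacking_ensemble(cfg: EnsembleConfig, X_train, y) -> FittedEnsemble:
    """Out-of-fold stacking with a logistic meta-learner.

    Every training row receives exactly one meta-feature vector, produced by
    members fitted on folds that exclude that row; the meta-learner is fitted
    on these leak-free probabilities, and members are refitted on the full
    training matrix for prediction time.
    """
    if cfg.strategy != "stacking":
        raise ConfigError("config strategy must be 'stacking'")
    Xa = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, dtype=float)
    ya = np.asarray(y, dtype=int).ravel()
    skf = StratifiedKFold(n_splits=cfg.k_oof, shuffle=True, random_state=cfg.seed)
    meta_X = np.full((len(ya), len(cfg.members)), np.nan)
    for tr, va in skf.split(Xa, ya):
        X_tr = X_train.take_rows(tr) if isinstance(X_train, FeatureMatrix) else Xa[tr]
        X_va = X_train.take_rows(va) if isinstance(X_train, FeatureMatrix) else Xa[va]
        for j, mcfg in enumerate(cfg.members):
            fold_model = build_and_fit(mcfg, X_tr, ya[tr])
            meta_X[va, j] = predict_proba(fold_model, X_va)
    assert not np.isnan(meta_X).any(), "every row must receive meta features"
    if cfg.meta != "logistic":
        raise ConfigError(f"unsupported meta-learner {cfg.meta!r}")
    meta = LogisticRegression(max_iter=1000, random_state=cfg.seed)
    meta.fit(meta_X, ya)
    return FittedEnsemble(
        config=cfg,
        members=_fit_members(cfg.members, X_train, ya),
        meta_model=meta,
        feature_names=_feature_names(X_train),
    )


def train_ensemble(cfg: EnsembleConfig, X_train, y) -> FittedEnsemble:
    """Dispatch on strategy."""
    trainer = {
        "voting": train_voting_ensemble,
        "bagging": train_bagging_ensemble,
        "stacking": train_stacking_ensemble,
    }[cfg.strategy]
    return trainer(cfg, X_train, y)


# ------------------------------------------------------------------ persistence
def save_ensemble(ensemble: FittedEnsemble, out_dir: str | Path) -> Path:
    """Persist manifest JSON + per-member directories under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    member_dirs = []
    flat: list[tuple[str, FittedModel]] = []
    if ensemble.config.strategy == "bagging":
        for k, reps in enumerate(ensemble.replicates):
            for r, m in enumerate(reps):
                flat.append((f"member_{k:02d}_{m.config.algorithm}_rep{r}", m))
    else:
        for k, m in enumerate(ensemble.members):
            flat.append((f"member_{k:02d}_{m.config.algorithm}", m))
    for name, model in flat:
        mdir = out / name
        mdir.mkdir(exist_ok=True)
        (mdir / "config.json").write_text(json.dumps(model.config.to_dict(), indent=1))
        (mdir / "feature_names.txt").write_text("\n".join(model.feature_names))
        joblib.dump(model.estimator, mdir / "estimator.joblib")
        if model.training_log:
            (mdir / "training_log.csv").write_text(
                "epoch,loss\n" + "\n".join(f"{i},{v}" for i, v in enumerate(model.training_log, 1))
            )
        member_dirs.append(name)
    if ensemble.meta_model is not None:
        joblib.dump(ensemble.meta_model, out / "meta_model.joblib")
    manifest = {"config": ensemble.config.to_dict(), "member_dirs": member_dirs,
                "feature_names": ensemble.feature_names}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_ensemble(in_dir: str | Path) -> FittedEnsemble:
    """Rebuild a :class:`FittedEnsemble` from :func:`save_ensemble` output."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    cfg = EnsembleConfig.from_dict(manifest["config"])
    models = []
    for name in manifest["member_dirs"]:
        mdir = root / name
        mcfg = ModelConfig.from_dict(json.loads((mdir / "config.json").read_text()))
        names = (mdir / "feature_names.txt").read_text().splitlines()
        est = joblib.load(mdir / "estimator.joblib")
        log_file = mdir / "training_log.csv"
        log = []
        if log_file.exists():
            log = [float(l.split(",")[1]) for l in log_file.read_text().splitlines()[1:]]
        models.append(FittedModel(config=mcfg, feature_names=names, estimator=est, training_log=log))
    if cfg.strategy == "bagging":
        replicates: list[list[FittedModel]] = []
        for k in range(len(cfg.members)):
            replicates.append(models[k * cfg.n_bootstrap : (k + 1) * cfg.n_bootstrap])
        members = [reps[0] for reps in replicates]
        meta = None
    else:
        replicates, members = [], models
        meta = None
    meta_file = root / "meta_model.joblib"
    if meta_file.exists():
        meta = joblib.load(meta_file)
    return FittedEnsemble(
        config=cfg,
        members=members,
        replicates=replicates,
        meta_model=meta,
        feature_names=manifest["feature_names"],
    )
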