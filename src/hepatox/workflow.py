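"""Reproducible end-to-end runs driven by a single validated config file.

A run executes curate -> featurize -> split -> (select) -> fit members ->
fit ensemble -> evaluate and leaves a self-describing run directory:

    resolved_config.yaml   the fully-resolved config actually executed
    curated.csv            surviving compounds (smiles, label, source_id)
    curation_log.csv       excluded rows with reasons
    selected_features.txt  newline-delimited retained feature names
    ensemble/              persisted ensemble (manifest + member dirs)
    metrics.json           ensemble + per-member holdout metrics (+ CV)
    metrics.csv            the same table as CSV
    roc.csv                ROC curve points (fpr, tpr, threshold)
    run.log                stage log with seeds and package versions

All randomness flows from the single ``seed`` field. Re-running the
resolved config reproduces metrics byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .base_models import ALGORITHMS, ModelConfig
from .dataset import curate_dataset, read_compound_table
from .ensembles import EnsembleConfig, save_ensemble
from .errors import ConfigError
from .model import HepatotoxicityClassifier, SelectionConfig
from .synthetic import RuleLabeledSmilesSpec, generate_rule_labeled_smiles

logger = logging.getLogger(__name__)


class InputBlock(BaseModel):
    """Where compounds come from: a table on disk or the SMILES generator."""

    path: Optional[str] = None
    smiles_col: str = "smiles"
    label_col: str = "label"
    synth_smiles: Optional[dict] = None  # RuleLabeledSmilesSpec overrides

    def resolve(self, seed: int) -> pd.DataFrame:
        if (self.path is None) == (self.synth_smiles is None):
            raise ConfigError("input needs exactly one of 'path' or 'synth_smiles'")
        if self.path is not None:
            return read_compound_table(self.path, self.smiles_col, self.label_col)
        spec = RuleLabeledSmilesSpec(**{"seed": seed, **self.synth_smiles})
        return generate_rule_labeled_smiles(spec)


class FeatureBlock(BaseModel):
    kind: Literal["physchem_descriptors", "extended_descriptors", "circular_fingerprints"] = (
        "circular_fingerprints"
    )
    radius: int = Field(2, ge=0)
    n_bits: int = Field(2048, ge=8)
    scale: Optional[bool] = None  # None = auto (descriptors yes, bits no)


class SelectionBlock(BaseModel):
    enabled: bool = False
    ranker: Literal["embedded_forest", "univariate_auc"] = "embedded_forest"
    step_size: Optional[int] = Field(None, ge=1)


class EnsembleBlock(BaseModel):
    strategy: Literal["voting", "bagging", "stacking"] = "voting"
    members: list[str] = ["knn", "svc", "rf", "et", "rnn"]
    voting_mode: Literal["soft", "hard"] = "soft"
    n_bootstrap: int = Field(5, ge=1)
    k_oof: int = Field(5, ge=2)

    @field_validator("members")
    @classmethod
    def _known_algorithms(cls, v):
        unknown = set(v) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown member algorithms: {sorted(unknown)}")
        if not v:
            raise ValueError("members must be non-empty")
        return v


class EvaluationBlock(BaseModel):
    test_fraction: float = Field(0.2, gt=0, lt=1)
    k_folds: Optional[int] = Field(None, ge=2)
    n_repeats: Optional[int] = Field(None, ge=2)


class RunConfig(BaseModel):
    """The validated, YAML-round-trippable run configuration."""

    seed: int = 0
    input: InputBlock
    features: FeatureBlock = FeatureBlock()
    selection: SelectionBlock = SelectionBlock()
    ensemble: EnsembleBlock = EnsembleBlock()
    evaluation: EvaluationBlock = EvaluationBlock()
    output_dir: str = "runs/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the run directory.

    Each stage failure aborts with a stage-tagged error; artifacts written
    before the failure are preserved for debugging.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hepatox")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "resolved_config.yaml")
        import sklearn
        import rdkit

        logger.info(
            "run seed=%d (numpy %s, sklearn %s, rdkit %s)",
            config.seed, np.__version__, sklearn.__version__, rdkit.__version__,
        )

        stage = "curate"
        rows = config.input.resolve(config.seed)
        dataset = curate_dataset(rows)
        dataset.to_frame().to_csv(out / "curated.csv", index=False)
        dataset.log_frame().to_csv(out / "curation_log.csv", index=False)
        logger.info("curated %d compounds (%d excluded)", len(dataset), len(dataset.curation_log))

        stage = "featurize"
        members = tuple(ModelConfig(alg, seed=config.seed) for alg in config.ensemble.members)
        ens_cfg = EnsembleConfig(
            strategy=config.ensemble.strategy,
            members=members,
            voting_mode=config.ensemble.voting_mode,
            n_bootstrap=config.ensemble.n_bootstrap,
            k_oof=config.ensemble.k_oof,
            seed=config.seed,
        )
        model = HepatotoxicityClassifier.from_dataframe(
            dataset.to_frame(),
            feature_kind=config.features.kind,
            radius=config.features.radius,
            n_bits=config.features.n_bits,
            ensemble_config=ens_cfg,
            selection=SelectionConfig(
                enabled=config.selection.enabled,
                ranker=config.selection.ranker,
                step_size=config.selection.step_size,
            ),
            scale=config.features.scale,
            seed=config.seed,
        )

        stage = "train"
        results = model.fit(test_fraction=config.evaluation.test_fraction)
        (out / "selected_features.txt").write_text("\n".join(results.selected_features) + "\n")
        save_ensemble(results.ensemble, out / "ensemble")

        stage = "evaluate"
        metrics = {
            "seed": config.seed,
            "n_train": int(len(results.train_idx)),
            "n_test": int(len(results.test_idx)),
            "n_selected_features": len(results.selected_features),
            "ensemble": results.report.as_dict(),
            "members": {k: v.as_dict() for k, v in results.member_reports.items()},
        }
        if config.evaluation.k_folds:
            cv = model.cross_validate(k=config.evaluation.k_folds)
            metrics["cross_validation"] = {"k": cv.k, "mean": cv.mean, "sd": cv.sd}
        if config.evaluation.n_repeats:
            mean, sd, _ = model.repeated_holdout(
                n_repeats=config.evaluation.n_repeats,
                test_fraction=config.evaluation.test_fraction,
            )
            metrics["repeated_holdout"] = {
                "n_repeats": config.evaluation.n_repeats, "mean": mean, "sd": sd,
            }
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=1, sort_keys=True, default=_json_default, allow_nan=True)
        )
        results.metrics_table().to_csv(out / "metrics.csv")
        results.roc_frame().to_csv(out / "roc.csv", index=False)
        logger.info("ensemble holdout metrics: %s", results.report.as_dict())
        return out
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        exc.stage = stage  # tag for callers; partial artifacts remain on disk
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
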