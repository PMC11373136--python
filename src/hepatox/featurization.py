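"""Molecular feature matrices: descriptors, circular fingerprints, scaling.

Three representations are supported, mirroring common QSAR practice:

``physchem_descriptors``
    The full 2D physico-chemical descriptor set exposed by RDKit
    (:func:`rdkit.Chem.Descriptors.CalcMolDescriptors`, ~210 attributes),
    column order fixed alphabetically.
``extended_descriptors``
    A larger all-2D set assembled from RDKit's descriptor blocks: the
    physchem set plus 2D autocorrelations (192), molecular quantum numbers
    (42) and BCUT2D eigenvalue descriptors (8). No conformers are ever
    generated; 3D descriptors are deliberately out of scope.
``circular_fingerprints``
    Hashed Morgan/circular fingerprints (default radius 2, 2048 bits).

Descriptor matrices are cleaned (columns with any missing/non-finite value
dropped) and min-max scaled to [0, 1]; the scaler is fitted on training rows
only and clips out-of-range test values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .dataset import CuratedDataset
from .errors import FeaturizationError, SchemaError

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("physchem_descriptors", "extended_descriptors", "circular_fingerprints")


@dataclass
class FeatureMatrix:
    """Compounds x named numeric features of one representation kind."""

    values: np.ndarray  # shape (n_compounds, n_features), float64
    feature_names: list[str]
    kind: str
    scaled: bool = False
    #: positions (into the source dataset) of the rows actually featurized;
    #: None means every record produced a row, in input order.
    row_index: list[int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order (names must all be present)."""
        pos = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise SchemaError(f"unknown feature names: {missing[:5]}")
        cols = [pos[n] for n in names]
        return replace(self, values=self.values[:, cols], feature_names=list(names))

    def take_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        return replace(self, values=self.values[list(idx), :], row_index=None)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ScalerState:
    """Per-feature min/max fitted on training rows (persistable as JSON)."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {"min": float(lo), "max": float(hi)}
            for name, lo, hi in zip(self.feature_names, self.mins, self.maxs)
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        payload = json.loads(Path(path).read_text())
        names = list(payload)
        mins = np.array([payload[n]["min"] for n in names])
        maxs = np.array([payload[n]["max"] for n in names])
        return cls(names, mins, maxs)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # curated datasets never hit this
        raise FeaturizationError(f"cannot rebuild molecule from {smiles!r}")
    return mol


def _physchem_row(mol: Chem.Mol) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Descriptors.CalcMolDescriptors(mol)


def _extended_row(mol: Chem.Mol) -> dict[str, float]:
    row = _physchem_row(mol)
    row.update({f"AUTOCORR2D_{i:03d}": v for i, v in enumerate(rdMolDescriptors.CalcAUTOCORR2D(mol), 1)})
    row.update({f"MQN_{i:02d}": v for i, v in enumerate(rdMolDescriptors.MQNs_(mol), 1)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bcut = rdMolDescriptors.BCUT2D(mol)
        except Exception:  # some atoms lack Gasteiger parameters
            bcut = [float("nan")] * 8
    row.update({f"BCUT2D_{i}": v for i, v in enumerate(bcut, 1)})
    return row


def compute_descriptors(dataset: CuratedDataset, kind: str = "physchem_descriptors") -> FeatureMatrix:
    """Compute a 2D descriptor matrix, one row per compound in input order.

    Compounds whose descriptor generation raises are dropped with a logged
    warning (``row_index`` records the surviving positions). Values are left
    raw: run :func:`clean_feature_matrix` before modeling.

    Raises
    ------
    FeaturizationError
        If every compound fails.
    """
    if kind not in ("physchem_descriptors", "extended_descriptors"):
        raise ValueError(f"kind must be a descriptor kind, got {kind!r}")
    row_fn = _physchem_row if kind == "physchem_descriptors" else _extended_row

    rows, kept = [], []
    for pos, smi in enumerate(dataset.smiles):
        try:
            rows.append(row_fn(_mol(smi)))
            kept.append(pos)
        except Exception as exc:  # pragma: no cover - rare RDKit failures
            logger.warning("descriptor generation failed for %s: %s", smi, exc)
    if not rows:
        raise FeaturizationError("descriptor generation failed for every compound")

    names = sorted(rows[0])
    values = np.array([[float(r.get(n, np.nan)) for n in names] for r in rows])
    return FeatureMatrix(
        values=values,
        feature_names=names,
        kind=kind,
        row_index=None if len(kept) == len(dataset) else kept,
    )


def compute_morgan_fingerprints(
    dataset: CuratedDataset, radius: int = 2, n_bits: int = 2048
) -> FeatureMatrix:
    """Hashed circular (Morgan) fingerprints as a binary n x n_bits matrix."""
    if n_bits < 8 or radius < 0:
        raise ValueError("require n_bits >= 8 and radius >= 0")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    values = np.zeros((len(dataset), n_bits))
    for i, smi in enumerate(dataset.smiles):
        fp = gen.GetFingerprintAsNumPy(_mol(smi))
        values[i, :] = fp
    names = [f"bit_{i:04d}" for i in range(n_bits)]
    return FeatureMatrix(values=values, feature_names=names, kind="circular_fingerprints")


def clean_feature_matrix(m: FeatureMatrix) -> FeatureMatrix:
    """Drop every column containing any missing or non-finite entry.

    Column order is otherwise preserved; dropped names are logged. Binary
    fingerprint matrices pass through unchanged.

    Raises
    ------
    FeaturizationError
        If all columns are defective.
    """
    finite = np.isfinite(m.values).all(axis=0)
    if not finite.any():
        raise FeaturizationError("every feature column contains defective values")
    dropped = [n for n, ok in zip(m.feature_names, finite) if not ok]
    if dropped:
        logger.info("clean_feature_matrix: dropping %d columns (%s...)", len(dropped), dropped[:5])
    return replace(
        m,
        values=m.values[:, finite],
        feature_names=[n for n, ok in zip(m.feature_names, finite) if ok],
    )


def fit_minmax(train: FeatureMatrix) -> ScalerState:
    """Fit per-feature min/max on training rows only."""
    return ScalerState(
        feature_names=list(train.feature_names),
        mins=train.values.min(axis=0),
        maxs=train.values.max(axis=0),
    )


def apply_minmax(state: ScalerState, m: FeatureMatrix) -> FeatureMatrix:
    """Scale to [0, 1] as ``(x - min) / (max - min)``.

    Constant training columns map to 0 everywhere; values outside the
    training range are clipped to [0, 1].

    Raises
    ------
    SchemaError
        If the matrix schema differs from the fitted one.
    """
    if list(m.feature_names) != list(state.feature_names):
        raise SchemaError("feature names do not match the fitted scaler")
    span = state.maxs - state.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (m.values - state.mins) / safe
    scaled[:, span == 0] = 0.0
    scaled = np.clip(scaled, 0.0, 1.0)
    return replace(m, values=scaled, scaled=True)


def concat_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation with kind-prefixed names (combined runs)."""
    if a.n_samples != b.n_samples:
        raise SchemaError("row counts differ")
    names = [f"{a.kind}:{n}" for n in a.feature_names] + [f"{b.kind}:{n}" for n in b.feature_names]
    return FeatureMatrix(
        values=np.hstack([a.values, b.values]),
        feature_names=names,
        kind=a.kind,
        scaled=a.scaled and b.scaled,
    )
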