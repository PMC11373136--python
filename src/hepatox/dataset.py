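"""Compound-table curation and splitting.

Raw QSAR tables assembled from heterogeneous sources (literature, toxicant
databases) carry duplicates, salts/mixtures, inorganics and entries whose
hepatotoxicity call is ambiguous. This module reads such tables, applies a
fixed ordered set of curation rules, and produces stratified train/test
splits. Labels follow the convention 1 = hepatotoxic, 0 = non-hepatotoxic.

Curation rule order (fixed so exclusion counts are reproducible):
parseable -> single fragment (mixture filter) -> contains carbon (inorganic
filter) -> duplicate collapse (label conflict => ambiguous) -> explicit
ambiguous flags dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from sklearn.model_selection import train_test_split

from .errors import EmptyDataset, StratificationError, UnparseableSmiles

logger = logging.getLogger(__name__)

# RDKit is chatty about every bad SMILES; we log exclusions ourselves.
RDLogger.DisableLog("rdApp.error")

#: Label values accepted as an explicit "ambiguous activity" marker.
AMBIGUOUS_MARKERS = {"ambiguous", "?", "na", "nan", ""}


@dataclass(frozen=True)
class CompoundRecord:
    """A curated compound: canonical SMILES, binary label, provenance tag."""

    smiles: str
    label: int
    source_id: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class ExclusionEntry:
    """One excluded input row and the single rule that removed it."""

    input_row: int
    smiles: str
    reason: str  # duplicate | mixture | inorganic | ambiguous | unparseable


@dataclass
class CuratedDataset:
    """Ordered curated records plus a per-exclusion reason log."""

    records: list[CompoundRecord]
    curation_log: list[ExclusionEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": self.smiles,
                "label": self.labels,
                "source_id": [r.source_id for r in self.records],
            }
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.input_row, e.smiles, e.reason) for e in self.curation_log],
            columns=["input_row", "smiles", "reason"],
        )


@dataclass(frozen=True)
class SplitIndex:
    """A stratified train/test partition of record positions."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int
    test_fraction: float


def canonicalize_smiles(smiles: str) -> str:
    """Return the unique canonical SMILES form of ``smiles``.

    Two encodings of the same molecule (e.g. ``OCC`` and ``CCO``, or kekulized
    vs aromatic benzene) map to the same output.

    Raises
    ------
    UnparseableSmiles
        If the string is not valid SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise UnparseableSmiles(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparseableSmiles(smiles)
    return Chem.MolToSmiles(mol)


def _is_ambiguous_marker(label) -> bool:
    if label is None:
        return True
    if isinstance(label, float) and pd.isna(label):
        return True
    if isinstance(label, str):
        return label.strip().lower() in AMBIGUOUS_MARKERS
    return False


def _coerce_label(label) -> int | None:
    """Return 0/1, or None for an ambiguous marker. Raises on anything else."""
    if _is_ambiguous_marker(label):
        return None
    value = int(label)
    if value not in (0, 1):
        raise ValueError(f"label must be 0, 1 or an ambiguous marker, got {label!r}")
    return value


def curate_dataset(rows: Iterable) -> CuratedDataset:
    """Apply the ordered curation rules to raw labeled rows.

    ``rows`` may be a DataFrame with ``smiles``/``label`` (optional
    ``source_id``) columns, or an iterable of ``(smiles, label[, source_id])``
    tuples. Survivors are unique canonical organic single-fragment molecules
    with an unambiguous binary label; every excluded row is logged with
    exactly one reason.

    Raises
    ------
    EmptyDataset
        If no rows were supplied, or every row was excluded (the full
        curation log is attached to the exception as ``log``).
    """
    if isinstance(rows, pd.DataFrame):
        iterator = [
            (row.smiles, row.label, getattr(row, "source_id", ""))
            for row in rows.itertuples(index=False)
        ]
    else:
        iterator = [tuple(r) + ("",) * (3 - len(tuple(r))) for r in rows]

    if not iterator:
        raise EmptyDataset("no input rows")

    log: list[ExclusionEntry] = []
    stage1: list[tuple[int, str, int | None, str]] = []  # row, canon, label, src

    for i, (smi, label, src) in enumerate(iterator):
        try:
            canon = canonicalize_smiles(smi)
        except UnparseableSmiles:
            log.append(ExclusionEntry(i, str(smi), "unparseable"))
            continue
        if "." in canon:
            log.append(ExclusionEntry(i, canon, "mixture"))
            continue
        mol = Chem.MolFromSmiles(canon)
        if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
            log.append(ExclusionEntry(i, canon, "inorganic"))
            continue
        stage1.append((i, canon, _coerce_label(label), src))

    # Duplicate collapse on canonical SMILES: agreeing labels keep the first
    # copy; any conflict (including an ambiguous marker among copies) drops
    # every copy as "ambiguous activity".
    groups: dict[str, list[tuple[int, int | None, str]]] = {}
    for i, canon, label, src in stage1:
        groups.setdefault(canon, []).append((i, label, src))

    survivors: list[tuple[int, CompoundRecord]] = []
    for canon, members in groups.items():
        labels = {label for _, label, _ in members}
        if len(labels) > 1:
            for i, _, _ in members:
                log.append(ExclusionEntry(i, canon, "ambiguous"))
            continue
        (only_label,) = labels
        if only_label is None:  # explicitly flagged ambiguous
            for i, _, _ in members:
                log.append(ExclusionEntry(i, canon, "ambiguous"))
            continue
        keep_row, _, keep_src = members[0]
        for i, _, _ in members[1:]:
            log.append(ExclusionEntry(i, canon, "duplicate"))
        survivors.append((keep_row, CompoundRecord(canon, only_label, keep_src)))

    survivors.sort(key=lambda t: t[0])
    log.sort(key=lambda e: e.input_row)
    records = [rec for _, rec in survivors]

    if not records:
        exc = EmptyDataset("all rows excluded by curation")
        exc.log = log
        raise exc

    for entry in log:
        logger.info("curation: row %d excluded (%s): %s", entry.input_row, entry.reason, entry.smiles)
    return CuratedDataset(records=records, curation_log=log)


def stratified_split(dataset: CuratedDataset, test_fraction: float = 0.2, seed: int = 0) -> SplitIndex:
    """Stratified train/test partition of the curated records.

    Deterministic given ``seed``; test size is ``round(test_fraction * n)``
    up to the ±1 forced by integer per-class allocation.

    Raises
    ------
    StratificationError
        If either class has fewer than 2 records.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = dataset.labels
    for cls in (0, 1):
        if labels.count(cls) < 2:
            raise StratificationError(f"class {cls} has <2 records")
    idx = list(range(len(labels)))
    train, test = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    return SplitIndex(
        train_idx=tuple(sorted(train)),
        test_idx=tuple(sorted(test)),
        seed=seed,
        test_fraction=test_fraction,
    )


def read_compound_table(
    path: str | Path,
    smiles_col: str = "smiles",
    label_col: str = "label",
) -> pd.DataFrame:
    """Read a compound table (CSV, TSV, or whitespace-separated SMI).

    Returns a DataFrame with ``smiles``/``label``/``source_id`` columns; labels
    are kept raw so that ambiguous markers survive until curation.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".smi":
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["smiles", "label"], dtype=str)
    else:
        sep = "\t" if suffix in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        df = df.rename(columns={smiles_col: "smiles", label_col: "label"})
    if "smiles" not in df or "label" not in df:
        raise KeyError(f"columns {smiles_col!r}/{label_col!r} not found in {path}")
    if "source_id" not in df:
        df["source_id"] = ""
    return df[["smiles", "label", "source_id"]]


def write_curated(dataset: CuratedDataset, out_csv: str | Path, log_csv: str | Path | None = None) -> None:
    """Persist curated records, and optionally the exclusion log, as CSV."""
    dataset.to_frame().to_csv(out_csv, index=False)
    if log_csv is not None:
        dataset.log_frame().to_csv(log_csv, index=False)
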