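"""Synthetic benchmark generators with planted, known structure.

Real hepatotoxicity compilations are assembled by hand from literature and
toxicant databases and cannot be redistributed as a single machine-readable
table, so every stage of this package is exercised on two generators whose
ground truth is known by construction:

``generate_planted_fingerprints``
    An abstract fingerprint-like binary matrix. A chosen set of
    "informative" bits fires at different Bernoulli rates in the two
    classes (default 0.7 in hepatotoxicants vs 0.3 in non-toxicants);
    every other bit is class-independent background noise. Class balance
    defaults to 0.625 positives, mirroring the roughly 1618/970
    positive/negative imbalance typical of curated hepatotoxicity sets.
    This is the fast, quantitative test bed for ranking/ensemble math.

``generate_rule_labeled_smiles``
    Concrete chemistry: valid organic molecules enumerated by decorating
    small scaffolds (benzene, pyridine, phenol, alkyl chains, ...) with
    substituents, labeled 1 iff a decidable structural alert (default: a
    nitro group) is present, optionally with label noise and planted
    duplicate rows to exercise curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import SpecError
from .featurization import FeatureMatrix


@dataclass(frozen=True)
class PlantedSignalSpec:
    """Conditions of the planted-bit generator."""

    n_samples: int = 600
    n_features: int = 2048
    n_informative: int = 40
    p_active_pos: float = 0.7
    p_active_neg: float = 0.3
    p_background: float = 0.1
    class_balance: float = 0.625
    seed: int = 0

    def __post_init__(self):
        rates = (self.p_active_pos, self.p_active_neg, self.p_background, self.class_balance)
        if not all(0 <= r <= 1 for r in rates):
            raise SpecError("all rates must lie in [0, 1]")
        if self.n_informative > self.n_features:
            raise SpecError("n_informative cannot exceed n_features")
        if self.n_samples < 2:
            raise SpecError("need at least 2 samples")


def generate_planted_fingerprints(
    spec: PlantedSignalSpec,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Binary matrix + labels + the planted informative bit indices.

    Deterministic per ``spec.seed``. The positive count is the rounded
    ``class_balance`` fraction (exact up to rounding, so the empirical
    balance matches the spec), with row order shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_samples, spec.n_features
    n_pos = int(round(spec.class_balance * n))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)

    informative = np.sort(rng.choice(f, size=spec.n_informative, replace=False))
    X = (rng.random((n, f)) < spec.p_background).astype(float)
    pos = y == 1
    X[np.ix_(pos, informative)] = (
        rng.random((pos.sum(), spec.n_informative)) < spec.p_active_pos
    ).astype(float)
    X[np.ix_(~pos, informative)] = (
        rng.random(((~pos).sum(), spec.n_informative)) < spec.p_active_neg
    ).astype(float)

    matrix = FeatureMatrix(
        values=X,
        feature_names=[f"bit_{i:04d}" for i in range(f)],
        kind="circular_fingerprints",
    )
    return matrix, y, informative


# --------------------------------------------------------------------- SMILES
#: Scaffold templates with one substitution slot ({0}); all valid SMILES.
SCAFFOLD_TEMPLATES = (
    "c1ccc({0})cc1",          # benzene
    "c1ccnc({0})c1",          # pyridine
    "Oc1ccc({0})cc1",         # phenol
    "c1ccc2c(c1)cccc2{0}",    # naphthalene  (slot on ring 2)
    "C1CCC({0})CC1",          # cyclohexane
    "CCCC{0}",                # butyl chain
    "CCOC(=O)C{0}",           # ethyl ester chain
    "CC(C){0}",               # isopropyl
)

#: Substituents placed into a scaffold slot. The nitro group is the default
#: structural alert; the remainder are common innocuous decorations.
SUBSTITUENTS = (
    "[N+](=O)[O-]",            # nitro (the toxic alert)
    "C[N+](=O)[O-]",           # nitromethyl
    "CC[N+](=O)[O-]",          # nitroethyl
    "c1ccc([N+](=O)[O-])cc1",  # p-nitrophenyl
    "C",
    "O",
    "N",
    "F",
    "Cl",
    "Br",
    "C(=O)O",
    "C(=O)N",
    "OC",
    "C#N",
    "S",
    "CC",
    "CO",
    "C(C)O",
    "CCl",
)

TOXIC_RULES = {"nitro": "[N+](=O)[O-]"}


@dataclass(frozen=True)
class RuleLabeledSmilesSpec:
    """Conditions of the rule-labeled molecule generator."""

    n_molecules: int = 500
    toxic_rule: str = "nitro"
    scaffolds: tuple[str, ...] = SCAFFOLD_TEMPLATES
    substituents: tuple[str, ...] = SUBSTITUENTS
    label_noise: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.toxic_rule not in TOXIC_RULES:
            raise SpecError(f"unknown toxic_rule {self.toxic_rule!r}")
        if not 0 <= self.label_noise <= 1 or not 0 <= self.duplicate_fraction < 1:
            raise SpecError("label_noise in [0,1], duplicate_fraction in [0,1)")


def _enumerate_pool(spec: RuleLabeledSmilesSpec) -> list[str]:
    """All distinct canonical single- and double-decorated molecules."""
    seen: dict[str, None] = {}
    for scaf in spec.scaffolds:
        for sub in spec.substituents:
            smi = scaf.format(sub)
            mol = Chem.MolFromSmiles(smi)
            if mol is None or "." in Chem.MolToSmiles(mol):
                continue
            seen.setdefault(Chem.MolToSmiles(mol), None)
        # double decoration: append a second substituent to the scaffold tail
        for sub in spec.substituents:
            for sub2 in ("C", "O", "Cl", "CC", "N"):
                smi = scaf.format(sub) + sub2
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canon = Chem.MolToSmiles(mol)
                if "." not in canon:
                    seen.setdefault(canon, None)
    return list(seen)


def rule_label(smiles: str, toxic_rule: str = "nitro") -> int:
    """Deterministic structural label: 1 iff the alert substructure matches."""
    pattern = Chem.MolFromSmarts(TOXIC_RULES[toxic_rule])
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SpecError(f"generator produced invalid SMILES {smiles!r}")
    return int(mol.HasSubstructMatch(pattern))


def generate_rule_labeled_smiles(spec: RuleLabeledSmilesSpec) -> pd.DataFrame:
    """Raw labeled rows (smiles, label, source_id) ready for curation.

    Molecules are drawn without replacement from the enumerated scaffold x
    substituent pool, so duplicates appear only when ``duplicate_fraction``
    plants them (copies of earlier rows, overwriting the tail). Labels are
    the structural rule, then flipped with probability ``label_noise``.

    Raises
    ------
    SpecError
        If ``n_molecules`` exceeds the enumerable pool.
    """
    rng = np.random.default_rng(spec.seed)
    pool = _enumerate_pool(spec)
    if spec.n_molecules > len(pool):
        raise SpecError(
            f"n_molecules={spec.n_molecules} exceeds the enumerable space ({len(pool)})"
        )
    chosen = list(rng.choice(len(pool), size=spec.n_molecules, replace=False))
    smiles = [pool[i] for i in chosen]

    n_dup = int(round(spec.duplicate_fraction * spec.n_molecules))
    if n_dup:
        originals = rng.choice(spec.n_molecules - n_dup, size=n_dup, replace=True)
        for j, orig in enumerate(originals):
            smiles[spec.n_molecules - n_dup + j] = smiles[orig]

    labels = np.array([rule_label(s, spec.toxic_rule) for s in smiles])
    flips = rng.random(spec.n_molecules) < spec.label_noise
    labels = np.where(flips, 1 - labels, labels)
    return pd.DataFrame(
        {
            "smiles": smiles,
            "label": labels,
            "source_id": [f"synth_{i:04d}" for i in range(spec.n_molecules)],
        }
    )
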