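"""Exception hierarchy shared across the pipeline stages."""


class HepatoxError(Exception):
    """Base class for all package-specific errors."""


class UnparseableSmiles(HepatoxError):
    """A SMILES string could not be parsed into a molecule.

    Carries the offending input on the ``smiles`` attribute.
    """

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class EmptyDataset(HepatoxError):
    """No rows were supplied, or curation excluded every row."""


class StratificationError(HepatoxError):
    """A class has too few members for the requested stratified split/folds."""


class SchemaError(HepatoxError):
    """Feature names of a matrix do not match the expected schema."""


class FeaturizationError(HepatoxError):
    """Descriptor/fingerprint generation failed for every compound or column."""


class ConfigError(HepatoxError):
    """Invalid model or ensemble configuration."""


class DomainError(HepatoxError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class DegenerateLabels(HepatoxError):
    """Labels contain a single class where two are required."""


class SpecError(HepatoxError):
    """A synthetic-data specification is unsatisfiable."""
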