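import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from hepatox.featurization import FeatureMatrix
from hepatox.synthetic import PlantedSignalSpec, generate_planted_fingerprints


@pytest.fixture
def toy_rows():
    """8-row curation fixture exercising every exclusion rule.

    Hand-applied rule outcome: survivors CCO (kept once) and CCN; excluded
    are the second CCO copy (duplicate), both phenol copies (conflicting
    labels -> ambiguous), NaCl (mixture), sulfuric acid (inorganic) and the
    syntactically broken SMILES (unparseable).
    """
    return pd.DataFrame(
        {
            "smiles": [
                "CCO", "CCO",
                "c1ccccc1O", "c1ccccc1O",
                "[Na+].[Cl-]",
                "O=S(=O)(O)O",
                "CCN",
                "C(",
            ],
            "label": [1, 1, 1, 0, 0, 1, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def small_planted():
    """Fast planted-signal problem: 200 samples, 128 bits, 12 informative."""
    spec = PlantedSignalSpec(
        n_samples=200, n_features=128, n_informative=12, seed=7
    )
    return generate_planted_fingerprints(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, names=None, kind="circular_fingerprints", **kw):
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values=values, feature_names=names, kind=kind, **kw)
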