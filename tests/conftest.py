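import numpy as np
import pandas as pd
import pytest

from mietox import fixtures, structprep


@pytest.fixture(scope="session")
def score_table() -> pd.DataFrame:
    """Small deterministic score table with known cell values."""
    return pd.DataFrame(
        {
            "720516": [0.0, 40.0, 39.0, 100.0, np.nan, 5.0],
            "720552": [1.0, 0.0, 30.0, np.nan, 70.0, 0.0],
        },
        index=pd.Index([f"S{i}" for i in range(1, 7)], name="SID"),
    )


@pytest.fixture(scope="session")
def toy_conformers():
    """Minimum-energy conformers for a handful of toy molecules.

    Small candidate counts keep this fast; session scope avoids
    re-embedding in every test.
    """
    out = []
    for mol_id, smiles in fixtures.toy_molecule_set()[:6]:
        std = structprep.standardize_structure(smiles, mol_id=mol_id)
        out.append(structprep.generate_conformer(std, n_candidates=8, seed=7))
    return out


@pytest.fixture(scope="session")
def gaussian_dataset():
    """Separable two-class descriptor dataset (d = 3)."""
    spec = fixtures.SyntheticDatasetSpec(
        n_compounds=150, n_features=10, effect_size=3.0, active_ratio=0.3, seed=5
    )
    return fixtures.synth_descriptor_dataset(spec)
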