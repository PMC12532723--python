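import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


@pytest.fixture
def hand_homogeneity_table() -> pd.DataFrame:
    """Two bottles with replicates (1,3) and (2,4): M_between=1, M_within=2."""
    return pd.DataFrame(
        {
            "analyte": ["X"] * 4,
            "bottle": [1, 1, 2, 2],
            "replicate": [1, 2, 1, 2],
            "value": [1.0, 3.0, 2.0, 4.0],
        }
    )


@pytest.fixture
def pfhxa_like_spec():
    """Simulation spec mimicking a mid-range perfluorocarboxylate analyte."""
    from crmcert import HomogeneitySimSpec

    return HomogeneitySimSpec(analyte="PFHxA", mu=35.0, sigma_bb=0.425,
                              sigma_wb=0.945, N=14, n=3, seed=7)
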