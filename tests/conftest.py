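import numpy as np
import pandas as pd
import pytest

from mirpair.containers import PairedCountMatrix, PatientPair


@pytest.fixture()
def tiny_counts() -> PairedCountMatrix:
    """3 features x 2 patients with easily hand-checked counts."""
    counts = pd.DataFrame(
        {
            "P1T": [100, 10, 50],
            "P1N": [25, 10, 100],
            "P2T": [200, 20, 40],
            "P2N": [50, 20, 160],
        },
        index=["fA", "fB", "fC"],
    )
    manifest = [PatientPair("P1", "P1T", "P1N"), PatientPair("P2", "P2T", "P2N")]
    return PairedCountMatrix(counts, manifest)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)
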