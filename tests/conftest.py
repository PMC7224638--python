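import numpy as np
import pytest

from omicsense import CountMatrix


@pytest.fixture
def tiny_multimodal() -> CountMatrix:
    """4 barcodes x (2 rna + 2 protein + 2 sample_tag) with hand-set counts."""
    counts = np.array(
        [
            [3, 0, 10, 1, 80, 2],
            [1, 5, 0, 7, 3, 90],
            [2, 2, 4, 4, 50, 40],
            [0, 1, 1, 0, 0, 0],
        ]
    )
    return CountMatrix(
        counts,
        barcodes=["AAAC", "AAAG", "AAAT", "AACA"],
        feature_names=["G1", "G2", "P1", "P2", "Tag1", "Tag2"],
        modalities=["rna", "rna", "protein", "protein", "sample_tag", "sample_tag"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
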