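import numpy as np
import pytest

from tdbench import ScoreTable, SyntheticConfig, generate_table


@pytest.fixture
def tiny_table() -> ScoreTable:
    """Two targets, two decoys, two features."""
    return ScoreTable(
        ids=np.array(["a", "b", "c", "d"], object),
        is_target=np.array([True, True, False, False]),
        entrapment=np.array([False, True, False, False]),
        scores=np.array([[1.0, 2.0], [3.0, 4.0], [0.5, -1.0], [0.0, 0.25]]),
        feature_names=["s1", "s2"],
        sequences=np.array(["PEPTIDEK", "ASATSATA", "PDPTIDDK", "ATATSASA"], object),
    )


@pytest.fixture(scope="session")
def signal_table():
    """Moderate-size synthetic table with clear signal, shared across tests."""
    cfg = SyntheticConfig(
        n_targets=600,
        pi_true=0.3,
        n_features=12,
        n_informative=5,
        effect_size=3.0,
        seed=42,
        with_sequences=False,
    )
    return generate_table(cfg)
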