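import pandas as pd
import pytest

from borylsite import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_table() -> pd.DataFrame:
    """A small, fast synthetic site table (clean labels) for unit tests."""
    cfg = SyntheticConfig(
        n_substrates=40,
        label_noise=0.0,
        n_noise_descriptors=10,
        include_final_descriptor_names=False,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_table() -> pd.DataFrame:
    """Default-condition synthetic dataset (189 substrates, 5% label noise)."""
    return generate_dataset(SyntheticConfig(seed=0))
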