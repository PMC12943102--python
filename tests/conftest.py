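import numpy as np
import pytest

from polyphenolkit.synth import SynthesisConfig, generate_compounds


@pytest.fixture(scope="session")
def small_config():
    """Compact generator settings shared by tests that only need structure."""
    return SynthesisConfig(
        seed=11,
        n_flavonoids=40,
        n_phenolic_acids=20,
        n_activities={"flavonoid": 60, "phenolic_acid": 40},
    )


@pytest.fixture(scope="session")
def small_compounds(small_config):
    df, truth = generate_compounds(small_config)
    return df, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def write_csv(path, text):
    path.write_text(text.strip() + "\n")
    return path
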