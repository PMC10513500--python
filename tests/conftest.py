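import numpy as np
import pytest

from methsubtype.synthetic import SyntheticSpec, generate_omics


@pytest.fixture(scope="session")
def four_group_spec() -> SyntheticSpec:
    """Small, well-separated 4-subgroup cohort used across module tests."""
    return SyntheticSpec(
        class_counts={"WNT": 15, "SHH": 20, "Group3": 20, "Group4": 25},
        n_probes=200,
        n_informative=40,
        delta=0.4,
        noise_sd=0.05,
        n_genes=80,
        coupling=0.85,
        seed=123,
    )


@pytest.fixture(scope="session")
def four_group_omics(four_group_spec):
    return generate_omics(four_group_spec)


@pytest.fixture(scope="session")
def separable_xy(four_group_omics):
    """(x, y) classifier view of the small cohort: samples x informative probes."""
    omics = four_group_omics
    x = omics.beta.loc[omics.informative_probes].to_numpy().T
    y = omics.labels.to_numpy()
    return x, y


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
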