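import pytest

from ternadiff.core_model import BindingSystem, SpeciesDiffusivities, load_binding_system
from ternadiff.io import packaged_path, read_dtable


@pytest.fixture(scope="session")
def cd_diffusivities() -> SpeciesDiffusivities:
    """Limiting diffusivities of the drug + cyclodextrin system (1e-9 m^2/s)."""
    return SpeciesDiffusivities(
        d_free_drug=1.050,
        d_free_carrier=0.399,
        d_complex=0.390,
        d_drug_infinite_dilution=1.168,
    )


@pytest.fixture(scope="session")
def sds_diffusivities() -> SpeciesDiffusivities:
    """Limiting diffusivities of the drug + surfactant system; the complex
    diffusivity equals the micelle value."""
    return SpeciesDiffusivities(
        d_free_drug=1.050,
        d_free_carrier=0.378,
        d_complex=0.100,
        d_drug_infinite_dilution=1.168,
    )


@pytest.fixture(scope="session")
def cd_system(cd_diffusivities) -> BindingSystem:
    return BindingSystem(diffusivities=cd_diffusivities, k_assoc=10.0)


@pytest.fixture(scope="session")
def sds_system(sds_diffusivities) -> BindingSystem:
    return BindingSystem(diffusivities=sds_diffusivities, k_assoc=20.0, cmc=0.0083)


@pytest.fixture(scope="session")
def cd_rows():
    return read_dtable(packaged_path("beta_cd_table2.csv"))


@pytest.fixture(scope="session")
def sds_rows():
    return read_dtable(packaged_path("sds_table5.csv"))


@pytest.fixture(scope="session")
def cd_system_yaml():
    return packaged_path("beta_cd_system.yaml")


@pytest.fixture(scope="session")
def sds_system_yaml():
    return packaged_path("sds_system.yaml")
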