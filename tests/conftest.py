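import pytest

from symbiotag.simdata import (
    HostSpec,
    SimConfig,
    generate_references,
    generate_run,
    paper_mimic_config,
)


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A fast two-host scenario for unit tests (4 phylotypes, 6 libraries)."""
    defaults = dict(
        seed=seed,
        hosts=(
            HostSpec("Hostus alpha", "Termitus unus", 2, 3),
            HostSpec("Hostus beta", "Termitus duo", 2, 3),
        ),
        library_depth_range=(30, 80),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def paper_config():
    return paper_mimic_config(seed=1)


@pytest.fixture(scope="session")
def paper_refs(paper_config):
    return generate_references(paper_config)


@pytest.fixture(scope="session")
def paper_run(paper_config, paper_refs):
    """One full paper-mimic synthetic run (~74k reads), shared across tests."""
    return generate_run(paper_config, paper_refs)
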