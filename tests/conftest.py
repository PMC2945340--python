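import pytest

from barcodeval.synthdata import PathologyConfig, SyntheticConfig, generate


def small_config(seed: int = 7, n_species: int = 20, **kwargs) -> SyntheticConfig:
    """A 20-species dataset carrying only the three core pathologies."""
    defaults = dict(
        n_species=n_species,
        marker_identity_groups={"D3": (), "V4": (), "V7": ()},
        pathologies=PathologyConfig(cross_genus_identical_pair=False),
        seed=seed,
    )
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """20 species, seed 7: shared-haplotype pair, all-rDNA-identical pair,
    one deep-split species."""
    return generate(small_config())


@pytest.fixture(scope="session")
def full_dataset():
    """Default-scale dataset (75 species) used by the slower checks."""
    return generate(SyntheticConfig(seed=11))
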