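import pytest

from melanoseek.synthetic import SyntheticConfig, generate_all
from melanoseek.types import Source


def small_config(seed: int = 7) -> SyntheticConfig:
    """A scaled-down generator configuration for fast unit tests."""
    return SyntheticConfig(
        seed=seed,
        source_sizes={
            Source.GWAS: 8,
            Source.PHEWAS: 20,
            Source.METABOLOMICS: 40,
            Source.TRANSCRIPTOMICS: 5,
            Source.BIOMEDICAL: 4,
        },
        multi_source_overlap=6,
        n_metabolites=5,
        n_assocs=55,
        n_phewas_rows=40,
        n_gwas_decoy_rows=5,
        n_phewas_decoy_rows=8,
        n_mapped_targets=15,
        n_mapped_drugs=40,
        trial_overlap=6,
        n_trial_drugs=20,
        n_survivor_drugs=12,
        n_annotated_targets=6,
        n_nonapproved_decoys=5,
        n_outofset_decoys=5,
        n_cmap_active=4,
        n_cmap_missing=2,
        n_cmap_inactive=0,
        instances_per_drug=3,
        signature_universe=200,
        n_up_tags=10,
        n_down_tags=10,
        concentration=0.05,
    )


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Full small fixture tree + its ground-truth manifest."""
    out = tmp_path_factory.mktemp("fixtures_small")
    truth = generate_all(small_config(), out)
    return out, truth


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Fixture tree under the study-condition defaults (seed fixed)."""
    out = tmp_path_factory.mktemp("fixtures_default")
    truth = generate_all(SyntheticConfig(seed=1), out)
    return out, truth
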