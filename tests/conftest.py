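import pytest

from vdp.synth import SyntheticConfig, generate_community, simulate_alignments


def nano_config(seed: int = 1, **overrides) -> SyntheticConfig:
    """A very small but fully featured community for fast tests."""
    defaults = dict(
        n_genera=4,
        contigs_per_genus=4,
        contig_length_range=(1500, 3000),
        n_viral_contigs=20,
        viral_length_range=(1500, 2500),
        n_samples_per_condition=4,
        reads_per_sample=8000,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def community():
    """Default-sized synthetic community shared by read-only tests."""
    cfg = SyntheticConfig(seed=1)
    contigs, features, truth = generate_community(cfg)
    return cfg, contigs, features, truth


@pytest.fixture(scope="session")
def community_alignments(community):
    cfg, contigs, _features, truth = community
    return simulate_alignments(contigs, truth, cfg)
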