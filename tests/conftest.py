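import pytest

from srnalink.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast, fully planted study: every pipeline sees signal."""
    return SimConfig(
        seed=11,
        n_chroms=4,
        chrom_length=2_000_000,
        n_genes=400,
        n_de_genes=80,
        n_te_loci=4_000,
        n_de_families=120,
        n_enriched_regions=5,
        n_te_seqs=60,
        n_pirnas=2,
        n_mirnas=3,
        n_target_genes=60,
        planted_or=20.0,
        fraction_te_with_site=0.5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg, tmp_path_factory):
    """Generated files + truth for the small study, shared across tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    truth = simulate_all(small_cfg, outdir)
    return small_cfg, outdir, truth
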