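import numpy as np
import pytest

from gevescan import pipeline
from gevescan.synthetic_data import SimConfig, simulate


def small_config(seed: int = 7) -> SimConfig:
    """A compact simulation for module-level tests (fast, ~0.65 Mb)."""
    return SimConfig(
        seed=seed,
        chrom_bp={"chr1": 500_000, "scaffold_1": 150_000},
        n_host_genes=60,
        n_host_tes=25,
        n_geve=2, n_adinto=1, n_plavaka=1, n_te_rich=1,
        geve_bp=(25_000, 40_000),
        adinto_bp=(20_000, 30_000),
        plavaka_bp=(20_000, 28_000),
        te_rich_bp=(20_000, 25_000),
        island_margin_bp=30_000,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: seed 1, 2-Mb genome, coverage ~20."""
    return simulate(SimConfig(seed=1))


def run_pipeline(bundle):
    cfg = bundle.config
    return pipeline.run_full_analysis(
        bundle.genome,
        dict(bundle.sites_by_condition),
        bundle.genes,
        bundle.tes,
        expr=bundle.expression,
        de=bundle.de,
        domains=bundle.domains,
        untreated_condition="control",
        treatment_condition=cfg.treatment_condition,
        spike_sites=bundle.spike_sites_by_condition["control"],
        spike_chroms=(cfg.lambda_chrom, cfg.puc19_chrom),
        placed_chroms=set(cfg.placed_chroms),
        unplaced_chroms=set(cfg.unplaced_chroms),
    )


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_712)
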