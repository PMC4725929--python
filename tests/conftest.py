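import pytest

from grazetx.simulate import OntologySpec, SimulationConfig, SnpSpec, simulate_experiment


def small_config() -> SimulationConfig:
    """A reduced experiment for fast unit tests (same structure as default)."""
    return SimulationConfig(
        n_genes=300,
        n_suppressed=5,
        n_upregulated=5,
        ontologies={
            "GO": OntologySpec(n_terms=20, term_size_range=(10, 40), n_enriched=3, enriched_de_members=6),
            "KEGG": OntologySpec(n_terms=12, term_size_range=(8, 30), n_enriched=2, enriched_de_members=6),
        },
        snps=SnpSpec(n_consistent=6, n_decoys_per_class=2),
    )


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_experiment(small_config(), seed=11)
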