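import pytest

from teguide.design import DesignConfig
from teguide.index import build_index
from teguide.scan import scan_genome
from teguide.simulate import (GeneModelSpec, SimulationParams, SubfamilySpec,
                              simulate_genome)


def tiny_params(seed: int = 3) -> SimulationParams:
    """A small but complete genome: focal subfamily, decoy at 10%
    divergence from the focal consensus, two genes, one 12-kb chromosome."""
    return SimulationParams(
        seed=seed, n_chroms=1, chrom_length=12000,
        subfamilies=[
            SubfamilySpec("FOC", consensus_length=200, n_copies=8,
                          divergence=0.03),
            SubfamilySpec("DEC", consensus_length=200, n_copies=3,
                          divergence=0.02, decoy_of="FOC",
                          decoy_divergence=0.10),
        ],
        genes=GeneModelSpec(n_genes=2, exons_per_gene=2, exon_length=120,
                            intron_length=200),
    )


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_genome(tiny_params())


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_sim):
    """(sim, index, tes, elements) for the tiny genome."""
    index = build_index(scan_genome(tiny_sim.sequences))
    return (tiny_sim, index, tiny_sim.to_te_annotation(),
            tiny_sim.to_element_annotation())


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory, tiny_sim):
    out = tmp_path_factory.mktemp("fixture")
    tiny_sim.write(out)
    return out


@pytest.fixture
def default_cfg():
    return DesignConfig()
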