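import numpy as np
import pytest

from alukit.genome_io import Genome, RepeatCatalog, exclusion_mask
from alukit.simulate import (
    build_ppm,
    default_consensus_library,
    default_nic_sites,
    random_genome,
)


@pytest.fixture(scope="session")
def library():
    return default_consensus_library()


@pytest.fixture(scope="session")
def ppm():
    return build_ppm(default_nic_sites(), pseudocount=1)


@pytest.fixture(scope="session")
def small_genome(library):
    genome, catalog = random_genome(
        {"chr1": 120_000}, seed=11, n_reference_alus=3,
        consensus_library=library,
    )
    return genome, catalog


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_genome, library, ppm):
    """A small simulated cohort shared by discovery/assembly/breakpoint tests."""
    from alukit.genome_io import exclusion_mask
    from alukit.simulate import (
        implant_insertions,
        sample_implant_cohort,
        simulate_paired_reads,
    )

    genome, catalog = small_genome
    mask = exclusion_mask(catalog, "Alu", 500, genome)
    specs = sample_implant_cohort(
        genome, ppm, 4, library, mask=mask, seed=5,
        blunt_fraction=0.0, deletion_fraction=0.0,
    )
    hap, truth = implant_insertions(genome, specs, library)
    reads = simulate_paired_reads(
        [hap], coverage=30, read_len=100, frag_mean=300, frag_sd=30,
        error_rate=0.0, seed=7,
    )
    sam_path = tmp_path_factory.mktemp("sim") / "reads.sam"
    reads.write_sam(str(sam_path), genome)
    return {
        "genome": genome,
        "catalog": catalog,
        "mask": mask,
        "truth": truth,
        "specs": specs,
        "sam": str(sam_path),
        "reads": reads,
    }
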