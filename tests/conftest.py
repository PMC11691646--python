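from dataclasses import dataclass

import pytest

from censat.families import RepeatFamilyClusterer, assembly_route
from censat.simulate import SimulationConfig, generate_genome, simulate_coverage
from censat.windows import CentromereWindowCaller


@dataclass
class Simulation:
    config: SimulationConfig
    genome: list
    truth: object
    chip: object
    control: object
    caller: CentromereWindowCaller
    clusterer: RepeatFamilyClusterer
    kept_arrays: list


def run_simulation(config: SimulationConfig) -> Simulation:
    genome, truth = generate_genome(config)
    chip, control = simulate_coverage(genome, truth, config)
    caller = CentromereWindowCaller().fit(chip, control, truth.scaffold_lengths)
    clusterer, kept = assembly_route(truth.planted_arrays, caller.windows_)
    return Simulation(config, genome, truth, chip, control, caller, clusterer, kept)


@pytest.fixture(scope="session")
def noise_free_sim() -> Simulation:
    """Default study conditions with noise off: exact recovery expected."""
    return run_simulation(SimulationConfig(seed=1, noise_model="none"))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, reduced genome for unit tests that do not need full scale."""
    return SimulationConfig(
        seed=7,
        n_scaffolds=3,
        scaffold_length=60_000,
        centromere_length=20_000,
        n_families=3,
        motif_lengths=(5, 63, 150),
        arrays_per_family=2,
        noise_model="none",
        n_reads_chip=5_000,
        n_reads_input=5_000,
    )
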