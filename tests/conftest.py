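"""Shared fixtures: small configurations and a reusable synthetic bundle."""

import pytest

from cistranskit.config import SimulationConfig, Thresholds
from cistranskit import simulate as sim
from cistranskit.genome import build_pseudogenome


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(genome_length=20_000, n_features=20, mean_depth=300, seed=7)


@pytest.fixture(scope="session")
def genome_bundle(small_config):
    """Reference, per-strain variants, pseudogenomes, and coordinate maps."""
    reference, variants = sim.simulate_strain_genomes(small_config)
    genomes, maps = {}, {}
    for strain, vt in variants.items():
        genomes[strain], maps[strain] = build_pseudogenome(reference, vt, strain=strain)
    return {
        "reference": reference,
        "variants": variants,
        "genomes": genomes,
        "maps": maps,
        "config": small_config,
    }
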