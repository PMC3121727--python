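import numpy as np
import pytest

from mitotile.genome import AnnotatedGenome, Feature
from mitotile.normalize import normalize_pipeline
from mitotile.probes import identity_map, tile_probes
from mitotile.simulate import (
    simulate_experiment,
    simulate_genome,
    simulate_truth,
)


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def dup_genome():
    """50-kb circular genome with one planted 12-kb exact duplication."""
    return simulate_genome(
        length=50_000, n_housekeeping=3, n_iorf=5, n_te=2,
        duplication_lengths=[12_000], background_regions=2, seed=1,
    )


@pytest.fixture(scope="session")
def plain_genome():
    """40-kb circular genome, no duplications, for expression-stage tests."""
    return simulate_genome(
        length=40_000, n_housekeeping=3, n_iorf=4, n_te=2,
        duplication_lengths=[], background_regions=2, seed=7,
    )


@pytest.fixture(scope="session")
def sim_bundle(plain_genome):
    """End-to-end small dataset: truth, probes, raw matrix, normalized track."""
    genome = plain_genome
    truths = simulate_truth(
        genome,
        [("calli", 0.45, 3.0), ("seedling", 0.30, 3.0)],
        nested=True,
        seed=7,
        typical_interval_bp=6_000,
    )
    nr_map = identity_map(genome)
    probes = tile_probes(nr_map, genome, probe_length=60, step=2, circular=True)
    matrix = simulate_experiment(probes, truths, seed=7)
    track = normalize_pipeline(matrix)
    return {
        "genome": genome,
        "truths": truths,
        "nr_map": nr_map,
        "probes": probes,
        "matrix": matrix,
        "track": track,
    }


@pytest.fixture()
def toy_genome():
    """Tiny deterministic genome with hand-placed features."""
    seq = random_dna(4_000, seed=42)
    features = [
        Feature("gene1", 500, 1500, "+", "housekeeping"),
        Feature("bg1", 2000, 2620, "+", "background_control"),
        Feature("orfA", 3000, 3300, "-", "iorf"),
    ]
    return AnnotatedGenome("toy", seq, circular=True, features=features)
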