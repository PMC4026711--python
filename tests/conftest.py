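from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import rrbsim as R

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference():
    """A 100 kb two-chromosome genome with the default compartment layout."""
    genome, features = R.simulate_genome(
        R.GenomeConfig(chromosome_lengths=(60_000, 40_000), rng_seed=11))
    methylome = R.simulate_methylome(genome, features,
                                     R.MethylomeParams(rng_seed=12))
    return genome, features, methylome


@pytest.fixture(scope="session")
def rrbs_run(small_reference):
    """An end-to-end RRBS library on the small genome: reads, trimmed reads,
    alignments and the call table (moderate depth, shared across tests)."""
    genome, features, methylome = small_reference
    library = R.rrbs_library(genome, R.SizeWindow(150, 250))
    pairs = R.generate_reads(
        library, genome, methylome, n_pairs=12 * len(library),
        params=R.ConversionParams(conversion_rate=0.995, sequencing_error_rate=0.001),
        seed=13)
    trimmed = R.trim_pairs(pairs, R.TrimConfig(rrbs_mode=True))
    index = R.build_index(genome, 50)
    config = R.MapperConfig(insert_min_bp=130, insert_max_bp=270)
    alignments = R.map_pairs(trimmed, index, config)
    table = R.call_methylation(alignments, trimmed, genome)
    return {
        "genome": genome, "features": features, "methylome": methylome,
        "library": library, "pairs": pairs, "trimmed": trimmed,
        "index": index, "mapper_config": config,
        "alignments": alignments, "table": table,
    }
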