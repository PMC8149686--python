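import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hcgkit.simulate import (
    SimConfig,
    simulate_baseline_methylome,
    simulate_ectopic_gain,
    simulate_genome,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length_bp=100_000,
        n_genes=60,
        n_tes=24,
        coverage_mean=6.0,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Genome + annotation + accessibility + baseline/gained ground truth."""
    genome, annotation, accessibility = simulate_genome(small_config)
    baseline = simulate_baseline_methylome(genome, annotation, small_config)
    gained = simulate_ectopic_gain(
        baseline, annotation, accessibility, small_config, seed=7, label="T2"
    )
    return {
        "config": small_config,
        "genome": genome,
        "annotation": annotation,
        "accessibility": accessibility,
        "baseline": baseline,
        "gained": gained,
        "chrom_lengths": {c: len(s) for c, s in genome.items()},
    }


def make_table(rows):
    """CytosineTable from (chrom, pos, strand, context, meth, total) tuples."""
    from hcgkit.calling import CytosineTable

    return CytosineTable(
        pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth", "total"]
        )
    )


def make_bin_methylome(sample_id, starts, meth, total, n_cyt, chrom="chr1", context="CG", bin_size=200):
    """Single-context BinMethylome directly from per-bin arrays."""
    from hcgkit.bins import BinMethylome

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.asarray(starts, dtype=np.int64),
            "context": context,
            "meth": np.asarray(meth, dtype=np.int64),
            "total": np.asarray(total, dtype=np.int64),
            "n_cyt": np.asarray(n_cyt, dtype=np.int64),
        }
    )
    return BinMethylome(sample_id, bin_size, df)
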