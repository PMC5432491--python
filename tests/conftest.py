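import numpy as np
import pandas as pd
import pytest

from pedscan.datasets import study_pedigree
from pedscan.io import GenotypeMatrix, MarkerMap
from pedscan.simulate import SimConfig, simulate_pedigree


def make_map(n_markers: int, chrom: str = "A01", spacing: int = 100_000) -> MarkerMap:
    """Evenly spaced single-chromosome map for hand-built matrices."""
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"{chrom}_m{i}" for i in range(n_markers)],
                "chromosome": chrom,
                "position": [(i + 1) * spacing for i in range(n_markers)],
            }
        )
    )


def make_gm(calls, sample_ids=None, chrom="A01", spacing=100_000) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(sample_ids, make_map(calls.shape[1], chrom, spacing), calls)


@pytest.fixture(scope="session")
def study_ped():
    return study_pedigree()


@pytest.fixture(scope="session")
def sim_result(study_ped):
    """One error-free simulated study pedigree shared across tests."""
    config = SimConfig(
        n_chromosomes=4,
        markers_per_chromosome=400,
        maf_distribution=("fixed", 0.5),
        rng_seed=11,
    )
    return simulate_pedigree(study_ped, config)
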