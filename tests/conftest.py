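import numpy as np
import pandas as pd
import pytest

from cldla.genoio import GenotypeMatrix, HaplotypePanel, MarkerMap
from cldla.pedigree import (AFFECTED_MALE, CARRIER_FEMALE, UNKNOWN, WT_FEMALE,
                            WT_MALE, Pedigree)
from cldla.simcohort import SimConfig, simulate_pedigree


def small_map(n=12, chrom="1", spacing=50_000):
    return MarkerMap(
        np.array([chrom] * n, dtype=object),
        np.array([f"snp{chrom}_{k}" for k in range(n)], dtype=object),
        np.arange(1, n + 1) * spacing,
    )


@pytest.fixture
def trio_pedigree():
    """One founder couple and two offspring (one case, one carrier)."""
    table = pd.DataFrame([
        {"id": "S1", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "M",
         "xclass": WT_MALE, "generation": 0},
        {"id": "D1", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "F",
         "xclass": CARRIER_FEMALE, "generation": 0},
        {"id": "C1", "sire": "S1", "dam": "D1", "sex": "M",
         "xclass": AFFECTED_MALE, "generation": 1},
        {"id": "C2", "sire": "S1", "dam": "D1", "sex": "F",
         "xclass": CARRIER_FEMALE, "generation": 1},
    ])
    return Pedigree(table)


@pytest.fixture(scope="session")
def small_cohort():
    """A complete small simulated cohort reused across read-only tests."""
    from cldla.simcohort import (make_marker_map, simulate_haplotypes,
                                 simulate_phenotype)

    config = SimConfig(seed=42, n_chromosomes=1, markers_per_chromosome=120,
                       chromosome_length_bp=6_000_000, n_litters=6,
                       n_cases_target=None)
    ped = simulate_pedigree(config)
    markers = make_marker_map(config)
    panel = simulate_haplotypes(ped, markers, config)
    phen = simulate_phenotype(ped, panel, config)
    return config, ped, markers, panel, phen
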