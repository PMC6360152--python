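import pytest

from kirdiv.sequence_io import AlleleRecord, DomainMap
from kirdiv.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_domain_map() -> DomainMap:
    return DomainMap(
        segments=[("Leader", 1, 2), ("D0", 3, 6), ("D1", 7, 10)],
        leader_length_codons=2,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """20-allele cohort under mild purifying selection, 3 populations."""
    cfg = SimulationConfig(seed=11, n_alleles=20, n_codons=60, default_omega=0.4,
                           n_populations=3, n_individuals=30)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_records() -> list[AlleleRecord]:
    return [
        AlleleRecord(name="KIR3DL3*00101", cds="ATGGTGACGCATGGG"),
        AlleleRecord(name="KIR3DL3*00102", cds="ATGGTCACGCATGGG"),  # syn at codon 2
        AlleleRecord(name="KIR3DL3*002", cds="ATGGTGACGCGTGGG"),  # His->Arg codon 4
    ]
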