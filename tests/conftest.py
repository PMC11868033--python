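import numpy as np
import pytest

from genmon.geno_io import MISSING, GenotypeMatrix
from genmon.simulate import SimConfig, simulate_founder_freqs, simulate_release_and_spread


@pytest.fixture(scope="session")
def founder_freqs():
    """Calibrated founder frequency table (A, B, CreekI, CreekII)."""
    return simulate_founder_freqs(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_state():
    """One default release-and-spread run with mid-run archive points."""
    cfg = SimConfig(seed=11)
    return simulate_release_and_spread(cfg, archive_generations=(0, 3, 4, 6))


@pytest.fixture()
def toy_two_pop():
    """Four individuals, two populations, two loci, one missing call."""
    dosage = np.array([[2, 1], [1, 1], [0, MISSING], [1, 0]])
    return GenotypeMatrix(
        ["a1", "a2", "b1", "b2"], ["L1", "L2"], dosage,
        ["P1", "P1", "P2", "P2"],
    )


def random_matrix(rng, n_ind=12, n_loci=6, missing_rate=0.1):
    dosage = rng.integers(0, 3, size=(n_ind, n_loci)).astype(np.int16)
    mask = rng.random(dosage.shape) < missing_rate
    dosage[mask] = MISSING
    # keep every locus biallelic-typed somewhere
    dosage[0] = np.abs(dosage[0]) % 3
    pops = ["P1"] * (n_ind // 2) + ["P2"] * (n_ind - n_ind // 2)
    return GenotypeMatrix(
        [f"i{k}" for k in range(n_ind)],
        [f"L{k}" for k in range(n_loci)],
        dosage, pops,
    )
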