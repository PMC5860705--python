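import numpy as np
import pytest

from svcohort.popmerge import PopulationSv
from svcohort.simdata import SimConfig
from svcohort.sv_io import SvCall

CHROMS = ("1", "2", "3", "x")


def random_call(rng, sample_id="s1", caller_id="cA", chroms=CHROMS,
                max_pos=1_000_000, sv_types=("DEL", "INS", "DUP", "INV")):
    sv_type = sv_types[rng.integers(0, len(sv_types))]
    chrom = chroms[rng.integers(0, len(chroms))]
    start = int(rng.integers(0, max_pos))
    length = int(rng.integers(50, 5000))
    if sv_type == "INS":
        return SvCall(sample_id, caller_id, chrom, start, start, "INS",
                      length, int(rng.integers(0, 30)))
    return SvCall(sample_id, caller_id, chrom, start, start + length, sv_type,
                  length, int(rng.integers(0, 30)))


def random_population_sv(rng, sv_id, chroms=CHROMS, max_pos=9_000_000,
                         carriers=("a", "b")):
    sv_type = ("DEL", "INS", "DUP", "INV")[rng.integers(0, 4)]
    chrom = chroms[rng.integers(0, len(chroms))]
    start = int(rng.integers(0, max_pos))
    length = int(rng.integers(50, 5000))
    end = start if sv_type == "INS" else start + length
    return PopulationSv(sv_id, chrom, start, end, sv_type, length,
                        frozenset(carriers))


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_config():
    """Small but fully structured cohort used by several test modules."""
    return SimConfig(seed=7, n_truth_svs=400)


@pytest.fixture(scope="session")
def toy_genes(small_config):
    from svcohort.simdata import simulate_gene_models

    return simulate_gene_models(small_config)
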