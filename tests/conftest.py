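import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from isletpop.core_io import GenotypeMatrix, VariantTable
from isletpop.synthetic_data import SimConfig, gen_balding_nichols


def make_geno(calls, pos=None, chrom="1", samples=None, ancestral=None):
    """Small GenotypeMatrix from a literal call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    variants = VariantTable(
        [chrom] * m, pos, [f"snp{j + 1}" for j in range(m)],
        ["A"] * m, ["G"] * m, ancestral,
    )
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, variants, calls)


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two populations at F=0.05, shared across structure tests."""
    cfg = SimConfig(seed=11, n_pops=2, samples_per_pop=100, n_snps=20_000, fst=0.05)
    return gen_balding_nichols(cfg)


@pytest.fixture(scope="session")
def panmictic_cohort():
    cfg = SimConfig(seed=12, n_pops=1, samples_per_pop=120, n_snps=20_000)
    return gen_balding_nichols(cfg)
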