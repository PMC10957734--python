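import io

import numpy as np
import pytest

from mrkit import HarmonizedDataset, SimulationConfig, simulate_two_sample


def make_harmonized(bx, sy, by, sx=None, snp_id=None):
    """Aligned dataset straight from arrays (exposure SEs default tiny)."""
    bx = np.asarray(bx, dtype=float)
    if sx is None:
        sx = np.full_like(bx, 1e-6)
    return HarmonizedDataset.from_arrays(bx, sx, by, sy, snp_id=snp_id)


@pytest.fixture
def small_study():
    """A deterministic biobank-like study with a positive causal effect."""
    return simulate_two_sample(SimulationConfig(theta=0.157, seed=11))


@pytest.fixture
def summary_tsv():
    """A tiny well-formed summary-statistics table (default dialect)."""
    text = (
        "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tsamplesize\n"
        "rs1\tA\tG\t0.2\t0.05\t0.01\t1e-9\t100000\n"
        "rs2\tC\tT\t0.4\t-0.03\t0.012\t2e-5\t100000\n"
        "rs3\tG\tA\t0.1\t0.02\t0.009\t0.03\t100000\n"
    )
    return io.StringIO(text)
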