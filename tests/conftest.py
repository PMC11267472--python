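import numpy as np
import pandas as pd
import pytest

from matescan import synthetic_data as sd
from matescan.datatypes import GenotypeMatrix, InversionBlock, PoolCounts


@pytest.fixture(scope="session")
def small_panel():
    """12 inbred founders, 80 variants, one inversion block on 3R."""
    return sd.simulate_founders(
        12,
        80,
        seed=7,
        wolbachia_rate=0.4,
        inversion_spec={"In(3R)K": InversionBlock("3R", 2_000_000, 18_000_000, 0.3)},
    )


@pytest.fixture(scope="session")
def forty_line_panel():
    """Founder panel at the real design's size (40 lines)."""
    return sd.simulate_founders(40, 200, seed=11)


@pytest.fixture(scope="session")
def aip(forty_line_panel):
    return sd.build_aip(forty_line_panel, generations=5, seed=13)


def make_pool(ref, alt, n_flies=50, pool_id="p", group="g", replicate=1):
    """PoolCounts from raw count arrays with placeholder variant metadata."""
    ref = np.asarray(ref)
    variants = pd.DataFrame(
        {"chrom": "2L", "pos": np.arange(1, len(ref) + 1) * 100, "ref": "A", "alt": "T"}
    )
    return PoolCounts(
        pool_id=pool_id,
        group=group,
        replicate=replicate,
        n_flies=n_flies,
        variants=variants,
        ref_count=ref,
        alt_count=np.asarray(alt),
    )


def genotype_matrix_from_freqs(freqs, n_lines, seed=0):
    """Inbred dosage matrix with the requested exact alt-line counts."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    dosage = np.zeros((n_lines, len(freqs)))
    for j, f in enumerate(freqs):
        n_alt = int(round(f * n_lines))
        rows = rng.choice(n_lines, size=n_alt, replace=False)
        dosage[rows, j] = 2.0
    variants = pd.DataFrame(
        {"chrom": "2L", "pos": np.arange(1, len(freqs) + 1) * 1000, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(
        line_ids=[f"L{i:03d}" for i in range(n_lines)], variants=variants, dosage=dosage
    )
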