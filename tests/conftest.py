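import numpy as np
import pandas as pd
import pytest

from rohsignal.genotype_io import MISSING, GenotypeMatrix


def make_gm(calls, populations=None, positions=None, chroms=None, sample_ids=None):
    """Build a GenotypeMatrix from a raw call array plus optional metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_loci = calls.shape
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 1000
    if chroms is None:
        chroms = ["1"] * n_loci
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    if populations is None:
        populations = ["pop1"] * n_samples
    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"m{j:05d}" for j in range(n_loci)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeMatrix(samples, loci, calls)


def random_gm(rng, n_samples=10, n_loci=50, populations=None, missing_rate=0.1):
    """Random dosage matrix with missingness, single chromosome."""
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    mask = rng.random(calls.shape) < missing_rate
    calls[mask] = MISSING
    return make_gm(calls, populations=populations)


def haplotypes_from_calls(calls):
    """Expand diploid dosages into 2N pseudo-haplotypes per locus (nan = missing).

    Dosage 1 contributes one 0 and one 1 (order irrelevant for pairwise
    difference counts); used by brute-force diversity oracles.
    """
    calls = np.asarray(calls)
    n, L = calls.shape
    haps = np.full((2 * n, L), np.nan)
    for i in range(n):
        for j in range(L):
            d = calls[i, j]
            if d == MISSING:
                continue
            if d == 0:
                haps[2 * i, j], haps[2 * i + 1, j] = 0, 0
            elif d == 2:
                haps[2 * i, j], haps[2 * i + 1, j] = 1, 1
            else:
                haps[2 * i, j], haps[2 * i + 1, j] = 0, 1
    return haps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
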