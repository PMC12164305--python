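import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fstscan.genio import GenotypeMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_panel(dosages, chroms=None, positions=None, populations=None, alts=None):
    """Build a small GenotypeMatrix from a dense dosage array.

    ``dosages`` is samples x SNPs with entries {0,1,2,-1}. Defaults: all SNPs
    on chromosome "1" at positions 100, 200, ...; one population "P1"; ALT "C".
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_snps = dosages.shape
    chroms = list(chroms) if chroms is not None else ["1"] * n_snps
    if positions is None:
        positions = []
        counters = {}
        for c in chroms:
            counters[c] = counters.get(c, 0) + 100
            positions.append(counters[c])
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * n_snps,
            "alt": list(alts) if alts is not None else ["C"] * n_snps,
        }
    )
    populations = (
        list(populations) if populations is not None else ["P1"] * n_samples
    )
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n_samples)], "population": populations}
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


@pytest.fixture
def tiny_two_pop_panel():
    """Four samples in two populations, three SNPs, no missing data."""
    return make_panel(
        [[0, 1, 2], [1, 1, 2], [2, 0, 0], [2, 1, 0]],
        populations=["A", "A", "B", "B"],
    )
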