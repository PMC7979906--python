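import numpy as np
import pandas as pd
import pytest

from radpop.genotype_io import SITE_COLUMNS, GenotypeMatrix
from radpop.simulate import default_preset, simulate_genotypes


def make_gm(calls, samples=None, locus_ids=None, pos=None):
    """Build a GenotypeMatrix from a plain genotype array for hand cases."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    locus_ids = locus_ids or [f"L{j + 1}" for j in range(m)]
    pos = pos or [j + 1 for j in range(m)]
    sites = pd.DataFrame(
        {
            "chrom": locus_ids,
            "pos": pos,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "locus_id": locus_ids,
        },
        columns=SITE_COLUMNS,
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def random_gm(rng, n_samples=8, n_sites=50, missing_rate=0.1):
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    return make_gm(calls)


@pytest.fixture(scope="session")
def preset_dataset():
    """One shared realisation of the default study-shaped simulation."""
    cfg = default_preset(seed=20210319)
    gm, truth = simulate_genotypes(cfg)
    return gm, truth
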