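import numpy as np
import pytest

import repgwas as rg


@pytest.fixture(scope="session")
def small_gm():
    """60 related individuals x 150 SNPs, enough structure for end-to-end runs."""
    return rg.simulate_genotypes(
        n_families=15, sibs_per_family=2, n_unrelated=30, n_snps=150, seed=0
    )


@pytest.fixture(scope="session")
def small_grm(small_gm):
    return rg.compute_grm(small_gm)


@pytest.fixture(scope="session")
def pop300():
    """300 related individuals x 1200 SNPs with a precomputed GRM."""
    gm = rg.simulate_genotypes(
        n_families=75, sibs_per_family=2, n_unrelated=150, n_snps=1200, seed=0
    )
    return gm, rg.compute_grm(gm)


def toy_repeated_pheno(seed=0, n_ind=12, obs=(1, 2, 3)):
    """Small unbalanced phenotype table + genotypes + GRM for oracle tests."""
    rng = np.random.default_rng(seed)
    gm = rg.simulate_genotypes(n_families=3, sibs_per_family=2, n_unrelated=n_ind - 6,
                               n_snps=40, seed=seed)
    grm = rg.compute_grm(gm)
    counts = rng.choice(obs, size=n_ind)
    rows = []
    for i, c in zip(gm.individual_ids, counts):
        for _ in range(c):
            rows.append({"id": i, "value": rng.normal(), "age": rng.normal()})
    import pandas as pd

    return gm, grm, pd.DataFrame(rows)
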