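import numpy as np
import pandas as pd
import pytest

from triadscan.genotypes import MISSING, GenotypeMatrix


def make_matrix(genotypes, populations, scaffold="scaf0", start=1, spacing=10):
    """Build a GenotypeMatrix from a dense dosage array and pop labels."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_loc = g.shape
    loci = pd.DataFrame(
        {
            "scaffold": [scaffold] * n_loc,
            "pos": np.arange(start, start + spacing * n_loc, spacing)[:n_loc],
            "ref": "A",
            "alt": "C",
        }
    )
    individuals = pd.DataFrame(
        {"id": [f"i{k}" for k in range(n_ind)], "population": populations}
    )
    return GenotypeMatrix(g, loci, individuals)


def from_counts(nAA, nAa, naa, population="P", **kw):
    """Single-locus matrix with given genotype counts (dosage 0/1/2)."""
    dos = np.array([0] * nAA + [1] * nAa + [2] * naa, dtype=np.int8)[:, None]
    return make_matrix(dos, [population] * len(dos), **kw)


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test: results independent of test order
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_pop_random():
    """Random 2x20-individual toy dataset with 30 loci and some missing."""
    rng = np.random.default_rng(915)
    p = rng.uniform(0.1, 0.9, 30)
    dos = rng.binomial(2, p, size=(40, 30)).astype(np.int8)
    dos[rng.random(dos.shape) < 0.05] = MISSING
    return make_matrix(dos, ["A"] * 20 + ["B"] * 20)


@pytest.fixture(scope="session")
def small_sim():
    """One small selected-mode simulation shared across tests."""
    from triadscan.simulate import SimConfig, simulate

    cfg = SimConfig(seed=77, N=100, n_loci=400, n_scaffolds=40,
                    sample_size=25, burn_in=20, n_selected_loci=30)
    return simulate(cfg)
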