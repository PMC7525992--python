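import numpy as np
import pandas as pd
import pytest

from genopred.genio import GenotypeMatrix
from genopred.simdata import SimConfig, simulate_population


def make_genotypes(values, chrom=None, bp=None, ids=None):
    """Build a GenotypeMatrix from a plain array for hand-computed tests."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    chrom = chrom if chrom is not None else ["chr1"] * m
    bp = bp if bp is not None else (1 + 100 * np.arange(m))
    ids = ids if ids is not None else [f"s{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "bp": np.asarray(bp, dtype=np.int64),
            "allele_ref": "A",
            "allele_alt": "B",
            "freq": np.nan,
        }
    )
    gm = GenotypeMatrix(values=values, snp_meta=meta,
                        sample_ids=np.array([f"i{i}" for i in range(n)], dtype=object))
    return gm.with_recomputed_freq()


@pytest.fixture(scope="session")
def small_population():
    """Family-structured oligogenic population reused across modules."""
    cfg = SimConfig(n_individuals=300, n_snps=600, n_chromosomes=3,
                    n_families=20, n_qtl=10, architecture="oligogenic",
                    h2=0.3, seed=42)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def polygenic_population():
    cfg = SimConfig(n_individuals=400, n_snps=800, n_chromosomes=2,
                    n_families=25, n_qtl=300, h2=0.25, seed=7)
    return simulate_population(cfg)
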