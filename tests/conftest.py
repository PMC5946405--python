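import numpy as np
import pandas as pd
import pytest

from evoenrich import GwasTable, SyntheticConfig, generate


@pytest.fixture(scope="session")
def null_dataset():
    """Default desk-scale genome, no planted signal."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def enriched_dataset():
    """Default genome with signal (mean z = 3) in 10% of target intervals."""
    return generate(SyntheticConfig(noncentrality=3.0, seed=7))


def make_gwas(snp_ids, chroms, positions, pvalues, maf=None, trait="toy"):
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "pvalue": pvalues,
            "maf": maf if maf is not None else np.nan,
        }
    )
    return GwasTable(trait, df)


@pytest.fixture
def toy_gwas():
    return make_gwas(
        ["rs1", "rs2", "rs3", "rs4"],
        ["chr1", "chr1", "chr1", "chr2"],
        [11, 21, 150, 500],
        [0.5, 0.01, 1.0, 0.2],
        maf=[0.3, 0.04, 0.5, np.nan],
    )
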