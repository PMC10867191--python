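import numpy as np
import pandas as pd
import pytest

import hexaflora as hf

# 20-taxon ultrametric tree with polytomies used for the frozen external
# reference values (see test_models.py); generated with sim_tree(20, seed=5).
ORACLE_TREE = (
    "(((S0001:0.7266039196047102,(((S0002:0.21986265909876432,(S0003:0.10330988435347581,"
    "S0004:0.10330988435347581):0.1165527747452885):0.06888554213487169,"
    "S0005:0.28874820123363604):0.0695013646458266,(S0006:0.3403469222722095,"
    "((S0009:0.019481831878861045,S0007:0.019481831878861048,S0008:0.019481831878861048)"
    ":0.2900216264661701,S0010:0.3095034583450311):0.03084346392717833)"
    ":0.01790264360725313):0.36835435372524744):0.2653470362681364,"
    "(S0011:0.21944700848969023,(S0012:0.10777696986094677,S0013:0.10777696986094677)"
    ":0.11167003862874345):0.7725039473831563):0.008049044127153397,"
    "((S0017:0.09982389984211328,S0018:0.09982389984211328):0.20988549466973844,"
    "S0014:0.30970939451185175,S0015:0.30970939451185175,S0016:0.30970939451185175)"
    ":0.6902906054881481,(S0019:0.8317108759160952,S0020:0.8317108759160952)"
    ":0.16828912408390487):0.5333813390534099;"
)

ORACLE_TRAITS_CSV = """species,x,y
S0001,0.421707,0.322867
S0002,0.167878,0.088408
S0003,0.220199,0.129062
S0004,0.489706,0.261613
S0005,0.597691,0.271537
S0006,0.128227,0.102904
S0009,0.093299,0.088229
S0007,0.149453,0.136386
S0008,0.247806,0.143329
S0010,0.143291,0.131489
S0011,0.373818,0.252677
S0012,0.389244,0.279542
S0013,0.107962,0.164537
S0017,0.361152,0.343922
S0018,0.052546,0.141225
S0014,0.305816,0.317941
S0015,0.586592,0.361799
S0016,0.489686,0.291457
S0019,0.378252,0.323973
S0020,0.228942,0.172679
"""


@pytest.fixture(scope="session")
def curves():
    return hf.default_curves()


@pytest.fixture(scope="session")
def oracle_tree():
    return hf.read_newick(ORACLE_TREE)


@pytest.fixture(scope="session")
def oracle_cov(oracle_tree):
    return hf.phylo_cov(oracle_tree)


@pytest.fixture(scope="session")
def oracle_traits(oracle_cov):
    import io

    df = pd.read_csv(io.StringIO(ORACLE_TRAITS_CSV)).set_index("species")
    return df.loc[oracle_cov.taxa]


def random_reflectance(rng, n=1):
    """Random smooth non-negative reflectance curves on the common grid."""
    g = hf.GRID
    out = np.empty((n, g.size))
    for i in range(n):
        base = rng.uniform(0.0, 0.6)
        step = rng.uniform(0, 1) / (1 + np.exp(-(g - rng.uniform(350, 650)) / rng.uniform(5, 50)))
        band = rng.uniform(0, 0.8) * np.exp(-(((g - rng.uniform(300, 700)) / rng.uniform(15, 90)) ** 2))
        out[i] = np.clip(base + step + band, 0, None)
    return out
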