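import pandas as pd
import pytest

from invrisk.census_io import Census, HostRecord, InsectRecord, PairRecord
from invrisk.phylo import parse_newick
from invrisk.synthetic_data import SimulationConfig, simulate_census


@pytest.fixture(scope="session")
def default_census():
    """One synthetic census at the published study dimensions."""
    return simulate_census(SimulationConfig(seed=20240917))


@pytest.fixture(scope="session")
def congener_counts_data():
    """Two-group congener data reconstructed from the published group
    probabilities (0.102, 0.013) and group sizes (128, 75):
    13/128 and 1/75 high-impact pairs."""
    return pd.DataFrame({
        "shared_genus": ["no"] * 128 + ["yes"] * 75,
        "high_impact": [1] * 13 + [0] * 115 + [1] * 1 + [0] * 74,
    })


@pytest.fixture
def tiny_tree():
    return parse_newick("((A:1,B:1):2,C:3);")


@pytest.fixture
def tiny_census():
    insects = (
        InsectRecord("adelges_x", "hemiptera", "adelgidae", "adelges",
                     "sap_feeder", "univoltine", "asexual", "passive",
                     "asia", "pest", 2, ("B", "C")),
        InsectRecord("sawfly_y", "hymenoptera", "diprionidae", "neodiprion",
                     "folivore", "univoltine", "sexual", "active",
                     "europe", "non_pest", 1, ("C",)),
    )
    hosts = (
        HostRecord("A", "high", "low", "slow", 0.41, "fine", "none",
                   (("adelges", "adelgidae"), ("pineus", "adelgidae"))),
        HostRecord("B", "low", "high", "rapid", 0.52, "coarse", "high",
                   (("dendroctonus", "curculionidae"),)),
        HostRecord("C", "moderate", "none", "moderate", 0.47, "medium",
                   "low", ()),
    )
    pairs = (
        PairRecord("adelges_x", "A", 8),
        PairRecord("adelges_x", "B", 2),
        PairRecord("sawfly_y", "C", 5),
    )
    return Census(insects, hosts, pairs)
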