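import numpy as np
import pandas as pd
import pytest

import phyloassembly as pa
from phyloassembly.data_model import StemTable


@pytest.fixture(scope="session")
def balanced_tree():
    return pa.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def five_tip_tree():
    # shared oracle fixture, cross-checked against R (picante) in-session
    return pa.parse_newick("((A:1,B:2):0.5,((C:0.7,D:0.7):0.9,E:1.6):0.4);")


@pytest.fixture(scope="session")
def yule_tree():
    return pa.simulate_tree(20, seed=11)


def make_stems(rows, n_subplots=25):
    df = pd.DataFrame(rows, columns=["stem_id", "plot_id", "subplot_id",
                                     "species", "dbh"])
    return StemTable(df, n_subplots=n_subplots)


@pytest.fixture()
def tiny_stems():
    rows = [
        ("s1", "P1", 1, "A", 10.0),
        ("s2", "P1", 2, "A", 20.0),
        ("s3", "P1", 3, "B", 15.0),
        ("s4", "P2", 1, "B", 12.0),
        ("s5", "P2", 5, "C", 30.0),
        ("s6", "P2", 25, "C", 11.0),
    ]
    return make_stems(rows)


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small neutral synthetic community reused by several statistical tests."""
    from phyloassembly.synthetic_data import ScenarioConfig, generate
    cfg = ScenarioConfig(process="neutral", n_species_pool=30, n_plots=6,
                         stems_per_plot=40, seed=5)
    return generate(cfg)
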