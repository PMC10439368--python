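import numpy as np
import pandas as pd
import pytest

from frogmorph import morphometrics as mm
from frogmorph import phylo as ph
from frogmorph.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Study-shaped synthetic dataset at reduced size for fast module tests."""
    return generate(SimulationConfig(n_tips=48, seed=11))


@pytest.fixture(scope="session")
def full_dataset():
    """Study-sized synthetic dataset (164 tips), shared across tests."""
    return generate(SimulationConfig(n_tips=164, seed=7))


@pytest.fixture()
def toy_table():
    df = pd.DataFrame(
        {
            "skull": [1.0, 2.0, 1.5],
            "vert": [2.0, 3.0, 2.5],
            "pelv": [1.0, 1.5, 1.2],
            "fem": [2.0, 3.0, 2.0],
            "tib": [2.0, 3.5, 2.0],
            "calc": [1.0, 1.5, 1.1],
            "foot": [1.0, 2.0, 1.4],
            "hum": [1.5, 2.0, 1.6],
            "rad": [1.0, 1.2, 1.0],
            "hand": [0.5, 0.8, 0.6],
            "sacr_w": [0.3, 0.5, 0.4],
            "ESD": [2.0, 2.5, 2.2],
            "ilium": [2.0, 2.8, 2.3],
            "uro": [1.8, 2.2, 2.0],
            "fem_w": [0.15, 0.2, 0.18],
            "hum_w": [0.18, 0.22, 0.2],
            "iliac_angle": [8.0, 10.0, 9.0],
            "locomotor_mode": ["TJ", "WH", "AQ"],
            "habitat": ["terrestrial", "riparian", "aquatic"],
            "phylo_group": ["Hyloidea", "Ranoidea", "basal"],
        },
        index=pd.Index(["sp1", "sp2", "sp3"], name="species_id"),
    )
    return mm.MeasurementTable(df)


@pytest.fixture()
def toy_tree():
    return ph.read_newick("((A:1,B:1):1,C:2);")
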