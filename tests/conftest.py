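import numpy as np
import pandas as pd
import pytest

import namqtl as nq


@pytest.fixture(scope="session")
def small_map():
    """2 chromosomes x 10 markers at 5 cM mean spacing."""
    return nq.simulate_map(2, 10, 5.0, seed=11)


@pytest.fixture(scope="session")
def nam_map():
    """Study-scale map: 10 chromosomes x 20 markers at 1.6 cM spacing."""
    return nq.simulate_map(10, 20, 1.6, seed=1)


@pytest.fixture(scope="session")
def family156(nam_map):
    """One RIL family of 156 lines on the study-scale map."""
    return nq.simulate_ril_family(nam_map, 156, seed=2)


@pytest.fixture(scope="session")
def nam_panel(nam_map):
    """Four-family NAM panel with the study's family sizes."""
    specs = [("CML103", 154), ("CML333", 159), ("NC358", 151), ("Tx303", 160)]
    return nq.simulate_nam(nam_map, specs, seed=5)


@pytest.fixture()
def qtl_pheno(family156):
    """Phenotype with one QTL at marker 24 explaining 12% of variance."""
    truth = nq.SimTruth(qtl=[(24, 1.0)], h2=0.12)
    df = nq.simulate_phenotype(family156, truth, seed=3)
    return df.set_index("genotype")["trait"], truth


def genotype_series(df: pd.DataFrame, trait: str = "trait") -> pd.Series:
    return df.set_index("genotype")[trait]
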