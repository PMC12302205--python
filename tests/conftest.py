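import numpy as np
import pytest

from deltasolv.dataset_io import MoleculeRecord
from deltasolv.featurization import FeatureConfig, featurize_molecule

SAMPLE_DB = """\
# FreeSolv-dialect sample
# compound id; SMILES; iupac name; expt (kcal/mol); d(expt); calc (kcal/mol); d(calc)
mobley_001; CCO; ethanol; -5.00; 0.60; -4.20; 0.05
mobley_002; c1ccccc1; benzene; -0.86; 0.20; -0.95; 0.04; Some reference; extra note
mobley_003; C; methane; 2.00; 0.60; 2.50; 0.02
mobley_004; CC(=O)O; acetic acid; -6.70; 0.50; -6.00; 0.10
"""


@pytest.fixture
def sample_db_text():
    return SAMPLE_DB


@pytest.fixture
def sample_records():
    from deltasolv.dataset_io import parse_freesolv

    return parse_freesolv(SAMPLE_DB)


def _record(i, smiles, hfe, unc=0.1):
    return MoleculeRecord(id=f"m{i:03d}", smiles=smiles, name=f"mol{i}",
                          expt_hfe=hfe, expt_uncertainty=unc, calc_hfe=hfe + 0.3)


SMILES_POOL = [
    "CCO", "CCC", "CCN", "CC(=O)O", "c1ccccc1", "Cc1ccccc1", "c1ccncc1",
    "CCCl", "CCBr", "COC", "CC#N", "C1CCCCC1", "CC(C)O", "CCS", "OCCO",
    "c1ccc2ccccc2c1", "CC(C)(C)O", "CCCCCC", "O=c1cc[nH]c(=O)[nH]1", "FC(F)F",
]


@pytest.fixture
def random_records_factory():
    """Factory: n records with random HFEs over a fixed SMILES pool."""

    def make(n=20, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            smi = SMILES_POOL[int(rng.integers(len(SMILES_POOL)))]
            recs.append(_record(i, smi, float(rng.normal(-4, 4)),
                                unc=float(rng.uniform(0.05, 1.0))))
        return recs

    return make


@pytest.fixture
def chem_graphs(random_records_factory):
    recs = random_records_factory(n=12, seed=3)
    cfg = FeatureConfig(feature_set="chem")
    graphs = [featurize_molecule(r, cfg) for r in recs]
    for g, r in zip(graphs, recs):
        g.y_phys = r.calc_hfe
    return graphs
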