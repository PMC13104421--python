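import numpy as np
import pytest

from graphlda.backbone import BackboneConfig, GraphAutoencoder
from graphlda.fixtures import FixtureSpec, gen_molecules
from graphlda.molgraph import build_schema
from graphlda.training import prepare_dataset


@pytest.fixture(scope="session")
def zinc_schema():
    return build_schema("zinc")


@pytest.fixture(scope="session")
def desk_config():
    return BackboneConfig.desk()


@pytest.fixture(scope="session")
def fixture_smiles():
    """60 distinct valid molecules, <= 9 heavy atoms, alphabet C/N/O/F."""
    return gen_molecules(FixtureSpec(n_molecules=60, seed=11))


@pytest.fixture(scope="session")
def fixture_graphs(fixture_smiles, zinc_schema):
    return prepare_dataset(fixture_smiles, zinc_schema, 9)


@pytest.fixture(scope="session")
def untrained_model(zinc_schema, desk_config):
    return GraphAutoencoder(zinc_schema, desk_config, seed=0)


def permute_graph(graph, perm, schema):
    """Re-featurize a molecule with its atoms renumbered by `perm`."""
    from rdkit import Chem

    from graphlda.molgraph import featurize

    mol = Chem.MolFromSmiles(graph.smiles)
    pmol = Chem.RenumberAtoms(mol, [int(i) for i in perm])
    psmi = Chem.MolToSmiles(pmol, canonical=False)
    return featurize(psmi, schema, graph.n_max)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
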