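import numpy as np
import pytest
from hypothesis import settings

from pocketgcn import chemio, curate, featurize, gcnmodel, synthdata

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study used across modules (6 receptors x 30 ligands)."""
    return synthdata.generate_dataset(
        synthdata.SynthConfig(n_proteins=6, n_ligands=30, seed=7)
    )


@pytest.fixture(scope="session")
def embedding_table(small_bundle):
    return featurize.default_embedding_table(
        list(small_bundle.ligand_smiles.values()), seed=0, epochs=5
    )


@pytest.fixture(scope="session")
def small_bc_pairs(small_bundle, embedding_table):
    pairs, info = synthdata.build_labeled_pairs(
        small_bundle, mode="bc", table=embedding_table
    )
    return pairs, info


@pytest.fixture(scope="session")
def tiny_model(small_bc_pairs):
    """A small untrained classification model matching the fixture dims."""
    pairs, _ = small_bc_pairs
    cfg = gcnmodel.ModelConfig(
        pocket_widths=(8, 8), ligand_widths=(8, 8), fc_widths=(16, 8),
        pooling="mean", head="bc",
    )
    return gcnmodel.build_model(
        cfg,
        pairs[0].pocket.node_features.shape[1],
        pairs[0].ligand.node_features.shape[1],
        seed=3,
    )
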