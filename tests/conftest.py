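import warnings

import numpy as np
import pandas as pd
import pytest

from exprevo import synth
from exprevo.synth import ORGANS

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def species6():
    """Six-species dated tree, root at 400 MY."""
    return synth.SpeciesTreeSpec.random(6, 400.0, seed=11)


@pytest.fixture(scope="session")
def species8():
    return synth.SpeciesTreeSpec.random(8, 400.0, seed=7)


@pytest.fixture(scope="session")
def family_with_events(species8):
    """A gene family containing duplications and a retrotransposition."""
    for seed in range(50):
        params = synth.FamilySimParams(dup_rate=0.002, loss_rate=0.0005,
                                       retro_rate=0.001, seed=seed)
        tree, truth = synth.simulate_gene_family(species8, params)
        if tree is None:
            continue
        cats = set(truth.extra["branch_categories"].values())
        if {"S", "D", "R"} <= cats and len(tree.leaves()) >= 8:
            return tree, truth
    raise RuntimeError("no suitable family found")


@pytest.fixture(scope="session")
def truth_means():
    """Genes x organs log2 truth table for sample simulation."""
    rng = np.random.default_rng(3)
    genes = [f"g{i:03d}" for i in range(120)]
    vals = rng.normal(4.0, 2.0, (len(genes), 6)).clip(0.0)
    return pd.DataFrame(vals, index=genes, columns=list(ORGANS))
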