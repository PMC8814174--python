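import dendropy
import numpy as np
import pandas as pd
import pytest

from movemeta.effect_sizes import compute_effect_sizes
from movemeta.phylogeny import correlation_matrix
from movemeta.synthetic import SyntheticTruth, simulate_individual_dataset


def tree_from_newick(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic individual-movement dataset (k=120) with its truth."""
    truth = SyntheticTruth(k=120, n_species=20, n_studies=15, seed=42)
    raw, tree, latents = simulate_individual_dataset(truth)
    effects = compute_effect_sizes(raw).effects
    return {"truth": truth, "raw": raw, "tree": tree,
            "effects": effects, "latents": latents,
            "phylo": correlation_matrix(tree)}


@pytest.fixture
def two_point():
    """Degenerate dataset with a closed-form pooled estimate of 0.30."""
    return pd.DataFrame({"z": [0.2, 0.4], "v_z": [0.01, 0.01]})
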