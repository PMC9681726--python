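import numpy as np
import pytest

import larimorph as lm


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); height 2, C_AB = 1."""
    return lm.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def gull_tree():
    """50-tip ultrametric pure-birth tree of height 0.21 (default conditions)."""
    return lm.simulate_tree(50, 0.21, seed=101)


@pytest.fixture(scope="session")
def gull_dataset(gull_tree):
    """Synthetic species table + derived morphology on the 50-tip tree."""
    cfg = lm.GeneratorConfig(seed=101)
    records = lm.simulate_species_table(gull_tree, cfg)
    morph = lm.derive_morphology(records)
    return {"tree": gull_tree, "config": cfg, "records": records, "morph": morph}


@pytest.fixture(scope="session")
def mantle_design(gull_dataset):
    """(tree, y, X) for the mantle analysis, aligned to tip order."""
    morph = gull_dataset["morph"]
    tree = gull_dataset["tree"]
    order = {lab: i for i, lab in enumerate(tree.tip_labels)}
    morph = morph.sort_values("species", key=lambda s: s.map(order))
    X = np.column_stack(
        [np.ones(len(morph)), morph["wing_loading_std"], morph["abs_latitude"]]
    )
    y = morph["mantle_kgs"].to_numpy()
    return tree, y, X
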