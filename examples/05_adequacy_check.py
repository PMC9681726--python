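"""Simulate-and-refit check that an OU preference is not a tree artifact.

Fits BM and OU to synthetic mantle data, then simulates traits from both
fitted models, refits each replicate, and places the observed AIC
difference within the two simulated reference distributions.
"""

import numpy as np

import larimorph as lm

tree = lm.simulate_tree(50, height=0.21, seed=31)
records = lm.simulate_species_table(tree, lm.GeneratorConfig(seed=31))
morph = lm.derive_morphology(records)
order = {lab: i for i, lab in enumerate(tree.tip_labels)}
morph = morph.sort_values("species", key=lambda s: s.map(order))
X = np.column_stack([np.ones(50), morph["wing_loading_std"], morph["abs_latitude"]])
y = morph["mantle_kgs"].to_numpy()

bm = lm.fit_model(tree, y, X, "BM")
ou = lm.fit_model(tree, y, X, "OU")
print(f"observed AIC: BM {bm.aic:.2f}, OU {ou.aic:.2f} "
      f"(delta = {bm.aic - ou.aic:.2f} in favour of OU)")

res = lm.run_adequacy(tree, X, bm, ou, n_reps=100, seed=31)
print(f"\nsimulated delta-AIC medians: BM-generated {np.median(res.sim_delta_bm):.2f}, "
      f"OU-generated {np.median(res.sim_delta_ou):.2f}")
print(f"observed delta sits at quantile {res.quantile_in_bm:.2f} of the BM reference")
print(f"and quantile {res.quantile_in_ou:.2f} of the OU reference")
print("\nAn observed delta in the far tail of the BM-generated distribution but")
print("central in the OU-generated one means the OU preference reflects signal")
print("in the trait, not a bias produced by this particular tree shape.")
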