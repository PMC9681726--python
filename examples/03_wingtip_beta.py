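"""Phylogenetic beta regression of wingtip black proportion.

Simulates wingtip proportions from the logit-beta model with a phylogenetic
random effect, fits the model, and prints the coefficient table with
exponentiated ratios plus baseline predictions.
"""

import numpy as np

import larimorph as lm

n = 49
tree = lm.simulate_tree(n, height=0.21, seed=21)
rng = np.random.default_rng(21)
wl_std = rng.normal(size=n)
abs_lat = np.abs(rng.uniform(-70, 70, size=n))
X = np.column_stack([np.ones(n), wl_std, abs_lat])

y = lm.simulate_beta_traits(
    tree, X, {"beta": (1.65, 0.34, -0.05), "phi": 30.0, "sigma2_phylo": 0.5}, seed=22
)
y = lm.squeeze(y)  # boundary proportions 0/1 would be mapped to 1e-4 / 0.9999

fit = lm.fit_phylo_beta(X, y, tree.correlation_matrix(),
                        coef_names=["intercept", "WL", "AL"])

print(f"{'term':10} {'est':>6} {'se':>6} {'ratio':>6} {'z':>6} {'p':>7}")
for nm, b, se, z, p in zip(fit.coef_names, fit.beta, fit.se, fit.z_stat, fit.p_value):
    print(f"{nm:10} {b:6.2f} {se:6.2f} {np.exp(b):6.2f} {z:6.2f} {p:7.3f}")
print(f"precision phi = {fit.phi:.1f}, phylogenetic variance = {fit.sigma2_phylo:.3f}, "
      f"loglik = {fit.loglik:.2f}")

print("\nRatios are exp(coefficient): black/non-black odds multipliers per unit.")
for k in (0, 1, 2):
    p = lm.predict_proportion(fit, wl_std=float(k), abs_lat=0.0)
    print(f"predicted black proportion at the equator, wing loading +{k} SD: {p:.2f}")

res = lm.quantile_residuals(fit, n_sim=250, seed=1)
print(f"\nsimulation-based residual uniformity: KS p = {res.ks_p_value:.3f}")
print("Small values flag misfit, but read them cautiously here: a strong shared")
print("phylogenetic effect clusters the residual quantiles, so the pooled KS")
print("test rejects too readily (see docs/methods.md); the residual spread is")
print(f"mean {res.quantiles.mean():.2f}, sd {res.quantiles.std():.2f} "
      "(uniform would be 0.50, 0.29).")
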