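"""Bootstrap comparison of K between two candidate trees.

Resamples the per-plant feeding observations within species, recomputes
species means and K on both trees each iteration, and summarises
Delta-K = K(chemical) - K(genetic) with a bias-corrected 95% interval.
"""

import chemosignal as cs
from chemosignal.profiles import aggregate_profiles
from chemosignal.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=3, chem_signal_weight=1.0,
                                        phylo_signal_weight=0.0))
matrix = aggregate_profiles(study.concentrations,
                            study.ground_truth["compounds"], "all")
dendrogram = cs.neighbor_joining(cs.profile_distance(matrix))
phylogram = cs.neighbor_joining(study.genetic_distances)

res = cs.compare_k(dendrogram, phylogram, study.feeding_for("specialist"),
                   b=1000, seed=2)
print(f"K chemical dendrogram : {res.K_a:.2f}")
print(f"K genetic phylogram   : {res.K_b:.2f}")
print(f"Delta-K               : {res.delta:.2f}")
print(f"95% CI (bias-corr.)   : [{res.ci95[0]:.2f}, {res.ci95[1]:.2f}]")
print(f"two-sided p           : {res.p_two_sided:.3f}")
print()
print("A CI above zero says the feeding trait is more structured on the")
print("chemical tree than on the genetic tree, robustly to which individual")
print("plants happened to be measured.")
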