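"""Fit expression-divergence models to simulated class programs.

Simulates class programs for 15 species diverging under a power law
MSD = 0.4 * t^0.3, then fits power-law, linear and Ornstein-Uhlenbeck
curves to the 105 species-pair (distance, MSD) points. The power law
should win on R-squared and recover its exponent.
"""

import numpy as np

from orthotyper.divergence import fit_all_models
from orthotyper.orthology import tree_distance_matrix
from orthotyper.synthetic import SimulationConfig, simulate_class_programs, simulate_tree

cfg = SimulationConfig(
    seed=1, n_species=15, n_genes=4000, classes={"PR": 30},
    divergence_model="powerlaw", divergence_params={"a": 0.4, "b": 0.3},
)
tree = simulate_tree(15, cfg.tree_depth, seed=1)
programs = simulate_class_programs(tree, cfg)
D = tree_distance_matrix(tree)

species = list(programs)
t, y = [], []
for i, s1 in enumerate(species):
    for s2 in species[i + 1:]:
        t.append(D.loc[s1, s2])
        y.append(np.mean((programs[s1]["PR"] - programs[s2]["PR"]) ** 2))

print(f"{len(t)} species pairs, distances {min(t):.1f}-{max(t):.1f} "
      "substitutions/100bp")
for name, fit in fit_all_models(np.array(t), np.array(y)).items():
    print(f"  {name:9s} a={fit.a:6.3f} b={fit.b:6.3f} R^2={fit.r_squared:.4f}")
# The power-law R^2 exceeds the linear and OU fits, and (a, b) sit near
# the generating values (0.4, 0.3): divergence decelerates with time.
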