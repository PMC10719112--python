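"""Factorized LDA: recover attribute axes and rank type quadruples.

First solves discriminant axes on a balanced polarity x kinetics x
species design with planted orthogonal effect directions. Then, on a
two-species atlas with 20 attribute-annotated types, ranks all 432
one-per-quadrant candidate quadruples against a fixed four-type
reference; the candidate sharing the reference's planted expression
programs should rank first.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np

from orthotyper import benchmarks
from orthotyper.flda import decompose_covariance, solve_axes
from orthotyper.synthetic import simulate_attribute_design

# --- axis recovery on a clean factorial design -------------------------
X, attrs, dirs = simulate_attribute_design(n_per_combo=250, n_genes=60,
                                           noise_sd=0.2, seed=3)
axes = solve_axes(decompose_covariance(X, attrs))
print("planted-direction cosines (1.0 = perfect recovery):")
for a, d in dirs.items():
    cos = abs(axes.axes[a].to_numpy() @ d) / np.linalg.norm(d)
    print(f"  {a:9s} {cos:.3f}")

# --- quadruple ranking on a simulated two-species atlas ----------------
rank, n_candidates = benchmarks._atlas_ranking_once(seed=5)
print(f"\nplanted orthologous quadruple ranks {rank} of {n_candidates} "
      "candidates")
# Rank 1 means the four types orthologous to the reference capture the
# most polarity+kinetics variance of any attribute-consistent quadruple.
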