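"""Targeted sanctioner placement by network centrality.

On heterogeneous networks, placing sanctioners at high-degree or
high-betweenness nodes can fragment the paths fake news needs.  This
example compares random, degree-targeted and betweenness-targeted
placement on a small-world ensemble at one density.  Small worlds are
fairly homogeneous, so the improvement is modest — the effect is far
stronger on heavy-tailed empirical graphs (load one with
``misinfogame.read_edge_list``).
"""

import numpy as np

import misinfogame as mg


def factory(seed):
    return mg.make_small_world(300, 8, 0.03, seed=seed).graph


cfg = mg.DynamicsConfig(beta=0.5, max_steps=2000)
density = [0.18]
for placement, scores_fn in (
    ("random", None),
    ("degree", mg.degree_scores),
    ("betweenness", mg.betweenness_scores),
):
    sweep = mg.dominance_sweep(
        factory, density, reps=20, dynamics_config=cfg, master_seed=11,
        placement="by_score" if scores_fn else "random", scores_fn=scores_fn,
    )
    print(f"{placement:12s} placement: P(truth dominates at pC=0.18) = "
          f"{sweep.p_dominant_a[0]:.2f}")

print("\nEach probability is the fraction of 20 fresh small-world populations")
print("in which the factual narrative held the viable majority.")
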