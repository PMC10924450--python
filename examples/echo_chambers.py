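"""Echo chambers of fake-news sharers on the lattice.

Runs the news-sharing game on the 30x30 periodic lattice at a sanctioner
density inside the bistable band, then quantifies the surviving
communities: a component census of each narrative on the viable subgraph
(interior members never see the other narrative), the step at which the
population settles into a pseudosteady state, and how persistent the
fake-news community is over a long continuation.
"""

import numpy as np

import misinfogame as mg
from misinfogame.experiments import pseudosteady_onset

graph = mg.make_lattice(30, 30)
init = mg.place_random(graph, mg.InitSpec(pC=0.2, seed=3))
result = mg.run(init, graph, mg.DEFAULT_PAYOFFS,
                mg.DynamicsConfig(beta=0.5, max_steps=2000, seed=4))

census = mg.echo_chamber_census(result.final_state, graph)
onsets = {thr: pseudosteady_onset(result, threshold=thr, window=10)
          for thr in (0.01, 0.02, 0.05)}
persistence = mg.persistence_probe(result.final_state, graph, mg.DEFAULT_PAYOFFS,
                                   mg.DynamicsConfig(beta=0.5, seed=5), horizon=2000)

nA, nB, nC = result.final_state.counts()
print(f"outcome after {result.steps_run} steps: {result.outcome}, "
      f"counts A={nA} B={nB} C={nC}")
print(f"fake-news components: {[c.size for c in census.components_b]}")
for c in census.components_b[:3]:
    print(f"  size {c.size}: interior {c.interior}, boundary {c.boundary}")
for thr, onset in onsets.items():
    print(f"pseudosteady onset (activity < {thr:.0%} for 10 steps): {onset}")
print(f"fake-news community Jaccard persistence over 2000 more steps: {persistence:.3f}")
print()
print("Interior members are surrounded by their own narrative and anchor the")
print("chamber; only boundary members keep flickering.  That residual border")
print("activity is why the onset detector is threshold-sensitive even though")
print("the chamber itself barely changes (see the Jaccard persistence).")
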