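# Methods

This note records the modeling conventions, calibrations and numerical
choices behind `misinfogame`, and what the test suite does and does not
establish.

## Model

Nodes of an undirected simple graph hold one of three behaviors: sharing
a factual narrative (A), sharing a false narrative (B), or sanctioning
(C). The pairwise game is read row-player-wise from the matrix
(a, b, α / c, d, γ / 0, 0, 0); the default instantiation a=1, b=0, α=1,
c=0, d=2, γ=−4 makes news sharing a coordination game with a built-in
fake-news advantage (d > a) and a strong sanctioning punishment (γ < 0).
The C row is identically zero: sanctioners never adapt, so their own
payoff is irrelevant.

Per update, payoffs are recomputed fresh from the current configuration
(no accumulation across steps). Node i's payoff π_i aggregates the
pairwise game over all neighbors — sanctioner neighbors included, which
is exactly how they punish — and fitness is f_i = exp(β π_i). A focal
node updates by death–birth imitation: it copies one *non-sanctioner*
neighbor drawn with probability ∝ f; its own fitness plays no role, and
a node whose neighbors are all sanctioners can never change. Synchronous
updating sweeps every viable node at once against the frozen payoff
profile (double-buffered); asynchronous updating draws one node uniformly
from all n nodes per step (draws landing on sanctioners are no-ops, so n
asynchronous steps ≈ one synchronous step).

## Payoff aggregation: accumulated by default

π_i can be the accumulated payoff over all neighbors (`payoff_mode="sum"`,
the default) or the per-interaction expectation (`"mean"`). On a
k-regular graph the two differ only by rescaling β by k, so the choice is
a calibration of what "β = 0.5" means. The accumulated convention is the
standard one in the spatial-game literature this model belongs to, and it
is the calibration under which the simulator reproduces the reference
critical densities at β = 0.5 (lattice ≈ 0.25 vs reference ≈ 0.235;
small world ≈ 0.21–0.22 vs reference ≈ 0.2). Under the mean convention
the same protocol yields ≈ 0.19 and ≈ 0.14. Both modes are first-class;
every result records which was used. The well-mixed replicator layer
(`analytics`) is per-interaction by construction and is unaffected.

Numerical guard: fitness exponents are shifted by a global constant only
when they would overflow (`exp` cap at 500); every imitation lottery is
invariant to such shifts, and a unit test asserts this invariance.

## Networks

- **Lattice**: rows × cols, von Neumann (k=4, default) or Moore (k=8)
  neighborhood, periodic by default so all vertices are equivalent
  (degree and betweenness exactly constant — asserted in tests).
  Non-periodic boundaries are supported.
- **Small world**: Watts–Strogatz ring lattice (base degree k, each node
  linked to k/2 neighbors per side) with *per-stub* rewiring: every
  undirected ring edge receives two independent rewiring considerations,
  one anchored at each endpoint, each firing with probability p and
  redrawing the far endpoint uniformly (self-loops/duplicates rejected;
  exhausted redraws are skipped with a warning). Expected rewire count
  is n·k·p — 216 for the reference WS(900, 8, 0.03), matching the
  "approximately 200 shortcuts" calibration — whereas the common
  single-pass convention (also selectable) gives half that. The
  generator conserves the degree sum but not individual degrees.
- **Edge lists**: whitespace `u v` pairs with `#` comments; read as
  undirected (symmetrized), self-loops dropped, ids remapped to 0..n−1
  with the mapping returned. Generated graphs export to the same format.

Betweenness is exact Brandes (unnormalized, each unordered pair counted
once) via networkx; for very large graphs a seeded source-sampled
estimate rescaled to the exact range is available (with all n sources it
coincides with the exact values — asserted).

## Initialization

Exactly round(p_C·n) sanctioners — an exact count, not a Bernoulli
draw, so density sweeps control the density itself. Placement is uniform
or score-targeted (top-round(p_C·n) nodes by a centrality vector, with
seeded uniform tie-breaking at the admission boundary; constant scores
reduce to uniform placement — verified distributionally). Each remaining
node is independently A with probability `ratio_a` (default 0.5).

## Experiments

**Dominance sweeps** tally, per density, the probability that A holds a
strict majority of viable nodes at the end of a trajectory (fixation or
a 5,000-step synchronous cap); exact ties count 1/2, which is what makes
the fully fragmented high-density regime hover at 1/2. Replicate streams
derive from `SeedSequence([master_seed, density_index, rep])`, so any
cell is reproducible in isolation. Deterministic substrates (lattices)
are fixed across replicates; random ensembles (small worlds) are
regenerated per replicate.

**Critical density**: the dominance curve is non-monotone at extreme
densities, so the fit is restricted to the grid up to the curve's argmax,
monotone-smoothed by isotonic regression, and linearly interpolated at
1/2. On an analytically generated well-mixed step curve this recovers
the replicator threshold exactly.

**Echo-chamber census**: connected components of each news strategy on
the viable induced subgraph; a member is *interior* if every viable
neighbor shares its strategy (vacuously so for sanctioner-walled
singletons), else boundary.

**Pseudosteady detection**: first step from which the per-step fraction
of viable nodes changing strategy stays below a threshold for a full
window (defaults 1% and 10 steps; fixated runs count as quiet from their
end). The detector is deliberately simple and *threshold-sensitive*: at
moderate densities the settled state keeps a few boundary nodes
flickering, so the 1% first-passage time on the 30×30 lattice at
p_C=0.15 has a 20-run median anywhere between ≈ 100 and ≈ 200 steps
depending on the seed set, while thresholds of 2–3% give medians of
≈ 20–40 steps. Qualitative "chambers form fast, then barely
change" behavior is better captured by the persistence probe (Jaccard
similarity of the fake-news set across a long continuation; median
≳ 0.9 over 10⁴ steps at p_C=0.15 in our runs).

## Closed forms

**Well-mixed threshold** (exact rational arithmetic): with density p_C
and the rest split evenly, initial expected payoffs are
f_A(0) = a·p_A + b·p_B + α·p_C and f_B(0) = c·p_A + d·p_B + γ·p_C with
p_A = p_B = (1−p_C)/2; in a coordination game the initially fitter
narrative only gains, so the threshold solves f_A(0) = f_B(0):
p_C\* = (c+d−a−b)/((c+d−a−b)+2(α−γ)) = 1/11 for the defaults.
Thresholds outside [0,1] are clipped and flagged with the strategy
favored at every interior density.

**Weak selection** (k-regular graphs, β ≪ 1): fixation probabilities are
first-order corrections to neutral drift,

    ρ_A(p) ≈ p + (β N p (1−p) / 6k) (−u₁ − 3u₂),
    ρ_B(p) ≈ p + (β N p (1−p) / 6k) (−w₁ − 3w₂),

with w₁ = u₁, w₂ = −(u₁+u₂) (identities asserted exactly), and

    u₂ = −a+b+c−d − ak + bk − bk² + dk² + (k−1)(c + (b−α+γ)k − d(1+k))·p_C.

N is the *viable* population size: the single-mutant benchmark for the
headline 30×30 / p_C=0.2 setup is 1/((1−0.2)·900) = 1/720 ≈ 0.0014.
β = 0 reduces both forms to ρ(p) = p exactly; the correction is exactly
linear in β.

**Transcription of u₁.** Our source for these closed forms is text-extracted
and the inner factor of u₁ is corrupted (superscripts and fraction bars
lost). The module ships the candidate readings and defaults to

    u₁ = (a − b − c + d) · (−2k + k(p_C − 1)) · (1 − p_C),

selected by measurement: Monte-Carlo estimates of the O(β) fixation
coefficient on a 12×12 periodic lattice (40,000 asynchronous absorptions
per condition at β ≤ 10⁻³, conditions spanning p_C ∈ {0, 0.1} and
γ ∈ {0, −4, −8}) match this reading — on the accumulated-payoff β
scale, consistent with the simulator calibration — and exclude the
flat-superscript and lost-fraction readings at >2.5σ. A constant-offset
variant (`2(1−k)−1+k(p_C−1)`) is statistically indistinguishable; both
give the same qualitative phase structure. With the default payoffs the
resulting p_C–γ phase diagram shows fake news favored only at very low
sanctioner density, a wide band where selection favors neither invader
(the coordination game penalizes lone mutants), and a truth-favored
region whose minimal density is ≈ 0.47 as γ → 0 and ≤ 0.18 for γ ≤ −4 —
matching the qualitative structure reported for these closed forms.

**Simulation check of the crossing.** The Monte-Carlo validation of the
single-mutant crossing (where ρ_A crosses 1/N as γ varies) runs on an
8×8 lattice at β = 0.005, the upper edge of the weak-selection regime:
at the printed β = 10⁻⁴ the O(β) signal is ~10⁻⁴ in probability and
would need >10⁸ absorptions to resolve. Because the predicted correction
is exactly linear in β, the predicted crossing location is
β-independent, so the check tests the same quantity at a feasible scale.
Observed: empirical crossing at γ ≈ −4.9 vs predicted −3.1 on N=51
(finite-N and frozen-fragment effects bias the favorable branch down;
the sign structure and location agree to within the γ-grid coarseness).

## Exact oracle and batched Monte Carlo

For fixtures with ≤ 12 viable nodes, `exact_fixation_oracle` enumerates
all A/B labelings, builds the asynchronous single-step transition matrix
and solves the absorbing-chain linear system; frozen mixed
configurations (sanctioner-walled) are closed states with absorption
value 0. The simulator's empirical fixation frequencies match the oracle
within 3 Monte-Carlo standard errors on every fixture, and the β=0
voter-model identity (fixation probability = initial abundance on
regular graphs with no sanctioners) holds for both the oracle and the
numba-batched Monte-Carlo kernel (`fixation_frequency`), which is the
workhorse for weak-selection validation. Batched replicates that are
still mixed at the draw cap — possible only through frozen fragments —
are reported separately as `stalled`.

## Reference protocol sizes

The reproduction protocols (`misinfogame.benchmarks`) use 24 replicates
at 9 densities for each critical-density estimate (grid 0.16–0.32 on the
lattice, 0.10–0.30 on small worlds), 200 generator seeds for the
shortcut count, 20 trajectories for the onset median, and 40,000
absorptions per γ point for the crossing check — the package's reference
choices balancing Monte-Carlo error (±0.01–0.02 on the thresholds)
against single-CPU runtime of a few minutes each.

## Known limitations

- The synthetic substrates (lattice, small world) lack the heavy-tailed
  degree distribution, clustering and community structure of real social
  graphs; passing tests establish the mechanism, not quantitative claims
  about any particular platform. The edge-list reader accepts empirical
  graphs, but none is bundled.
- The pair-approximation forms assume large N, k-regularity and
  uniformly mixed sanctioners; at the small N used for Monte-Carlo
  validation, finite-size deviations of order 1/N are visible (see the
  crossing check above).
- The 1% pseudosteady threshold is an operationalization choice; see its
  sensitivity discussion above before comparing onset times across
  models.
- On small worlds we observe degree-targeted placement clearly
  outperforming random placement near the tipping point while
  betweenness-targeted placement does not, a sharper split than the
  qualitative parity sometimes reported; the comparison is sensitive to
  the rewiring convention and to how ties in nearly-constant score
  vectors are broken.
- Sanctioner errors (occasionally punishing accurate news), strategy
  mutation, dynamic rewiring and payoff accumulation across rounds are
  out of scope.
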