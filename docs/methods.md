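# Methods

This note records the models, parameter values, and numerical choices
implemented by the package. Everything stated here is computed by the
code; the test suite checks the quantitative claims.

## Brain model

A brain has 16 binary nodes: sensors 0–3 (written by the environment,
read-only for gates), motor outputs 4–5, hidden nodes 6–15. Updates
are synchronous and double-buffered: every gate reads the pre-update
state and writes into a fresh zero next-state; simultaneous writes to
a node combine by OR. Consequences:

- gate order never affects the result,
- outputs are not latched — any information kept across updates must
  be actively rewritten into hidden nodes,
- a signal needs one update per gate hop to propagate.

Gates have 1–4 input and 1–4 output wires. Deterministic gates map
each input pattern to an output pattern. Probabilistic gates hold a
row-stochastic table `P[input pattern, output pattern]` and sample one
output pattern per update. Input and output patterns pack wire bits
little-endian (first listed wire is bit 0); the 2-bit motor option is
`node4 + 2*node5`.

## Feedback gates

A feedback gate is a probabilistic gate plus:

- a decision buffer of depth 1–4 holding its most recent
  (input, output) pairs, most recent first, oldest evicted;
- two feedback wires (positive, negative) reading arbitrary nodes;
- per-buffer-slot maximum shifts `delta_pos[k]`, `delta_neg[k]` in
  [0, 1].

At the start of each brain update, before any gate samples, each
feedback gate reads its feedback wires from the pre-update state (so
feedback always refers to consequences of past decisions). For each
wire reading 1 and each buffered decision `(i, o)` at slot `k`, a
shift `u ~ Uniform[0, delta[k]]` is drawn; `P[i, o]` is increased
(positive) or decreased (negative) by `u`, and the row is
renormalized. Positive feedback is applied before negative when both
wires read 1.

Numerical rules of the row update:

- the target entry is clamped to `[0.01, min(0.99, 1 − 0.01·(K−1))]`
  for a K-column row; the upper cap beyond 0.99 is forced by the
  floor — with K > 2 columns an entry of 0.99 would be incompatible
  with keeping every other entry at or above 0.01;
- the remaining entries are scaled proportionally to absorb the mass
  change; entries pushed below the 0.01 floor are pinned there and the
  deficit is re-absorbed by the still-free entries, iterating until
  consistent (the iteration terminates because the cap guarantees
  enough free mass);
- when the target sits at its cap and every other entry is pinned at
  the floor, the row is fully determined and the update stops.

Under these rules row sums stay at 1 to within 1e-9 over at least
1,000 arbitrary updates (tested to tighter than 1e-12 in practice),
and every touched entry stays in [0.01, 0.99], so no decision ever
becomes impossible or certain.

Disabling plasticity (`set_feedback_enabled(brain, False)`) keeps the
sampling and buffering behavior but never alters tables; this is the
frozen-feedback control.

## Genome and decoding

A genome is a byte string (1,000–20,000 sites; initial length 5,000).
Genes begin at two-byte start codons — (42, 213) deterministic,
(43, 212) probabilistic, (44, 211) feedback; the second byte is the
ones' complement of the first. Freshly generated genomes receive 12
codons (4 per enabled gate kind) at non-overlapping random positions
at least 200 sites from the end. The scan for codons and the 288-byte
payload reads are circular, and every payload decodes to a valid gate
(sizes and addresses are taken modulo their ranges; output addresses
land on nodes 4–15, so sensors are write-protected), making decoding
total: mutation can never produce an invalid brain.

Payload layout (byte offsets): 0 input count (`%4+1`), 1 output count
(`%4+1`), 2–5 input node addresses (`%16`), 6–9 output addresses
(`4 + %12`); feedback gates add 10 positive wire (`%16`), 11 negative
wire (`%16`), 12 buffer depth (`%4+1`), 13–16 positive deltas
(`byte/255`), 17–20 negative deltas; the table follows (deterministic:
one byte per input pattern, `% 2^n_out`; probabilistic/feedback:
`2^n_in · 2^n_out` bytes, each `+1` then row-normalized, so no decoded
entry is zero).

Mutation (asexual, applied to every offspring in order): per-site
point mutation at rate 0.003 (resampled uniformly over 0–255), then
with probability 0.02 duplication of a random 128–512-site stretch
inserted at a position outside the copied interval, then with
probability 0.02 deletion of a random 128–255-site stretch. Stretch
sizes are clipped so the length bounds [1,000, 20,000] are never
crossed.

## Environment and fitness

Mazes are 64×64: border tiles are walls, interior tiles are walls
independently with probability 1/7, the goal is uniform over empty
tiles. Every reachable tile gets its shortest-path distance `d` to the
goal (breadth-first search; unit costs make this identical to
Dijkstra's algorithm, which a test verifies against an independent
oracle) and an arrow toward a uniformly chosen neighbor at `d − 1`.
Mazes without any tile at `d = 32` are discarded and regenerated.
Agents spawn on a uniformly random `d = 32` tile with a uniformly
random heading; following arrows greedily from any spawn tile reaches
the goal in exactly 32 moves.

The agent's percept is the 4-bit one-hot code of the arrow under it
rotated into its frame: `(arrow − heading) mod 4`, ordered [forward,
right, backward, left]. Actions are forward (no-op against walls),
do-nothing, turn-left, turn-right. The 2-bit motor option is
translated to an action through one of the 24 bijections
(`itertools.permutations(range(4))`, lexicographic).

One lifetime is T = 512 updates on a fresh maze. Each update the agent
perceives, steps its brain, acts, and accrues `1/(1 + d)` from its
post-action distance; reaching the goal adds a bonus `b = 512` and
respawns the agent at a random `d = 32` tile of the same maze. The
per-mapping score is the dwell sum plus `goals · b`; total fitness is
the product `W` of the 24 per-mapping scores (one fresh maze each),
kept as `log W` to avoid overflow — selection only compares, so this
is exact. A stationary agent scores exactly `512/33` per mapping.

## Evolution

Generational replacement with population N = 100 (configurable): each
of the N offspring descends from the winner of an independent
tournament of 5 individuals drawn uniformly with replacement (highest
`log W`; exact ties broken uniformly). Every individual's parent link,
fitness, gate census, and (optionally) full genome are archived. The
line of descent of a random final individual is its ancestor chain to
generation 0; the most recent common ancestor of the final population
is found by walking the final generation's ancestor sets backward to
the first singleton (reported as absent if the population never
coalesces).

## Reproducibility

All randomness derives from one master seed through named integer
substreams (`numpy.random.default_rng([seed, tag, ...])`): genome
initialization, per-(generation, individual) evaluation, per-generation
selection, and the analysis streams. Evaluation replays are therefore
independent of execution order; re-running a manifest reproduces every
archive byte for byte, and `replay` re-derives any archived
evaluation's exact mazes, trajectories, and scores. The Python-level
replay path and the compiled kernel consume random draws identically;
a test asserts bit-equality of their outcomes.

## Mutual-information analysis

For a row-stochastic table, `I(I; O) = H(O) − H(O|I)` in bits with the
input marginal uniform over rows by default (row-visit weights may be
supplied). The lifetime change Δ̄ is the mean of
`MI(end-of-life table) − MI(birth table)` over feedback gates and
mappings. `binned_delta_vs_performance` bins (performance, Δ) pairs
into unit-width performance bins and reports the Pearson correlation
between bin centers and bin mean Δ; it refuses degenerate inputs
(fewer than two bins or constant means) rather than returning NaN.

## Numerical and performance choices

- The episode and feedback arithmetic run in a numba-compiled kernel
  (`_kernel.py`); the object layer shares the same compiled primitives
  and exposes gate tables as views into the kernel arrays, so there is
  a single implementation of the numerics.
- `log W` accumulates `sum(log(score))`; a zero score (impossible
  while the agent is on a labeled tile, since every dwell term is
  positive) would map to `−inf`, which compares correctly.
- Probability tables are float64 throughout; feedback renormalization
  is exact to ~1e-15 per event and does not drift over 10⁴ events.

## Limitations

- Desk scale only: the evolutionary dynamics demonstrated by the test
  suite (population 50, 200 generations) show statistically reliable
  improvement, not converged high-performing learners; long runs are
  the user's responsibility.
- Fitness evaluation is sequential on one CPU core.
- The frozen-feedback control freezes tables but not hidden-state
  dynamics; it isolates table plasticity, not all forms of lifetime
  adaptation.
- Maze regeneration conditions on the existence of a distance-32 tile,
  which biases wall statistics very slightly relative to independent
  Bernoulli(1/7) fill.
- `analyze` computes the table-MI change for the final
  line-of-descent agent only; population-wide MI studies should use
  `collect_snapshot_pairs` directly.
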