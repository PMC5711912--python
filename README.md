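# markovbrains

Evolvable Markov Brains with self-adapting **feedback gates**, an
arrow-labeled maze navigation task, and the analyses that separate
*evolved reflexes* from *evolved learning*.

## The science

A Markov Brain is a network of small logic gates wired between 16
binary nodes — 4 sensors, 2 motor outputs, 10 hidden — encoded on a
byte-string genome and shaped by a genetic algorithm. Three gate types
can evolve:

- **deterministic** gates (fixed truth tables),
- **probabilistic** gates (row-stochastic probability tables sampled
  each update),
- **feedback** gates: probabilistic gates that *change their own
  tables during the agent's lifetime*. A feedback gate buffers its
  recent input→output decisions and carries two extra input wires.
  When the "positive" wire reads 1 the gate multiplicatively
  reinforces its buffered decisions; the "negative" wire weakens them.
  Crucially, those wires are connected by evolution to other nodes
  *inside* the brain — no objective reward signal is delivered from
  outside. The brain must evolve both a policy substrate and its own
  critic.

The task makes lifetime learning necessary. An agent lives in a 64×64
maze whose tiles carry arrows pointing one step down the shortest-path
gradient to a goal. The agent sees only the arrow under its feet,
rotated into its own frame of reference, and commands one of four
motor options. The catch: the bijection between its four motor options
and the four physical actions (forward, do-nothing, turn-left,
turn-right) is shuffled every lifetime, and fitness is the *product*
of scores over all 24 possible bijections. A hard-wired reflex can be
right under only some mappings; consistently high product fitness
requires figuring out, within each lifetime, what one's own motors
currently mean — which is exactly what feedback gates make possible.

The package provides the full loop: genome encoding and mutation, gate
decoding, brain simulation, maze generation and evaluation, tournament
selection with complete lineage archiving, line-of-descent and
most-recent-common-ancestor reconstruction, and the two analyses that
quantify learning:

- the **frozen-feedback control**: re-evaluate an agent with table
  updates disabled; the performance drop is the contribution of
  lifetime plasticity,
- **table mutual information**: the change, from birth to end of a
  lifetime, in the mutual information between a feedback gate's input
  and output patterns — how much structure the agent wrote into its
  own tables.

## Worked example

A hand-built learner (`markovbrains.exemplars.make_feedback_learner`)
wires one feedback gate from the arrow percept to the motors, starting
from uniform tables, plus three deterministic gates forming an
internal critic ("did my last move bring the goal-ward arrow into
view?"). Comparing it with and without plasticity:

```python
import numpy as np
from markovbrains import fitness
from markovbrains.analysis import (
    frozen_performance, collect_snapshot_pairs, delta_mi,
)
from markovbrains.exemplars import make_feedback_learner

brain = make_feedback_learner()
normal = fitness(brain, np.random.default_rng(1))
frozen = frozen_performance(brain, np.random.default_rng(2))
print(f"plastic: {normal.goals.sum():3d} goals over 24 mappings, log W = {normal.logW:.2f}")
print(f"frozen:  {frozen.goals.sum():3d} goals over 24 mappings, log W = {frozen.logW:.2f}")

pairs, _ = collect_snapshot_pairs(brain, np.random.default_rng(3))
print(f"mean lifetime table-MI change: {delta_mi(pairs):+.3f} bits")
fb = brain.feedback_gates[0]
print("end-of-life 'arrow ahead' row:", np.round(np.asarray(fb.P)[1], 3))
```

Output:

```
plastic:  16 goals over 24 mappings, log W = 128.62
frozen:    0 goals over 24 mappings, log W = 67.32
mean lifetime table-MI change: +0.238 bits
end-of-life 'arrow ahead' row: [0.01  0.011 0.943 0.035]
```

The same brain reaches the goal 16 times when its tables may adapt and
never when they are frozen, and each lifetime writes about a quarter
bit of input–output structure into the gate: the "arrow ahead" row,
uniform (0.25 each) at birth, ends concentrated on a single motor
option.

## Command-line interface

```bash
# a small evolution run
cat > config.yaml <<'YAML'
population_size: 50
generations: 200
T: 128
seed: 0
YAML
mbrain evolve config.yaml --out runs/demo

# line of descent, frozen control, table-MI change of the final agent
mbrain analyze runs/demo

# deterministically re-run an archived evaluation
mbrain replay runs/demo --id 0 --mapping 3
```

`evolve` writes a self-describing run directory (`manifest.json`,
`archive.csv`, `stats.csv`, `genomes.csv`). All randomness flows from
the manifest's seed through named substreams, so two runs of the same
manifest are byte-identical and any archived evaluation can be
replayed exactly — `replay` writes the trajectory CSV and an ASCII
maze render.

Config keys (YAML, all optional): `population_size` (100),
`generations` (100), `tournament_size` (5), `genome_length` (5000),
`point_rate` (0.003), `dup_prob` (0.02), `del_prob` (0.02), `T`
lifetime updates (512), `b` goal bonus (512), `n_mappings` (24),
`seed` (0), `gate_kinds` (all three), `record_genomes` (true).

## Package layout

| module | contents |
| --- | --- |
| `markovbrains.genome` | byte-string genomes, start codons, point/duplication/deletion mutation, gene scanning |
| `markovbrains.gates` | the three gate types, feedback updates, gene decoding |
| `markovbrains.brain` | brain assembly and synchronous updates (compiled-kernel backed) |
| `markovbrains.environment` | maze generation and labeling, sensors, kinematics, product fitness, replay |
| `markovbrains.evolution` | tournament selection, the generational loop, lineage archive, line of descent |
| `markovbrains.analysis` | table mutual information, frozen-feedback control, usage summaries |
| `markovbrains.exemplars` | hand-built reference brains |
| `markovbrains.cli` | the `mbrain` command group |
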