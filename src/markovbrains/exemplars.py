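"""Hand-built reference brains.

These small, fully specified networks exercise the machinery without
evolution: a pass-through wire for plumbing checks, and a lifetime
learner whose navigation ability depends on a feedback gate adapting
its probability table. The learner also demonstrates the internal
generation of feedback: deterministic gates evaluate the sensor stream
("did my last move bring a goal-ward arrow into view?") and drive the
feedback lines of the plastic gate, so no objective reward signal
enters from outside the brain.
"""

from __future__ import annotations

import numpy as np

from .brain import MarkovBrain
from .gates import DeterministicGate, FeedbackGate

__all__ = ["make_wire_brain", "make_feedback_learner"]


def make_wire_brain() -> MarkovBrain:
    """A single deterministic gate copying sensor 0 to output node 4."""
    gate = DeterministicGate([0], [4], np.array([0, 1]))
    return MarkovBrain([gate])


def make_feedback_learner(delta: float = 0.05, depth: int = 2) -> MarkovBrain:
    """A minimal agent that learns its option-to-action mapping.

    One feedback gate maps the 4-bit one-hot arrow percept straight to
    the 2-bit motor option, starting from uniform rows (it knows
    nothing about the mapping at birth). Three deterministic gates
    build the internal critic:

    * node 6 latches last update's forward-arrow bit,
    * node 7 fires when the percept just *became* forward (the last
      completed action aligned the agent with the path) -> positive
      feedback,
    * node 8 fires when a forward percept was just *lost* -> negative
      feedback.

    Because the percept produced by an action is only visible one
    update later, the causal decision sits at buffer slot 1, so the
    delta schedules put all their weight there. The critic is noisy
    (it also fires on arrow changes the agent did not cause), so a
    small delta -- many weak nudges rather than few large ones --
    learns far more reliably than an aggressive one.
    """
    latch = DeterministicGate([0], [6], np.array([0, 1]))
    # node7 = s0 AND NOT node6 (became forward)
    became = DeterministicGate([0, 6], [7], np.array([0, 1, 0, 0]))
    # node8 = NOT s0 AND node6 (lost forward)
    lost = DeterministicGate([0, 6], [8], np.array([0, 0, 1, 0]))
    P = np.full((16, 4), 0.25)
    deltas = np.zeros(depth)
    if depth > 1:
        deltas[1] = delta
    else:
        deltas[0] = delta
    policy = FeedbackGate(
        input_nodes=[0, 1, 2, 3],
        output_nodes=[4, 5],
        P=P,
        pos_node=7,
        neg_node=8,
        depth=depth,
        delta_pos=deltas.copy(),
        delta_neg=deltas.copy(),
    )
    return MarkovBrain([latch, became, lost, policy])
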