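"""Post-hoc analyses of evolved agents.

The central quantity is the mutual information a probability table
conveys between its input and output patterns, I(I;O) = H(O) - H(O|I)
in bits, with the input marginal taken as uniform over rows (an
empirical row-weighting mode is available). For feedback gates the
lifetime change delta-bar -- the mean difference between end-of-task
and birth-table mutual information across gates and mappings --
quantifies how much information the agent wrote into its tables while
solving the task. The frozen-feedback control re-evaluates an agent
with table updates disabled, isolating how much of its performance
depends on lifetime learning rather than hidden-state working memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .brain import MarkovBrain, set_feedback_enabled
from .environment import (
    DEFAULT_BONUS,
    DEFAULT_T,
    FitnessRecord,
    NOTHING,
    FORWARD,
    fitness,
)

__all__ = [
    "TableSnapshotPair",
    "PerformanceBin",
    "table_mutual_information",
    "delta_mi",
    "collect_snapshot_pairs",
    "frozen_performance",
    "gate_census",
    "action_usage",
    "binned_delta_vs_performance",
]


@dataclass
class TableSnapshotPair:
    """Birth and end-of-lifetime probability tables of one feedback
    gate under one option-to-action mapping."""

    P_birth: np.ndarray
    P_end: np.ndarray
    mapping: int = 0


@dataclass
class PerformanceBin:
    lo: float
    hi: float
    mean_delta: float
    var_delta: float
    n: int

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


def table_mutual_information(
    P: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Mutual information (bits) between input and output patterns of a
    row-stochastic table. Rows are conditional output distributions;
    the input marginal is uniform unless ``weights`` (e.g. row visit
    counts) is given."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("P must be a matrix")
    sums = P.sum(axis=1)
    if (P < 0).any() or not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("P rows must be probability distributions")
    if weights is None:
        w = np.full(P.shape[0], 1.0 / P.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (P.shape[0],) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative, one per row")
        w = w / w.sum()
    marginal = w @ P

    def _h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_cond = float(sum(w[i] * _h(P[i]) for i in range(P.shape[0])))
    return _h(marginal) - h_cond


def delta_mi(pairs: list[TableSnapshotPair], weights=None) -> float:
    """Mean lifetime change in table mutual information,
    MI(P_end) - MI(P_birth), over all gates and mappings."""
    if not pairs:
        raise ValueError("no snapshot pairs")
    deltas = []
    for pair in pairs:
        if np.shape(pair.P_birth) != np.shape(pair.P_end):
            raise ValueError("snapshot pair has mismatched shapes")
        deltas.append(
            table_mutual_information(pair.P_end, weights)
            - table_mutual_information(pair.P_birth, weights)
        )
    return float(np.mean(deltas))


def collect_snapshot_pairs(
    brain: MarkovBrain,
    rng: np.random.Generator,
    T: int = DEFAULT_T,
    b: float = DEFAULT_BONUS,
    n_mappings: int = 24,
) -> tuple[list[TableSnapshotPair], FitnessRecord]:
    """Evaluate the brain on all mappings recording each feedback
    gate's table at birth and at the end of every lifetime."""
    record = fitness(brain, rng, b=b, T=T, n_mappings=n_mappings,
                     record_tables=True)
    pairs = []
    for m in range(n_mappings):
        for g, gate in enumerate(brain.gates):
            if gate.kind != "feedback":
                continue
            R, C = 2 ** gate.n_inputs, 2 ** gate.n_outputs
            pairs.append(
                TableSnapshotPair(
                    P_birth=np.asarray(gate.P_birth).copy(),
                    P_end=record.table_snapshots[m, g, :R, :C].copy(),
                    mapping=m,
                )
            )
    return pairs, record


def frozen_performance(
    brain: MarkovBrain,
    rng: np.random.Generator,
    b: float = DEFAULT_BONUS,
    T: int = DEFAULT_T,
    n_mappings: int = 24,
) -> FitnessRecord:
    """Fitness of the brain with its feedback gates kept from changing
    their probability tables (the frozen-feedback control)."""
    previous = brain.feedback_enabled
    set_feedback_enabled(brain, False)
    try:
        record = fitness(brain, rng, b=b, T=T, n_mappings=n_mappings)
    finally:
        set_feedback_enabled(brain, previous)
    return record


def gate_census(brain: MarkovBrain) -> tuple[int, int, int]:
    """(n_deterministic, n_probabilistic, n_feedback) of a brain."""
    n_det = sum(1 for g in brain.gates if g.kind == "deterministic")
    n_prob = sum(1 for g in brain.gates if g.kind == "probabilistic")
    n_fb = sum(1 for g in brain.gates if g.kind == "feedback")
    return n_det, n_prob, n_fb


def action_usage(traces) -> tuple[float, float, float]:
    """Proportions of (forward, nothing, turn) commands over a set of
    action traces; left and right turns are pooled."""
    actions = np.concatenate(
        [np.asarray(t)[:, 5] if np.asarray(t).ndim == 2 else np.asarray(t)
         for t in traces]
    )
    if actions.size == 0:
        raise ValueError("no actions in traces")
    n = actions.size
    f = float(np.count_nonzero(actions == FORWARD)) / n
    s = float(np.count_nonzero(actions == NOTHING)) / n
    return f, s, 1.0 - f - s


def binned_delta_vs_performance(
    records,
) -> tuple[list[PerformanceBin], float]:
    """Bin (performance, delta-MI) pairs into unit-width performance
    bins and correlate bin centers with bin mean deltas.

    ``records`` is an iterable of (performance, delta) pairs;
    performance is the mean number of goals reached per mapping.
    Returns the non-empty bins and the Pearson correlation
    coefficient. Raises if the correlation is undefined (fewer than
    two distinct performance values, or constant bin means).
    """
    data = np.asarray(list(records), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("need at least two (performance, delta) records")
    perf, delta = data[:, 0], data[:, 1]
    lo = float(np.floor(perf.min()))
    hi = float(np.ceil(perf.max()))
    if hi == lo:
        hi = lo + 1.0
    edges = np.arange(lo, hi + 1.0, 1.0)
    bins: list[PerformanceBin] = []
    for k in range(len(edges) - 1):
        right_closed = k == len(edges) - 2
        mask = (perf >= edges[k]) & (
            (perf <= edges[k + 1]) if right_closed else (perf < edges[k + 1])
        )
        if mask.any():
            bins.append(
                PerformanceBin(
                    float(edges[k]), float(edges[k + 1]),
                    float(delta[mask].mean()),
                    float(delta[mask].var()),
                    int(mask.sum()),
                )
            )
    centers = np.array([b.center for b in bins])
    means = np.array([b.mean_delta for b in bins])
    if len(bins) < 2 or np.allclose(means, means[0]) or np.allclose(centers, centers[0]):
        raise ValueError("correlation undefined: degenerate bins")
    r = float(stats.pearsonr(centers, means).statistic)
    return bins, r
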