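"""The arrow-labeled maze task.

Agents navigate a 64x64 gridworld whose border is walled and whose
interior tiles are walls with probability 1/7. A random empty tile is
the goal; every reachable tile is labeled with the shortest-path
distance to the goal and an arrow toward a neighbor one step closer
(ties broken uniformly at random). Agents spawn on tiles exactly 32
steps from the goal, see only the arrow of the tile they stand on
(rotated into their own frame), and act through one of the 24
bijections between their four 2-bit motor options and the four actions
forward / do-nothing / turn-left / turn-right. The mapping is fixed
per lifetime but unknown to the agent, which is what makes the task a
learning problem rather than a reflex problem.

Fitness multiplies per-mapping scores over all 24 mappings; each
per-mapping score accrues 1/(1+d) per update (d = current distance to
goal) plus a bonus b per goal reached.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import MAZE_SIZE, SPAWN_DISTANCE
from .brain import MarkovBrain

__all__ = [
    "Maze",
    "AgentState",
    "FitnessRecord",
    "MappingResult",
    "ACTION_NAMES",
    "HEADING_NAMES",
    "FORWARD",
    "NOTHING",
    "TURN_LEFT",
    "TURN_RIGHT",
    "enumerate_action_maps",
    "generate_maze",
    "label_maze",
    "random_spawn",
    "sensor_vector",
    "apply_action",
    "evaluate_on_mapping",
    "fitness",
    "replay_evaluation",
    "render_maze",
]

# actions
FORWARD, NOTHING, TURN_LEFT, TURN_RIGHT = 0, 1, 2, 3
ACTION_NAMES = ("forward", "nothing", "turn_left", "turn_right")
# headings / absolute arrow directions; "up" decreases the row index
HEADING_NAMES = ("up", "right", "down", "left")
_DR = (-1, 0, 1, 0)
_DC = (0, 1, 0, -1)

DEFAULT_T = 512
DEFAULT_BONUS = 512.0


@dataclass
class Maze:
    """Wall grid plus goal, distance field, arrow labels, spawn tiles."""

    walls: np.ndarray  # bool (64, 64)
    goal: tuple[int, int]
    dist: np.ndarray  # int16, -1 on walls/unreachable tiles
    arrows: np.ndarray  # int8 absolute directions, -1 where undefined
    spawns: np.ndarray  # (n, 2) tiles with dist == SPAWN_DISTANCE

    @property
    def size(self) -> int:
        return int(self.walls.shape[0])


@dataclass
class AgentState:
    position: tuple[int, int]
    heading: int  # 0=up 1=right 2=down 3=left


def generate_maze(rng: np.random.Generator) -> Maze:
    """Generate a maze, regenerating from scratch until a spawn tile at
    distance 32 exists (raises if the retry cap is ever exhausted)."""
    ok, walls, dist, arrows, goal = _kernel.generate_maze_arrays(rng)
    if not ok:
        raise RuntimeError("maze generation retry cap exceeded")
    spawns = _kernel.spawn_tiles(dist)
    return Maze(
        walls.copy(), (int(goal[0]), int(goal[1])), dist.copy(),
        arrows.copy(), spawns,
    )


def label_maze(
    walls: np.ndarray, goal: tuple[int, int], rng: np.random.Generator | None = None
) -> Maze:
    """Distance-label an explicit wall grid (fixture construction and
    replay rendering). Arrow ties are broken with ``rng`` when given,
    otherwise by the first direction in up/right/down/left order."""
    walls = np.asarray(walls, dtype=bool)
    n = walls.shape[0]
    gr, gc = goal
    if walls[gr, gc]:
        raise ValueError("goal lies on a wall")
    dist = np.full((n, n), -1, dtype=np.int16)
    dist[gr, gc] = 0
    q = deque([(gr, gc)])
    while q:
        r, c = q.popleft()
        for a in range(4):
            rr, cc = r + _DR[a], c + _DC[a]
            if 0 <= rr < n and 0 <= cc < n and not walls[rr, cc] and dist[rr, cc] < 0:
                dist[rr, cc] = dist[r, c] + 1
                q.append((rr, cc))
    arrows = np.full((n, n), -1, dtype=np.int8)
    for r in range(n):
        for c in range(n):
            d = dist[r, c]
            if d <= 0:
                continue
            options = [
                a for a in range(4)
                if 0 <= r + _DR[a] < n and 0 <= c + _DC[a] < n
                and dist[r + _DR[a], c + _DC[a]] == d - 1
            ]
            if rng is None:
                arrows[r, c] = options[0]
            else:
                arrows[r, c] = options[int(rng.integers(0, len(options)))]
    spawns = np.argwhere(dist == SPAWN_DISTANCE).astype(np.int64)
    return Maze(walls, (int(gr), int(gc)), dist, arrows, spawns)


def random_spawn(maze: Maze, rng: np.random.Generator) -> AgentState:
    """Place an agent on a uniformly random spawn-distance tile with a
    uniformly random heading."""
    if maze.spawns.shape[0] == 0:
        raise ValueError("maze has no spawn tiles")
    j = int(rng.integers(0, maze.spawns.shape[0]))
    heading = int(rng.integers(0, 4))
    return AgentState((int(maze.spawns[j, 0]), int(maze.spawns[j, 1])), heading)


def sensor_vector(maze: Maze, agent: AgentState) -> np.ndarray:
    """One-hot 4-bit percept [forward, right, backward, left]: the
    tile's absolute arrow rotated into the agent's frame."""
    r, c = agent.position
    arrow = int(maze.arrows[r, c])
    if arrow < 0:
        raise ValueError(f"tile {agent.position} carries no arrow")
    rel = (arrow - agent.heading) % 4
    out = np.zeros(4, dtype=np.uint8)
    out[rel] = 1
    return out


def apply_action(maze: Maze, agent: AgentState, action: int) -> AgentState:
    """Kinematics: forward advances one tile unless blocked by a wall
    (then a no-op), turns rotate the heading 90 degrees, nothing leaves
    the agent unchanged."""
    r, c = agent.position
    h = agent.heading
    if action == FORWARD:
        rr, cc = r + _DR[h], c + _DC[h]
        if not maze.walls[rr, cc]:
            r, c = rr, cc
    elif action == TURN_LEFT:
        h = (h + 3) % 4
    elif action == TURN_RIGHT:
        h = (h + 1) % 4
    elif action != NOTHING:
        raise ValueError(f"unknown action {action}")
    return AgentState((r, c), h)


def enumerate_action_maps() -> list[tuple[int, int, int, int]]:
    """All 24 bijections from the 2-bit option {00,01,10,11} to the
    four actions, in lexicographic order."""
    return list(itertools.permutations(range(4)))


@dataclass
class MappingResult:
    score: float  # dwell sum + goals * b
    goal_count: int
    trace: np.ndarray  # (T, 7) int32: t, row, col, heading, option, action, d
    maze: Maze


@dataclass
class FitnessRecord:
    """Outcome of a full 24-mapping evaluation (Eq.-style product
    fitness, accumulated in the log domain)."""

    scores: np.ndarray  # (n_mappings,) per-mapping scores
    goals: np.ndarray  # (n_mappings,) goal counts
    action_counts: np.ndarray  # (n_mappings, 4)
    b: float
    T: int
    logW: float = field(init=False)
    traces: np.ndarray | None = None  # (n_mappings, T, 7)
    table_snapshots: np.ndarray | None = None  # (n_mappings, G, 16, 16)

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore"):
            self.logW = float(np.sum(np.log(self.scores)))

    @property
    def W(self) -> float:
        return float(np.exp(self.logW))

    @property
    def mean_goals(self) -> float:
        return float(np.mean(self.goals))


def evaluate_on_mapping(
    brain: MarkovBrain,
    action_map,
    rng: np.random.Generator,
    T: int = DEFAULT_T,
    b: float = DEFAULT_BONUS,
    maze: Maze | None = None,
) -> MappingResult:
    """Reset the brain and run one lifetime under one option-to-action
    mapping (fresh maze unless one is supplied)."""
    brain.reset()
    if maze is None:
        maze = generate_maze(rng)
    amap = np.asarray(action_map, dtype=np.int8)
    trace = np.zeros((T, 7), dtype=np.int32)
    inner, goal_count = _kernel.run_episode(
        *brain._kernel_args(), brain.state, brain.feedback_enabled,
        maze.walls, maze.dist, maze.arrows, maze.spawns,
        amap, T, rng, trace,
    )
    return MappingResult(float(inner) + goal_count * b, int(goal_count), trace, maze)


def fitness(
    brain: MarkovBrain,
    rng: np.random.Generator,
    b: float = DEFAULT_BONUS,
    T: int = DEFAULT_T,
    n_mappings: int = 24,
    record_tables: bool = False,
) -> FitnessRecord:
    """Evaluate the brain on all 24 option-to-action mappings, with the
    brain reset to its birth state before each, and combine the
    per-mapping scores into the product fitness W (kept as log W)."""
    maps = np.asarray(enumerate_action_maps()[:n_mappings], dtype=np.int8)
    n_gates = max(len(brain.gates), 1)
    table_out = np.zeros(
        (maps.shape[0] if record_tables else 1, n_gates, 16, 16), dtype=np.float64
    )
    trace_out = np.zeros((maps.shape[0], T, 7), dtype=np.int32)
    scores, goals, action_counts = _kernel.evaluate_all_mappings(
        *brain._kernel_args()[:7], brain._P_birth, *brain._kernel_args()[7:],
        brain.state, brain.feedback_enabled,
        maps, T, float(b), rng, record_tables, table_out, trace_out,
    )
    if np.isnan(scores).any():
        raise RuntimeError("maze generation failed during evaluation")
    return FitnessRecord(
        scores=scores, goals=goals, action_counts=action_counts,
        b=float(b), T=int(T), traces=trace_out,
        table_snapshots=table_out if record_tables else None,
    )


def replay_evaluation(
    brain: MarkovBrain,
    rng: np.random.Generator,
    T: int = DEFAULT_T,
    b: float = DEFAULT_BONUS,
    n_mappings: int = 24,
) -> list[MappingResult]:
    """Step-for-step equivalent of :func:`fitness` that keeps each
    mapping's maze and trajectory (used to replay archived
    evaluations). Given the same generator state it reproduces the
    exact random draws of :func:`fitness`."""
    results = []
    for amap in enumerate_action_maps()[:n_mappings]:
        brain.reset()
        maze = generate_maze(rng)
        results.append(
            evaluate_on_mapping(brain, amap, rng, T=T, b=b, maze=maze)
        )
    return results


def render_maze(maze: Maze, trace: np.ndarray | None = None) -> str:
    """ASCII picture of a maze: '#' walls, 'G' goal, '.' empty tiles;
    with a trajectory, visited tiles become '*' and the first position
    'S'."""
    n = maze.size
    grid = [
        ["#" if maze.walls[r, c] else "." for c in range(n)] for r in range(n)
    ]
    if trace is not None and len(trace):
        for row in trace:
            grid[int(row[1])][int(row[2])] = "*"
        grid[int(trace[0][1])][int(trace[0][2])] = "S"
    gr, gc = maze.goal
    grid[gr][gc] = "G"
    return "\n".join("".join(row) for row in grid)
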