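"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def bfs_distance_field(walls: np.ndarray, goal: tuple[int, int]) -> np.ndarray:
    """Independent breadth-first distance field (the test oracle),
    written against the raw wall grid only."""
    n_rows, n_cols = walls.shape
    dist = np.full(walls.shape, -1, dtype=np.int32)
    dist[goal] = 0
    queue = deque([goal])
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                if not walls[rr, cc] and dist[rr, cc] < 0:
                    dist[rr, cc] = dist[r, c] + 1
                    queue.append((rr, cc))
    return dist


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def open_maze():
    """A fully open 64x64 maze (border walls only) with a fixed goal,
    labeled deterministically."""
    from markovbrains import label_maze

    walls = np.zeros((64, 64), dtype=bool)
    walls[0, :] = walls[-1, :] = walls[:, 0] = walls[:, -1] = True
    return label_maze(walls, (31, 31))
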