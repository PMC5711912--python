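"""Byte-string genomes for Markov Brains.

A genome is an ordered sequence of byte-valued sites. Genes begin at
two-byte start codons, one codon per gate type, and each gene encodes a
single logic gate (its wiring and its logic table). Mutation acts on
offspring genomes through per-site point mutation and per-genome
stretch duplication / deletion, with hard length bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genome",
    "GeneSpan",
    "GATE_KINDS",
    "START_CODONS",
    "MIN_GENOME_LENGTH",
    "MAX_GENOME_LENGTH",
    "DEFAULT_GENOME_LENGTH",
    "PAYLOAD_LENGTH",
    "random_genome",
    "mutate",
    "find_genes",
    "save_genomes",
    "load_genomes",
]

GATE_KINDS = ("deterministic", "probabilistic", "feedback")

# Two-byte start codons; the second byte is the ones'-complement of the
# first, which makes accidental codons rare in random sequence.
START_CODONS = {
    "deterministic": (42, 213),
    "probabilistic": (43, 212),
    "feedback": (44, 211),
}
_CODON_BY_PAIR = {pair: kind for kind, pair in START_CODONS.items()}

MIN_GENOME_LENGTH = 1_000
MAX_GENOME_LENGTH = 20_000
DEFAULT_GENOME_LENGTH = 5_000

#: Number of payload bytes read (circularly) after a start codon. Large
#: enough for the widest gate: counts + wiring + feedback parameters +
#: a full 16x16 probability table.
PAYLOAD_LENGTH = 288

# How far from the genome end initial codons are kept, so that typical
# payloads do not wrap.
_CODON_END_MARGIN = 200


@dataclass
class Genome:
    """An agent's hereditary material: a byte string plus lineage tags."""

    sites: np.ndarray
    id: int | None = None
    parent_id: int | None = None

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.uint8)
        if self.sites.ndim != 1:
            raise ValueError("genome sites must be one-dimensional")

    def __len__(self) -> int:
        return int(self.sites.size)

    def copy(self) -> "Genome":
        return Genome(self.sites.copy(), id=self.id, parent_id=self.parent_id)


@dataclass
class GeneSpan:
    """One gene: a start codon location plus the raw payload behind it."""

    gate_kind: str
    start: int
    payload: np.ndarray = field(repr=False)


def random_genome(
    length: int,
    rng: np.random.Generator,
    gate_kinds: Sequence[str] = GATE_KINDS,
    n_codons: int = 12,
) -> Genome:
    """Generate a uniformly random genome seeded with start codons.

    ``n_codons`` codon pairs are overwritten at non-overlapping random
    positions, split evenly over ``gate_kinds`` and kept away from the
    genome end so their payloads do not wrap.
    """
    if length < MIN_GENOME_LENGTH:
        raise ValueError(
            f"genome length must be at least {MIN_GENOME_LENGTH}, got {length}"
        )
    for kind in gate_kinds:
        if kind not in START_CODONS:
            raise ValueError(f"unknown gate kind: {kind!r}")
    sites = rng.integers(0, 256, size=length, dtype=np.uint8)

    per_kind = n_codons // len(gate_kinds)
    n_total = per_kind * len(gate_kinds)
    positions: list[int] = []
    limit = length - _CODON_END_MARGIN
    while len(positions) < n_total:
        p = int(rng.integers(0, limit))
        if all(abs(p - q) >= 2 for q in positions):
            positions.append(p)
    for j, p in enumerate(positions):
        kind = gate_kinds[j // per_kind]
        a, b = START_CODONS[kind]
        sites[p] = a
        sites[p + 1] = b
    return Genome(sites)


def mutate(
    genome: Genome,
    rng: np.random.Generator,
    point_rate: float = 0.003,
    dup_prob: float = 0.02,
    del_prob: float = 0.02,
    dup_len: tuple[int, int] = (128, 512),
    del_len: tuple[int, int] = (128, 255),
    min_length: int = MIN_GENOME_LENGTH,
    max_length: int = MAX_GENOME_LENGTH,
) -> Genome:
    """Produce a mutated offspring copy of ``genome``.

    Operators are applied in a fixed order, each rolled once per
    offspring: per-site point mutation, stretch duplication (only below
    ``max_length``), stretch deletion (only above ``min_length``).
    Stretch sizes are clipped so the offspring stays within the length
    bounds.
    """
    sites = genome.sites.copy()

    if point_rate > 0:
        mask = rng.random(sites.size) < point_rate
        n_hits = int(mask.sum())
        if n_hits:
            sites[mask] = rng.integers(0, 256, size=n_hits, dtype=np.uint8)

    length = sites.size
    if dup_prob > 0 and rng.random() < dup_prob and length < max_length:
        d = int(rng.integers(dup_len[0], dup_len[1] + 1))
        d = min(d, max_length - length, length)
        src = int(rng.integers(0, length - d + 1))
        # insertion point chosen outside the copied interval so the copy
        # appears as a distinct second occurrence
        n_slots = length - d + 2
        slot = int(rng.integers(0, n_slots))
        ins = slot if slot <= src else slot + d - 1
        sites = np.concatenate([sites[:ins], sites[src : src + d], sites[ins:]])

    length = sites.size
    if del_prob > 0 and rng.random() < del_prob and length > min_length:
        d = int(rng.integers(del_len[0], del_len[1] + 1))
        d = min(d, length - min_length)
        start = int(rng.integers(0, length - d + 1))
        sites = np.concatenate([sites[:start], sites[start + d :]])

    return Genome(sites, parent_id=genome.id)


def find_genes(
    genome: Genome, kinds: Iterable[str] | None = None
) -> list[GeneSpan]:
    """Scan for start codons and return one :class:`GeneSpan` per hit.

    The scan is left to right over all sites; codon pairs and payloads
    are read circularly, so a gene near the genome end wraps around to
    the beginning. Overlapping genes are allowed. ``kinds`` restricts
    the reported gate kinds (used by the single-gate-type experimental
    conditions).
    """
    allowed = set(GATE_KINDS if kinds is None else kinds)
    sites = genome.sites
    n = sites.size
    spans: list[GeneSpan] = []
    first = int(sites[0]) if n else 0
    for i in range(n):
        a = int(sites[i])
        b = int(sites[i + 1]) if i + 1 < n else first
        kind = _CODON_BY_PAIR.get((a, b))
        if kind is not None and kind in allowed:
            payload = np.take(
                sites, np.arange(i + 2, i + 2 + PAYLOAD_LENGTH), mode="wrap"
            )
            spans.append(GeneSpan(kind, i, payload))
    return spans


def save_genomes(
    path: str | Path,
    genomes: Sequence[Genome],
    generations: Sequence[int] | None = None,
) -> None:
    """Write genomes as plain-text CSV (one genome per row) plus a JSON
    sidecar carrying id / parent_id / generation."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(",".join(str(int(v)) for v in g.sites))
            fh.write("\n")
    meta = [
        {
            "id": g.id,
            "parent_id": g.parent_id,
            "generation": None if generations is None else int(generations[i]),
        }
        for i, g in enumerate(genomes)
    ]
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh)


def load_genomes(path: str | Path) -> list[Genome]:
    """Inverse of :func:`save_genomes`."""
    path = Path(path)
    genomes: list[Genome] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                sites = np.array([int(v) for v in line.split(",")], dtype=np.uint8)
                genomes.append(Genome(sites))
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        for g, m in zip(genomes, meta):
            g.id = m.get("id")
            g.parent_id = m.get("parent_id")
    return genomes
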