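"""Generational evolution: tournament selection, lineage recording,
and line-of-descent reconstruction.

Selection is asexual with complete generational replacement: each of
the N offspring inherits the (mutated) genome of the winner of an
independent size-5 tournament drawn with replacement. Fitness
comparisons use log W so that the 24-factor product fitness never
overflows. Every individual's parent link is archived, which lets the
line of descent (LOD) of any final individual be traced back to
generation 0; all mutations that swept the population lie on the LOD
at or before the most recent common ancestor (MRCA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .brain import build_brain
from .environment import DEFAULT_BONUS, DEFAULT_T, FitnessRecord, fitness
from .genome import (
    DEFAULT_GENOME_LENGTH,
    GATE_KINDS,
    Genome,
    load_genomes,
    mutate,
    random_genome,
    save_genomes,
)

__all__ = [
    "EvolutionConfig",
    "Individual",
    "LineageArchive",
    "LodResult",
    "tournament_select",
    "next_generation",
    "run_evolution",
    "trace_lod",
]


@dataclass
class EvolutionConfig:
    population_size: int = 100
    generations: int = 100
    tournament_size: int = 5
    genome_length: int = DEFAULT_GENOME_LENGTH
    point_rate: float = 0.003
    dup_prob: float = 0.02
    del_prob: float = 0.02
    T: int = DEFAULT_T
    b: float = DEFAULT_BONUS
    n_mappings: int = 24
    seed: int = 0
    gate_kinds: tuple[str, ...] = GATE_KINDS
    record_genomes: bool = True

    def __post_init__(self) -> None:
        if self.tournament_size > self.population_size:
            raise ValueError("tournament_size must not exceed population_size")
        self.gate_kinds = tuple(self.gate_kinds)
        for kind in self.gate_kinds:
            if kind not in GATE_KINDS:
                raise ValueError(f"unknown gate kind {kind!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - valid)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gate_kinds"] = list(self.gate_kinds)
        return d


@dataclass
class Individual:
    genome: Genome
    id: int
    parent_id: int | None
    generation: int
    record: FitnessRecord | None = None
    census: tuple[int, int, int] = (0, 0, 0)  # (n_det, n_prob, n_fb)


class LineageArchive:
    """Append-only ancestry store with per-generation statistics and
    (optionally) full genome snapshots for exact replay."""

    def __init__(self, record_genomes: bool = True):
        self.record_genomes = record_genomes
        self.parents: dict[int, int | None] = {}
        self.generation_of: dict[int, int] = {}
        self.generation_ids: dict[int, list[int]] = {}
        self.rows: list[dict] = []  # one row per individual
        self.stats: list[dict] = []  # one row per generation
        self.genomes: dict[int, np.ndarray] = {}

    def add_individual(self, ind: Individual) -> None:
        if ind.id in self.parents:
            raise ValueError(f"duplicate individual id {ind.id}")
        self.parents[ind.id] = ind.parent_id
        self.generation_of[ind.id] = ind.generation
        self.generation_ids.setdefault(ind.generation, []).append(ind.id)
        rec = ind.record
        self.rows.append(
            {
                "generation": ind.generation,
                "id": ind.id,
                "parent_id": -1 if ind.parent_id is None else ind.parent_id,
                "logW": np.nan if rec is None else rec.logW,
                "mean_goals": np.nan if rec is None else rec.mean_goals,
                "n_det": ind.census[0],
                "n_prob": ind.census[1],
                "n_fb": ind.census[2],
            }
        )
        if self.record_genomes:
            self.genomes[ind.id] = ind.genome.sites.copy()

    def add_generation_stats(self, row: dict) -> None:
        self.stats.append(row)

    @property
    def final_generation(self) -> int:
        return max(self.generation_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def stats_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats)

    def genome_of(self, ind_id: int) -> Genome:
        if ind_id not in self.genomes:
            raise KeyError(f"no genome snapshot for id {ind_id}")
        g = Genome(self.genomes[ind_id].copy(), id=ind_id,
                   parent_id=self.parents[ind_id])
        return g

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "archive.csv", index=False)
        self.stats_dataframe().to_csv(directory / "stats.csv", index=False)
        if self.record_genomes:
            ids = sorted(self.genomes)
            save_genomes(
                directory / "genomes.csv",
                [Genome(self.genomes[i], id=i, parent_id=self.parents[i])
                 for i in ids],
                generations=[self.generation_of[i] for i in ids],
            )

    @classmethod
    def load(cls, directory: str | Path) -> "LineageArchive":
        directory = Path(directory)
        arch = cls(record_genomes=(directory / "genomes.csv").exists())
        df = pd.read_csv(directory / "archive.csv")
        for row in df.itertuples(index=False):
            pid = None if row.parent_id < 0 else int(row.parent_id)
            arch.parents[int(row.id)] = pid
            arch.generation_of[int(row.id)] = int(row.generation)
            arch.generation_ids.setdefault(int(row.generation), []).append(int(row.id))
            arch.rows.append(row._asdict())
        stats_path = directory / "stats.csv"
        if stats_path.exists():
            arch.stats = pd.read_csv(stats_path).to_dict("records")
        if arch.record_genomes:
            for g in load_genomes(directory / "genomes.csv"):
                arch.genomes[g.id] = g.sites
        return arch


def tournament_select(
    population: list[Individual], k: int, rng: np.random.Generator
) -> Individual:
    """Sample ``k`` individuals uniformly with replacement and return
    the fittest (log W); exact ties are broken uniformly at random."""
    if not population:
        raise ValueError("population is empty")
    idx = rng.integers(0, len(population), size=k)
    contenders = [population[int(i)] for i in idx]
    best = max(c.record.logW for c in contenders)
    tied = [c for c in contenders if c.record.logW == best]
    return tied[int(rng.integers(0, len(tied)))] if len(tied) > 1 else tied[0]


def _evaluate(
    ind: Individual, config: EvolutionConfig, rng: np.random.Generator
) -> None:
    brain = build_brain(ind.genome, gate_kinds=config.gate_kinds)
    ind.record = fitness(
        brain, rng, b=config.b, T=config.T, n_mappings=config.n_mappings
    )
    n_det = sum(1 for g in brain.gates if g.kind == "deterministic")
    n_prob = sum(1 for g in brain.gates if g.kind == "probabilistic")
    n_fb = sum(1 for g in brain.gates if g.kind == "feedback")
    ind.census = (n_det, n_prob, n_fb)


def next_generation(
    population: list[Individual],
    config: EvolutionConfig,
    rng: np.random.Generator,
    id_start: int | None = None,
) -> list[Individual]:
    """Produce N offspring by independent tournaments + mutation.
    The returned individuals are unevaluated."""
    if id_start is None:
        id_start = max(ind.id for ind in population) + 1
    generation = population[0].generation + 1
    offspring = []
    for j in range(config.population_size):
        parent = tournament_select(population, config.tournament_size, rng)
        child_genome = mutate(
            parent.genome, rng,
            point_rate=config.point_rate,
            dup_prob=config.dup_prob,
            del_prob=config.del_prob,
        )
        child_genome.id = id_start + j
        child_genome.parent_id = parent.id
        offspring.append(
            Individual(child_genome, id_start + j, parent.id, generation)
        )
    return offspring


def _generation_stats(population: list[Individual], generation: int) -> dict:
    logW = np.array([ind.record.logW for ind in population])
    mean_goals = np.array([ind.record.mean_goals for ind in population])
    best = int(np.argmax(logW))
    counts = np.sum([ind.record.action_counts.sum(axis=0) for ind in population],
                    axis=0).astype(float)
    total = counts.sum()
    frac = counts / total if total > 0 else np.zeros(4)
    census = np.sum([ind.census for ind in population], axis=0)
    return {
        "generation": generation,
        "best_id": population[best].id,
        "best_logW": float(logW[best]),
        "mean_logW": float(np.mean(logW)),
        "best_mean_goals": float(mean_goals[best]),
        "mean_mean_goals": float(np.mean(mean_goals)),
        "frac_forward": float(frac[0]),
        "frac_nothing": float(frac[1]),
        "frac_turn": float(frac[2] + frac[3]),
        "n_det": int(census[0]),
        "n_prob": int(census[1]),
        "n_fb": int(census[2]),
    }


def eval_rng(seed: int, generation: int, index: int) -> np.random.Generator:
    """The named evaluation stream for one individual; replays are
    independent of evaluation order."""
    return np.random.default_rng([seed, 2, generation, index])


def run_evolution(
    config: EvolutionConfig, progress: bool = False
) -> tuple[list[Individual], LineageArchive]:
    """Run the full generational loop, fully reproducible from
    ``config.seed``. Returns the final evaluated population and the
    lineage archive."""
    archive = LineageArchive(record_genomes=config.record_genomes)
    population = []
    for i in range(config.population_size):
        g = random_genome(
            config.genome_length,
            np.random.default_rng([config.seed, 1, i]),
            gate_kinds=config.gate_kinds,
        )
        g.id = i
        population.append(Individual(g, i, None, 0))

    next_id = config.population_size
    iterator = range(config.generations + 1)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="generations")
    for gen in iterator:
        for i, ind in enumerate(population):
            _evaluate(ind, config, eval_rng(config.seed, gen, i))
            archive.add_individual(ind)
        archive.add_generation_stats(_generation_stats(population, gen))
        if gen == config.generations:
            break
        select_rng = np.random.default_rng([config.seed, 3, gen])
        population = next_generation(population, config, select_rng, id_start=next_id)
        next_id += config.population_size
    return population, archive


@dataclass
class LodResult:
    ids: list[int]  # chronological, generation 0 first
    mrca_id: int | None  # None if the final population has not coalesced
    mrca_generation: int | None


def trace_lod(
    archive: LineageArchive, rng: np.random.Generator | None = None
) -> LodResult:
    """Trace the line of descent of a random final-generation
    individual back to generation 0, and locate the most recent common
    ancestor of the whole final population. If the final population
    descends from more than one founder (possible in short runs) the
    MRCA fields are ``None``."""
    final = archive.generation_ids[archive.final_generation]
    pick = final[0] if rng is None else final[int(rng.integers(0, len(final)))]

    lod = [pick]
    cur = pick
    while archive.parents.get(cur) is not None:
        parent = archive.parents[cur]
        if parent not in archive.parents:
            raise ValueError(f"broken parent link: {cur} -> {parent}")
        lod.append(parent)
        cur = parent
    lod.reverse()

    ancestors = set(final)
    mrca_id, mrca_gen = None, None
    gen = archive.final_generation
    while True:
        if len(ancestors) == 1:
            mrca_id = next(iter(ancestors))
            mrca_gen = gen
            break
        if gen == 0:
            break  # multiple founders survive: no common ancestor
        next_ancestors = set()
        for a in ancestors:
            if a not in archive.parents:
                raise ValueError(f"broken parent link: missing ancestor {a}")
            parent = archive.parents[a]
            next_ancestors.add(a if parent is None else parent)
        ancestors = next_ancestors
        gen -= 1
    return LodResult(
        lod,
        None if mrca_id is None else int(mrca_id),
        None if mrca_gen is None else int(mrca_gen),
    )
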