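"""Toroidal-grid population dynamics and experimental protocols.

The population lives on a width x height torus with exactly one
individual per cell (``N`` is fixed).  Generations are synchronous: each
cell is simultaneously replaced by a mutated replicate of a parent drawn
from its 3x3 Moore neighbourhood (self included) by fitness-proportionate
roulette.  A dominant individual can therefore leave at most 9 offspring,
and at least ceil(N/9) distinct parents reproduce each generation.

Protocols
---------
* ``wildtype`` — start from a naive random genome (cloned across the
  grid) under mild mutation rates;
* ``control`` — resume a source population under unchanged rates;
* ``mutator`` — resume a source population with the point-mutation rate
  raised 100-fold, all other rates unchanged;
* ``native_mutator`` — start from naive genomes directly under the
  elevated point rate.

Runs are deterministic under a fixed master seed: generation ``t`` uses
an RNG stream seeded by ``(seed, t)``, and cells are processed in fixed
row-major order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, read_genomes, write_genomes
from .mutation import (
    MutationEvent,
    MutationRates,
    Duplication,
    Inversion,
    LargeDeletion,
    PointMutation,
    SmallDeletion,
    SmallInsertion,
    Translocation,
    _REARR_KINDS,
    _LOCAL_KINDS,
    _RATE_FIELD,
    _draw_local,
    _draw_rearrangement,
    DEFAULT_LENGTH_CEILING,
)
from .phenotype import (
    DEFAULT_GAUSSIANS,
    DEFAULT_K,
    Evaluator,
    N_INTERVALS,
    PhenotypicTarget,
)

__all__ = [
    "ExperimentConfig",
    "GridPopulation",
    "GenerationRecord",
    "RunResult",
    "select_parent",
    "step_generation",
    "run_experiment",
]

#: Moore-neighbourhood offsets (dy, dx), row-major; index 4 is "self".
MOORE_OFFSETS = tuple((dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one run."""

    width: int = 32
    height: int = 32
    rates: MutationRates = field(default_factory=MutationRates.wildtype)
    gaussians: Sequence[tuple[float, float, float]] = DEFAULT_GAUSSIANS
    k: float = DEFAULT_K
    generations: int = 1000
    seed: int = 0
    protocol: str = "wildtype"
    init_genome_length: int = 5000
    n_intervals: int = N_INTERVALS
    length_ceiling: int = DEFAULT_LENGTH_CEILING

    def __post_init__(self):
        if self.protocol not in ("wildtype", "control", "mutator", "native_mutator"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol in ("mutator", "native_mutator"):
            if self.rates == MutationRates.wildtype():
                # convenience: derive the x100 point rate, other rates unchanged
                self.rates = MutationRates.mutator()

    @property
    def n(self) -> int:
        return self.width * self.height

    def make_target(self) -> PhenotypicTarget:
        return PhenotypicTarget(self.gaussians, self.n_intervals)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rates"] = dataclasses.asdict(self.rates)
        d["gaussians"] = [list(g) for g in self.gaussians]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["rates"] = MutationRates(**d["rates"])
        d["gaussians"] = tuple(tuple(g) for g in d["gaussians"])
        return cls(**d)


class GridPopulation:
    """One individual per cell of a toroidal grid (flat row-major storage)."""

    def __init__(
        self,
        genomes: Sequence[Genome],
        width: int,
        height: int,
        evaluator: Evaluator,
        generation: int = 0,
    ):
        if len(genomes) != width * height:
            raise ValueError("need exactly one genome per grid cell")
        self.genomes: list[Genome] = list(genomes)
        self.width = width
        self.height = height
        self.evaluator = evaluator
        self.generation = generation
        self._g: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.width * self.height

    @property
    def g(self) -> np.ndarray:
        """Per-cell metabolic error."""
        if self._g is None:
            self._g = np.array([self.evaluator.error_of(gm) for gm in self.genomes])
        return self._g

    @property
    def fitness(self) -> np.ndarray:
        return np.exp(-self.evaluator.k * self.g)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(gm) for gm in self.genomes], dtype=np.int64)

    def best_cell(self) -> int:
        return int(np.argmin(self.g))

    def clone(self) -> "GridPopulation":
        return GridPopulation(
            list(self.genomes), self.width, self.height, self.evaluator, self.generation
        )


def select_parent(
    grid: GridPopulation, cell: tuple[int, int] | int, rng: np.random.Generator
) -> int:
    """Fitness-proportionate roulette over the cell's Moore neighbourhood.

    Returns the flat index of the chosen parent among the 9 toroidal
    neighbours (self included), each with probability fitness_i / sum_9.
    """
    if isinstance(cell, tuple):
        y, x = cell
    else:
        y, x = divmod(int(cell), grid.width)
    H, W = grid.height, grid.width
    fit = grid.fitness
    neigh = [((y + dy) % H) * W + (x + dx) % W for dy, dx in MOORE_OFFSETS]
    w = fit[neigh]
    cum = np.cumsum(w)
    u = rng.random() * cum[-1]
    return int(neigh[int(np.searchsorted(cum, u, side="right"))])


@dataclass
class GenerationRecord:
    """Per-generation bookkeeping sufficient for lineage replay."""

    generation: int                      # generation index being *produced*
    parents: np.ndarray                  # flat parent cell per child cell
    events: dict[int, list[MutationEvent]]
    g: np.ndarray                        # child metabolic errors
    lengths: np.ndarray                  # child genome lengths

    @property
    def n_distinct_parents(self) -> int:
        return int(np.unique(self.parents).size)


def _select_all_parents(
    grid: GridPopulation, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised Moore-roulette for every cell at once (flat indices)."""
    H, W = grid.height, grid.width
    F = grid.fitness.reshape(H, W)
    idx = np.arange(H * W).reshape(H, W)
    stacks = []
    nidx = []
    for dy, dx in MOORE_OFFSETS:
        stacks.append(np.roll(np.roll(F, -dy, axis=0), -dx, axis=1))
        nidx.append(np.roll(np.roll(idx, -dy, axis=0), -dx, axis=1))
    stack = np.stack(stacks, axis=0)          # (9, H, W)
    nidx = np.stack(nidx, axis=0)
    cum = np.cumsum(stack, axis=0)
    u = rng.random((H, W)) * cum[-1]
    choice = np.sum(u[None, :, :] >= cum, axis=0)
    choice = np.minimum(choice, 8)
    return nidx[choice, np.arange(H)[:, None], np.arange(W)[None, :]].ravel()


def _replicate_with_counts(
    g: Genome,
    counts: dict[str, int],
    rng: np.random.Generator,
    length_ceiling: int,
) -> tuple[Genome, list[MutationEvent]]:
    """Apply a pre-drawn event count schedule (rearrangements first)."""
    schedule: list[str] = []
    for group in (_REARR_KINDS, _LOCAL_KINDS):
        kinds: list[str] = []
        for kind in group:
            kinds.extend([kind] * counts.get(kind, 0))
        if len(kinds) > 1:
            kinds = [kinds[i] for i in rng.permutation(len(kinds))]
        schedule.extend(kinds)
    child = g
    events: list[MutationEvent] = []
    for kind in schedule:
        arr = child.seq
        if kind in _REARR_KINDS:
            if arr.size < 2:
                continue
            ev = _draw_rearrangement(arr, kind, rng, length_ceiling)
        else:
            ev = _draw_local(arr, kind, rng)
        child = ev.apply(child)
        events.append(ev)
    return child, events


def step_generation(
    grid: GridPopulation, cfg: ExperimentConfig, rng: np.random.Generator
) -> tuple[GridPopulation, GenerationRecord]:
    """Advance one synchronous generation (full replacement).

    Every cell is replaced by a mutated replicate of its roulette-selected
    parent; event counts are Binomial(L_parent, rate) per event type.
    """
    N = grid.n
    parents = _select_all_parents(grid, rng)
    parent_lengths = grid.lengths[parents]

    all_kinds = list(_REARR_KINDS + _LOCAL_KINDS)
    counts = np.zeros((len(all_kinds), N), dtype=np.int64)
    for i, kind in enumerate(all_kinds):
        rate = getattr(cfg.rates, _RATE_FIELD[kind])
        if rate > 0:
            counts[i] = rng.binomial(parent_lengths, rate)

    new_genomes: list[Genome] = []
    events: dict[int, list[MutationEvent]] = {}
    total = counts.sum(axis=0)
    for cell in range(N):
        parent_genome = grid.genomes[parents[cell]]
        if total[cell] == 0:
            new_genomes.append(parent_genome)  # genomes are immutable: share
            continue
        cell_counts = {k: int(counts[i, cell]) for i, k in enumerate(all_kinds)}
        try:
            child, evs = _replicate_with_counts(
                parent_genome, cell_counts, rng, cfg.length_ceiling
            )
        except Exception:  # replication failure: copy parent unmutated
            child, evs = parent_genome, []
        new_genomes.append(child)
        if evs:
            events[cell] = evs

    new_grid = GridPopulation(
        new_genomes, grid.width, grid.height, grid.evaluator, grid.generation + 1
    )
    record = GenerationRecord(
        generation=new_grid.generation,
        parents=parents.astype(np.int32),
        events=events,
        g=new_grid.g.copy(),
        lengths=new_grid.lengths,
    )
    return new_grid, record


# ---------------------------------------------------------------------------
# whole runs


class RunResult:
    """A completed run: config, initial genomes, per-generation records."""

    def __init__(
        self,
        config: ExperimentConfig,
        initial_genomes: list[Genome],
        records: list[GenerationRecord],
        population: GridPopulation,
        initial_g: np.ndarray,
    ):
        self.config = config
        self.initial_genomes = initial_genomes
        self.records = records
        self.population = population
        self.initial_g = initial_g

    @property
    def generations(self) -> int:
        return len(self.records)

    def stats(self) -> pd.DataFrame:
        """Per-generation summary table (generation 0 = initial state)."""
        rows = [
            {
                "generation": 0,
                "mean_g": float(self.initial_g.mean()),
                "best_g": float(self.initial_g.min()),
                "mean_length": float(np.mean([len(g) for g in self.initial_genomes])),
                "n_distinct_parents": self.config.n,
            }
        ]
        for rec in self.records:
            rows.append(
                {
                    "generation": rec.generation,
                    "mean_g": float(rec.g.mean()),
                    "best_g": float(rec.g.min()),
                    "mean_length": float(rec.lengths.mean()),
                    "n_distinct_parents": rec.n_distinct_parents,
                }
            )
        return pd.DataFrame(rows)

    # -- persistence --------------------------------------------------------
    def save(self, run_dir: str | Path) -> Path:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        with open(run_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        self.stats().to_csv(run_dir / "stats.tsv", sep="\t", index=False)
        with open(run_dir / "initial_population.fa", "w") as fh:
            write_genomes(
                fh, ((f"cell={i} gen=0", g) for i, g in enumerate(self.initial_genomes))
            )
        with open(run_dir / "final_population.fa", "w") as fh:
            write_genomes(
                fh,
                (
                    (f"cell={i} gen={self.population.generation}", g)
                    for i, g in enumerate(self.population.genomes)
                ),
            )
        np.savetxt(
            run_dir / "parents.tsv",
            np.stack([r.parents for r in self.records]),
            fmt="%d",
            delimiter="\t",
        )
        with open(run_dir / "events.jsonl", "w") as fh:
            for rec in self.records:
                for cell, evs in sorted(rec.events.items()):
                    for ev in evs:
                        fh.write(json.dumps(_event_to_json(rec.generation, cell, ev)) + "\n")
        np.savetxt(
            run_dir / "errors.tsv",
            np.stack([self.initial_g] + [r.g for r in self.records]),
            delimiter="\t",
        )
        return run_dir

    @classmethod
    def load(cls, run_dir: str | Path) -> "RunResult":
        run_dir = Path(run_dir)
        with open(run_dir / "config.yaml") as fh:
            config = ExperimentConfig.from_dict(yaml.safe_load(fh))
        with open(run_dir / "initial_population.fa") as fh:
            initial = [g for _, g in read_genomes(fh)]
        with open(run_dir / "final_population.fa") as fh:
            final = [g for _, g in read_genomes(fh)]
        parents = np.loadtxt(run_dir / "parents.tsv", dtype=np.int32, delimiter="\t", ndmin=2)
        errors = np.loadtxt(run_dir / "errors.tsv", delimiter="\t", ndmin=2)
        events_by_gen: dict[int, dict[int, list[MutationEvent]]] = {}
        ev_path = run_dir / "events.jsonl"
        if ev_path.exists():
            with open(ev_path) as fh:
                for line in fh:
                    gen, cell, ev = _event_from_json(json.loads(line))
                    events_by_gen.setdefault(gen, {}).setdefault(cell, []).append(ev)
        evaluator = Evaluator(config.make_target(), k=config.k)
        pop = GridPopulation(final, config.width, config.height, evaluator,
                             generation=parents.shape[0])
        records = []
        for t in range(parents.shape[0]):
            lengths = np.zeros(config.n, dtype=np.int64)
            records.append(
                GenerationRecord(
                    generation=t + 1,
                    parents=parents[t],
                    events=events_by_gen.get(t + 1, {}),
                    g=errors[t + 1],
                    lengths=lengths,
                )
            )
        return cls(config, initial, records, pop, errors[0])


_EVENT_TYPES = {
    "point": PointMutation,
    "small_insertion": SmallInsertion,
    "small_deletion": SmallDeletion,
    "duplication": Duplication,
    "large_deletion": LargeDeletion,
    "translocation": Translocation,
    "inversion": Inversion,
}


def _event_to_json(gen: int, cell: int, ev: MutationEvent) -> dict:
    d = {k: v for k, v in ev.__dict__.items() if not k.startswith("_")}
    if "payload" in d:
        d["payload"] = list(d["payload"])
    d.update(gen=gen, cell=cell, kind=ev.kind)
    return d


def _event_from_json(d: dict) -> tuple[int, int, MutationEvent]:
    d = dict(d)
    gen = d.pop("gen")
    cell = d.pop("cell")
    cls = _EVENT_TYPES[d.pop("kind")]
    if "payload" in d:
        d["payload"] = tuple(d["payload"])
    return gen, cell, cls(**d)


def run_experiment(
    cfg: ExperimentConfig,
    source: GridPopulation | None = None,
    run_dir: str | Path | None = None,
    progress: bool = False,
) -> RunResult:
    """Execute one protocol at the configured scale.

    ``wildtype`` and ``native_mutator`` start from a fresh naive genome
    cloned across the grid; ``control`` and ``mutator`` resume from the
    ``source`` population (its genomes are copied, then evolution
    continues under the protocol's rates).
    """
    target = cfg.make_target()
    evaluator = Evaluator(target, k=cfg.k)

    if cfg.protocol in ("wildtype", "native_mutator"):
        from .fixtures import make_naive_genome

        rng0 = np.random.Generator(np.random.PCG64(np.random.SeedSequence((cfg.seed, 0xA11CE))))
        naive = make_naive_genome(cfg.init_genome_length, rng0)
        genomes = [naive] * cfg.n
    else:
        if source is None:
            raise ValueError(f"protocol {cfg.protocol!r} requires a source population")
        if source.n != cfg.n:
            raise ValueError("source population does not match the configured grid")
        genomes = list(source.genomes)

    grid = GridPopulation(genomes, cfg.width, cfg.height, evaluator)
    initial_genomes = list(genomes)
    initial_g = grid.g.copy()

    records: list[GenerationRecord] = []
    for t in range(cfg.generations):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((cfg.seed, t))))
        grid, rec = step_generation(grid, cfg, rng)
        records.append(rec)
        if progress and (t + 1) % 100 == 0:
            print(f"  gen {t + 1}/{cfg.generations}  mean_g={rec.g.mean():.5f}")

    result = RunResult(cfg, initial_genomes, records, grid, initial_g)
    if run_dir is not None:
        result.save(run_dir)
    return result
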