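"""Desk-scale experiment presets.

The published-scale protocol (32x32 grid, 300,000 pre-evolution
generations, 100,000-generation propagations, 100 mutator replicates) is
cluster work.  These presets reproduce the protocol's *structure* at
desk scale, in the minutes range on one CPU:

* an 8x8 grid (N = 64);
* a well-adapted cloning ancestor built by inverse design
  (:func:`~digevol.fixtures.make_adapted_genome`, error comparable to
  the published wild types) and polished to a point-mutation local
  optimum, then equilibrated for a few hundred generations under mild
  rates so the population carries its own mutational history;
* clone propagations of a few thousand generations under control
  (unchanged) or mutator (x100 point rate) conditions.

Selection intensity is ``k = 50`` at this scale: with the published
default of 1000 and only 64 individuals, every encodable deleterious
step has a selection coefficient far above 1/N, the ratchet cannot
operate and no mutational burden can exist; k = 50 places the desk
system in the regime the full-scale experiments exhibit — stable
wild-type lineages at mild rates, an operating Muller's ratchet under
the mutator rate.  All analyses are scale-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import Lineage, reconstruct_lineage
from .evolution import ExperimentConfig, GridPopulation, RunResult, run_experiment
from .fixtures import make_adapted_genome, polish_genome
from .mutation import MutationRates
from .phenotype import Evaluator

__all__ = [
    "DESK_GRID",
    "DESK_K",
    "DESK_FOUNDER_BP",
    "DESK_EQUILIBRATION_GENERATIONS",
    "DESK_CLONE_GENERATIONS",
    "desk_config",
    "make_preevolved_population",
    "CloneOutcome",
    "run_clone_protocol",
]

DESK_GRID = (8, 8)
DESK_K = 50.0
DESK_FOUNDER_BP = 1000           # naive founders in from-scratch runs
DESK_EQUILIBRATION_GENERATIONS = 500
DESK_CLONE_GENERATIONS = 4000
DESK_LENGTH_CEILING = 16_000


def desk_config(
    protocol: str,
    seed: int,
    generations: int,
) -> ExperimentConfig:
    """An :class:`ExperimentConfig` at desk scale for any protocol."""
    if protocol in ("mutator", "native_mutator"):
        rates = MutationRates.mutator()
    else:
        rates = MutationRates.wildtype()
    return ExperimentConfig(
        width=DESK_GRID[0],
        height=DESK_GRID[1],
        rates=rates,
        k=DESK_K,
        generations=generations,
        seed=seed,
        protocol=protocol,
        init_genome_length=DESK_FOUNDER_BP,
        length_ceiling=DESK_LENGTH_CEILING,
    )


def make_preevolved_population(
    seed: int,
    generations: int = DESK_EQUILIBRATION_GENERATIONS,
) -> RunResult:
    """A wild-type-like source population for clone protocols.

    Builds the inverse-designed near-target ancestor, polishes it to a
    point-mutation local optimum, clones it across the desk grid and
    equilibrates under wild-type rates.
    """
    rng = np.random.default_rng(seed)
    founder, _ = make_adapted_genome(rng)
    cfg = desk_config("control", seed, generations)
    evaluator = Evaluator(cfg.make_target(), k=cfg.k)
    founder, _ = polish_genome(founder, evaluator, rng)
    source = GridPopulation([founder] * cfg.n, cfg.width, cfg.height, evaluator)
    return run_experiment(cfg, source=source)


@dataclass
class CloneOutcome:
    """Directional summary of one cloned propagation."""

    run: RunResult
    lineage: Lineage
    origin_g: float
    peak_g: float              # worst windowed-median error along the lineage
    final_g: float
    origin_essential: int
    final_essential: int
    origin_nonessential: int
    final_nonessential: int
    late_population_mean_g: float
    late_lineage_mean_g: float

    @property
    def burden_rose(self) -> bool:
        return self.peak_g > self.origin_g

    @property
    def recovered_from_peak(self) -> bool:
        return self.final_g < self.peak_g

    @property
    def essential_shrank(self) -> bool:
        return self.final_essential < self.origin_essential

    @property
    def nonessential_grew(self) -> bool:
        return self.final_nonessential > self.origin_nonessential

    @property
    def population_lags_lineage(self) -> bool:
        return self.late_population_mean_g > self.late_lineage_mean_g


def run_clone_protocol(
    source: RunResult | GridPopulation,
    seed: int,
    protocol: str = "mutator",
    generations: int = DESK_CLONE_GENERATIONS,
    window: int = 100,
) -> CloneOutcome:
    """Propagate a clone of a pre-evolved population and summarise it.

    The summary captures the directional observables of the full-scale
    experiments: mutational burden (worst windowed-median lineage error
    vs. the clone origin), recovery from the peak, essential-compartment
    streamlining, non-essential inflation, and the late-run gap between
    population-mean and lineage error.
    """
    pop = source.population if isinstance(source, RunResult) else source
    cfg = desk_config(protocol, seed, generations)
    run = run_experiment(cfg, source=pop)
    lineage = reconstruct_lineage(run)
    g = lineage.g_series()

    tail = max(1, generations // 5)
    pop_mean = np.array([rec.g.mean() for rec in run.records[-tail:]])

    first, last = lineage.records[0], lineage.records[-1]
    return CloneOutcome(
        run=run,
        lineage=lineage,
        origin_g=float(g[0]),
        peak_g=lineage.worst_error(window=window),
        final_g=float(g[-1]),
        origin_essential=first.essential_bp,
        final_essential=last.essential_bp,
        origin_nonessential=first.nonessential_bp,
        final_nonessential=last.nonessential_bp,
        late_population_mean_g=float(pop_mean.mean()),
        late_lineage_mean_g=float(g[-tail:].mean()),
    )
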