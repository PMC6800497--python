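"""Measurement layer: lineages, genome compartments, mutational neighborhoods.

* :func:`reconstruct_lineage` backtracks the line of descent of the
  fittest final individual and replays its mutational events from the
  origin genome (bit-exact), yielding per-generation error, genome length
  and essential / non-essential compartment sizes.
* :func:`quantify_compartments` splits a genome into the *essential*
  compartment (promoters and terminators of coding RNAs, initiation
  motifs and ORFs — positions whose mutation generally alters the
  phenotype) and the *non-essential* remainder, where point mutations are
  neutral but whose mere presence scales rearrangement counts and sizes.
* :func:`sample_neighborhood` draws mutant offspring with the very
  replication procedure of the evolutionary runs and records the
  offspring-minus-parent error differences (the local fitness-landscape
  profile); :func:`bin_deltas` bins them into the standard 7-bin
  deleterious scheme or a 6-bin scheme with a beneficial bin.
* :func:`reduce_noncoding` shrinks the non-essential compartment to a
  requested size by randomly deleting single bases, keeping only
  deletions that leave the metabolic error bit-identical.
* :func:`wilcoxon_paired` is the exact two-sided signed-rank test used
  for paired before/after comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, AnnotationParams, DEFAULT_PARAMS, annotate
from .evolution import RunResult
from .genome import Genome, splice
from .mutation import Duplication, MutationEvent, MutationRates, replicate_genome
from .phenotype import Evaluator, Individual, PhenotypicTarget

__all__ = [
    "CompartmentStats",
    "LineageRecord",
    "Lineage",
    "NeighborhoodProfile",
    "quantify_compartments",
    "reconstruct_lineage",
    "duplication_effects",
    "sample_neighborhood",
    "bin_deltas",
    "reduce_noncoding",
    "wilcoxon_paired",
    "FIG6_LABELS",
    "FIG5_LABELS",
]


# ---------------------------------------------------------------------------
# genome compartments


@dataclass(frozen=True)
class CompartmentStats:
    """Aggregate genome-structure measures of one individual."""

    total_bp: int
    essential_bp: int
    nonessential_bp: int
    n_rnas: int
    n_coding_rnas: int
    n_genes: int

    @property
    def coding_fraction(self) -> float:
        return self.essential_bp / self.total_bp


def quantify_compartments(ind: Individual | Annotation | Genome,
                          params: AnnotationParams = DEFAULT_PARAMS) -> CompartmentStats:
    """Essential / non-essential split plus RNA and gene counts."""
    if isinstance(ind, Individual):
        ann = ind.annotation
    elif isinstance(ind, Genome):
        ann = annotate(ind, params)
    else:
        ann = ind
    total = len(ann.genome)
    essential = ann.essential_bp()
    return CompartmentStats(
        total_bp=total,
        essential_bp=essential,
        nonessential_bp=total - essential,
        n_rnas=ann.n_rnas,
        n_coding_rnas=ann.n_coding_rnas,
        n_genes=ann.n_genes,
    )


# ---------------------------------------------------------------------------
# lineage reconstruction


@dataclass
class LineageRecord:
    """One ancestor on the line of descent."""

    generation: int
    cell: int
    parent_cell: int
    events: list[MutationEvent]
    genome: Genome
    g: float
    genome_length: int
    essential_bp: int = -1

    @property
    def nonessential_bp(self) -> int:
        return self.genome_length - self.essential_bp if self.essential_bp >= 0 else -1


@dataclass
class Lineage:
    """Line of descent from the run origin to the fittest final individual."""

    records: list[LineageRecord]
    fixation_buffer_start: int   # generations >= this are possibly unfixed

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fixed_records(self) -> list[LineageRecord]:
        return [r for r in self.records if r.generation < self.fixation_buffer_start]

    def g_series(self) -> np.ndarray:
        return np.array([r.g for r in self.records])

    def worst_error(self, window: int = 100) -> float:
        """Worst per-window median of the error along the lineage.

        The windowed median excludes extreme errors that are compensated
        within a few generations.
        """
        g = self.g_series()
        medians = [
            float(np.median(g[i : i + window])) for i in range(0, g.size, window)
        ]
        return max(medians)

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "g": [r.g for r in self.records],
                "genome_length": [r.genome_length for r in self.records],
                "essential_bp": [r.essential_bp for r in self.records],
                "nonessential_bp": [r.nonessential_bp for r in self.records],
                "n_events": [len(r.events) for r in self.records],
            }
        )


def reconstruct_lineage(
    run: RunResult | str | Path,
    final_generation: int | None = None,
    fixation_buffer: float | int = 0.1,
    compute_compartments: bool = True,
) -> Lineage:
    """Backtrack the fittest final individual to the run origin and replay.

    ``fixation_buffer`` marks a trailing window excluded from fixed-event
    analyses: a fraction of the run length if < 1, else an absolute
    number of generations.
    """
    if not isinstance(run, RunResult):
        run = RunResult.load(run)
    n_gen = run.generations
    if final_generation is None:
        final_generation = n_gen
    if not 0 < final_generation <= n_gen:
        raise ValueError(f"final_generation must be in (0, {n_gen}]")

    last = run.records[final_generation - 1]
    cell = int(np.argmin(last.g))

    # walk the parent chain backwards
    chain: list[tuple[int, int, int]] = []  # (generation, cell, parent_cell)
    c = cell
    for t in range(final_generation - 1, -1, -1):
        rec = run.records[t]
        if rec.parents.size != run.config.n:
            raise ValueError(f"broken parent chain at generation {t + 1}")
        p = int(rec.parents[c])
        chain.append((t + 1, c, p))
        c = p
    chain.reverse()
    origin_cell = chain[0][2]

    evaluator = run.population.evaluator
    params = evaluator.params
    genome = run.initial_genomes[origin_cell]
    records: list[LineageRecord] = []

    def compartments(gm: Genome) -> int:
        return annotate(gm, params).essential_bp()

    rec0 = LineageRecord(
        generation=0,
        cell=origin_cell,
        parent_cell=-1,
        events=[],
        genome=genome,
        g=evaluator.error_of(genome),
        genome_length=len(genome),
        essential_bp=compartments(genome) if compute_compartments else -1,
    )
    records.append(rec0)
    prev_essential = rec0.essential_bp
    for gen, c, p in chain:
        evs = run.records[gen - 1].events.get(c, [])
        new_genome = genome
        for ev in evs:
            new_genome = ev.apply(new_genome)
        if compute_compartments:
            essential = prev_essential if not evs and new_genome is genome else \
                compartments(new_genome)
        else:
            essential = -1
        genome = new_genome
        prev_essential = essential
        records.append(
            LineageRecord(
                generation=gen,
                cell=c,
                parent_cell=p,
                events=list(evs),
                genome=genome,
                g=evaluator.error_of(genome),
                genome_length=len(genome),
                essential_bp=essential,
            )
        )

    # replay contract: the reconstructed ancestor must equal the stored one
    if final_generation == n_gen:
        stored = run.population.genomes[cell]
        if stored != genome:
            raise RuntimeError("lineage replay does not reproduce the final genome")

    if fixation_buffer < 1:
        buffer_gens = int(round(fixation_buffer * final_generation))
    else:
        buffer_gens = int(fixation_buffer)
    return Lineage(records, fixation_buffer_start=final_generation - buffer_gens)


def duplication_effects(
    lineage: Lineage,
    evaluator: Evaluator,
    include_buffer: bool = False,
) -> list[tuple[int, Duplication, float]]:
    """Error change of every fixed large duplication on the line of descent.

    For each duplication the genome immediately before and after that
    single event is reconstructed within the replication's event order;
    returns ``(generation, event, delta_g)`` triples.
    """
    out = []
    for i, rec in enumerate(lineage.records[1:], start=1):
        if not rec.events:
            continue
        if not include_buffer and rec.generation >= lineage.fixation_buffer_start:
            continue
        genome = lineage.records[i - 1].genome
        for ev in rec.events:
            after = ev.apply(genome)
            if isinstance(ev, Duplication) and not ev.rejected:
                dg = evaluator.error_of(after) - evaluator.error_of(genome)
                out.append((rec.generation, ev, float(dg)))
            genome = after
        if genome != rec.genome:
            raise RuntimeError(f"replay mismatch at generation {rec.generation}")
    return out


# ---------------------------------------------------------------------------
# mutational neighborhood


@dataclass
class NeighborhoodProfile:
    """Offspring error differences around one genotype."""

    parent_g: float
    deltas: np.ndarray
    rates: MutationRates
    scheme: str = "raw"

    @property
    def R(self) -> int:
        return int(self.deltas.size)

    def fraction_neutral(self, eps: float = 0.0) -> float:
        return float(np.mean(np.abs(self.deltas) <= eps))

    def fraction_beneficial(self, eps: float = 0.0) -> float:
        return float(np.mean(self.deltas < -eps))

    def fraction_deleterious(self, eps: float = 0.0) -> float:
        return float(np.mean(self.deltas > eps))


def sample_neighborhood(
    ind: Individual | Genome,
    rates: MutationRates,
    R: int,
    rng: np.random.Generator,
    evaluator: Evaluator | None = None,
) -> NeighborhoodProfile:
    """Draw R offspring with the run's replication procedure; record delta g.

    The offspring error distribution is the local structure of the
    fitness landscape around the parent (it depends on the mutation
    rates, genome length and genome organisation, not just on the coding
    content).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    genome = ind.genome if isinstance(ind, Individual) else ind
    if evaluator is None:
        target = ind.target if isinstance(ind, Individual) else PhenotypicTarget()
        evaluator = Evaluator(target)
    parent_g = evaluator.error_of(genome)
    deltas = np.zeros(R)
    for i in range(R):
        child, events = replicate_genome(genome, rates, rng)
        if events:
            deltas[i] = evaluator.error_of(child) - parent_g
    return NeighborhoodProfile(parent_g=parent_g, deltas=deltas, rates=rates)


FIG6_LABELS = (
    "neutral", "(0,0.002]", "(0.002,0.004]", "(0.004,0.006]",
    "(0.006,0.008]", "(0.008,0.01]", ">0.01",
)
FIG5_LABELS = (
    "beneficial", "neutral", "(0,0.00025]", "(0.00025,0.0005]",
    "(0.0005,0.001]", ">0.001",
)


def bin_deltas(
    profile: NeighborhoodProfile, scheme: str = "fig6", eps: float = 0.0
) -> tuple[tuple[str, ...], np.ndarray]:
    """Bin a neighborhood profile; counts always sum to R.

    ``fig6``: 7 bins — neutral (|dg| <= eps; the rare beneficial
    offspring are folded in here), five 0.002-wide intermediately
    deleterious bins up to 0.01, and all heavily deleterious offspring
    (dg > 0.01).  ``fig5``: 6 bins — beneficial (dg < -eps), neutral, and
    deleterious bins with edges 0.00025, 0.0005, 0.001 (provisional,
    config-overridable).
    """
    d = profile.deltas
    if scheme == "fig6":
        edges = [0.002, 0.004, 0.006, 0.008, 0.01]
        counts = [np.sum(d <= eps)]
        lo = eps
        for hi in edges:
            counts.append(np.sum((d > lo) & (d <= hi)))
            lo = hi
        counts.append(np.sum(d > edges[-1]))
        return FIG6_LABELS, np.array(counts, dtype=np.int64)
    if scheme == "fig5":
        edges = [0.00025, 0.0005, 0.001]
        counts = [np.sum(d < -eps), np.sum(np.abs(d) <= eps)]
        lo = eps
        for hi in edges:
            counts.append(np.sum((d > lo) & (d <= hi)))
            lo = hi
        counts.append(np.sum(d > edges[-1]))
        return FIG5_LABELS, np.array(counts, dtype=np.int64)
    raise ValueError(f"unknown binning scheme {scheme!r}")


# ---------------------------------------------------------------------------
# genetic engineering


def reduce_noncoding(
    ind: Individual,
    target_nonessential_bp: int,
    rng: np.random.Generator,
) -> Individual:
    """Shrink the non-essential compartment to a requested size, neutrally.

    Single bases are removed at random positions; a removal is kept only
    if the metabolic error of the edited genome is *bit-identical* to the
    original (otherwise the base is restored and another one is tried).
    Candidate positions are drawn from the current non-essential
    compartment.  Raises if the target cannot be reached, reporting the
    length achieved.
    """
    evaluator = Evaluator(ind.target, ind.params, ind.k)
    g0 = evaluator.error_of(ind.genome)
    genome = ind.genome
    ann = annotate(genome, ind.params)

    def noness(a: Annotation) -> np.ndarray:
        return np.nonzero(~a.essential_mask())[0]

    current = noness(ann)
    if target_nonessential_bp > current.size:
        raise ValueError(
            f"target {target_nonessential_bp} exceeds current non-essential "
            f"length {current.size}"
        )
    while current.size > target_nonessential_bp:
        accepted = False
        for pos in rng.permutation(current):
            trial = splice(genome, int(pos), 1)
            if evaluator.error_of(trial) == g0:
                genome = trial
                ann = annotate(genome, ind.params)
                current = noness(ann)
                accepted = True
                break
        if not accepted:
            raise RuntimeError(
                "non-essential reduction stalled: no neutral single-base "
                f"removal left at non-essential length {current.size} "
                f"(target {target_nonessential_bp})"
            )
    out = Individual(genome, ind.target, ind.params, ind.k)
    return out


# ---------------------------------------------------------------------------
# paired statistics


def wilcoxon_paired(before, after) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired values."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must have equal length")
    if before.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = after - before
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; test is degenerate")
        return 0.0, 1.0
    try:
        res = stats.wilcoxon(after, before, alternative="two-sided", method="exact")
    except ValueError:
        res = stats.wilcoxon(after, before, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
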