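# Methods

## The model

`digevol` simulates asexual populations of virtual organisms whose
genotype-to-phenotype map is itself free to evolve. Each individual
carries a **circular double-stranded binary genome** (only the leading
strand is stored; the lagging strand is its base-wise complement read in
reverse). The genome is decoded in three stages:

1. **Transcription.** Every 22-bp window on either strand within
   Hamming distance `d ≤ d_max` of a promoter consensus starts an RNA
   with expression level `e = 1 − d/(d_max+1)`; transcription runs from
   the first base after the promoter to the end of the first
   *terminator* — an 11-bp window able to form a hairpin with a 4-bp
   stem and 3-bp loop (`t[10−j] = 1 − t[j]` for `j = 0..3`).
2. **Translation.** Within a transcript, every Ribosome Binding Site
   (`011011`) followed by a 4-bp spacer and the START codon `000` opens
   a reading frame of consecutive 3-bit codons, closed by the first
   in-frame STOP codon `001`; frames whose STOP lies outside the
   transcript are discarded. One RNA may carry several genes (an
   operon) and one gene may sit on several RNAs; each (RNA, gene) pair
   contributes one protein instance scaled by that RNA's `e`.
3. **Protein folding.** The six non-signal codons encode six amino
   acids, paired into classes M, W and H. Within a gene, the bits of
   each class are collected in order, decoded as a reflected-binary
   (Gray) code and normalised: `m = v_M/(2^n−1)` (trait position),
   `w = w_max · v_W/(2^n−1)` (pleiotropy half-width), `h = 2·v_H/(2^n−1) − 1`
   (contribution height). An empty class yields fraction 0, so a gene
   missing a class is deterministically non-functional rather than
   undefined.

The **phenotype** is built on the trait axis [0, 1]: each functional
protein (`w > 0`, `h ≠ 0`) is a triangle `x ↦ e·h·max(0, 1 − |x−m|/w)`;
activating (h > 0) and inhibiting (h < 0) contributions are summed
separately, each capped at 1, and the phenotype is their difference
floored at 0. The **environment** is the optimal phenotypic function: a
sum of three Gaussians — heights 1.2, −1.4, 0.3, means 0.5, 0.52, 0.8,
standard deviations 0.12, 0.07, 0.03 — clipped to [0, 1]. The
**metabolic error** `g` is `∫₀¹ |P(x) − T(x)| dx` and fitness is
`exp(−k·g)`; lower error means fitter.

**Mutation.** During replication a genome draws, per event type, a
Binomial(`L_parent`, rate) number of events: point mutations (single-bit
flips), small insertions/deletions of 1–6 bp, and four chromosomal
rearrangements — duplications, large deletions, translocations
(reinserted inverted with probability ½) and inversions — acting on the
circular arc between two uniformly drawn breakpoints (expected length
L/2). Rearrangements are applied first in random interleaved order, then
local events, with positions drawn on the genome as it currently stands.
Default rates are 10⁻⁶ per bp per generation for local events and 10⁻⁵
for rearrangements; the *mutator* condition raises the point rate
100-fold to 10⁻⁴, all other rates unchanged. Because event counts are
binomial in genome length, non-coding sequence — though phenotypically
silent under point mutation — increases the number and mean size of
rearrangements: genome structure sets mutational robustness.

**Population dynamics.** `N` individuals occupy a toroidal grid, one per
cell. Generations are synchronous with full replacement: each cell picks
a parent from its 3×3 Moore neighbourhood (self included) by
fitness-proportionate roulette. A dominant individual leaves at most 9
offspring, and at least ⌈N/9⌉ distinct parents reproduce each
generation — the soft, kin-local competition that matters for the
antirobustness dynamics below.

## Genome compartments

The **essential** compartment is the union of the promoters and
terminators of coding RNAs, each gene's initiation motif (RBS + spacer)
and its ORF from START through STOP inclusive, overlaps counted once.
Everything else — non-transcribed sequence, non-coding RNAs, RNA leaders
and trailers — is **non-essential**: a point mutation there is neutral
unless it spontaneously creates a new gene. Non-essential length still
feeds the rearrangement pressure, which is what couples genome
architecture to evolvability.

## Measurement layer

* **Lineage reconstruction** backtracks the fittest final individual
  through the per-generation parent grid to the run origin and replays
  its logged mutational events; replay must reproduce the stored final
  genome bit-exactly or the reconstruction errors out. A trailing
  fixation buffer (10 % of the run at desk scale) is excluded from
  fixed-event analyses. The "worst error along the lineage" statistic
  takes the maximum of per-window medians (window 100 generations) so
  that strongly deleterious mutations that are compensated within a few
  generations do not dominate.
* **Duplication effects** re-evaluate the genome immediately before and
  after every fixed large duplication inside the replication's event
  order, yielding exact Δg per event.
* **Mutational neighborhoods** draw R offspring with the very
  replication procedure of the runs and record Δg per offspring. Binning
  schemes: `fig6` (7 bins — exactly neutral, five 0.002-wide
  intermediately deleterious bins up to 0.01, and Δg > 0.01; the rare
  beneficial offspring are folded into the first bin so counts conserve
  R) and `fig5` (6 bins — beneficial, neutral, and deleterious bins with
  provisional edges 0.00025 / 0.0005 / 0.001, overridable since only two
  of the published edges are printed).
* **Neutral genome reduction** removes random single bases from the
  non-essential compartment, keeping a removal only when the metabolic
  error is *bit-identical* (identical code path, exact float equality),
  until the non-essential length reaches a requested value. Candidates
  are drawn from the current non-essential positions — an essential
  removal would almost surely be rejected anyway, so this only saves
  trials.
* **Paired statistics** use the exact two-sided Wilcoxon signed-rank
  test (scipy's exact method; verified in the tests against brute-force
  enumeration of all 2ⁿ sign patterns for n ≤ 12).

## Synthetic genomes

* `make_naive_genome` rejection-samples uniform random sequences until
  the decoder finds a gene. The default criterion requires the decoded
  phenotype to be *strictly better than the empty phenotype*: a genome
  whose only protein is, e.g., a lone inhibitor is phenotypically silent,
  the local landscape is flat, and short runs stall; requiring a
  beneficial founder gives selection a foothold without changing the
  construction (a uniform random 5000-bp sequence with at least one
  gene).
* `make_annotated_fixture` inverse-designs genomes whose annotation is
  known exactly: each transcription unit is built cistron by cistron,
  redrawing spacers, codon interleavings, inter-cistronic pads and
  terminators until the transcript contains no premature hairpin and
  exactly the designed initiation motifs, and the assembled genome is
  screened for spurious promoters on both strands. With `filler="inert"`
  the padding is all-zero — no window of it or of its single-bit mutants
  can form a promoter or hairpin — which makes every filler position
  exactly neutral under point mutation (the exhaustive-neutrality
  fixtures). The promoter consensus itself contains two hairpin windows;
  fixtures that need terminator loss to be phenotypically visible flip
  consensus position 11, which breaks both.
* `make_adapted_genome` emulates a *pre-evolved* ancestor: full-width
  activator triangles placed on the representable trait grid with
  heights quantised to the target tile the environment piecewise-
  linearly, reaching g ≈ 0.009 — the error scale of fully evolved wild
  types. `polish_genome` then walks it to a point-mutation local optimum
  (greedy single-flip descent), the situation in which an elevated
  mutation rate imposes load instead of accelerating adaptation. This
  mimics the structure of an evolved genome, not its history; desk
  protocols therefore equilibrate a clonal population of it for a few
  hundred generations under mild rates before cloning.

## Desk-scale protocol and parameter choices

Published-scale experiments (32×32 grid, 300,000 pre-evolution
generations, 100,000-generation propagations, 100 mutator replicates)
are cluster work. The desk presets in `digevol.experiments` run the same
protocol structure in minutes on one CPU: an 8×8 grid (N = 64), the
polished adapted ancestor equilibrated for 500 generations, and
4000-generation control/mutator propagations with a hard genome-length
ceiling of 16 kb guarding runaway duplication. Directional outcomes
(burden then recovery, essential streamlining, non-essential inflation,
population mean lagging the lineage) are majority statements over ≥ 5
seeds, not value matches; absolute magnitudes scale with system size.

Two parameters deserve comment:

* **Selection intensity k.** The exponential fitness scale is not fixed
  by the model's published description; the package default is k = 1000.
  The desk presets use **k = 50**: with N = 64 and the deliberately
  coarse effect spectrum of a designed genome, k = 1000 maps every
  encodable deleterious step to a selection coefficient far above 1/N,
  Muller's ratchet cannot click, and no mutational burden can exist at
  any mutation rate. k = 50 places the desk system in the regime the
  model is known for — wild-type and control lineages stable under mild
  rates, an operating ratchet under the 100× point rate. This is a
  regime calibration, made once; all error comparisons in tests and
  analyses use g itself, never fitness.
* **Grid discretisation.** Phenotype and target live on 301 uniform grid
  points with trapezoidal integration; halving the spacing moves g by
  well under 1 % (tested), and the empty-phenotype error agrees with
  adaptive quadrature to ~10⁻⁴ relative.

## Numerical conventions

* Coordinates are 0-based; segments are half-open on the circle; the
  lagging-strand position i maps to leading position L−1−i.
* Neutrality in `reduce_noncoding` and the neutrality tests means exact
  float equality of g computed through the identical code path — no
  epsilon.
* Runs are deterministic under a master seed: generation t uses an RNG
  stream seeded (seed, t); cells are processed in fixed row-major order.
  Identical seeds give bit-identical populations (tested).
* Events that would empty the genome or exceed the length ceiling are
  rejected and flagged, never redrawn.
* A translocation/duplication/deletion of a zero-length arc (equal
  breakpoints) is a recorded no-op.

## What the synthetic data do and do not show

The generators emulate the *structure* of evolved genomes (gene density,
operons, coding fraction, near-target phenotypes) and the exact
bookkeeping of the decoder, so passing tests certify the machinery:
decoding, mutation accounting, selection calibration, compartment
quantification, engineering neutrality, statistics. The desk-scale
directional experiments additionally show that the qualitative
evolutionary phenomenology — mutational burden, partial recovery, coding
compaction with non-coding inflation, and the widening gap between
population mean and lineage error — emerges at N = 64 within thousands
of generations. They do not reproduce full-scale magnitudes (bp counts,
percentages, replicate fractions), which depend on population size, run
length and the mutational history of real pre-evolved wild types; and a
hand-designed ancestor has a coarser distribution of mutational effects
than an evolved one, which is precisely why the desk selection intensity
differs from the package default.

## Known limitations

* No regulatory or metabolic network; the genotype-to-phenotype map ends
  at the triangle sum.
* No mutational biases and no mutator-allele competition: whole
  populations switch rates at clone time and cannot revert.
* The environment is constant; nothing varies the target over time.
* `reduce_noncoding` accepts any error-conserving removal, including the
  rare one that rearranges annotation silently; on screened fixtures the
  protein multiset is additionally verified unchanged in the tests.
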