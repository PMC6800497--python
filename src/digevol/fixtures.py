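"""Synthetic genomes for testing and for seeding experiments.

Two generators:

* :func:`make_naive_genome` — uniform random binary sequences,
  rejection-sampled until the decoder finds at least one gene (the
  construction used for experiment founders);
* :func:`make_annotated_fixture` — inverse-designed genomes whose gene
  content is known *by construction*: each requested protein is encoded
  as ``[promoter (d flips)] [RBS + spacer + START] [codons] [STOP]
  [terminator]``, separated by filler that is screened (and re-drawn)
  against spurious promoters, premature terminators and stray initiation
  motifs, so the decoder's output can be predicted exactly.

With ``filler="inert"`` the padding is all-zero: no window of it (or of
its single-bit mutants) can form a promoter or a hairpin, which makes
*every* filler position exactly neutral under point mutation — the
construction used by the exhaustive-neutrality tests.  With
``filler="random"`` the padding is uniform random conditioned on passing
the screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .annotation import (
    AnnotationParams,
    DEFAULT_PARAMS,
    _bits,
    _promoter_hits,
    _terminator_starts,
    annotate,
    gray_to_int,
)
from .genome import Genome

__all__ = [
    "GeneSpec",
    "FixtureSpec",
    "ExpectedAnnotation",
    "FixtureError",
    "make_naive_genome",
    "make_annotated_fixture",
    "make_adapted_genome",
]


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneSpec:
    """One requested protein, given as per-class bit strings.

    The triangle parameters follow from the bits: ``m = gray(m_bits) /
    (2^n - 1)``, ``w = w_max * gray(w_bits) / (2^n - 1)``, ``h = 2 *
    gray(h_bits) / (2^n - 1) - 1`` (empty class -> fraction 0).
    """

    m_bits: tuple[int, ...] = (1,)
    w_bits: tuple[int, ...] = (1,)
    h_bits: tuple[int, ...] = (1,)

    @staticmethod
    def _frac(bits: tuple[int, ...]) -> float:
        return gray_to_int(bits) / (2 ** len(bits) - 1) if bits else 0.0

    def expected(self, params: AnnotationParams) -> tuple[float, float, float]:
        return (
            self._frac(self.m_bits),
            self._frac(self.w_bits) * params.w_max,
            2.0 * self._frac(self.h_bits) - 1.0,
        )

    @classmethod
    def from_values(
        cls,
        m: float,
        w: float,
        h: float,
        n_bits: int = 4,
        params: AnnotationParams = DEFAULT_PARAMS,
    ) -> "GeneSpec":
        """Encode target (m, w, h); errors name the closest representable value."""

        def enc(value: float, name: str) -> tuple[int, ...]:
            denom = 2**n_bits - 1
            fr = Fraction(value).limit_denominator(10**9)
            v = fr * denom
            if v.denominator != 1 or not 0 <= v.numerator <= denom:
                nearest = round(float(value) * denom) / denom
                raise FixtureError(
                    f"{name}={value} is not representable with {n_bits} bits; "
                    f"closest representable fraction is {nearest}"
                )
            # invert the Gray decoding: gray = binary xor (binary >> 1)
            gray = v.numerator ^ (v.numerator >> 1)
            return tuple((gray >> (n_bits - 1 - i)) & 1 for i in range(n_bits))

        return cls(
            m_bits=enc(m, "m"),
            w_bits=enc(w / params.w_max, "w/w_max"),
            h_bits=enc((h + 1.0) / 2.0, "(h+1)/2"),
        )


@dataclass
class FixtureSpec:
    """A genome design: transcription units, promoter distances, padding."""

    genes: list[GeneSpec] = field(default_factory=lambda: [GeneSpec()])
    d: int = 0                 # Hamming distance of every promoter to consensus
    filler_bp: int = 100       # total non-transcribed padding
    operon: bool = False       # all genes on one RNA (single promoter/terminator)
    filler: str = "random"     # "random" (screened) or "inert" (all zeros)
    mutation_safe: bool = True # screen filler so no single flip creates a promoter
    #: explicit promoter flip positions (len == d); None -> drawn at random.
    #: E.g. (11,) breaks both hairpin windows the consensus itself contains,
    #: so that losing a terminator is not silently rescued at the next
    #: promoter (used by the exhaustive-neutrality fixtures).
    promoter_flips: tuple[int, ...] | None = None


@dataclass
class ExpectedAnnotation:
    """What the decoder must report for a constructed fixture."""

    n_rnas: int
    n_coding_rnas: int
    n_genes: int
    proteins: tuple              # sorted (m, w, h, e) tuples
    essential_mask: np.ndarray   # leading-strand boolean mask
    promoter_positions: tuple[int, ...]
    filler_positions: np.ndarray


def make_naive_genome(
    length: int = 5000,
    rng: np.random.Generator | None = None,
    params: AnnotationParams = DEFAULT_PARAMS,
    require: str = "beneficial",
    max_tries: int = 10_000,
) -> Genome:
    """Uniform random genome rejection-sampled to carry at least one gene.

    ``require`` controls the rejection criterion:

    * ``"gene"`` — any translated gene, functional or not;
    * ``"functional"`` — at least one protein with w > 0 and h != 0;
    * ``"beneficial"`` (default) — the decoded phenotype strictly reduces
      the metabolic error relative to the empty phenotype.  Founders
      whose proteins are phenotypically silent (e.g. a lone inhibitor)
      present a flat landscape and stall desk-scale adaptation; this
      criterion guarantees selection a foothold.
    """
    if rng is None:
        rng = np.random.default_rng()
    if require not in ("gene", "functional", "beneficial"):
        raise ValueError(f"unknown requirement {require!r}")
    if length < params.promoter_len + params.motif_len + 3 + params.terminator_len:
        raise ValueError("length is below the minimal gene footprint")
    if require == "beneficial":
        from .phenotype import PhenotypicTarget, compute_phenotype, metabolic_error

        target = PhenotypicTarget()
        g_empty = metabolic_error(compute_phenotype([]), target)
    for _ in range(max_tries):
        g = Genome(rng.integers(0, 2, size=length, dtype=np.uint8))
        ann = annotate(g, params)
        if ann.n_genes == 0:
            continue
        if require == "gene":
            return g
        if require == "functional":
            if any(p.is_functional for p in ann.proteins):
                return g
            continue
        P = compute_phenotype(ann.proteins)
        if metabolic_error(P, target) < g_empty:
            return g
    raise FixtureError(
        f"no acceptable genome found in {max_tries} attempts at L={length}"
    )


# ---------------------------------------------------------------------------
# inverse design


def _make_terminator(rng: np.random.Generator, params: AnnotationParams) -> np.ndarray:
    stem = rng.integers(0, 2, size=params.terminator_stem, dtype=np.uint8)
    loop = rng.integers(0, 2, size=params.terminator_loop, dtype=np.uint8)
    return np.concatenate([stem, loop, (1 - stem)[::-1]])


def _make_promoter(
    d: int,
    rng: np.random.Generator,
    params: AnnotationParams,
    flips: tuple[int, ...] | None = None,
) -> np.ndarray:
    prom = _bits(params.promoter_consensus).copy()
    if d > params.d_max:
        raise FixtureError(f"promoter distance {d} exceeds d_max={params.d_max}")
    if flips is not None:
        if len(flips) != d:
            raise FixtureError("promoter_flips length must equal d")
        idx = np.asarray(flips, dtype=int)
    else:
        idx = rng.choice(prom.size, size=d, replace=False)
    prom[idx] ^= 1
    return prom


def _interleave_codons(
    gene: GeneSpec, rng: np.random.Generator, params: AnnotationParams
) -> np.ndarray:
    inverse = {aa: cod for cod, aa in params.codon_table.items()}
    labels = (
        ["M"] * len(gene.m_bits) + ["W"] * len(gene.w_bits) + ["H"] * len(gene.h_bits)
    )
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in sorted(range(len(labels)), key=lambda i: order[i])]
    iters = {"M": iter(gene.m_bits), "W": iter(gene.w_bits), "H": iter(gene.h_bits)}
    codons = [inverse[f"{cls}{next(iters[cls])}"] for cls in labels]
    return np.concatenate([_bits(c) for c in codons]) if codons else np.empty(0, np.uint8)


def _hairpin_window(t: np.ndarray, stem: int) -> bool:
    W = t.size
    return all(t[W - 1 - j] == 1 - t[j] for j in range(stem))


def _unit(
    genes: list[GeneSpec],
    d: int,
    rng: np.random.Generator,
    params: AnnotationParams,
    flips: tuple[int, ...] | None = None,
    max_intercistronic: int = 6,
    stage_tries: int = 400,
) -> tuple[np.ndarray, list[int], np.ndarray]:
    """One transcription unit, built cistron by cistron.

    Returns ``(bits, gene motif offsets within the RNA, essential mask)``.
    Each cistron (and finally the terminator) is redrawn until the
    transcript so far contains no premature hairpin window and exactly
    the designed initiation motifs — staged construction succeeds where
    whole-unit rejection sampling practically never does for operons.
    Operons carry a short random inter-cistronic pad between consecutive
    genes (transcribed but non-essential), which supplies the free bits
    needed to break hairpins at the STOP/RBS junction.
    """
    W_t = params.terminator_len
    stem = params.terminator_stem
    rbs = _bits(params.rbs)
    start_cod = _bits(params.start_codon)
    ml = params.motif_len

    def new_hairpin_free(trans: np.ndarray, prev_len: int) -> bool:
        lo = max(0, prev_len - (W_t - 1))
        for s in range(lo, trans.size - W_t + 1):
            if _hairpin_window(trans[s : s + W_t], stem):
                return False
        return True

    def new_motifs(trans: np.ndarray, prev_len: int) -> list[int]:
        lo = max(0, prev_len - (ml - 1))
        out = []
        for r in range(lo, trans.size - ml + 1):
            if np.array_equal(trans[r : r + len(rbs)], rbs) and np.array_equal(
                trans[r + len(rbs) + params.spacer_len : r + ml], start_cod
            ):
                out.append(r)
        return out

    promoter = _make_promoter(d, rng, params, flips)
    trans = np.empty(0, dtype=np.uint8)
    ess_trans = np.empty(0, dtype=bool)
    offsets: list[int] = []
    for i, gene in enumerate(genes):
        prev_len = trans.size
        for _ in range(stage_tries):
            pad_len = int(rng.integers(0, max_intercistronic + 1)) if i > 0 else 0
            pad = rng.integers(0, 2, size=pad_len, dtype=np.uint8)
            block = np.concatenate(
                [
                    rbs,
                    rng.integers(0, 2, size=params.spacer_len, dtype=np.uint8),
                    start_cod,
                    _interleave_codons(gene, rng, params),
                    _bits(params.stop_codon),
                ]
            )
            cand = np.concatenate([trans, pad, block])
            if not new_hairpin_free(cand, prev_len):
                continue
            if new_motifs(cand, prev_len) != [prev_len + pad_len]:
                continue
            trans = cand
            ess_trans = np.concatenate(
                [ess_trans, np.zeros(pad_len, dtype=bool),
                 np.ones(block.size, dtype=bool)]
            )
            offsets.append(prev_len + pad_len)
            break
        else:
            raise FixtureError(
                f"could not place cistron {i} cleanly in {stage_tries} tries"
            )
    prev_len = trans.size
    for _ in range(stage_tries):
        cand = np.concatenate([trans, _make_terminator(rng, params)])
        # every hairpin window before the designed one would truncate the RNA
        ok = True
        for s in range(max(0, prev_len - (W_t - 1)), cand.size - W_t):
            if _hairpin_window(cand[s : s + W_t], stem):
                ok = False
                break
        if ok and new_motifs(cand, prev_len) == []:
            trans = cand
            ess_trans = np.concatenate([ess_trans, np.ones(W_t, dtype=bool)])
            break
    else:
        raise FixtureError(f"could not place a terminator cleanly in {stage_tries} tries")

    bits = np.concatenate([promoter, trans])
    ess = np.concatenate([np.ones(promoter.size, dtype=bool), ess_trans])
    return bits, offsets, ess


def _screen(
    arr: np.ndarray,
    units: list[tuple[int, int, list[int]]],  # (unit_start, unit_len, motif offsets)
    filler_mask: np.ndarray,
    spec: FixtureSpec,
    params: AnnotationParams,
) -> bool:
    """True iff the assembled genome decodes to exactly the designed content."""
    L = arr.size
    W = params.promoter_len
    lag = (1 - arr[::-1]).astype(np.uint8)

    designed = {(s, spec.d) for s, _, _ in units}
    lead_pos, lead_d = _promoter_hits(arr, params)
    if {(int(p), int(dd)) for p, dd in zip(lead_pos, lead_d)} != designed:
        return False
    lag_pos, _ = _promoter_hits(lag, params)
    if lag_pos.size:
        return False

    term_starts = set(_terminator_starts(arr, params).tolist())
    rbs = _bits(params.rbs)
    start_cod = _bits(params.start_codon)
    ml = params.motif_len
    for s, ln, offsets in units:
        rna_start = (s + W) % L
        rna_len = ln - W  # through the terminator's last base
        term_start = (s + ln - params.terminator_len) % L
        idx = (rna_start + np.arange(rna_len)) % L
        rna_seq = arr[idx]
        # no premature hairpin inside the transcript
        for t in range(rna_len):
            p_abs = (rna_start + t) % L
            if p_abs == term_start:
                break
            if p_abs in term_starts:
                return False
        # initiation motifs exactly where designed
        found = []
        for r in range(rna_len - ml + 1):
            if np.array_equal(rna_seq[r : r + rbs.size], rbs) and np.array_equal(
                rna_seq[r + rbs.size + params.spacer_len : r + ml], start_cod
            ):
                found.append(r)
        if found != offsets:
            return False

    if spec.mutation_safe and filler_mask.any():
        # any window touching filler must stay >= d_max + 2 from consensus
        # (one flip can lower the distance by at most 1)
        def touch_windows(mask: np.ndarray) -> np.ndarray:
            ext = np.concatenate([mask, mask[: W - 1]]).astype(int)
            return np.convolve(ext, np.ones(W, dtype=int), mode="valid")[:L] > 0

        cons = _bits(params.promoter_consensus)
        for strand_seq, strand_filler in ((arr, filler_mask), (lag, filler_mask[::-1])):
            ext2 = np.concatenate([strand_seq, strand_seq[: W - 1]])
            dist = np.zeros(L, dtype=np.int16)
            for j in range(W):
                dist += ext2[j : j + L] != cons[j]
            if np.any(dist[touch_windows(strand_filler)] <= params.d_max + 1):
                return False
    return True


def make_annotated_fixture(
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    params: AnnotationParams = DEFAULT_PARAMS,
    max_tries: int = 500,
) -> tuple[Genome, ExpectedAnnotation]:
    """Assemble a genome whose decoded annotation is known by construction."""
    if rng is None:
        rng = np.random.default_rng()
    if not spec.genes:
        raise FixtureError("a fixture needs at least one gene")
    if spec.filler not in ("random", "inert"):
        raise FixtureError(f"unknown filler mode {spec.filler!r}")

    unit_groups: list[list[GeneSpec]] = (
        [list(spec.genes)] if spec.operon else [[g] for g in spec.genes]
    )
    n_units = len(unit_groups)

    def clean_unit(group: list[GeneSpec]) -> tuple[np.ndarray, list[int]]:
        """Draw a unit until it decodes cleanly in an inert circular probe.

        Long units (operons) rarely avoid spurious hairpins in any given
        draw, so the per-unit retry budget is generous.
        """
        unit_tries = max(max_tries, 3000 * len(group))
        for _ in range(unit_tries):
            bits, offs, ess = _unit(group, spec.d, rng, params, spec.promoter_flips)
            probe = np.concatenate([bits, np.zeros(40, dtype=np.uint8)])
            probe_units = [(0, bits.size, offs)]
            probe_filler = np.zeros(probe.size, dtype=bool)
            probe_spec = FixtureSpec(
                genes=group, d=spec.d, filler_bp=0, mutation_safe=False
            )
            if _screen(probe, probe_units, probe_filler, probe_spec, params):
                return bits, offs, ess
        raise FixtureError(
            f"could not draw a clean transcription unit in {unit_tries} tries"
        )

    prescreened = [clean_unit(group) for group in unit_groups]

    for _ in range(max_tries):
        # split the filler between units (first split absorbs the remainder)
        per = spec.filler_bp // n_units
        fills = [per] * n_units
        fills[0] += spec.filler_bp - per * n_units
        parts = []
        units = []
        filler_mask_parts = []
        essential_parts = []
        pos = 0
        for (bits, offs, ess), fbp in zip(prescreened, fills):
            units.append((pos, bits.size, offs))
            parts.append(bits)
            filler_mask_parts.append(np.zeros(bits.size, dtype=bool))
            essential_parts.append(ess)
            pos += bits.size
            if fbp:
                if spec.filler == "inert":
                    pad = np.zeros(fbp, dtype=np.uint8)
                else:
                    pad = rng.integers(0, 2, size=fbp, dtype=np.uint8)
                parts.append(pad)
                filler_mask_parts.append(np.ones(fbp, dtype=bool))
                essential_parts.append(np.zeros(fbp, dtype=bool))
                pos += fbp
        arr = np.concatenate(parts)
        filler_mask = np.concatenate(filler_mask_parts)
        essential_mask = np.concatenate(essential_parts)
        if not _screen(arr, units, filler_mask, spec, params):
            # cross-boundary artefact: re-draw the units and the filler
            prescreened = [clean_unit(group) for group in unit_groups]
            continue

        genome = Genome(arr)
        proteins = []
        e = params.expression(spec.d)
        for group in unit_groups:
            for gene in group:
                m, w, h = gene.expected(params)
                proteins.append((m, w, h, e))
        expected = ExpectedAnnotation(
            n_rnas=n_units,
            n_coding_rnas=n_units,
            n_genes=len(spec.genes),
            proteins=tuple(sorted(proteins)),
            essential_mask=essential_mask,
            promoter_positions=tuple(s for s, _, _ in units),
            filler_positions=np.nonzero(filler_mask)[0],
        )
        return genome, expected

    raise FixtureError(
        f"could not assemble a clean fixture in {max_tries} tries "
        "(requested content may be too dense to screen)"
    )


# ---------------------------------------------------------------------------
# pre-evolved-like ancestors


def _gray_bits(v: int, n: int) -> tuple[int, ...]:
    g = v ^ (v >> 1)
    return tuple((g >> (n - 1 - i)) & 1 for i in range(n))


def make_adapted_genome(
    rng: np.random.Generator | None = None,
    params: AnnotationParams = DEFAULT_PARAMS,
    m_bits: int = 5,
    h_bits: int = 6,
    min_height: float = 0.03,
    intergenic_bp: int = 30,
    n_candidates: int = 10,
    max_tries: int = 400,
) -> tuple[Genome, float]:
    """A well-adapted multi-gene genome emulating a pre-evolved ancestor.

    Full-width activator triangles (w = w_max, e = 1) are placed on the
    representable trait grid ``j / (2^m_bits - 1)`` wherever the target
    exceeds ``min_height``, with heights quantised to the target value;
    adjacent triangles spaced about one half-width apart interpolate the
    target piecewise-linearly, so the decoded phenotype lands close to
    it.  Each transcription unit is validated in isolation (exactly one
    coding RNA with the designed protein) and units are concatenated with
    random intergenic filler; the best of ``n_candidates`` assemblies by
    measured metabolic error is returned as ``(genome, g)``.

    This construction mimics the *structure* of an evolved genome (many
    genes, high coding fraction, near-target phenotype) but not its
    mutational history; evolving it briefly under mild rates before use
    lets a population settle into its own local equilibrium.
    """
    from .phenotype import PhenotypicTarget, compute_phenotype, metabolic_error

    if rng is None:
        rng = np.random.default_rng()
    target = PhenotypicTarget()
    denom_m = 2**m_bits - 1
    denom_h = 2**h_bits - 1
    genes: list[GeneSpec] = []
    for j in range(1, denom_m):
        t = float(target(np.array([j / denom_m]))[0])
        if t < min_height:
            continue
        fh = round((t + 1) / 2 * denom_h)
        genes.append(
            GeneSpec(
                m_bits=_gray_bits(j, m_bits),
                w_bits=(1,),
                h_bits=_gray_bits(fh, h_bits),
            )
        )
    if not genes:
        raise FixtureError("target admits no gene above min_height")

    def good_unit(gene: GeneSpec) -> np.ndarray:
        expected = gene.expected(params)
        for _ in range(max_tries):
            bits, _, _ = _unit([gene], 0, rng, params)
            probe = Genome(np.concatenate([bits, np.zeros(60, dtype=np.uint8)]))
            ann = annotate(probe, params)
            if ann.n_rnas == 1 and ann.n_coding_rnas == 1 and ann.n_genes == 1:
                p = ann.proteins[0]
                if np.allclose((p.m, p.w, p.h), expected) and p.e == 1.0:
                    return bits
        raise FixtureError("could not assemble a clean transcription unit")

    unit_bits = [good_unit(g) for g in genes]
    best: tuple[Genome, float] | None = None
    for _ in range(n_candidates):
        parts: list[np.ndarray] = []
        for bits in unit_bits:
            parts.append(bits)
            parts.append(rng.integers(0, 2, size=intergenic_bp, dtype=np.uint8))
        genome = Genome(np.concatenate(parts))
        ann = annotate(genome, params)
        g = metabolic_error(compute_phenotype(ann.proteins), target)
        if best is None or g < best[1]:
            best = (genome, g)
    return best


def polish_genome(
    genome: Genome,
    evaluator=None,
    rng: np.random.Generator | None = None,
    max_passes: int = 100,
) -> tuple[Genome, float]:
    """Greedy single-flip descent to a point-mutation local optimum.

    Repeatedly sweeps the genome in random order, keeping any single-base
    flip that strictly reduces the metabolic error, until a full sweep
    finds none.  The result is a genotype at which every point mutation
    is neutral or deleterious — the situation of a well-adapted wild
    type, where an elevated mutation rate imposes load instead of
    accelerating adaptation.
    """
    from .phenotype import Evaluator

    if evaluator is None:
        evaluator = Evaluator()
    if rng is None:
        rng = np.random.default_rng()
    g0 = evaluator.error_of(genome)
    for _ in range(max_passes):
        improved = False
        for pos in rng.permutation(len(genome)):
            trial = genome.seq.copy()
            trial[pos] ^= 1
            trial_genome = Genome(trial)
            gt = evaluator.error_of(trial_genome)
            if gt < g0:
                genome, g0 = trial_genome, gt
                improved = True
        if not improved:
            break
    return genome, g0
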