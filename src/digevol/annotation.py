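"""Decode a circular binary genome into RNAs, genes and proteins.

The decoding grammar mimics prokaryotic gene structure on a two-letter
alphabet:

* a *promoter* is any 22-bp window (either strand) within Hamming
  distance ``d_max`` of a consensus sequence; its distance ``d`` sets the
  expression level ``e = 1 - d / (d_max + 1)`` of the RNA it drives;
* transcription proceeds from the first base after the promoter until a
  *terminator*, an 11-bp window able to form a 4-bp-stem / 3-bp-loop
  hairpin (``t[10-j] == 1 - t[j]`` for ``j in 0..3``);
* a *gene* starts at each Ribosome Binding Site (``011011``) followed by
  a 4-bp spacer and the START codon ``000``, and is read in consecutive
  3-bit codons until the in-frame STOP codon ``001`` (genes without an
  in-frame STOP inside the RNA are discarded);
* the six remaining codons encode six "amino acids", paired into three
  classes M, W and H; the per-class bit strings are Gray-decoded and
  normalised into the protein's triangle parameters ``m`` (trait
  position, in [0, 1]), ``w`` (pleiotropy half-width, in [0, w_max]) and
  ``h`` (contribution height, in [-1, 1]).

One RNA can carry several genes (an operon) and one gene can sit on
several RNAs; each (RNA, gene) pair yields one protein instance scaled by
that RNA's expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genome import Genome

__all__ = [
    "AnnotationParams",
    "DEFAULT_PARAMS",
    "Rna",
    "Gene",
    "Protein",
    "Annotation",
    "gray_to_int",
    "find_promoters",
    "find_terminators",
    "transcribe",
    "translate",
    "compute_protein",
    "annotate",
    "annotation_to_gff",
]

#: Default genetic code: START/STOP plus three AA classes in bit pairs.
DEFAULT_CODON_TABLE: Mapping[str, str] = {
    "000": "START",
    "001": "STOP",
    "100": "M0",
    "101": "M1",
    "010": "W0",
    "011": "W1",
    "110": "H0",
    "111": "H1",
}


@dataclass(frozen=True)
class AnnotationParams:
    """Tunable constants of the decoding grammar (config-overridable)."""

    promoter_consensus: str = "0101011001110010010110"  # 22 bp
    d_max: int = 4
    terminator_stem: int = 4
    terminator_loop: int = 3
    rbs: str = "011011"
    spacer_len: int = 4
    codon_table: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CODON_TABLE))
    w_max: float = 1.0 / 30.0

    @property
    def promoter_len(self) -> int:
        return len(self.promoter_consensus)

    @property
    def terminator_len(self) -> int:
        return 2 * self.terminator_stem + self.terminator_loop

    @property
    def start_codon(self) -> str:
        return next(c for c, a in self.codon_table.items() if a == "START")

    @property
    def stop_codon(self) -> str:
        return next(c for c, a in self.codon_table.items() if a == "STOP")

    @property
    def motif_len(self) -> int:
        """RBS + spacer + START codon footprint."""
        return len(self.rbs) + self.spacer_len + 3

    def expression(self, d: int) -> float:
        return 1.0 - d / (self.d_max + 1)


DEFAULT_PARAMS = AnnotationParams()


@dataclass
class Gene:
    """One open reading frame on one RNA (transcript-local coordinates)."""

    motif_offset: int          # offset of the RBS within the RNA
    codons: list[str]          # 3-bit codons between START and STOP (STOP excluded)
    aa_seq: list[str]          # amino-acid names, e.g. ["M1", "W1", "H0"]

    @property
    def start_codon_offset(self) -> int:
        return self.motif_offset + 10

    def footprint(self, params: AnnotationParams = DEFAULT_PARAMS) -> range:
        """Transcript-local offsets of RBS+spacer+START..STOP (inclusive)."""
        n = len(self.codons)
        return range(self.motif_offset, self.motif_offset + params.motif_len + 3 * n + 3)


@dataclass
class Rna:
    """One transcript."""

    strand: str                # "leading" or "lagging"
    promoter_pos: int          # strand-local window start of the promoter
    d: int                     # Hamming distance of the promoter to consensus
    e: float                   # expression level, 1 - d/(d_max+1)
    start: int                 # strand-local first transcribed base
    length: int                # transcript length incl. terminator window
    terminator_pos: int        # strand-local window start of the terminator
    genes: list[Gene] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return len(self.genes) > 0


@dataclass(frozen=True)
class Protein:
    """Triangular contribution to the phenotype."""

    m: float
    w: float
    h: float
    e: float

    @property
    def is_functional(self) -> bool:
        return self.w > 0.0 and self.h != 0.0

    def key(self) -> tuple[float, float, float, float]:
        return (self.m, self.w, self.h, self.e)


def _bits(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0")


def gray_to_int(bits) -> int:
    """Decode a reflected-binary (Gray) code, most significant bit first."""
    b = 0
    v = 0
    for g in bits:
        b ^= int(g)
        v = (v << 1) | b
    return v


# ---------------------------------------------------------------------------
# strand scans (vectorised; windows wrap the circle)


def _promoter_hits(strand_seq: np.ndarray, params: AnnotationParams):
    """Positions and distances of promoter windows on one strand."""
    L = strand_seq.size
    W = params.promoter_len
    if L < W:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int16)
    ext = np.concatenate([strand_seq, strand_seq[: W - 1]])
    cons = _bits(params.promoter_consensus)
    d = np.zeros(L, dtype=np.int16)
    for j in range(W):
        d += ext[j : j + L] != cons[j]
    hits = np.nonzero(d <= params.d_max)[0]
    return hits, d[hits]


def _terminator_starts(strand_seq: np.ndarray, params: AnnotationParams) -> np.ndarray:
    """Sorted window-start positions of all stem-loop terminators on one strand."""
    L = strand_seq.size
    W = params.terminator_len
    if L < W:
        return np.empty(0, dtype=np.int64)
    ext = np.concatenate([strand_seq, strand_seq[: W - 1]])
    ok = np.ones(L, dtype=bool)
    for j in range(params.terminator_stem):
        ok &= ext[j : j + L] != ext[W - 1 - j : W - 1 - j + L]
    return np.nonzero(ok)[0]


def find_promoters(g: Genome, params: AnnotationParams = DEFAULT_PARAMS):
    """All promoter windows on both strands as ``(strand, position, d)``.

    Positions are strand-local window starts (lagging-strand position
    ``i`` maps to leading-strand position ``L - 1 - i``).
    """
    out = []
    for strand, seq in (("leading", g.seq), ("lagging", g.lagging())):
        pos, dist = _promoter_hits(seq, params)
        out.extend((strand, int(p), int(d)) for p, d in zip(pos, dist))
    return out


def find_terminators(
    g: Genome, from_pos: int, strand: str = "leading",
    params: AnnotationParams = DEFAULT_PARAMS,
) -> int | None:
    """Last base position of the first terminator window at or past ``from_pos``.

    The scan is circular and bounded by one full revolution; ``None``
    means the RNA finds no terminator and is discarded.
    """
    seq = g.seq if strand == "leading" else g.lagging()
    starts = _terminator_starts(seq, params)
    if starts.size == 0:
        return None
    L = seq.size
    p = from_pos % L
    i = np.searchsorted(starts, p)
    t = int(starts[i]) if i < starts.size else int(starts[0])
    return (t + params.terminator_len - 1) % L


def _circular_slice(seq: np.ndarray, start: int, length: int) -> np.ndarray:
    idx = (start + np.arange(length)) % seq.size
    return seq[idx]


def transcribe(g: Genome, params: AnnotationParams = DEFAULT_PARAMS) -> list[Rna]:
    """One RNA per promoter with a reachable terminator (both strands).

    The transcript spans the bases strictly after the promoter window
    through the terminator's last base.
    """
    rnas: list[Rna] = []
    L = len(g)
    for strand, seq in (("leading", g.seq), ("lagging", g.lagging())):
        proms, dists = _promoter_hits(seq, params)
        terms = _terminator_starts(seq, params)
        if proms.size == 0 or terms.size == 0:
            continue
        for p, d in zip(proms, dists):
            start = (int(p) + params.promoter_len) % L
            i = np.searchsorted(terms, start)
            t = int(terms[i]) if i < terms.size else int(terms[0])
            length = (t - start) % L + params.terminator_len
            rnas.append(
                Rna(
                    strand=strand,
                    promoter_pos=int(p),
                    d=int(d),
                    e=params.expression(int(d)),
                    start=start,
                    length=length,
                    terminator_pos=t,
                )
            )
    return rnas


def translate(
    rna: Rna, g: Genome, params: AnnotationParams = DEFAULT_PARAMS
) -> list[Gene]:
    """All genes on one RNA.

    A gene starts at every RBS + spacer + START occurrence inside the
    transcript and runs to the first in-frame STOP; genes whose STOP is
    not reached within the transcript are discarded.
    """
    seq = g.seq if rna.strand == "leading" else g.lagging()
    rna_seq = _circular_slice(seq, rna.start, rna.length)
    rbs = _bits(params.rbs)
    start_cod = _bits(params.start_codon)
    stop = params.stop_codon
    n = rna_seq.size
    ml = params.motif_len
    genes: list[Gene] = []
    if n < ml:
        return genes
    # vectorised motif scan
    ok = np.ones(n - ml + 1, dtype=bool)
    for j, b in enumerate(rbs):
        ok &= rna_seq[j : j + n - ml + 1] == b
    off = len(params.rbs) + params.spacer_len
    for j, b in enumerate(start_cod):
        ok &= rna_seq[off + j : off + j + n - ml + 1] == b
    for r in np.nonzero(ok)[0]:
        codons: list[str] = []
        aa: list[str] = []
        c = int(r) + ml
        found = False
        while c + 3 <= n:
            cod = "".join("01"[b] for b in rna_seq[c : c + 3])
            if cod == stop:
                found = True
                break
            codons.append(cod)
            aa.append(params.codon_table[cod])
            c += 3
        if found:
            genes.append(Gene(motif_offset=int(r), codons=codons, aa_seq=aa))
    return genes


def compute_protein(
    gene: Gene, e: float = 1.0, params: AnnotationParams = DEFAULT_PARAMS
) -> Protein:
    """Fold a gene's amino-acid sequence into triangle parameters.

    Per class C in {M, W, H}: collect the bits of C-class amino acids in
    gene order, Gray-decode them to an integer ``v`` and normalise to the
    fraction ``v / (2**n - 1)``; an empty class yields fraction 0 (such
    genes are non-functional rather than undefined).
    """
    if not gene.codons:
        raise ValueError("cannot compute a protein from a zero-codon gene")
    frac = {}
    for cls in "MWH":
        bits = [int(a[1]) for a in gene.aa_seq if a[0] == cls]
        frac[cls] = gray_to_int(bits) / (2 ** len(bits) - 1) if bits else 0.0
    return Protein(
        m=frac["M"],
        w=frac["W"] * params.w_max,
        h=2.0 * frac["H"] - 1.0,
        e=e,
    )


# ---------------------------------------------------------------------------
# full annotation


class Annotation:
    """Decoded gene content of one genome plus essential-position bookkeeping."""

    def __init__(self, genome: Genome, params: AnnotationParams = DEFAULT_PARAMS):
        self.genome = genome
        self.params = params
        self.rnas = transcribe(genome, params)
        for rna in self.rnas:
            rna.genes = translate(rna, genome, params)
        # zero-codon genes (START immediately followed by STOP) yield no
        # protein; they still count as genes and as essential sequence
        self.proteins: list[Protein] = [
            compute_protein(gene, rna.e, params)
            for rna in self.rnas
            for gene in rna.genes
            if gene.codons
        ]

    # -- summary counts -----------------------------------------------------
    @property
    def n_rnas(self) -> int:
        return len(self.rnas)

    @property
    def n_coding_rnas(self) -> int:
        return sum(1 for r in self.rnas if r.is_coding)

    @property
    def n_genes(self) -> int:
        return sum(len(r.genes) for r in self.rnas)

    def protein_multiset(self) -> tuple:
        """Sorted (m, w, h, e) tuples — rotation-invariant fingerprint."""
        return tuple(sorted(p.key() for p in self.proteins))

    # -- essential positions ------------------------------------------------
    def _to_leading(self, strand: str, pos: np.ndarray) -> np.ndarray:
        L = len(self.genome)
        return pos % L if strand == "leading" else (L - 1 - (pos % L)) % L

    def essential_mask(self) -> np.ndarray:
        """Boolean mask (leading coordinates) of essential positions.

        Essential = promoters and terminators of coding RNAs, plus each
        gene's initiation motif (RBS + spacer) and ORF (START through
        STOP inclusive); overlaps are counted once.  Everything else —
        non-transcribed sequence, non-coding RNAs, leaders and trailers —
        is non-essential.
        """
        L = len(self.genome)
        p = self.params
        mask = np.zeros(L, dtype=bool)
        for rna in self.rnas:
            if not rna.is_coding:
                continue
            spans = [
                (rna.promoter_pos, p.promoter_len),
                (rna.terminator_pos, p.terminator_len),
            ]
            rbs_spacer = len(p.rbs) + p.spacer_len
            for gene in rna.genes:
                g0 = rna.start + gene.motif_offset
                spans.append((g0, rbs_spacer))                          # initiation motif
                orf_len = 3 + 3 * len(gene.codons) + 3                  # START..STOP
                spans.append((g0 + rbs_spacer, orf_len))
            for s0, ln in spans:
                pos = np.arange(s0, s0 + ln)
                mask[self._to_leading(rna.strand, pos)] = True
        return mask

    def essential_bp(self) -> int:
        return int(self.essential_mask().sum())


def annotate(g: Genome, params: AnnotationParams = DEFAULT_PARAMS) -> Annotation:
    """Decode a genome (deterministic and rotation-covariant)."""
    return Annotation(g, params)


def annotation_to_gff(ann: Annotation) -> str:
    """GFF-like tab-separated export (1-based inclusive leading coordinates)."""
    L = len(ann.genome)
    p = ann.params
    lines = ["#feature\tstrand\tstart\tend\tattributes"]

    def row(feature: str, strand: str, s0: int, ln: int, attrs: str) -> None:
        lead = sorted(ann._to_leading(strand, np.arange(s0, s0 + ln)))
        lines.append(f"{feature}\t{strand}\t{lead[0] + 1}\t{lead[-1] + 1}\t{attrs}")

    for i, rna in enumerate(ann.rnas):
        attrs = f"rna={i};d={rna.d};e={rna.e:.3f};coding={int(rna.is_coding)}"
        row("promoter", rna.strand, rna.promoter_pos, p.promoter_len, attrs)
        row("terminator", rna.strand, rna.terminator_pos, p.terminator_len, attrs)
        for gene in rna.genes:
            g0 = rna.start + gene.motif_offset
            prot = compute_protein(gene, rna.e, p)
            row("RBS", rna.strand, g0, len(p.rbs) + p.spacer_len, attrs)
            row(
                "gene", rna.strand, g0 + 10, 3 + 3 * len(gene.codons) + 3,
                attrs + f";m={prot.m:.6g};w={prot.w:.6g};h={prot.h:.6g};e={prot.e:.6g}",
            )
    return "\n".join(lines) + "\n"
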