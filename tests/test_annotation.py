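"""Decoder: promoter/terminator scans, transcription, translation, Gray code."""

import numpy as np
import pytest

from digevol.annotation import (
    DEFAULT_PARAMS,
    _bits,
    annotate,
    annotation_to_gff,
    compute_protein,
    find_promoters,
    find_terminators,
    gray_to_int,
    transcribe,
    translate,
)
from digevol.genome import Genome

P = DEFAULT_PARAMS


def consensus_with_flip(pos=11):
    """The promoter consensus with one bit flipped.

    Position 11 breaks both hairpin windows the consensus contains, so
    downstream terminator logic is not confounded by the promoter itself.
    """
    c = _bits(P.promoter_consensus).copy()
    c[pos] ^= 1
    return c


TERMINATOR = _bits("01010000101")  # stem 0101 / loop 000 / reversed complement


def brute_force_promoters(g: Genome):
    """Independent exhaustive window scan (string arithmetic only)."""
    s = g.to_string()
    L = len(s)
    cons = P.promoter_consensus
    lagging = "".join("1" if c == "0" else "0" for c in reversed(s))
    out = []
    for strand, seq in (("leading", s), ("lagging", lagging)):
        ext = seq + seq
        for i in range(L):
            d = sum(a != b for a, b in zip(ext[i : i + 22], cons))
            if d <= P.d_max:
                out.append((strand, i, d))
    return sorted(out)


def brute_force_terminators(g: Genome):
    s = g.to_string()
    ext = s + s
    out = []
    for i in range(len(s)):
        w = ext[i : i + 11]
        if all(w[10 - j] != w[j] for j in range(4)):
            out.append(i)
    return out


class TestPromoters:
    def test_exact_consensus_hit(self):
        g = Genome(np.concatenate([_bits(P.promoter_consensus), np.zeros(40, np.uint8)]))
        hits = [h for h in find_promoters(g) if h[0] == "leading"]
        assert ("leading", 0, 0) in hits
        rna = [r for r in transcribe(g) if r.promoter_pos == 0][0]
        assert rna.e == 1.0

    def test_one_flip_gives_d1_e08(self):
        g = Genome(np.concatenate([consensus_with_flip(), np.zeros(40, np.uint8)]))
        hit = [h for h in find_promoters(g) if h[0] == "leading" and h[1] == 0][0]
        assert hit[2] == 1
        assert P.expression(1) == pytest.approx(0.8)

    def test_all_zero_genome_has_no_promoters(self):
        # the consensus weight (11 ones) exceeds d_max on both strands
        assert find_promoters(Genome(np.zeros(100, np.uint8))) == []

    def test_short_genome_yields_empty(self):
        assert find_promoters(Genome("0101")) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        g = Genome(rng.integers(0, 2, size=300, dtype=np.uint8))
        assert sorted(find_promoters(g)) == brute_force_promoters(g)


class TestTerminators:
    def test_stem_rule_examples(self):
        # "0000xxx1111" satisfies the 4-bp stem rule, "0000xxx0111" fails j=0
        valid = Genome("0000101111100000000000")
        invalid = Genome("0000101011100000000000")
        assert 0 in brute_force_terminators(valid)
        assert find_terminators(valid, 0) == 10
        assert 0 not in brute_force_terminators(invalid)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        g = Genome(rng.integers(0, 2, size=200, dtype=np.uint8))
        brute = brute_force_terminators(g)
        for start in brute:
            assert find_terminators(g, start) == (start + 10) % len(g)

    def test_no_terminator_returns_none(self):
        assert find_terminators(Genome(np.zeros(50, np.uint8)), 0) is None


class TestTranscription:
    def test_fixture_rna_length(self):
        # promoter + 30 filler bases + terminator -> one 41-bp transcript
        g = Genome(np.concatenate(
            [consensus_with_flip(), np.zeros(30, np.uint8), TERMINATOR,
             np.zeros(37, np.uint8)]
        ))
        rnas = transcribe(g)
        assert len(rnas) == 1
        assert rnas[0].length == 41
        assert rnas[0].start == 22

    def test_two_promoters_share_one_terminator(self):
        g = Genome(np.concatenate(
            [consensus_with_flip(), np.zeros(10, np.uint8), consensus_with_flip(),
             np.zeros(30, np.uint8), TERMINATOR, np.zeros(30, np.uint8)]
        ))
        rnas = sorted(transcribe(g), key=lambda r: r.promoter_pos)
        assert [r.promoter_pos for r in rnas] == [0, 32]
        assert rnas[0].terminator_pos == rnas[1].terminator_pos
        assert rnas[0].length != rnas[1].length

    def test_rotation_gives_identical_rna_multiset(self):
        g = Genome(np.concatenate(
            [consensus_with_flip(), np.zeros(30, np.uint8), TERMINATOR,
             np.zeros(37, np.uint8)]
        ))
        base = sorted((r.strand, r.d, r.length) for r in transcribe(g))
        for off in (1, 17, 50, 99):
            rot = sorted((r.strand, r.d, r.length) for r in transcribe(g.rotated(off)))
            assert rot == base


class TestTranslation:
    def _genome(self, payload: np.ndarray) -> Genome:
        return Genome(np.concatenate(
            [consensus_with_flip(), payload, TERMINATOR, np.zeros(30, np.uint8)]
        ))

    def test_single_gene_example(self):
        # RBS + spacer + START + M1 W1 H0 + STOP
        g = self._genome(np.concatenate(
            [_bits("011011"), _bits("0000"), _bits("000"),
             _bits("101011110"), _bits("001")]
        ))
        ann = annotate(g)
        assert ann.n_genes == 1
        gene = ann.rnas[0].genes[0]
        assert gene.aa_seq == ["M1", "W1", "H0"]
        prot = ann.proteins[0]
        assert prot.m == 1.0
        assert prot.w == pytest.approx(P.w_max)
        assert prot.h == -1.0
        assert prot.e == pytest.approx(0.8)

    def test_start_without_stop_is_discarded(self):
        g = self._genome(np.concatenate(
            [_bits("011011"), _bits("0000"), _bits("000"), _bits("101011110")]
        ))
        assert annotate(g).n_genes == 0

    def test_two_motifs_share_one_stop(self):
        g = self._genome(np.concatenate(
            [_bits("011011"), _bits("0000"), _bits("000"), _bits("01"),
             _bits("011011"), _bits("0110"), _bits("000"),
             _bits("101011110"), _bits("001")]
        ))
        ann = annotate(g)
        genes = sorted((gene.aa_seq for rna in ann.rnas for gene in rna.genes),
                       key=len)
        assert len(genes) == 2
        assert genes[0] == ["M1", "W1", "H0"]
        assert genes[1][-3:] == ["M1", "W1", "H0"]  # nested codon sequences


class TestGrayCode:
    def test_matches_independent_table(self):
        # independent oracle: gray(v) = v ^ (v >> 1) enumerated for n <= 10
        for n in range(1, 11):
            for v in range(2**n):
                code = v ^ (v >> 1)
                bits = [(code >> (n - 1 - i)) & 1 for i in range(n)]
                assert gray_to_int(bits) == v

    def test_protein_parameter_examples(self):
        from digevol.annotation import Gene

        # H bits "10" -> gray 11 = 3 -> h = +1
        g = Gene(motif_offset=0, codons=["111", "110"], aa_seq=["H1", "H0"])
        assert compute_protein(g).h == 1.0
        # single 0-bit per class -> non-functional zero protein
        g = Gene(motif_offset=0, codons=["100", "010", "110"],
                 aa_seq=["M0", "W0", "H0"])
        p = compute_protein(g)
        assert (p.m, p.w, p.h) == (0.0, 0.0, -1.0)
        assert not p.is_functional
        # M bits "110" -> gray-decode 100 = 4 -> m = 4/7
        g = Gene(motif_offset=0, codons=["101", "101", "100"],
                 aa_seq=["M1", "M1", "M0"])
        assert compute_protein(g).m == pytest.approx(4 / 7)

    def test_zero_codon_gene_rejected(self):
        from digevol.annotation import Gene

        with pytest.raises(ValueError):
            compute_protein(Gene(motif_offset=0, codons=[], aa_seq=[]))


class TestAnnotationObject:
    def test_determinism(self, one_gene_fixture):
        (g, _), _ = one_gene_fixture
        a1, a2 = annotate(g), annotate(g)
        assert a1.protein_multiset() == a2.protein_multiset()
        assert np.array_equal(a1.essential_mask(), a2.essential_mask())

    def test_rotation_invariant_protein_multiset(self, one_gene_fixture):
        (g, _), _ = one_gene_fixture
        base = annotate(g).protein_multiset()
        for off in (1, 37, 101):
            assert annotate(g.rotated(off)).protein_multiset() == base

    def test_gff_export_lists_all_features(self, one_gene_fixture):
        (g, _), _ = one_gene_fixture
        gff = annotation_to_gff(annotate(g))
        for feature in ("promoter", "terminator", "RBS", "gene"):
            assert f"\n{feature}\t" in gff
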