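"""Measurement layer: compartments, lineage, neighborhood, reduction, stats."""

import numpy as np
import pytest
from scipy import stats as sstats

from digevol.analysis import (
    bin_deltas,
    duplication_effects,
    NeighborhoodProfile,
    quantify_compartments,
    reconstruct_lineage,
    reduce_noncoding,
    sample_neighborhood,
    wilcoxon_paired,
)
from digevol.evolution import ExperimentConfig, GridPopulation, run_experiment
from digevol.fixtures import FixtureSpec, GeneSpec, make_annotated_fixture
from digevol.genome import Genome
from digevol.mutation import Duplication, MutationRates
from digevol.phenotype import Evaluator, Individual


class TestCompartments:
    def test_no_coding_rna_means_no_essential(self):
        stats = quantify_compartments(Genome(np.zeros(100, np.uint8)))
        assert stats.essential_bp == 0
        assert stats.nonessential_bp == 100

    def test_five_codon_gene_footprint(self):
        """Disjoint features: 22 + 11 + 10 + (3 + 15 + 3) = 64 essential bp."""
        rng = np.random.default_rng(4)
        spec = FixtureSpec(
            genes=[GeneSpec(m_bits=(1, 0), w_bits=(1,), h_bits=(1, 1))],  # 5 AA
            d=0, filler_bp=90,
        )
        genome, expected = make_annotated_fixture(spec, rng)
        stats = quantify_compartments(genome)
        assert stats.essential_bp == 64
        assert stats.essential_bp + stats.nonessential_bp == stats.total_bp
        assert stats.n_genes == 1 and stats.n_coding_rnas == 1

    def test_operon_counts_shared_promoter_once(self):
        rng = np.random.default_rng(6)
        spec = FixtureSpec(
            genes=[GeneSpec(m_bits=(1, 0), w_bits=(1,), h_bits=(1, 1)),
                   GeneSpec(m_bits=(0, 1), w_bits=(1,), h_bits=(1, 0))],
            d=0, filler_bp=90, operon=True,
        )
        genome, expected = make_annotated_fixture(spec, rng)
        stats = quantify_compartments(genome)
        # one promoter + one terminator + two (motif + 5-codon ORF)
        assert stats.essential_bp == 22 + 11 + 2 * (10 + 21)
        assert stats.n_coding_rnas == 1 and stats.n_genes == 2

    def test_conservation_on_random_genomes(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            g = Genome(rng.integers(0, 2, 400, dtype=np.uint8))
            st = quantify_compartments(g)
            assert st.essential_bp + st.nonessential_bp == st.total_bp
            assert 0.0 <= st.coding_fraction <= 1.0


class TestLineage:
    def test_zero_rate_lineage_is_constant(self, one_gene_fixture, evaluator):
        (g, _), _ = one_gene_fixture
        cfg = ExperimentConfig(width=4, height=4, rates=MutationRates.zero(),
                               generations=20, seed=0, protocol="control")
        src = GridPopulation([g] * 16, 4, 4, Evaluator(evaluator.target))
        run = run_experiment(cfg, source=src)
        lin = reconstruct_lineage(run)
        assert len(lin) == 21
        assert all(r.genome == g for r in lin.records)
        assert lin.fixation_buffer_start == 18  # 10% of 20 generations

    def test_lineage_replay_with_mutations(self, one_gene_fixture, evaluator):
        (g, _), _ = one_gene_fixture
        rates = MutationRates(point=2e-3, small_insertion=1e-3, small_deletion=1e-3,
                              inversion=1e-3, translocation=1e-3,
                              large_duplication=1e-3, large_deletion=1e-3)
        cfg = ExperimentConfig(width=4, height=4, rates=rates, k=50.0,
                               generations=40, seed=3, protocol="control")
        src = GridPopulation([g] * 16, 4, 4, Evaluator(evaluator.target, k=50.0))
        run = run_experiment(cfg, source=src)
        lin = reconstruct_lineage(run)  # internally asserts bit-exact replay
        assert lin.records[-1].genome == run.population.genomes[
            int(np.argmin(run.records[-1].g))
        ]
        df = lin.dataframe()
        assert (df.essential_bp + df.nonessential_bp == df.genome_length).all()


class TestDuplicationEffects:
    def test_nonessential_duplication_is_neutral(self, one_gene_fixture, evaluator):
        (g, expected), _ = one_gene_fixture
        filler = expected.filler_positions
        ev = Duplication(b1=int(filler[5]), seg_len=10, insert_at=int(filler[30]))
        assert evaluator.error_of(ev.apply(g)) == evaluator.error_of(g)

    def test_gene_duplication_changes_error(self, one_gene_fixture, evaluator):
        (g, expected), _ = one_gene_fixture
        ess = np.nonzero(expected.essential_mask)[0]
        filler = expected.filler_positions
        ev = Duplication(b1=int(ess[0]), seg_len=len(ess), insert_at=int(filler[40]))
        assert evaluator.error_of(ev.apply(g)) != evaluator.error_of(g)

    def test_replay_delta_matches_direct_evaluation(self, one_gene_fixture, evaluator):
        (g, _), _ = one_gene_fixture
        cfg = ExperimentConfig(width=4, height=4,
                               rates=MutationRates(0, 0, 0, 0, 0, 2e-3, 0),
                               k=50.0, generations=15, seed=5, protocol="control",
                               length_ceiling=1200)
        src = GridPopulation([g] * 16, 4, 4, Evaluator(evaluator.target, k=50.0))
        run = run_experiment(cfg, source=src)
        lin = reconstruct_lineage(run)
        effects = duplication_effects(lin, src.evaluator, include_buffer=True)
        for gen, ev, dg in effects:
            idx = next(i for i, r in enumerate(lin.records) if r.generation == gen)
            before = lin.records[idx - 1].genome
            for e in lin.records[idx].events:
                after = e.apply(before)
                if e is ev:
                    direct = (src.evaluator.error_of(after)
                              - src.evaluator.error_of(before))
                    assert dg == direct
                before = after


class TestNeighborhood:
    def test_zero_rates_all_neutral(self, one_gene_fixture, evaluator):
        (g, _), _ = one_gene_fixture
        prof = sample_neighborhood(g, MutationRates.zero(), 200,
                                   np.random.default_rng(0), evaluator)
        assert np.all(prof.deltas == 0)
        assert prof.fraction_neutral() == 1.0

    def test_neutral_fraction_consistent_across_sample_sizes(
        self, one_gene_fixture, evaluator
    ):
        (g, _), _ = one_gene_fixture
        rates = MutationRates.mutator()
        p = []
        for R, seed in ((1000, 1), (4000, 2)):
            prof = sample_neighborhood(g, rates, R, np.random.default_rng(seed),
                                       evaluator)
            p.append(prof.fraction_neutral())
        # binomial comparison of the two estimated neutral fractions
        se = np.sqrt(p[0] * (1 - p[0]) * (1 / 1000 + 1 / 4000))
        assert abs(p[0] - p[1]) < 4 * max(se, 1e-3)

    def test_profile_invariant_to_genome_rotation(self, one_gene_fixture, evaluator):
        """Rotating the circle must not change the neighborhood distribution."""
        (g, _), _ = one_gene_fixture
        rates = MutationRates.mutator()
        p = []
        for genome, seed in ((g, 3), (g.rotated(57), 4)):
            prof = sample_neighborhood(genome, rates, 1500,
                                       np.random.default_rng(seed), evaluator)
            p.append(prof.fraction_neutral())
        se = np.sqrt(p[0] * (1 - p[0]) * 2 / 1500)
        assert abs(p[0] - p[1]) < 4 * max(se, 1e-3)

    def test_bin_schemes(self):
        prof = NeighborhoodProfile(
            parent_g=0.01,
            deltas=np.array([0.0, 0.0, -1e-4, 1e-3, 0.003, 0.0095, 0.0101, 0.5]),
            rates=MutationRates.wildtype(),
        )
        labels6, counts6 = bin_deltas(prof, "fig6")
        assert counts6.sum() == prof.R
        assert counts6[0] == 3          # neutral bin absorbs the beneficial draw
        assert counts6[-1] == 2         # 0.0101 and 0.5 are heavily deleterious
        assert counts6[1] == 1 and counts6[2] == 1 and counts6[5] == 1
        labels5, counts5 = bin_deltas(prof, "fig5")
        assert counts5.sum() == prof.R
        assert counts5[0] == 1          # beneficial counted separately
        with pytest.raises(ValueError):
            bin_deltas(prof, "fig7")

    def test_all_zero_deltas_fill_first_bin(self):
        prof = NeighborhoodProfile(0.0, np.zeros(50), MutationRates.zero())
        _, counts = bin_deltas(prof, "fig6")
        assert counts[0] == 50 and counts[1:].sum() == 0


class TestReduceNoncoding:
    def test_identity_at_current_length(self, one_gene_fixture, target):
        (g, _), _ = one_gene_fixture
        ind = Individual(g, target)
        current = quantify_compartments(ind).nonessential_bp
        out = reduce_noncoding(ind, current, np.random.default_rng(0))
        assert out.genome == g

    def test_reduction_conserves_error_exactly(self, one_gene_fixture, target):
        (g, _), _ = one_gene_fixture
        ind = Individual(g, target)
        before = quantify_compartments(ind)
        targeted = before.nonessential_bp - 40
        out = reduce_noncoding(ind, targeted, np.random.default_rng(1))
        after = quantify_compartments(out)
        assert after.nonessential_bp == targeted
        assert out.g == ind.g  # bit-identical, not approximately equal
        assert (out.annotation.protein_multiset()
                == ind.annotation.protein_multiset())

    def test_unreachable_target_rejected(self, one_gene_fixture, target):
        (g, _), _ = one_gene_fixture
        ind = Individual(g, target)
        with pytest.raises(ValueError):
            reduce_noncoding(ind, 10**6, np.random.default_rng(0))


class TestWilcoxon:
    @staticmethod
    def brute_force_p(diffs):
        diffs = np.asarray(diffs, float)
        ranks = sstats.rankdata(np.abs(diffs))
        W = ranks[diffs > 0].sum()
        n = len(diffs)
        ws = np.array([
            sum(ranks[i] for i in range(n) if (mask >> i) & 1)
            for mask in range(2**n)
        ])
        return min(1.0, 2 * min((ws <= W).mean(), (ws >= W).mean()))

    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2), (12, 3)])
    def test_matches_exhaustive_sign_pattern_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        for _ in range(4):
            mags = rng.permutation(np.arange(1.0, n + 1))
            signs = rng.choice([-1.0, 1.0], n)
            before = np.zeros(n)
            after = mags * signs
            _, p = wilcoxon_paired(before, after)
            assert p == pytest.approx(self.brute_force_p(after), abs=1e-12)

    def test_all_positive_ten_pairs(self):
        """n = 10 with every difference positive: p = 2/2^10 < 0.002."""
        before = np.zeros(10)
        after = np.arange(1.0, 11.0)
        _, p = wilcoxon_paired(before, after)
        assert p == pytest.approx(2 / 1024)
        assert p < 0.002

    def test_symmetric_differences_not_significant(self):
        before = np.zeros(8)
        after = np.array([1.0, -1.5, 2.0, -2.5, 3.0, -3.5, 4.0, -4.2])
        _, p = wilcoxon_paired(before, after)
        assert p > 0.5

    def test_degenerate_all_zero(self):
        with pytest.warns(UserWarning):
            stat, p = wilcoxon_paired(np.ones(6), np.ones(6))
        assert p == 1.0

    def test_length_checks(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2], [1, 2])
        with pytest.raises(ValueError):
            wilcoxon_paired([1] * 6, [1] * 5)
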