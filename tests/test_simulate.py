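"""Meiosis and single-seed-descent pedigree behaviour."""

import numpy as np
import pytest

from rilmap.containers import MATERNAL, PATERNAL
from rilmap.simulate import (
    ChromosomeModel,
    GenomeModel,
    Haplotype,
    ViabilityLocus,
    advance_ssd,
    heterozygous_genome_fraction,
    make_founder_f1,
    self_once,
    simulate_meiosis,
)


@pytest.fixture
def genome1():
    return GenomeModel(chromosomes=[ChromosomeModel("c1", 50.0, 50.0)])


class TestFounderF1:
    def test_seven_intact_pairs(self, genome7):
        f1 = make_founder_f1(genome7)
        assert len(f1.genome.pairs) == 7
        for name, (h0, h1) in f1.genome.pairs.items():
            assert h0.segments == [(0.0, 150.0, MATERNAL)]
            assert h1.segments == [(0.0, 150.0, PATERNAL)]
        assert f1.genome.total_junctions() == 0
        assert f1.generation == 1

    def test_single_chromosome_layout(self):
        g = GenomeModel(chromosomes=[ChromosomeModel("c1", 40.0, 60.0)])
        f1 = make_founder_f1(g)
        (h0, _h1) = f1.genome.pairs["c1"]
        assert h0.segments == [(0.0, 100.0, MATERNAL)]


class TestMeiosis:
    def test_invalid_seed_type(self, genome1):
        f1 = make_founder_f1(genome1)
        with pytest.raises(TypeError):
            simulate_meiosis(f1.genome, genome1, "not-a-seed")

    def test_chromosome_mismatch(self, genome1, genome7):
        f1 = make_founder_f1(genome7)
        with pytest.raises(ValueError):
            simulate_meiosis(f1.genome, genome1, 0)

    def test_homozygous_parent_gives_identical_gamete(self, genome1):
        f1 = make_founder_f1(genome1)
        hom = f1.genome
        hom.pairs["c1"] = (hom.pairs["c1"][0], hom.pairs["c1"][0].copy())
        for seed in range(5):
            gam = simulate_meiosis(hom, genome1, seed)
            assert gam["c1"].segments == hom.pairs["c1"][0].segments

    def test_full_suppression_transmits_intact_haplotype(self):
        g = GenomeModel(
            chromosomes=[ChromosomeModel("c1", 50.0, 50.0)],
            suppression_prob={"c1": 1.0},
        )
        f1 = make_founder_f1(g)
        for seed in range(10):
            gam = simulate_meiosis(f1.genome, g, seed)["c1"]
            assert gam.n_junctions == 0
            assert gam.segments in (
                [(0.0, 100.0, MATERNAL)],
                [(0.0, 100.0, PATERNAL)],
            )

    def test_obligate_mean_one_junction_per_gamete_chromosome(self, genome1):
        # each of the 2 chiasmata (one per arm) lands on a sampled chromatid
        # with probability 1/2, so E[junctions] = 1
        f1 = make_founder_f1(genome1)
        rng = np.random.default_rng(123)
        n = 20_000
        j = [simulate_meiosis(f1.genome, genome1, rng)["c1"].n_junctions for _ in range(n)]
        se = np.std(j) / np.sqrt(n)
        assert abs(np.mean(j) - 1.0) < 4 * se

    def test_segment_tiling_invariant_across_generations(self, cohort41, genome7):
        for g in sorted(cohort41.generations):
            for line in cohort41.lines(g):
                for name, (h0, h1) in line.genome.pairs.items():
                    length = genome7.chromosome(name).length
                    h0.validate(length)
                    h1.validate(length)


class TestSelfing:
    def test_homozygous_parent_breeds_true(self, genome1):
        f1 = make_founder_f1(genome1)
        hom = f1.genome
        hom.pairs["c1"] = (hom.pairs["c1"][0], hom.pairs["c1"][0].copy())
        child = self_once(f1, genome1, 3)
        assert child.genome.pairs["c1"][0].segments == hom.pairs["c1"][0].segments
        assert child.genome.pairs["c1"][1].segments == hom.pairs["c1"][0].segments
        assert child.generation == 2
        assert child.parent_id == f1.line_id

    def test_mendelian_segregation_at_one_locus(self, genome1):
        f1 = make_founder_f1(genome1)
        rng = np.random.default_rng(7)
        counts = {"A": 0, "H": 0, "B": 0}
        n = 20_000
        for _ in range(n):
            child = self_once(f1, genome1, rng)
            counts[child.genome.call_at("c1", 25.0)] += 1
        assert counts["A"] / n == pytest.approx(0.25, abs=0.015)
        assert counts["H"] / n == pytest.approx(0.50, abs=0.015)
        assert counts["B"] / n == pytest.approx(0.25, abs=0.015)

    def test_lethal_genotype_never_appears(self, genome1):
        g = GenomeModel(
            chromosomes=genome1.chromosomes,
            viability_loci=[ViabilityLocus("c1", 25.0, w_A=0.0, w_H=1.0, w_B=1.0)],
        )
        f1 = make_founder_f1(g)
        rng = np.random.default_rng(5)
        for _ in range(300):
            child = self_once(f1, g, rng)
            assert child.genome.call_at("c1", 25.0) != "A"


class TestAdvanceSSD:
    def test_pedigree_bookkeeping(self, cohort41):
        assert len(cohort41.lines(6)) == 41
        ped = cohort41.pedigree().set_index("line_id")
        for line in cohort41.lines(6):
            # walk the ancestor chain back to the F1
            cur = line
            for gen in (6, 5, 4, 3, 2):
                assert cur.generation == gen
                parent_id = ped.loc[cur.line_id, "parent_id"]
                cur = next(
                    ln for ln in cohort41.lines(gen - 1) if ln.line_id == parent_id
                )
            assert cur.generation == 1

    def test_target_before_f2_rejected(self, genome7):
        with pytest.raises(ValueError):
            advance_ssd(5, 1, genome7, 0)

    def test_full_suppression_fixes_intact_chromosomes(self):
        g = GenomeModel.ryegrass_default(suppression=1.0)
        cohort = advance_ssd(60, 6, g, rng_seed=2)
        het_pairs = 0
        total = 0
        for line in cohort.lines(6):
            for name, (h0, h1) in line.genome.pairs.items():
                assert h0.n_junctions == 0 and h1.n_junctions == 0
                total += 1
                het_pairs += h0.segments != h1.segments
        # with no crossovers each pair fixes at rate 1-(1/2)^5 by F6
        assert het_pairs / total == pytest.approx(0.5**5, abs=0.03)

    def test_heterozygosity_halves_each_generation(self, genome7):
        cohort = advance_ssd(600, 4, genome7, rng_seed=9)
        for g in (2, 3, 4):
            het = np.mean([heterozygous_genome_fraction(l) for l in cohort.lines(g)])
            assert het == pytest.approx(0.5 ** (g - 1), abs=0.02)

    def test_attrition_shrinks_cohort(self, genome7):
        cohort = advance_ssd(200, 6, genome7, rng_seed=4, attrition_rate=0.2)
        sizes = [len(cohort.lines(g)) for g in (2, 3, 4, 5, 6)]
        assert sizes[0] == 200
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] < 200

    def test_nonrecombinant_fraction_monotone_in_suppression(self):
        fracs = []
        for supp in (0.0, 0.4, 0.8):
            g = GenomeModel.ryegrass_default(suppression=supp)
            cohort = advance_ssd(120, 6, g, rng_seed=21)
            n_intact = 0
            total = 0
            for line in cohort.lines(6):
                for name, (h0, h1) in line.genome.pairs.items():
                    total += 1
                    n_intact += (
                        h0.n_junctions == 0
                        and h1.n_junctions == 0
                        and h0.segments == h1.segments
                    )
            fracs.append(n_intact / total)
        assert fracs == sorted(fracs)

    def test_reproducible_with_same_seed(self, genome7):
        a = advance_ssd(10, 4, genome7, rng_seed=33)
        b = advance_ssd(10, 4, genome7, rng_seed=33)
        for la, lb in zip(a.lines(4), b.lines(4)):
            for name in la.genome.pairs:
                assert la.genome.pairs[name][0].segments == lb.genome.pairs[name][0].segments
                assert la.genome.pairs[name][1].segments == lb.genome.pairs[name][1].segments


class TestHaplotypeValidation:
    def test_gap_rejected(self):
        h = Haplotype("c1", [(0.0, 40.0, MATERNAL), (45.0, 100.0, PATERNAL)])
        with pytest.raises(ValueError):
            h.validate(100.0)

    def test_same_founder_neighbours_rejected(self):
        h = Haplotype("c1", [(0.0, 40.0, MATERNAL), (40.0, 100.0, MATERNAL)])
        with pytest.raises(ValueError):
            h.validate(100.0)
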