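"""Crossover counting, chromosome classification, heterozygosity and the
observable-crossover expectation."""

import numpy as np
import pandas as pd
import pytest

from rilmap.constitution import (
    CLASS_MATERNAL,
    CLASS_PATERNAL,
    CLASS_RECOMBINANT,
    CLASS_UNCLASSIFIED,
    CrossoverTheory,
    analyze_constitution,
    classify_chromosome,
    cohort_summary,
    chromosome_pair_denominator,
    count_crossovers,
    expected_observable_crossovers,
    floor_one_decimal,
    heterozygosity_stats,
    lineal_coherence,
    truth_transition_count,
)
from tests.conftest import make_matrix


class TestCountCrossovers:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            (list("AAAA"), 0),
            (list("AABBB"), 1),  # B run of 3 confirms
            (list("AABBAAA"), 0),  # B run of 2 unconfirmed, A resumes
            (list("AABBBAAA"), 2),  # confirmed out and back
            (list("AAHHHBBB"), 2),  # A->H and H->B each one event
            (list("AA-B-B-BAA"), 1),  # confirmation over non-missing calls
            (list("AAB"), 0),  # truncated B run cannot confirm
            ([], 0),
            (list("----"), 0),
        ],
    )
    def test_rule_by_hand(self, calls, expected):
        _blocks, n = count_crossovers(calls, min_confirm=3)
        assert n == expected

    def test_min_confirm_one_counts_every_change(self):
        _b, n = count_crossovers(list("ABABAB"), min_confirm=1)
        assert n == 5

    def test_end_exemption_flag(self):
        assert count_crossovers(list("AAAABB"), min_confirm=3)[1] == 0
        assert count_crossovers(list("AAAABB"), min_confirm=3, end_exempt=True)[1] == 1

    def test_exclusive_first_call_flag(self):
        # "followed by three calls" excluding the first call of the block
        calls = list("AABBB")
        assert count_crossovers(calls, min_confirm=3, count_includes_first=True)[1] == 1
        assert count_crossovers(calls, min_confirm=3, count_includes_first=False)[1] == 0
        assert count_crossovers(list("AABBBB"), min_confirm=3,
                                count_includes_first=False)[1] == 1

    def test_blocks_cover_confirmed_states(self):
        blocks, n = count_crossovers(list("AAABBBAAA"), min_confirm=3)
        assert n == 2
        assert [b.state for b in blocks] == ["A", "B", "A"]

    def test_matches_truth_on_error_free_data(self, cohort41, truth41):
        # min_confirm=1 on error-free calls equals the brute-force
        # segment/marker-intersection oracle, individual by individual
        for i, line in enumerate(cohort41.lines(6)):
            oracle = truth_transition_count(line, truth41.markers)
            for chrom, sub in truth41.markers.groupby("chromosome", sort=False):
                order = sub.sort_values("pos_cM").index.to_numpy()
                _b, n = count_crossovers(truth41.calls[i, order], min_confirm=1)
                assert n == oracle[chrom]

    def test_confirmation_rule_suppresses_error_inflation(self, truth41, cohort41):
        from tests.test_qc import _inject_errors

        noisy = _inject_errors(truth41, rate=0.01, seed=55)
        truth_total = sum(
            truth_transition_count(line, truth41.markers).sum()
            for line in cohort41.lines(6)
        )

        def total(m, min_confirm):
            out = 0
            for chrom, sub in m.markers.groupby("chromosome", sort=False):
                order = sub.sort_values("pos_cM").index.to_numpy()
                for i in range(m.n_individuals):
                    out += count_crossovers(m.calls[i, order], min_confirm=min_confirm)[1]
            return out

        loose = total(noisy, 1)
        confirmed = total(noisy, 3)
        assert loose > 1.5 * truth_total  # raw counting inflates badly
        assert confirmed <= 1.05 * truth_total  # the rule recovers the truth


class TestClassifyChromosome:
    def test_all_maternal(self):
        assert classify_chromosome(["B"] * 50) == CLASS_MATERNAL

    def test_all_paternal(self):
        assert classify_chromosome(["A"] * 50) == CLASS_PATERNAL

    def test_mixed_recombinant(self):
        assert classify_chromosome(["A"] * 25 + ["B"] * 25) == CLASS_RECOMBINANT

    def test_mostly_missing_unclassified(self):
        assert classify_chromosome(["A"] * 5 + ["-"] * 50) == CLASS_UNCLASSIFIED

    def test_consistent_with_crossover_count(self, truth41):
        report = analyze_constitution(truth41)
        for chrom in report.chromosomes:
            codes = report.class_codes[chrom]
            non_rec = codes.isin([CLASS_MATERNAL, CLASS_PATERNAL])
            assert (report.junctions.loc[non_rec.to_numpy(), chrom] == 0).all()


class TestHeterozygosity:
    def test_no_h_gives_zero(self):
        m = make_matrix(np.array([list("AB"), list("BA")]))
        _per, avg = heterozygosity_stats(m)
        assert avg == 0.0

    def test_two_of_41(self):
        col = ["H", "H"] + ["A"] * 20 + ["B"] * 19
        m = make_matrix(np.array(col).reshape(-1, 1))
        per, avg = heterozygosity_stats(m)
        assert avg == pytest.approx(2 / 41)

    def test_nonmissing_denominator(self):
        col = ["H", "-", "A", "B"]
        m = make_matrix(np.array(col).reshape(-1, 1))
        _per, avg_all = heterozygosity_stats(m)
        _per, avg_nm = heterozygosity_stats(m, denominator="nonmissing")
        assert avg_all == pytest.approx(1 / 4)
        assert avg_nm == pytest.approx(1 / 3)


class TestCrossoverTheory:
    def test_f1_base_is_14(self):
        assert expected_observable_crossovers(1) == 14.0

    def test_halves_each_generation(self):
        t = CrossoverTheory()
        for g in range(1, 10):
            assert t.per_generation(g + 1) / t.per_generation(g) == 0.5

    def test_linear_in_base(self):
        assert CrossoverTheory(28.0).per_generation(3) == pytest.approx(
            2 * CrossoverTheory(14.0).per_generation(3)
        )

    def test_printed_values(self):
        assert expected_observable_crossovers(3) == pytest.approx(3.50)
        assert expected_observable_crossovers(2, cumulative=True) == pytest.approx(21.0)
        assert CrossoverTheory().cumulative(6) == pytest.approx(27.5625)
        assert expected_observable_crossovers(6, cumulative=True, floored=True) == 27.5

    def test_floor_one_decimal(self):
        assert floor_one_decimal(27.5625) == 27.5
        assert floor_one_decimal(21.0) == 21.0


class TestLinealCoherence:
    def test_heterozygous_ancestor_permits_everything(self):
        frac, v = lineal_coherence(list("HHHH"), list("ABHB"))
        assert frac == 1.0 and v == []

    def test_homozygote_flip_is_violation(self):
        frac, v = lineal_coherence(list("AABB"), list("AABA"))
        assert v == [3]
        assert frac == pytest.approx(3 / 4)

    def test_missing_uninformative(self):
        frac, v = lineal_coherence(list("A-B"), list("A-A"))
        assert frac == pytest.approx(1 / 2)

    def test_simulated_lineage_is_fully_coherent(self, cohort41, panel_dense, truth41):
        from rilmap.containers import SNP
        from rilmap.simulate import truth_genotype_matrix

        f2 = truth_genotype_matrix(cohort41.lines(2), panel_dense.subset(SNP))
        f2_of = {ln.split("_")[0]: i for i, ln in enumerate(f2.individuals)}
        for i, ind in enumerate(truth41.individuals):
            stem = ind.split("_")[0]
            frac, violations = lineal_coherence(
                f2.calls[f2_of[stem]], truth41.calls[i]
            )
            assert frac == 1.0, violations

    def test_empty_locus_set_rejected(self):
        with pytest.raises(ValueError):
            lineal_coherence([], [])


class TestCohortSummary:
    def test_study_denominators(self):
        assert chromosome_pair_denominator(41, 7) == 287
        assert chromosome_pair_denominator(167, 7) == 1169

    def test_summary_counts(self, truth41):
        report = analyze_constitution(truth41)
        s = cohort_summary(report)
        assert s["denominator"] == 287
        assert (
            s["non_recombinant"] + s["recombinant"] + s["unclassified"]
            == s["denominator"]
        )
        assert (
            s["maternal_non_recombinant"] + s["paternal_non_recombinant"]
            == s["non_recombinant"]
        )
        per = pd.DataFrame(s["per_chromosome"]).T
        assert per["non_recombinant"].sum() == s["non_recombinant"]

    def test_all_recombinant_gives_zero_fraction(self):
        calls = np.array([list("AAABBB"), list("BBBAAA")])
        m = make_matrix(calls)
        report = analyze_constitution(m, min_informative=3)
        s = cohort_summary(report)
        assert s["non_recombinant_fraction"] == 0.0
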