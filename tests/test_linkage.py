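"""Two-point linkage, grouping, segregation distortion and LD statistics."""

import numpy as np
import pytest

from rilmap.linkage import (
    estimate_rf,
    group_markers,
    ld_r2,
    ld_long_table,
    pairwise_ril,
    rf_meiotic_to_ril,
    rf_ril_to_meiotic,
    sd_results_frame,
    segregation_test,
)
from rilmap.simulate import (
    ChromosomeModel,
    GenomeModel,
    advance_ssd,
    truth_genotype_matrix,
)
from tests.conftest import make_matrix


def two_marker_cohort(d_cM, n=500, seed=101, generation=6):
    """Two markers d cM apart on one 75 cM arm; obligate model gives the
    per-meiosis recombination fraction r = d / 150."""
    g = GenomeModel(chromosomes=[ChromosomeModel("c1", 75.0, 75.0)])
    cohort = advance_ssd(n, generation, g, seed)
    import pandas as pd

    panel = pd.DataFrame(
        {
            "marker_id": ["mL", "mR"],
            "chromosome": "c1",
            "pos_cM": [20.0, 20.0 + d_cM],
            "kind": "SNP_codominant",
        }
    )
    return truth_genotype_matrix(cohort.lines(generation), panel)


class TestRfRil:
    def test_identical_vectors(self):
        m = make_matrix(np.array([list("AA"), list("AA"), list("BB"), list("BB")]))
        pl = estimate_rf(m, ("m0", "m1"))
        assert pl.rf_hat == 0.0
        assert pl.lod == pytest.approx(4 * np.log10(2))

    def test_orthogonal_vectors(self):
        m = make_matrix(np.array([list("AA"), list("AB"), list("BA"), list("BB")]))
        pl = estimate_rf(m, ("m0", "m1"))
        assert pl.rf_hat == 0.5
        assert pl.lod == pytest.approx(0.0)

    def test_h_excluded_pairwise(self):
        m = make_matrix(np.array([list("AA"), list("HH"), list("BB"), list("HA")]))
        pl = estimate_rf(m, ("m0", "m1"))
        assert pl.n_informative == 2

    def test_too_few_informative_flagged(self):
        m = make_matrix(np.array([list("A-"), list("-B"), list("HH")]))
        pl = estimate_rf(m, ("m0", "m1"))
        assert not pl.valid

    def test_recovers_expected_ril_fraction(self):
        # true meiotic r = 0.1 -> observed R = 2r/(1+2r) = 1/6
        m = two_marker_cohort(d_cM=15.0, n=500, seed=19)
        pl = estimate_rf(m, ("mL", "mR"))
        R = rf_meiotic_to_ril(0.1)
        se = np.sqrt(R * (1 - R) / pl.n_informative)
        assert abs(pl.rf_hat - R) < 3 * se

    def test_relabel_invariance(self):
        m = two_marker_cohort(d_cM=15.0, n=200, seed=23)
        pl = estimate_rf(m, ("mL", "mR"))
        flipped = m.copy()
        col = flipped.column("mL")
        j = 0
        swap = {"A": "B", "B": "A"}
        flipped.calls[:, j] = [swap.get(c, c) for c in col]
        pf = estimate_rf(flipped, ("mL", "mR"))
        # rf reflects to 1-rf (capped at 0.5); LOD is invariant
        raw = pl.rf_hat  # below 0.5 here, so uncapped
        assert pf.rf_hat == pytest.approx(min(1 - raw, 0.5))
        assert pf.lod == pytest.approx(pl.lod, abs=1e-9)
        assert pf.n_informative == pl.n_informative

    def test_pairwise_matches_single_pair(self, truth41):
        sub = truth41.take_markers(np.arange(12))
        rf, lod, n = pairwise_ril(sub)
        for a in sub.marker_ids[:4]:
            for b in sub.marker_ids[4:8]:
                pl = estimate_rf(sub, (a, b))
                assert rf.loc[a, b] == pytest.approx(pl.rf_hat)
                assert lod.loc[a, b] == pytest.approx(pl.lod)
                assert n.loc[a, b] == pl.n_informative

    def test_lod_decreases_toward_half(self):
        # fixed n: LOD is non-increasing as rf rises to 0.5
        lods = []
        for n_d in range(0, 26):
            m_calls = [["A", "A"]] * (50 - n_d) + [["A", "B"]] * n_d
            m = make_matrix(np.array(m_calls))
            lods.append(estimate_rf(m, ("m0", "m1")).lod)
        assert all(a >= b - 1e-12 for a, b in zip(lods, lods[1:]))


class TestRilMeioticConversion:
    @pytest.mark.parametrize(
        "R, r",
        [(0.0, 0.0), (1 / 6, 0.1), (0.4, 1 / 3)],
    )
    def test_closed_form(self, R, r):
        assert rf_ril_to_meiotic(R) == pytest.approx(r, abs=1e-4)

    def test_inverse_of_forward(self):
        for r in (0.01, 0.1, 0.25, 0.49):
            assert rf_ril_to_meiotic(rf_meiotic_to_ril(r)) == pytest.approx(r)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rf_ril_to_meiotic(0.5)


class TestF2Coding:
    def test_f2_em_recovers_r(self):
        m = two_marker_cohort(d_cM=30.0, n=400, seed=29, generation=2)
        pl = estimate_rf(m, ("mL", "mR"), coding="f2")
        r_true = 30.0 / 150.0
        se = np.sqrt(r_true * (1 - r_true) / (2 * pl.n_informative))
        assert abs(pl.rf_hat - r_true) < 4 * se
        assert pl.lod > 3

    def test_f2_perfect_linkage(self):
        m = make_matrix(
            np.array([list("AA"), list("HH"), list("BB"), list("AA"), list("BB")])
        )
        pl = estimate_rf(m, ("m0", "m1"), coding="f2")
        assert pl.rf_hat == pytest.approx(0.0, abs=1e-6)

    def test_f2_independence(self):
        rng = np.random.default_rng(3)
        calls = rng.choice(list("AHHB"), size=(400, 2))
        m = make_matrix(calls)
        pl = estimate_rf(m, ("m0", "m1"), coding="f2")
        assert abs(pl.rf_hat - 0.5) < 0.06

    def test_dominant_marker_collapsed(self):
        # a dominant presence marker scored against its own codominant source
        import pandas as pd

        m = two_marker_cohort(d_cM=10.0, n=300, seed=31, generation=2)
        dom = np.where(np.isin(m.column("mR"), ["A", "H"]), "A", "B")
        calls = np.column_stack([m.calls, dom])
        markers = pd.concat(
            [
                m.markers,
                pd.DataFrame(
                    [{"marker_id": "pav", "chromosome": "c1", "pos_cM": 30.0,
                      "kind": "PAV_dominant", "pav_donor": 1}]
                ),
            ],
            ignore_index=True,
        )
        from rilmap.containers import GenotypeMatrix

        m2 = GenotypeMatrix(individuals=m.individuals, markers=markers, calls=calls)
        pl = estimate_rf(m2, ("mR", "pav"), coding="f2")
        assert pl.rf_hat == pytest.approx(0.0, abs=1e-6)


class TestGrouping:
    def test_two_linked_markers_one_group(self):
        m = make_matrix(np.tile(np.array(list("AB")), (20, 1)))
        m.calls[10:, :] = "B"
        m.calls[:10, :] = "A"
        rf, lod, _ = pairwise_ril(m)
        groups, sweep = group_markers(rf, lod, min_lod=3.0)
        assert len(groups) == 1

    def test_threshold_above_everything_isolates(self, truth41):
        sub = truth41.take_markers(np.arange(10))
        rf, lod, _ = pairwise_ril(sub)
        groups, _ = group_markers(rf, lod, min_lod=1e6)
        assert len(groups) == 10

    def test_seven_chromosomes_recovered(self, genome7):
        from rilmap.observe import sample_marker_panel

        cohort = advance_ssd(200, 6, genome7, 37)
        panel = sample_marker_panel(genome7, 420, 0, 39)
        m = truth_genotype_matrix(cohort.lines(6), panel.subset("SNP_codominant"))
        rf, lod, _ = pairwise_ril(m)
        groups, sweep = group_markers(rf, lod, min_lod=6.0)
        assert len(groups) == 7
        # groups must coincide with chromosomes
        chrom_of = m.markers.set_index("marker_id")["chromosome"]
        for grp in groups:
            assert len(set(chrom_of[mid] for mid in grp)) == 1
        assert sweep[6.0] == 7


class TestSegregationDistortion:
    def test_balanced_counts(self):
        m = make_matrix(np.array([["A"]] * 20 + [["B"]] * 20))
        res, _ = segregation_test(m)
        assert res[0].chi2 == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0)
        assert not res[0].distorted

    def test_30_10_example(self):
        m = make_matrix(np.array([["A"]] * 30 + [["B"]] * 10))
        res, _ = segregation_test(m)
        assert res[0].chi2 == pytest.approx(10.0)
        assert res[0].p_value == pytest.approx(0.00157, abs=2e-5)
        assert res[0].distorted

    def test_f2_coding_uses_1_2_1(self):
        m = make_matrix(np.array([["A"]] * 10 + [["H"]] * 20 + [["B"]] * 10))
        res, _ = segregation_test(m, coding="f2")
        assert res[0].chi2 == pytest.approx(0.0)

    def test_all_missing_marker_skipped(self):
        m = make_matrix(np.array([["-", "A"], ["-", "B"]]))
        res, per_chrom = segregation_test(m)
        assert res[0].skipped
        assert not np.isnan(per_chrom["c1"])

    def test_frame_export(self):
        m = make_matrix(np.array([["A", "B"], ["B", "A"]]))
        res, _ = segregation_test(m)
        df = sd_results_frame(res)
        assert list(df["marker_id"]) == ["m0", "m1"]


class TestLD:
    def test_diagonal_is_one(self, truth41):
        sub = truth41.take_markers(np.arange(8))
        r2 = ld_r2(sub)
        assert np.allclose(np.diag(r2.to_numpy()), 1.0)

    def test_repulsion_pair_r2_one(self):
        m = make_matrix(np.array([list("AB"), list("AB"), list("BA"), list("BA")]))
        r2 = ld_r2(m)
        assert r2.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        m = make_matrix(np.array([list("AA"), list("AB"), list("AA"), list("AB")]))
        r2 = ld_r2(m)
        assert np.isnan(r2.iloc[0, 1])

    def test_unlinked_null_scale(self):
        rng = np.random.default_rng(8)
        calls = rng.choice(["A", "B"], size=(500, 30))
        m = make_matrix(calls)
        r2 = ld_r2(m).to_numpy()
        off = r2[np.triu_indices(30, 1)]
        assert np.nanmean(off) < 0.01  # ~1/(n-1) null scale

    def test_within_exceeds_between_chromosome(self, truth41):
        r2 = ld_r2(truth41)
        long = ld_long_table(r2, truth41.markers)
        within = long.loc[long["same_chromosome"], "r2"].mean()
        between = long.loc[~long["same_chromosome"], "r2"].mean()
        assert within > between

    def test_symmetry(self, truth41):
        sub = truth41.take_markers(np.arange(15))
        r2 = ld_r2(sub).to_numpy()
        assert np.allclose(r2, r2.T, equal_nan=True)
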