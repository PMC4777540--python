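import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mupscent.errors import ValidationError
from mupscent.phenotypes import (
    CENTRAL_MUP_MASSES,
    CorrectionSpec,
    MassProfile,
    average_mass,
    individuality_stats,
    predict_mass_profile,
    predicted_vs_observed,
    proportional_profile,
    residue_mass_shift,
)
from mupscent.read_collapse import AcceptedRecord, ExonCatalog


class TestAverageMass:
    def test_glycine_dipeptide(self):
        assert average_mass("GG") == pytest.approx(2 * 57.0519 + 18.0153)

    def test_empty_sequence_is_water(self):
        assert average_mass("") == pytest.approx(18.0153)

    def test_phe_val_exchange_matches_published_peak_spacing(self):
        """F->V shifts mass by -48.04 Da, matching the 18693 - 18645 spacing
        of the published central-MUP peak list."""
        delta = average_mass("F") - average_mass("V")
        assert delta == pytest.approx(48.044)
        assert CENTRAL_MUP_MASSES[4] - CENTRAL_MUP_MASSES[0] == 48

    aa = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40)

    @given(aa, aa)
    @settings(deadline=None, derandomize=True)
    def test_additivity(self, left, right):
        water = 18.0153
        assert average_mass(left + right) == pytest.approx(
            average_mass(left) + average_mass(right) - water
        )

    def test_signal_peptide_cleavage(self):
        assert average_mass("MKLLLF", signal_peptide_length=3) == pytest.approx(
            average_mass("LLF")
        )

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            average_mass("ACX")

    def test_r161l_shift(self):
        assert residue_mass_shift("R161L") == pytest.approx(-43.0281)


def one_seq_catalog(pairs):
    total = sum(d for _, d in pairs)
    return ExonCatalog(
        "exon23",
        [AcceptedRecord(s, d, d / total) for s, d in pairs],
        [],
    )


class TestPredictMassProfile:
    def test_single_sequence(self):
        cat = one_seq_catalog([("AAA", 100)])
        prof = predict_mass_profile(cat, {"AAA": 18645.0}, "m1", bins=[18645.0])
        assert prof.proportions.tolist() == [1.0]

    def test_two_mass_classes(self):
        cat = one_seq_catalog([("AAA", 600), ("CCC", 400)])
        masses = {"AAA": 18693.0, "CCC": 18645.0}
        prof = predict_mass_profile(cat, masses, "m1", bins=[18645.0, 18693.0])
        assert prof.bins.tolist() == [18645.0, 18693.0]
        np.testing.assert_allclose(prof.proportions, [0.4, 0.6])

    def test_correction_moves_fraction(self):
        cat = one_seq_catalog([("AAA", 500), ("CCC", 500)])
        masses = {"AAA": 18708.0, "CCC": 18645.0}
        corr = CorrectionSpec("R161L", source_mass=18708.0, fraction=0.1)
        prof = predict_mass_profile(
            cat, masses, "m1",
            bins=[18645.0, 18665.0, 18708.0],
            corrections=[corr],
        )
        # 0.1 moves from the 18708 class to 18708 - 43.03 ~ 18665
        assert prof.proportion_at(18708.0) == pytest.approx(0.4)
        assert prof.proportion_at(18665.0, tolerance=1.0) == pytest.approx(0.1)
        assert prof.proportions.sum() == pytest.approx(1.0)

    def test_correction_order_invariance_on_distinct_bins(self):
        cat = one_seq_catalog([("AAA", 500), ("CCC", 500)])
        masses = {"AAA": 18708.0, "CCC": 18645.0}
        corrs = [
            CorrectionSpec("X1Y", 18708.0, 0.1, mass_shift=-20.0),
            CorrectionSpec("A1B", 18645.0, 0.2, mass_shift=+30.0),
        ]
        p1 = predict_mass_profile(cat, masses, "m", bins=[18645.0, 18708.0],
                                  corrections=corrs)
        p2 = predict_mass_profile(cat, masses, "m", bins=[18645.0, 18708.0],
                                  corrections=corrs[::-1])
        np.testing.assert_allclose(p1.bins, p2.bins)
        np.testing.assert_allclose(p1.proportions, p2.proportions)

    def test_unbinned_mass_opens_new_bin_with_warning(self):
        cat = one_seq_catalog([("AAA", 100)])
        with pytest.warns(UserWarning, match="new bin"):
            prof = predict_mass_profile(cat, {"AAA": 19000.0}, "m1",
                                        bins=[18645.0])
        assert prof.proportion_at(19000.0) == 1.0


class TestProportionalProfile:
    def test_intensity_shares(self):
        prof = proportional_profile(
            [(18645.0, 100.0), (18693.0, 300.0)], bins=[18645, 18693]
        )
        np.testing.assert_allclose(prof.proportions, [0.25, 0.75])

    def test_nearest_center_within_tolerance(self):
        prof = proportional_profile([(18646.0, 10.0)], bins=[18645, 18650],
                                    tolerance=2.0)
        assert prof.proportion_at(18645.0) == 1.0

    def test_duplicate_peaks_summed(self):
        prof = proportional_profile(
            [(18645.0, 10.0), (18645.4, 30.0), (18693.0, 60.0)],
            bins=[18645, 18693],
        )
        np.testing.assert_allclose(prof.proportions, [0.4, 0.6])

    def test_unmatched_peaks_dropped_with_tally(self):
        prof = proportional_profile(
            [(18645.0, 10.0), (19500.0, 99.0)], bins=[18645]
        )
        assert prof.n_unmatched == 1
        assert prof.proportions.tolist() == [1.0]

    def test_all_unmatched_rejected(self):
        with pytest.raises(ValidationError):
            proportional_profile([(19500.0, 1.0)], bins=[18645])


def profile(ind, props, bins=(18645.0, 18693.0, 18708.0), **kw):
    return MassProfile(ind, np.array(bins), np.array(props), **kw)


class TestIndividualityStats:
    def test_identical_replicates_r_one(self):
        profs = [
            profile("a", [0.5, 0.3, 0.2], sample_id="a1"),
            profile("a", [0.5, 0.3, 0.2], sample_id="a2"),
            profile("b", [0.1, 0.1, 0.8], sample_id="b1"),
            profile("b", [0.1, 0.1, 0.8], sample_id="b2"),
        ]
        res = individuality_stats(profs)
        np.testing.assert_allclose(res.self_r, 1.0)
        assert res.median_self_r > res.median_other_r

    def test_orthogonal_profiles_anticorrelated(self):
        profs = [
            profile("a", [1.0, 0.0], bins=(18645.0, 18693.0), sample_id="a1"),
            profile("a", [1.0, 0.0], bins=(18645.0, 18693.0), sample_id="a2"),
            profile("b", [0.0, 1.0], bins=(18645.0, 18693.0), sample_id="b1"),
        ]
        res = individuality_stats(profs)
        np.testing.assert_allclose(res.other_r, -1.0)

    def test_synthetic_population_separates_self_from_other(self):
        from mupscent.synthetic_data import GeneratorConfig, generate_population

        pop = generate_population(
            GeneratorConfig(seed=3, ms_noise_sd=0.02, silencing_prob=0.3)
        )
        res = individuality_stats(pop.observed_profiles())
        assert res.median_self_r > res.median_other_r
        assert res.ks.statistic > 0
        assert res.ks.p_value < 0.01

    def test_needs_replicates(self):
        with pytest.raises(ValidationError):
            individuality_stats([profile("a", [0.5, 0.3, 0.2])])


class TestPredictedVsObserved:
    def test_identity(self):
        pred = [profile("a", [0.5, 0.3, 0.2]), profile("b", [0.2, 0.2, 0.6])]
        obs = [
            profile("a", [0.5, 0.3, 0.2], source="observed_ms"),
            profile("b", [0.2, 0.2, 0.6], source="observed_ms"),
        ]
        res = predicted_vs_observed(pred, obs)
        assert res.regression.extra["slope"] == pytest.approx(1.0)
        assert res.regression.extra["r2"] == pytest.approx(1.0)

    def test_disjoint_bins_rejected(self):
        pred = [profile("a", [1.0], bins=(18645.0,))]
        obs = [profile("a", [1.0], bins=(18724.0,))]
        with pytest.raises(ValidationError):
            predicted_vs_observed(pred, obs)
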