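"""SPR kinetics, melting, CD arithmetic and stoichiometric inhibition."""

import math

import numpy as np
import pytest

from seqforge import biophysics as bp
from seqforge import synthetic as syn

#: Published-style rate-constant set used as fitting ground truths.
RATE_CONSTANTS = {
    "Sq_Ab1": (1.9e4, 1.71e-4),
    "Sq_Ab2": (2.97e4, 4.24e-4),
    "Sq_Ab6": (1.55e4, 3.16e-4),
    "Sq_Ab7": (9.21e3, 2.12e-4),
    "Sq_Ab9": (2.48e4, 9.49e-4),
    "Sq_Ab10": (5.13e4, 2.62e-4),
    "Sq_Ab14": (1.56e4, 4.47e-4),
    "Sq_Ab15": (7.52e3, 9.04e-4),
    "Sq_Ab16": (4.98e4, 5.65e-4),
    "Sq_Ab20": (2.12e4, 2.13e-4),
    "Sq_Ab22": (1.63e4, 1.70e-5),
    "Sq_Ab23": (2.16e4, 7.05e-5),
}


class TestSimulateSensorgram:
    def test_zero_concentration_gives_zero_response(self):
        params = bp.KineticParams(1e4, 1e-4)
        sg = bp.simulate_sensorgram(params, 0.0, np.arange(0.0, 801.0))
        assert np.all(sg.response == 0.0)

    def test_association_approaches_equilibrium_plateau(self):
        params = bp.KineticParams(1e5, 1e-4, Rmax=100.0)
        C = 100e-9
        sg = bp.simulate_sensorgram(params, C, np.arange(0.0, 1e6, 1e4),
                                    association_end=1e6, dissociation_end=2e6)
        assert sg.response[-1] == pytest.approx(100.0 * C / (C + params.KD), rel=1e-6)

    def test_fraction_of_equilibrium_at_injection_end(self):
        # strongest binder at the top analyte concentration, 200 s injection
        ka, kd, C = 1.63e4, 1.70e-5, 342e-9
        params = bp.KineticParams(ka, kd, Rmax=100.0)
        sg = bp.simulate_sensorgram(params, C, np.array([0.0, 200.0]))
        req = 100.0 * C / (C + kd / ka)
        fraction = sg.response[1] / req
        assert fraction == pytest.approx(1 - math.exp(-(ka * C + kd) * 200), rel=1e-12)
        assert fraction == pytest.approx(0.674, abs=0.001)

    def test_dissociation_is_pure_exponential(self):
        params = bp.KineticParams(1e4, 1e-3)
        t = np.array([0.0, 200.0, 500.0])
        sg = bp.simulate_sensorgram(params, 50e-9, t)
        assert sg.response[2] == pytest.approx(
            sg.response[1] * math.exp(-1e-3 * 300), rel=1e-12)


class TestFitKinetics:
    @pytest.mark.parametrize("name", ["Sq_Ab2", "Sq_Ab15", "Sq_Ab22", "Sq_Ab23"])
    def test_noiseless_round_trip_within_0p1_percent(self, name):
        ka, kd = RATE_CONSTANTS[name]
        truth = bp.KineticParams(ka, kd, Rmax=100.0)
        fit = bp.fit_kinetics(syn.gen_sensorgram_set(truth, sigma=0.0, seed=0, dt=2.0))
        assert fit.success
        assert fit.params.ka == pytest.approx(ka, rel=1e-3)
        assert fit.params.kd == pytest.approx(kd, rel=1e-3)
        assert fit.params.KD == pytest.approx(fit.params.kd / fit.params.ka, rel=1e-12)

    def test_noisy_recovery_within_5_percent(self):
        truth = bp.KineticParams(2.97e4, 4.24e-4, Rmax=100.0)
        fit = bp.fit_kinetics(syn.gen_sensorgram_set(truth, sigma=1.0, seed=21, dt=2.0))
        assert fit.success
        assert fit.params.ka == pytest.approx(truth.ka, rel=0.05)
        assert fit.params.kd == pytest.approx(truth.kd, rel=0.05)

    def test_flat_zero_curves_flagged_as_failure(self):
        times = np.arange(0.0, 801.0, 4.0)
        flat = [bp.Sensorgram(c, times, np.zeros_like(times))
                for c in (342e-9, 100e-9, 30e-9)]
        result = bp.fit_kinetics(flat)
        assert not result.success
        assert "no measurable response" in result.message

    def test_single_concentration_rejected(self):
        times = np.arange(0.0, 801.0, 4.0)
        sg = bp.simulate_sensorgram(bp.KineticParams(1e4, 1e-4), 100e-9, times)
        with pytest.raises(ValueError, match="2 analyte concentrations"):
            bp.fit_kinetics([sg])


class TestKdOverKa:
    @pytest.mark.parametrize("ka,kd,expected", [
        (2.97e4, 4.24e-4, 14.3),
        (1.55e4, 3.16e-4, 20.4),
        (2.48e4, 9.49e-4, 38.3),
    ])
    def test_self_consistent_table_rows(self, ka, kd, expected):
        assert bp.kd_over_ka(ka, kd) == expected

    def test_equal_rates_give_1e9_nm(self):
        assert bp.kd_over_ka(2.5, 2.5) == pytest.approx(1e9)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            bp.kd_over_ka(0.0, 1e-4)


class TestCDDifference:
    def test_non_interacting_sum_gives_zero_difference(self):
        a = syn.gen_cd_spectrum((1, 0, 0), sigma=0.0)
        b = syn.gen_cd_spectrum((0, 0, 1), sigma=0.0)
        total = bp.CDSpectrum(a.wavelengths, a.ellipticity + b.ellipticity)
        diff = bp.cd_difference(total, [a, b])
        assert np.allclose(diff.ellipticity, 0.0, atol=1e-12)
        assert bp.difference_norm(diff) == pytest.approx(0.0, abs=1e-12)

    def test_sheet_gain_helix_loss_has_nonzero_signature(self):
        free = syn.gen_cd_spectrum((0.8, 0.0, 0.2), sigma=0.0)
        peptide = syn.gen_cd_spectrum((0.0, 0.0, 1.0), sigma=0.0, amplitude=2.0)
        complexed = syn.gen_cd_spectrum((0.5, 0.4, 0.1), sigma=0.0, amplitude=12.0)
        diff = bp.cd_difference(complexed, [free, peptide])
        assert bp.difference_norm(diff) > 0.1
        assert diff.ellipticity.min() < 0 < diff.ellipticity.max()

    def test_linearity_under_scaling(self):
        a = syn.gen_cd_spectrum((0.6, 0.2, 0.2), sigma=0.0)
        b = syn.gen_cd_spectrum((0.2, 0.5, 0.3), sigma=0.0)
        diff = bp.cd_difference(a, [b])
        scaled = bp.cd_difference(
            bp.CDSpectrum(a.wavelengths, 3.0 * a.ellipticity),
            [bp.CDSpectrum(b.wavelengths, 3.0 * b.ellipticity)])
        assert np.allclose(scaled.ellipticity, 3.0 * diff.ellipticity, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = syn.gen_cd_spectrum((1, 0, 0))
        b = bp.CDSpectrum(a.wavelengths[:-1], a.ellipticity[:-1])
        with pytest.raises(ValueError, match="grid"):
            bp.cd_difference(a, [b])


class TestEstimateTm:
    @pytest.mark.parametrize("tm", [42.0, 48.0, 59.0, 68.0])
    def test_noiseless_recovery_within_half_degree(self, tm):
        curve = syn.gen_melting_curve(syn.MeltingTruth(tm=tm), sigma=0.0)
        assert bp.estimate_tm(curve).tm == pytest.approx(tm, abs=0.5)

    def test_linear_signal_flags_no_transition(self):
        T = np.arange(20.0, 91.0)
        with pytest.raises(bp.NoTransitionError):
            bp.estimate_tm(bp.MeltingCurve(T, -10.0 + 0.02 * T))

    def test_noisy_replicates_recover_median_within_one_degree(self):
        tms = []
        for rep in range(50):
            curve = syn.gen_melting_curve(syn.MeltingTruth(tm=48.0), sigma=0.02,
                                          seed=1000 + rep)
            tms.append(bp.estimate_tm(curve).tm)
        assert np.median(tms) == pytest.approx(48.0, abs=1.0)

    def test_invariant_to_affine_signal_transform(self):
        curve = syn.gen_melting_curve(syn.MeltingTruth(tm=55.0), sigma=0.02, seed=4)
        tm1 = bp.estimate_tm(curve).tm
        transformed = bp.MeltingCurve(curve.temperatures, -2.5 * curve.signal + 40.0)
        tm2 = bp.estimate_tm(transformed).tm
        assert tm2 == pytest.approx(tm1, abs=1e-6)


class TestRefolding:
    def test_identical_spectra_score_one(self):
        s = syn.gen_cd_spectrum((1, 0, 0))
        assert bp.refolding_score(s, s) == 1.0
        assert bp.refolding_label(1.0) == "Yes"

    def test_total_loss_scores_zero(self):
        s = syn.gen_cd_spectrum((1, 0, 0))
        dead = bp.CDSpectrum(s.wavelengths, np.zeros_like(s.ellipticity))
        assert bp.refolding_score(s, dead) == 0.0
        assert bp.refolding_label(0.0) == "No"

    def test_ten_percent_amplitude_loss_scores_point_nine(self):
        s = syn.gen_cd_spectrum((1, 0, 0))
        faded = bp.CDSpectrum(s.wavelengths, 0.9 * s.ellipticity)
        assert bp.refolding_score(s, faded) == pytest.approx(0.9, abs=1e-9)
        assert bp.refolding_label(0.7) == "Partly"


class TestStoichiometricInhibition:
    @pytest.mark.parametrize("total,inhibitor,expected", [
        (20.0, 20.0, 0.0),    # 1:1 -> complete inhibition
        (20.0, 4.0, 16.0),    # 1:5
        (20.0, 2.0, 18.0),    # 1:10
    ])
    def test_molar_ratio_series(self, total, inhibitor, expected):
        assert bp.stoichiometric_free_peptide(total, inhibitor) == expected

    def test_non_increasing_and_zero_beyond_equivalence(self):
        grid = np.linspace(0, 40, 81)
        free = [bp.stoichiometric_free_peptide(20.0, s) for s in grid]
        assert all(a >= b for a, b in zip(free, free[1:]))
        assert all(f == 0.0 for s, f in zip(grid, free) if s >= 20.0)


class TestEndpointStandard:
    STANDARD = [(0.0, 5.0), (12.0, 1200.0), (16.0, 1600.0), (20.0, 2000.0)]

    def test_exact_standard_point_returned(self):
        assert bp.endpoint_from_standard(16.0, self.STANDARD) == 1600.0

    def test_zero_free_peptide_gives_background(self):
        assert bp.endpoint_from_standard(0.0, self.STANDARD, background=5.0) == 5.0

    def test_linear_standard_interpolates_on_the_line(self):
        standard = [(c, 100.0 * c) for c in (10.0, 15.0, 20.0)]
        assert bp.endpoint_from_standard(16.0, standard) == pytest.approx(1600.0)

    def test_non_monotone_standard_warned_and_repaired(self):
        standard = [(10.0, 1000.0), (15.0, 900.0), (20.0, 2000.0)]
        with pytest.warns(UserWarning, match="isotonic"):
            value = bp.endpoint_from_standard(15.0, standard)
        assert 900.0 <= value <= 1000.0


class TestElisaNormalize:
    def test_zero_and_unit_ratios(self):
        assert bp.elisa_normalize(0.1, 0.1, 0.5, 0.1) == 0.0
        assert bp.elisa_normalize(0.5, 0.1, 0.5, 0.1) == 1.0

    def test_worked_arithmetic(self):
        assert bp.elisa_normalize(0.9, 0.1, 0.5, 0.1) == pytest.approx(2.0)

    def test_display_at_background_rejected(self):
        with pytest.raises(ValueError):
            bp.elisa_normalize(0.9, 0.1, 0.1, 0.1)


class TestAverageMass:
    def test_water_only_for_empty_sequence(self):
        assert bp.average_mass("") == pytest.approx(18.02, abs=0.01)

    def test_pentaglycine(self):
        assert bp.average_mass("GGGGG") == pytest.approx(303.3, abs=0.1)

    def test_scaffold_realization_is_11_to_12_kda(self, design):
        mass = bp.average_mass(design.scaffold.full_protein, modifications=-2.016)
        assert 11_000 < mass < 12_000

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            bp.average_mass("GGXGG")


class TestYieldRatio:
    def test_fold_improvement_one_decimal(self):
        assert bp.yield_ratio(6.7, 2.8) == 2.4
        assert bp.yield_ratio(6.1, 2.8) == 2.2
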