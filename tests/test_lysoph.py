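"""Single-lysosome pH pipeline: Weibull-5 fitting, ratio, calibration,
classification and distributions."""

import numpy as np
import pytest

from lysoquant import lysoph, synthetic_data as synth
from lysoquant.errors import CalibrationError, DomainError, NoPeakError
from lysoquant.lysoph import (
    CalibrationCurve,
    EmissionSpectrum,
    Weibull5Params,
    emission_ratio,
    fit_emission_calibration,
    fit_weibull5,
    ph_histogram,
    population_ph_excitation,
    ratio_to_ph,
    weibull5,
)

LAM = np.arange(420.0, 701.0, 10.0)


class TestWeibull5Function:
    @pytest.mark.parametrize("y0,a,x0,b,c", [
        (5.0, 100.0, 490.0, 60.0, 2.2),
        (0.0, 1.0, 500.0, 30.0, 1.5),
        (10.0, 50.0, 470.0, 100.0, 3.0),
    ])
    def test_peak_identity(self, y0, a, x0, b, c):
        # the parameterization guarantees f(x0) = y0 + a
        assert weibull5(x0, y0, a, x0, b, c) == pytest.approx(y0 + a, abs=1e-12)

    def test_baseline_left_of_onset(self):
        # far left of the peak the curve sits exactly on the baseline
        assert weibull5(0.0, 5.0, 100.0, 490.0, 60.0, 2.2) == 5.0

    def test_maximum_is_at_x0(self):
        lam = np.linspace(300, 800, 5001)
        vals = weibull5(lam, 5.0, 100.0, 490.0, 60.0, 2.2)
        assert abs(lam[np.argmax(vals)] - 490.0) < 0.2


class TestFitWeibull5:
    def test_noiseless_parameter_recovery(self):
        truth = (5.0, 100.0, 490.0, 60.0, 2.2)
        inten = weibull5(LAM, *truth)
        p = fit_weibull5(EmissionSpectrum(LAM, inten))
        fitted = (p.y0, p.a, p.x0, p.b, p.c)
        for got, want in zip(fitted, truth):
            assert got == pytest.approx(want, rel=1e-3)
        assert p.converged
        assert p.rss < 1e-12

    def test_fitted_peak_identity(self):
        inten = weibull5(LAM, 5.0, 100.0, 490.0, 60.0, 2.2)
        p = fit_weibull5(EmissionSpectrum(LAM, inten))
        assert p(p.x0) == pytest.approx(p.y0 + p.a, rel=1e-12)

    def test_flat_spectrum_raises(self):
        with pytest.raises(NoPeakError, match="no peak"):
            fit_weibull5(EmissionSpectrum(LAM, np.full_like(LAM, 7.0)))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="8 samples"):
            fit_weibull5((LAM[:5], np.arange(5.0)))

    def test_matches_grid_refined_oracle(self):
        """The nonlinear fit must reach the rss of an independent grid search
        (linear in y0/a at fixed shape) on fixed toy spectra."""
        rng = np.random.default_rng(11)
        toys = [
            (2.0, 80.0, 480.0, 50.0, 1.8),
            (0.0, 120.0, 500.0, 70.0, 2.5),
            (10.0, 60.0, 470.0, 40.0, 3.2),
            (5.0, 100.0, 520.0, 90.0, 2.0),
            (1.0, 150.0, 460.0, 55.0, 2.8),
        ]
        for truth in toys:
            inten = weibull5(LAM, *truth) + rng.normal(0, 1.0, LAM.size)

            def rss_linear(x0, b, c):
                g = weibull5(LAM, 0.0, 1.0, x0, b, c)
                X = np.column_stack([np.ones_like(LAM), g])
                beta, res, *_ = np.linalg.lstsq(X, inten, rcond=None)
                return float(np.sum((X @ beta - inten) ** 2))

            # coarse grid then two refinement rounds around the best cell
            x0s = np.linspace(440, 540, 21)
            bs = np.linspace(20, 120, 21)
            cs = np.linspace(1.2, 4.0, 15)
            for _ in range(3):
                best = min(
                    ((rss_linear(x, b, c), x, b, c)
                     for x in x0s for b in bs for c in cs),
                )
                _, x0c, bc, cc = best
                x0s = np.linspace(x0c - (x0s[1] - x0s[0]), x0c + (x0s[1] - x0s[0]), 9)
                bs = np.linspace(max(1, bc - (bs[1] - bs[0])), bc + (bs[1] - bs[0]), 9)
                cs = np.linspace(max(1.01, cc - (cs[1] - cs[0])), cc + (cs[1] - cs[0]), 9)
            oracle_rss = best[0]
            p = fit_weibull5(EmissionSpectrum(LAM, inten))
            assert p.rss <= oracle_rss * 1.01


class TestEmissionRatio:
    def test_matches_closed_form(self):
        inten = weibull5(LAM, 5.0, 100.0, 490.0, 60.0, 2.2)
        p = fit_weibull5(EmissionSpectrum(LAM, inten))
        expect = weibull5(470.0, 5.0, 100.0, 490.0, 60.0, 2.2) / weibull5(
            524.0, 5.0, 100.0, 490.0, 60.0, 2.2
        )
        assert emission_ratio(p) == pytest.approx(expect, rel=1e-6)

    def test_symmetric_positions_give_unity(self):
        # peak midway between the two readout wavelengths of a symmetric-enough
        # curve is not exactly 1, so force equality through the baseline limit
        p = Weibull5Params(y0=50.0, a=1e-9, x0=497.0, b=60.0, c=2.2)
        assert emission_ratio(p) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_denominator(self):
        p = Weibull5Params(y0=-10.0, a=5.0, x0=450.0, b=10.0, c=2.0)
        with pytest.raises(ValueError, match="invalid denominator"):
            emission_ratio(p)


class TestEmissionCalibration:
    EXACT = [(4.0, 2.4), (4.5, 2.2), (5.0, 2.0), (5.5, 1.8)]

    def test_exact_collinear_points(self):
        curve = fit_emission_calibration(self.EXACT)
        assert curve.slope == pytest.approx(-0.4)
        assert curve.intercept == pytest.approx(4.0)
        assert curve.fit_r2 == pytest.approx(1.0)

    def test_perturbed_points_match_ols_normal_equations(self):
        pts = [(4.0, 2.4), (4.5, 2.25), (5.0, 2.0), (5.5, 1.8)]
        ph = np.array([p for p, _ in pts])
        r = np.array([v for _, v in pts])
        slope = np.sum((ph - ph.mean()) * (r - r.mean())) / np.sum(
            (ph - ph.mean()) ** 2
        )
        intercept = r.mean() - slope * ph.mean()
        curve = fit_emission_calibration(pts)
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-12)

    def test_single_level_underdetermined(self):
        with pytest.raises(CalibrationError, match="underdetermined"):
            fit_emission_calibration([(4.5, 2.0), (4.5, 2.0)])

    def test_flat_standards_not_invertible(self):
        with pytest.raises(CalibrationError, match="not invertible"):
            fit_emission_calibration([(4.0, 2.0), (4.5, 2.0), (5.0, 2.0)])

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(CalibrationError, match="not invertible"):
            fit_emission_calibration([(4.0, 2.4), (4.5, 2.0), (5.0, 2.2)])

    def test_yaml_round_trip(self, tmp_path):
        curve = fit_emission_calibration(self.EXACT)
        path = tmp_path / "cal.yaml"
        curve.to_yaml(path)
        back = CalibrationCurve.from_yaml(path)
        assert back.slope == curve.slope
        assert back.valid_ph_range == curve.valid_ph_range


class TestRatioToPh:
    CURVE = CalibrationCurve(
        mode="emission_linear", slope=-0.4, intercept=4.0,
        valid_ph_range=(4.0, 5.5),
    )

    def test_line_inversion(self):
        ph, clamped = ratio_to_ph(self.CURVE, 2.0)
        assert ph == pytest.approx(5.0)
        assert not clamped

    def test_standards_map_to_their_ph(self):
        for ph0, r in [(4.0, 2.4), (4.5, 2.2), (5.5, 1.8)]:
            ph, clamped = ratio_to_ph(self.CURVE, r)
            assert ph == pytest.approx(ph0)
            assert not clamped

    def test_clamping_at_range_edge(self):
        # ratio implying pH 6.3 clamps to the 5.5 boundary
        ph, clamped = ratio_to_ph(self.CURVE, 4.0 - 0.4 * 6.3)
        assert ph == 5.5
        assert clamped

    def test_clamping_is_idempotent_and_monotone(self):
        ratios = np.linspace(1.0, 3.0, 41)
        phs = [ratio_to_ph(self.CURVE, r)[0] for r in ratios]
        # decreasing ratio axis -> increasing pH, never outside range
        assert all(4.0 <= p <= 5.5 for p in phs)
        assert all(a >= b for a, b in zip(phs, phs[1:]))


class TestClassifyApod:
    def test_zero_image_is_negative(self):
        roi = np.ones((5, 5), dtype=bool)
        assert lysoph.classify_apod(roi, np.zeros((5, 5)), 10.0) is False

    def test_bright_roi_is_positive(self):
        img = np.full((5, 5), 150.0)
        roi = np.zeros((5, 5), dtype=bool)
        roi[1:3, 1:3] = True
        assert lysoph.classify_apod(roi, img, 50.0) is True

    def test_empty_roi_raises(self):
        with pytest.raises(DomainError, match="empty ROI"):
            lysoph.classify_apod(np.zeros((4, 4), bool), np.ones((4, 4)), 1.0)

    def test_counts_match_direct_means(self, rng):
        img = rng.uniform(0, 100, (30, 10))
        rois = [np.zeros((30, 10), bool) for _ in range(30)]
        for i, m in enumerate(rois):
            m[i, :] = True
        flags = [lysoph.classify_apod(m, img, 50.0) for m in rois]
        expect = [img[i].mean() > 50.0 for i in range(30)]
        assert flags == expect


class TestPhDistribution:
    def test_hand_binned_example(self):
        centers, counts, modal = ph_histogram([4.65, 4.72, 4.68, 4.41])
        assert modal == pytest.approx(4.65)
        lookup = dict(zip(np.round(centers, 2), counts))
        assert lookup[4.65] == 2 and lookup[4.75] == 1 and lookup[4.45] == 1

    def test_single_record_on_bin_edge(self):
        _, _, modal = ph_histogram([4.7])
        assert modal == pytest.approx(4.75)

    def test_tie_breaks_toward_lower_ph(self):
        _, _, modal = ph_histogram([4.41, 4.62])
        assert modal == pytest.approx(4.45)

    def test_grouped_distribution_and_fractions(self):
        records = [
            lysoph.LysosomeRecord(i, 2.0, ph, apod_positive=i < 12,
                                  condition="control")
            for i, ph in enumerate(np.linspace(4.4, 4.9, 30))
        ]
        hist, modes = lysoph.ph_distribution(records)
        assert ("control", "ApoD+") in modes and ("control", "ApoD-") in modes
        frac = lysoph.apod_lysosome_fractions(records)
        row = frac.iloc[0]
        assert row["frac_positive"] == pytest.approx(0.4)
        assert row["frac_negative"] == pytest.approx(0.6)


class TestPopulationExcitation:
    STANDARDS = [(4.0, 1.8), (4.5, 1.6), (5.0, 1.4), (5.5, 1.2), (6.0, 1.0)]

    def test_ratio_at_standard_returns_its_ph(self):
        res = population_ph_excitation([[1.6] * 6], [[1.0] * 6], self.STANDARDS)
        assert res["ph"].iloc[0] == pytest.approx(4.5)
        assert not res["clamped"].iloc[0]

    def test_midway_ratio_interpolates(self):
        res = population_ph_excitation([[1.5] * 6], [[1.0] * 6], self.STANDARDS)
        assert res["ph"].iloc[0] == pytest.approx(4.75)

    def test_out_of_range_ratio_clamps(self):
        res = population_ph_excitation([[0.5] * 6], [[1.0] * 6], self.STANDARDS)
        assert res["ph"].iloc[0] == 6.0
        assert bool(res["clamped"].iloc[0])

    def test_replicates_are_averaged_before_ratio(self):
        res = population_ph_excitation(
            [[1.5, 1.7, 1.6, 1.6, 1.55, 1.65]], [[1.0] * 6], self.STANDARDS
        )
        assert res["ratio"].iloc[0] == pytest.approx(np.mean([1.5, 1.7, 1.6, 1.6, 1.55, 1.65]))

    def test_zero_f390_raises(self):
        with pytest.raises(ValueError, match="zero F390"):
            population_ph_excitation([[1.0] * 6], [[0.0] * 6], self.STANDARDS)

    def test_non_monotone_standards_raise(self):
        bad = [(4.0, 1.8), (4.5, 1.9), (5.0, 1.4)]
        with pytest.raises(CalibrationError):
            population_ph_excitation([[1.5] * 6], [[1.0] * 6], bad)


class TestClosedLoop:
    def test_noiseless_round_trip_recovers_true_ph(self, emission_calibration):
        """With calibration standards from the same spectral model, the full
        pipeline returns the true pH to 1e-3 on noiseless spectra."""
        for ph0 in (4.0, 4.3, 4.7, 5.1, 5.5):
            gt = synth.SpectrumGroundTruth(
                ph_mode=ph0, ph_sd=0.0, noise_sd=0.0, n_lysosomes=1
            )
            spectra, _ = synth.make_spectra(gt)
            rec = lysoph.estimate_ph(spectra, emission_calibration)[0]
            assert rec.ph == pytest.approx(ph0, abs=1e-3)
            assert not rec.clamped

    def test_spectra_csv_round_trip(self, tmp_path):
        gt = synth.SpectrumGroundTruth(n_lysosomes=3, seed=4)
        spectra, _ = synth.make_spectra(gt)
        path = tmp_path / "spectra.csv"
        lysoph.write_spectra_csv(path, spectra)
        back = lysoph.read_spectra_csv(path)
        assert len(back) == 3
        np.testing.assert_allclose(back[1].intensities, spectra[1].intensities)
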