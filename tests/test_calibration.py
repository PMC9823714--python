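"""Germination-flux calibration fitting, prediction and the model registry."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedlum as sl
from seedlum.exceptions import DegenerateDataError, UnitMismatchError, UnknownSpeciesError

from conftest import CALIBRATION_ROWS, PRINTED_COEFFS


def ols_closed_form(x, y):
    """Independent normal-equation oracle for simple OLS."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    tss = np.sum((y - ybar) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
    return slope, intercept, r2


class TestFitCalibration:
    @pytest.mark.parametrize("species", ["galega", "clover", "alfalfa"])
    def test_reproduces_published_coefficients(self, calibration_points, species):
        """The three published lines are recovered to their printed precision
        (one unit in the last printed digit; R^2 to 4 decimals)."""
        model = sl.fit_calibration(calibration_points(species))
        slope, intercept, r2 = PRINTED_COEFFS[species]
        assert model.slope_pct_per_microlumen == pytest.approx(slope, abs=0.01)
        assert model.intercept_pct == pytest.approx(intercept, abs=0.05)
        assert round(model.r_squared, 4) == r2
        assert model.n_points == 3

    def test_matches_normal_equation_oracle(self, calibration_points):
        for species, rows in CALIBRATION_ROWS.items():
            model = sl.fit_calibration(calibration_points(species))
            x = np.array([f for f, _ in rows]) * 1e6
            y = np.array([g for _, g in rows])
            slope, intercept, r2 = ols_closed_form(x, y)
            assert model.slope_pct_per_microlumen == pytest.approx(slope, abs=1e-9)
            assert model.intercept_pct == pytest.approx(intercept, abs=1e-9)
            assert model.r_squared == pytest.approx(r2, abs=1e-9)

    def test_no_grid_neighbour_beats_the_fit(self, calibration_points):
        """Brute-force check that the fitted line minimises SSE locally."""
        model = sl.fit_calibration(calibration_points("alfalfa"))
        x = np.array([f for f, _ in CALIBRATION_ROWS["alfalfa"]]) * 1e6
        y = np.array([g for _, g in CALIBRATION_ROWS["alfalfa"]])

        def sse(a, b):
            return float(np.sum((y - (a * x + b)) ** 2))

        best = sse(model.slope_pct_per_microlumen, model.intercept_pct)
        for da in np.linspace(-0.5, 0.5, 11):
            for db in np.linspace(-2, 2, 11):
                trial = sse(model.slope_pct_per_microlumen + da, model.intercept_pct + db)
                assert trial >= best - 1e-9

    def test_two_exact_points_give_r2_of_one(self):
        pts = [
            sl.CalibrationPoint(1e-6, 30.0),
            sl.CalibrationPoint(2e-6, 40.0),
        ]
        assert sl.fit_calibration(pts).r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_invariant_under_flux_rescaling(self, calibration_points):
        pts = calibration_points("clover")
        base = sl.fit_calibration(pts)
        rescaled = [
            sl.CalibrationPoint(p.flux_lm * 1e3, p.germination_pct, species=p.species)
            for p in pts
        ]
        other = sl.fit_calibration(rescaled)
        assert other.r_squared == pytest.approx(base.r_squared, rel=1e-12)
        assert other.slope_pct_per_microlumen == pytest.approx(
            base.slope_pct_per_microlumen / 1e3, rel=1e-9
        )

    def test_residuals_reproduce_one_minus_r2(self, calibration_points):
        pts = calibration_points("alfalfa")
        model = sl.fit_calibration(pts)
        y = np.array([p.germination_pct for p in pts])
        yhat = np.array(
            [sl.predict_germination(model, p.flux_lm).germination_pct for p in pts]
        )
        sse = np.sum((y - yhat) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert sse / tss == pytest.approx(1.0 - model.r_squared, abs=1e-9)

    def test_parameter_recovery_from_noisy_lots(self, registry):
        """n=50 fluxes across the training range, 1% germination noise:
        the refitted slope lands within 5% of the generating slope."""
        model = registry["alfalfa"]
        rng = np.random.default_rng(42)
        lo, hi = model.flux_range_lm
        flux = rng.uniform(lo, hi, size=50)
        germ = (
            model.slope_pct_per_microlumen * flux * 1e6
            + model.intercept_pct
            + rng.normal(0.0, 1.0, size=50)
        )
        pts = [sl.CalibrationPoint(f, g) for f, g in zip(flux, germ)]
        refit = sl.fit_calibration(pts)
        assert refit.slope_pct_per_microlumen == pytest.approx(
            model.slope_pct_per_microlumen, rel=0.05
        )

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDataError):
            sl.fit_calibration([sl.CalibrationPoint(1e-6, 30.0)])
        with pytest.raises(DegenerateDataError):
            sl.fit_calibration(
                [sl.CalibrationPoint(1e-6, 30.0), sl.CalibrationPoint(1e-6, 50.0)]
            )

    @given(
        slope=st.floats(min_value=0.5, max_value=10),
        intercept=st.floats(min_value=0, max_value=30),
    )
    @settings(max_examples=25, deadline=None)
    def test_exact_line_is_recovered(self, slope, intercept):
        flux = np.array([1.0, 2.0, 4.0, 7.0]) * 1e-6
        germ = np.clip(slope * flux * 1e6 + intercept, 0, 100)
        if np.ptp(germ) == 0:  # fully clamped: not a line any more
            return
        pts = [sl.CalibrationPoint(f, g) for f, g in zip(flux, germ)]
        model = sl.fit_calibration(pts)
        if np.all(germ < 100):
            assert model.slope_pct_per_microlumen == pytest.approx(slope, rel=1e-9)
            assert model.intercept_pct == pytest.approx(intercept, abs=1e-7)


class TestPredictGermination:
    def test_published_galega_point_rounds_to_43(self, calibration_points):
        model = sl.fit_calibration(calibration_points("galega"))
        pred = sl.predict_germination(model, sl.FluxValue(3.57e-6, sl.LUMENS))
        assert round(pred.germination_pct) == 43
        assert not pred.extrapolated

    def test_published_clover_point_rounds_to_21(self, calibration_points):
        model = sl.fit_calibration(calibration_points("clover"))
        pred = sl.predict_germination(model, 9.46e-6)
        assert round(pred.germination_pct) == 21

    def test_zero_flux_returns_intercept_flagged_extrapolated(self, registry):
        model = registry["galega"]
        pred = sl.predict_germination(model, 0.0)
        assert pred.germination_pct == pytest.approx(model.intercept_pct)
        assert pred.extrapolated

    def test_clamping_flags(self, registry):
        pred = sl.predict_germination(registry["alfalfa"], 1e-3)  # absurdly bright
        assert pred.germination_pct == 100.0
        assert pred.clamped and pred.extrapolated

    def test_relative_units_flux_rejected(self, registry):
        with pytest.raises(UnitMismatchError, match="to_lumens"):
            sl.predict_germination(registry["galega"], sl.FluxValue(572.0, sl.RELATIVE_UNITS))


class TestFluxRatio:
    def test_galega_double_over_none(self):
        r = sl.flux_ratio(
            sl.FluxValue(3.57e-6, sl.LUMENS), sl.FluxValue(2.15e-6, sl.LUMENS)
        )
        assert round(r, 1) == 1.7

    def test_identical_fluxes_give_one(self):
        f = sl.FluxValue(5e-6, sl.LUMENS)
        assert sl.flux_ratio(f, f) == 1.0

    def test_clover_ratio_is_three(self):
        r = sl.flux_ratio(
            sl.FluxValue(9.46e-6, sl.LUMENS), sl.FluxValue(3.15e-6, sl.LUMENS)
        )
        assert round(r, 1) == 3.0

    def test_unit_mismatch_and_zero_denominator(self):
        with pytest.raises(UnitMismatchError):
            sl.flux_ratio(sl.FluxValue(1.0, sl.RELATIVE_UNITS), sl.FluxValue(1e-6, sl.LUMENS))
        with pytest.raises(Exception):
            sl.flux_ratio(sl.FluxValue(1e-6, sl.LUMENS), sl.FluxValue(0.0, sl.LUMENS))


class TestRegistry:
    def test_default_registry_has_published_models(self, registry):
        assert set(registry) == {"galega", "clover", "alfalfa"}
        assert registry["galega"].slope_pct_per_microlumen == 5.62
        assert registry["clover"].intercept_pct == 5.72
        assert registry["alfalfa"].r_squared == 0.9315

    def test_save_load_round_trip(self, registry, tmp_path):
        path = tmp_path / "reg.json"
        sl.save_registry(registry, str(path))
        back = sl.load_registry(str(path))
        assert back == registry

    def test_stream_round_trip(self, calibration_points):
        model = sl.fit_calibration(calibration_points("clover"))
        buf = io.StringIO()
        sl.save_registry({"clover": model}, buf)
        buf.seek(0)
        assert sl.load_registry(buf)["clover"] == model

    def test_unknown_species_lists_known(self, registry):
        with pytest.raises(UnknownSpeciesError, match="alfalfa.*clover.*galega"):
            sl.lookup(registry, "wheat")
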