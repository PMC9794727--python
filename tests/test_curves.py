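"""Curve assembly, 5PL fitting, prediction, ICx inversion and max effect."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dspscreen import (
    ConcRange,
    CurveFit,
    FitError,
    assemble_dose_points,
    fit_asym_logistic,
    invert_icx,
    max_effect,
    normalize_plate,
    predict_inhibition,
)
from dspscreen.curves import DoseResponsePoints, _model, fit_asym_logistic_many
from dspscreen.model import WellRole

from conftest import bisect_icx

X_GRID = np.arange(-9.0, -4.0)  # log10 of the default 5-point grid
RANGE = ConcRange(-9.0, -5.0)


def _points(y, x=None, drug_id="d"):
    x = np.repeat(X_GRID, 2) if x is None else x
    return DoseResponsePoints(drug_id, np.asarray(x, float), np.asarray(y, float),
                              np.tile([0, 1], len(x) // 2), ["p"] * len(x))


def _fit(y_min, y_max, ec50, slope, asym):
    return CurveFit(y_min=y_min, y_max=y_max, log10_ec50=ec50, slope=slope,
                    asym=asym, r2=1.0, converged=True, n_points=10)


class TestAssemble:
    def test_full_grid_collects_ten_points(self, small_truth, small_layouts, small_plates):
        norm = [normalize_plate(p, small_layouts[p.layout_ref]) for p in small_plates]
        drug = small_truth.library.drugs[0]
        pts = assemble_dose_points(norm, small_layouts, drug.drug_id,
                                   concentrations=drug.concentrations)
        assert pts.log10_conc.size == 10
        assert pts.n_distinct_concentrations == 5
        assert len(pts.conc_means) == 5

    def test_one_missing_well_still_evaluable(self, small_truth, small_layouts, small_plates):
        from dspscreen.model import RawPlate

        norm_layout = small_layouts["plate_1"]
        drug = small_truth.library[norm_layout.drug_wells()[0].drug_id]
        victim = norm_layout.drug_wells()[0]
        plate = small_plates[0]
        damaged = RawPlate(plate.plate_id,
                           {w: c for w, c in plate.counts.items() if w != victim.well},
                           plate.layout_ref)
        norm = [normalize_plate(damaged, norm_layout)]
        pts = assemble_dose_points(norm, small_layouts, drug.drug_id,
                                   concentrations=drug.concentrations)
        assert pts.log10_conc.size == 9

    def test_drug_only_on_failed_plate_unevaluable(self, small_truth, small_layouts, small_plates):
        from dspscreen import degrade_controls

        layout = small_layouts["plate_1"]
        drug = small_truth.library[layout.drug_wells()[0].drug_id]
        bad = degrade_controls(small_plates[0], layout, "separation_loss", collapse_frac=0.95)
        norm = [normalize_plate(bad, layout)]
        assert not norm[0].qc.passed
        with pytest.raises(FitError, match="insufficient dose range"):
            assemble_dose_points(norm, small_layouts, drug.drug_id,
                                 concentrations=drug.concentrations)


class TestFit:
    def test_noise_free_parameter_recovery(self):
        truth = (0.0, 95.0, -7.0, 1.2, 1.8)
        x = np.repeat(X_GRID, 2)
        fit = fit_asym_logistic(_points(_model(x, *truth)))
        recovered = (fit.y_min, fit.y_max, fit.log10_ec50, fit.slope, fit.asym)
        assert np.allclose(recovered, truth, atol=1e-3)
        # curve itself reproduced far below a millipercent
        grid = np.linspace(-9, -5, 500)
        rmse = np.sqrt(np.mean((np.asarray(fit.predict_log10(grid)) - _model(grid, *truth)) ** 2))
        assert rmse < 1e-6
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_zero_data(self):
        fit = fit_asym_logistic(_points(np.zeros(10)))
        assert fit.y_min == fit.y_max == 0.0
        assert fit.r2 == 1.0
        assert max_effect(fit, conc_range=RANGE)[0] == pytest.approx(0.0)

    def test_four_concentrations_fixes_asym(self):
        x = np.repeat(X_GRID[:4], 2)
        y = _model(x, 0.0, 90.0, -7.0, 1.0, 1.0)
        fit = fit_asym_logistic(_points(y, x=x))
        assert fit.asym_fixed
        assert fit.asym == 1.0

    def test_below_four_concentrations_unevaluable(self, small_layouts):
        with pytest.raises(FitError, match="insufficient dose range"):
            assemble_dose_points([], small_layouts, "d001",
                                 concentrations=(1e-9, 1e-8, 1e-7, 1e-6, 1e-5))

    def test_batched_fit_matches_single_fits(self):
        rng = np.random.default_rng(11)
        x = np.repeat(X_GRID, 2)
        pts = []
        for i in range(12):
            y = _model(x, 0.0, rng.uniform(20, 100), rng.uniform(-8.5, -5.5),
                       rng.uniform(0.5, 3), rng.uniform(0.4, 2.5))
            y = y + rng.normal(0, 3, x.size)
            pts.append(_points(y, drug_id=f"d{i}"))
        batched = fit_asym_logistic_many(pts)
        for p in pts:
            single = fit_asym_logistic(p)
            b = batched[p.drug_id]
            assert b.log10_ec50 == pytest.approx(single.log10_ec50, abs=1e-9)
            assert b.r2 == pytest.approx(single.r2, abs=1e-12)

    def test_noisy_ic50_recovery_median_quarter_decade(self):
        """5% CV count noise: median absolute log10 IC50 error stays within
        a quarter decade for strong responders (true y_max >= 75)."""
        rng = np.random.default_rng(42)
        x = np.repeat(X_GRID, 2)
        base, floor = 1e5, 5e3
        errors = []
        n_strong = 0
        for _ in range(200):
            truth = (0.0, rng.uniform(40, 100), rng.uniform(-8.5, -5.5),
                     rng.uniform(0.8, 2.0), rng.uniform(0.5, 2.0))
            y_true = _model(x, *truth)
            counts = floor + (base - floor) * (1 - y_true / 100.0)
            sigma = math.sqrt(math.log(1 + 0.05**2))
            counts = counts * rng.lognormal(-sigma**2 / 2, sigma, x.size)
            y_obs = 100.0 * (counts - base) / (floor - base)
            fit = fit_asym_logistic(_points(y_obs))
            if truth[1] >= 75:
                n_strong += 1
                true_ic50 = bisect_icx(_fit(*truth), 50.0, -9.0, -5.0)
                est_ic50 = invert_icx(fit, 50.0, RANGE)
                if est_ic50 is None:
                    errors.append(np.inf)
                else:
                    errors.append(abs(math.log10(est_ic50) - math.log10(true_ic50)))
        assert n_strong > 50
        assert np.median(errors) <= 0.25

    def test_r2_degrades_with_noise(self):
        rng = np.random.default_rng(5)
        x = np.repeat(X_GRID, 2)
        y = _model(x, 0.0, 90.0, -7.0, 1.0, 1.0)
        r2s = []
        for noise in (0.0, 3.0, 15.0):
            fit = fit_asym_logistic(_points(y + rng.normal(0, noise, x.size)))
            r2s.append(fit.r2)
        assert r2s[0] == pytest.approx(1.0, abs=1e-9)
        assert r2s[0] > r2s[1] > r2s[2]


class TestPredict:
    def test_symmetric_midpoint(self):
        fit = _fit(0.0, 100.0, -7.0, 1.0, 1.0)
        assert predict_inhibition(fit, 1e-7) == pytest.approx(50.0)

    def test_asymptotes(self):
        fit = _fit(5.0, 95.0, -7.0, 1.5, 2.0)
        assert predict_inhibition(fit, 1e2) == pytest.approx(95.0, abs=1e-6)
        assert predict_inhibition(fit, 1e-15) == pytest.approx(5.0, abs=1e-3)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fit = _fit(rng.uniform(-5, 5), rng.uniform(50, 110), rng.uniform(-8, -6),
                       rng.uniform(0.5, 3), rng.uniform(0.3, 3))
            c = 10.0 ** rng.uniform(-9.5, -4.5)
            direct = fit.y_min + (fit.y_max - fit.y_min) / (
                1 + 10 ** (fit.slope * (fit.log10_ec50 - math.log10(c)))) ** fit.asym
            assert predict_inhibition(fit, c) == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(FitError):
            predict_inhibition(_fit(0, 100, -7, 1, 1), 0.0)

    @given(st.floats(min_value=-9.0, max_value=-5.5))
    def test_monotone_in_concentration(self, x):
        fit = _fit(0.0, 90.0, -7.2, 1.3, 0.7)
        assert fit.predict_log10(x) <= fit.predict_log10(x + 0.5) + 1e-12


class TestInvertIcx:
    def test_flat_zero_returns_none(self):
        assert invert_icx(_fit(0.0, 0.0, -7.0, 1.0, 1.0), 50.0, RANGE) is None

    def test_4pl_midpoint_identity(self):
        conc = invert_icx(_fit(0.0, 100.0, -7.0, 1.0, 1.0), 50.0, RANGE)
        assert conc == pytest.approx(1e-7, rel=1e-9)

    def test_agrees_with_bisection(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(100):
            fit = _fit(rng.uniform(-10, 10), rng.uniform(20, 110), rng.uniform(-10, -4),
                       rng.uniform(0.3, 4), rng.uniform(0.3, 3))
            p = rng.uniform(5, 95)
            lo = float(fit.predict_log10(RANGE.x_min))
            hi = float(fit.predict_log10(RANGE.x_max))
            if not lo < p < hi:
                continue  # no interior crossing: bisection premise absent
            checked += 1
            ours = invert_icx(fit, p, RANGE)
            oracle = bisect_icx(fit, p, RANGE.x_min, RANGE.x_max)
            assert ours is not None
            assert math.log10(ours) == pytest.approx(math.log10(oracle), abs=1e-6)
        assert checked > 30

    def test_inversion_consistency(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            fit = _fit(rng.uniform(-10, 5), rng.uniform(30, 110), rng.uniform(-9.5, -4.5),
                       rng.uniform(0.3, 4), rng.uniform(0.3, 3))
            p = rng.uniform(5, 95)
            conc = invert_icx(fit, p, RANGE)
            if conc is None or math.log10(conc) <= RANGE.x_min:
                continue  # unreached or censored at the range floor
            assert predict_inhibition(fit, conc) == pytest.approx(p, abs=1e-6)

    def test_curve_above_target_censors_at_lowest_tested(self):
        fit = _fit(60.0, 95.0, -7.0, 1.0, 1.0)
        assert invert_icx(fit, 50.0, RANGE) == pytest.approx(10.0 ** RANGE.x_min)

    def test_invalid_target_rejected(self):
        with pytest.raises(FitError):
            invert_icx(_fit(0, 100, -7, 1, 1), 0.0, RANGE)


class TestMaxEffect:
    def test_attained_asymptote(self):
        fitted, _ = max_effect(_fit(0.0, 95.0, -7.5, 2.0, 1.0), conc_range=RANGE)
        assert fitted == pytest.approx(95.0, abs=0.1)

    def test_ec50_above_range_caps_fitted_value(self):
        fit = _fit(0.0, 95.0, -4.0, 1.0, 1.0)
        fitted, _ = max_effect(fit, conc_range=RANGE)
        expected = float(fit.predict_log10(RANGE.x_max))
        assert fitted == pytest.approx(expected, rel=1e-12)
        assert fitted < 95.0

    def test_reports_observed_mean_alongside(self):
        pts = _points(_model(np.repeat(X_GRID, 2), 0.0, 80.0, -7.0, 1.0, 1.0))
        fit = fit_asym_logistic(pts)
        fitted, observed = max_effect(fit, points=pts)
        assert observed == pytest.approx(max(pts.conc_means.values()))
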