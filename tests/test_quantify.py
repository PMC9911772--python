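import numpy as np
import pytest
from dataclasses import replace

from neodrs import (
    BloodPanel,
    CENTERS_NM,
    GaussianComponent,
    apply_calibration,
    classify,
    component_auc,
    compute_indices,
    eval_cumulative,
    fit_calibration,
    fit_five_gaussians,
    load_calibration,
    save_calibration,
)
from neodrs.config import ClassifyConfig
from neodrs.errors import CalibrationError, DegenerateDataError, ValidationError
from neodrs.preprocess import AbsorbanceSpectrum
from neodrs.quantify import CalibrationModel, InstrumentIndices

from conftest import make_table


def fit_synthetic(grid, amps, widths=(15.0,) * 5, offset=0.05):
    comps = tuple(GaussianComponent(c, a, w) for c, a, w in zip(CENTERS_NM, amps, widths))
    spec = AbsorbanceSpectrum(grid, eval_cumulative(comps, offset, grid))
    return fit_five_gaussians(spec), spec


class TestComputeIndices:
    def test_equal_areas_algebra(self, grid):
        """If all four chromophore AUCs equal a, then spo2=1, hb=2a, bili=a.

        Equal areas at equal widths mean equal amplitudes."""
        result, spec = fit_synthetic(grid, amps=(0.3, 0.3, 0.3, 0.3, 0.2))
        # widths equal => amplitudes equal => AUCs equal up to edge truncation
        idx = compute_indices(result, spec.grid)
        a462 = component_auc(result.component_at(462.92), spec.grid)
        a539 = component_auc(result.component_at(539.34), spec.grid)
        a568 = component_auc(result.component_at(568.09), spec.grid)
        a577 = component_auc(result.component_at(577.2), spec.grid)
        assert idx.spo2_index == pytest.approx(a577 / a568, rel=1e-12)
        assert idx.hb_index == pytest.approx(a539 + a577, rel=1e-12)
        assert idx.bili_index == pytest.approx(a462, rel=1e-12)
        # interior components are >5 sigma from the edges, so AUCs agree
        assert idx.spo2_index == pytest.approx(1.0, rel=1e-4)

    def test_zero_bilirubin_component(self, grid):
        result, spec = fit_synthetic(grid, amps=(0.0, 0.3, 0.2, 0.4, 0.2))
        idx = compute_indices(result, spec.grid)
        assert idx.bili_index == pytest.approx(0.0, abs=1e-6)

    def test_matches_hand_summed_aucs(self, grid):
        result, spec = fit_synthetic(grid, amps=(0.25, 0.31, 0.17, 0.44, 0.3))
        idx = compute_indices(result, spec.grid)
        by_center = {c.center: component_auc(c, spec.grid) for c in result.components}
        assert idx.hb_index == pytest.approx(by_center[539.34] + by_center[577.2], abs=1e-12)
        assert idx.bili_index == pytest.approx(by_center[462.92], abs=1e-12)
        assert idx.spo2_index == pytest.approx(by_center[577.2] / by_center[568.09], abs=1e-12)

    def test_rejected_fit_requires_force(self, grid):
        result, spec = fit_synthetic(grid, amps=(0.2, 0.3, 0.2, 0.4, 0.2))
        rejected = replace(result, accepted=False)
        with pytest.raises(ValidationError):
            compute_indices(rejected, spec.grid)
        idx = compute_indices(rejected, spec.grid, force=True)
        assert idx.hb_index > 0

    def test_invariant_to_baseline_component(self, grid):
        """The 620 nm amplitude never leaks into any index."""
        r1, s1 = fit_synthetic(grid, amps=(0.25, 0.31, 0.17, 0.44, 0.1))
        r2, s2 = fit_synthetic(grid, amps=(0.25, 0.31, 0.17, 0.44, 0.5))
        i1 = compute_indices(r1, s1.grid)
        i2 = compute_indices(r2, s2.grid)
        assert i1.hb_index == pytest.approx(i2.hb_index, rel=1e-5)
        assert i1.bili_index == pytest.approx(i2.bili_index, rel=1e-4)
        assert i1.spo2_index == pytest.approx(i2.spo2_index, rel=1e-5)


class TestFitCalibration:
    def test_exact_linear_hb(self):
        x = np.linspace(5, 40, 12)
        table = make_table(device=x, reference=1.8 * x + 2.91)
        model = fit_calibration(table, "Hb")
        assert model.family == "linear"
        assert model.coefficients[1] == pytest.approx(1.8, abs=1e-9)
        assert model.coefficients[0] == pytest.approx(2.91, abs=1e-9)
        assert model.diagnostics["r"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_quadratic_tsb(self):
        x = np.linspace(1, 18, 15)
        y = 0.5 + 1.1 * x + 0.04 * x**2
        model = fit_calibration(make_table(device=x, reference=y), "TSB")
        np.testing.assert_allclose(model.coefficients, (0.5, 1.1, 0.04), rtol=1e-6)

    def test_exact_quartic_spo2(self):
        x = np.linspace(0.6, 3.0, 20)
        coeffs = (40.0, 30.0, -5.0, 0.8, -0.05)
        y = np.polynomial.polynomial.polyval(x, coeffs)
        model = fit_calibration(make_table(device=x, reference=y), "SpO2")
        np.testing.assert_allclose(model.coefficients, coeffs, rtol=1e-6)
        assert model.diagnostics["adjusted_r_squared"] == pytest.approx(1.0)

    def test_insufficient_rows_for_quartic(self):
        table = make_table(device=[1, 2, 3, 4], reference=[1, 2, 3, 4])
        with pytest.raises(ValidationError):
            fit_calibration(table, "SpO2")

    def test_constant_index_degenerate(self):
        table = make_table(device=[2, 2, 2, 2, 2], reference=[1, 2, 3, 4, 5])
        with pytest.raises(DegenerateDataError):
            fit_calibration(table, "Hb")


class TestApplyCalibration:
    def test_identity_linear_hb(self, models):
        identity = CalibrationModel(
            analyte="Hb", family="linear", coefficients=(0.0, 1.0), index_range=(0, 100)
        )
        local = dict(models, Hb=identity)
        idx = InstrumentIndices(hb_index=12.5, bili_index=5.0, spo2_index=1.5)
        panel = apply_calibration(idx, local)
        assert panel.hb == pytest.approx(12.5)

    def test_roundtrip_through_fitted_models(self):
        """fit_calibration on noiseless model-family data, then
        apply_calibration, reproduces the generating values."""
        x_hb = np.linspace(10, 60, 20)
        x_tsb = np.linspace(0.5, 17, 20)
        x_spo2 = np.linspace(0.7, 2.8, 20)  # quartic stays below the 100% clamp
        hb_true = 2.0 + 0.30 * x_hb
        tsb_true = 1.2 * x_tsb + 0.03 * x_tsb**2
        spo2_true = np.polynomial.polynomial.polyval(
            x_spo2, (40.0, 30.0, -5.0, 0.8, -0.05)
        )
        fitted = {
            "Hb": fit_calibration(make_table(x_hb, hb_true), "Hb"),
            "TSB": fit_calibration(make_table(x_tsb, tsb_true), "TSB"),
            "SpO2": fit_calibration(make_table(x_spo2, spo2_true), "SpO2"),
        }
        for i in (0, 7, 19):
            idx = InstrumentIndices(
                hb_index=float(x_hb[i]),
                bili_index=float(x_tsb[i]),
                spo2_index=float(x_spo2[i]),
            )
            panel = apply_calibration(idx, fitted)
            assert panel.hb == pytest.approx(hb_true[i], rel=1e-6)
            assert panel.tsb == pytest.approx(tsb_true[i], rel=1e-6)
            assert panel.spo2 == pytest.approx(spo2_true[i], rel=1e-6)

    def test_spo2_clamped_with_flag(self, models):
        steep = CalibrationModel(
            analyte="SpO2",
            family="poly4",
            coefficients=(103.0, 0.0, 0.0, 0.0, 0.0),
            index_range=(0, 10),
        )
        local = dict(models, SpO2=steep)
        idx = InstrumentIndices(hb_index=30.0, bili_index=5.0, spo2_index=1.0)
        panel = apply_calibration(idx, local)
        assert panel.spo2 == 100.0
        assert panel.spo2_clamped

    def test_extrapolation_flagged(self, models):
        idx = InstrumentIndices(hb_index=500.0, bili_index=5.0, spo2_index=1.5)
        panel = apply_calibration(idx, models)
        assert "Hb" in panel.extrapolated

    def test_missing_model_is_configuration_error(self, models):
        partial = {k: v for k, v in models.items() if k != "TSB"}
        idx = InstrumentIndices(hb_index=30.0, bili_index=5.0, spo2_index=1.5)
        with pytest.raises(CalibrationError):
            apply_calibration(idx, partial)


class TestCalibrationFile:
    def test_json_roundtrip(self, models, tmp_path):
        path = tmp_path / "calib.json"
        save_calibration(models, path)
        back = load_calibration(path)
        for analyte, model in models.items():
            assert back[analyte].coefficients == model.coefficients
            assert back[analyte].family == model.family

    def test_missing_file(self, tmp_path):
        with pytest.raises(CalibrationError):
            load_calibration(tmp_path / "nope.json")


class TestClassify:
    def test_sick_subject_panel(self):
        """A panel like the jaundiced/anemic subject: TSB 29.8, Hb 10.2,
        SpO2 92 flags jaundice and anemia but not hypoxia (strict <)."""
        result = classify(BloodPanel(tsb=29.8, hb=10.2, spo2=92.0))
        assert result.anemia and result.jaundice and not result.hypoxia

    def test_control_subject_all_clear(self):
        result = classify(BloodPanel(tsb=2.4, hb=19.1, spo2=95.0))
        assert not (result.anemia or result.hypoxia or result.jaundice)

    @pytest.mark.parametrize(
        "hb, spo2, tsb, flags",
        [
            (11.0, 92.0, 15.0, (False, False, True)),   # boundaries: <, <, >=
            (10.999, 91.999, 14.999, (True, True, False)),
        ],
    )
    def test_boundary_conventions(self, hb, spo2, tsb, flags):
        r = classify(BloodPanel(tsb=tsb, hb=hb, spo2=spo2))
        assert (r.anemia, r.hypoxia, r.jaundice) == flags

    def test_monotone_in_each_analyte(self):
        base = BloodPanel(tsb=10.0, hb=13.0, spo2=95.0)
        for hb_low, hb_high in [(8.0, 18.0)]:
            assert classify(replace(base, hb=hb_low)).anemia >= classify(
                replace(base, hb=hb_high)
            ).anemia
        assert classify(replace(base, spo2=80.0)).hypoxia >= classify(
            replace(base, spo2=99.0)
        ).hypoxia
        assert classify(replace(base, tsb=25.0)).jaundice >= classify(
            replace(base, tsb=3.0)
        ).jaundice

    def test_configurable_jaundice_cut(self):
        panel = BloodPanel(tsb=12.0, hb=15.0, spo2=98.0)
        assert not classify(panel).jaundice
        assert classify(panel, ClassifyConfig(tsb_jaundice=12.0)).jaundice
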