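"""Population-based input functions: normalization, averaging, tail scaling."""

import numpy as np
import pytest

from pbifpet.cohort_types import SubjectRecord, TriExpParams, true_aif
from pbifpet.input_function import InputFunction, TimeSeries, auc
from pbifpet.pbif import (
    NormScheme,
    auc_percent_error,
    build_pbif,
    evaluate_tail_timepoints,
    normalize_psaif,
    rescale_weight_dose,
    tail_scale,
)

GRID = np.arange(0.0, 5401.0)


def _psaif(scale=1.0, t_peak=0.5):
    aif = TriExpParams(t_peak, (50.0 * scale, 8.0 * scale, 3.0 * scale), (4.0, 0.35, 0.012))
    return InputFunction(GRID, true_aif(aif, GRID / 60.0))


def _subject(sid="S01", weight=70.0, dose=500.0):
    return SubjectRecord(sid, "HV", "HAB", weight, dose)


class TestNormalizePSAIF:
    def test_auc_scheme_yields_unit_area(self):
        out = normalize_psaif(_psaif(), _subject(), NormScheme.AUC)
        assert auc(out, 0, 90) == pytest.approx(1.0, rel=1e-12)

    def test_weight_dose_scheme_divides(self):
        f = InputFunction(GRID, np.full_like(GRID, 3.5))
        out = normalize_psaif(f, _subject(weight=70.0, dose=500.0), NormScheme.WEIGHT_DOSE)
        assert np.allclose(out.values, 1.0e-4)

    def test_weight_auc_scales_inversely_with_weight(self):
        a = normalize_psaif(_psaif(), _subject(weight=60.0), NormScheme.WEIGHT_AUC)
        b = normalize_psaif(_psaif(), _subject(weight=120.0), NormScheme.WEIGHT_AUC)
        assert np.allclose(a.values, 2.0 * b.values)

    def test_scheme_parsing(self):
        assert NormScheme.from_string("weight_auc") is NormScheme.WEIGHT_AUC
        with pytest.raises(ValueError):
            NormScheme.from_string("bsa")


class TestBuildPBIF:
    def test_identical_curves_have_zero_sd(self):
        curves = {f"S{i:02d}": _psaif() for i in range(5)}
        model = build_pbif(curves, exclude="S00", scheme=NormScheme.AUC)
        assert model.n == 4
        assert np.allclose(model.mean, _psaif().values)
        assert np.allclose(model.sd, 0.0)

    def test_leave_one_out_count(self):
        curves = {f"S{i:02d}": _psaif() for i in range(18)}
        model = build_pbif(curves, exclude="S03", scheme=NormScheme.AUC)
        assert model.n == 17

    def test_mean_and_sample_sd_of_two_curves(self):
        f = _psaif()
        curves = {"a": f, "b": InputFunction(GRID, 3.0 * f.values)}
        model = build_pbif({**curves, "c": f}, exclude="c", scheme=NormScheme.AUC)
        assert np.allclose(model.mean, 2.0 * f.values)
        # sample SD of {v, 3v} is sqrt(2) v
        assert np.allclose(model.sd, np.sqrt(2.0) * f.values)

    def test_unknown_exclusion_rejected(self):
        with pytest.raises(KeyError):
            build_pbif({"a": _psaif(), "b": _psaif()}, exclude="zz", scheme=NormScheme.AUC)

    def test_loo_means_average_to_grand_mean(self):
        rng = np.random.default_rng(0)
        curves = {
            f"S{i:02d}": InputFunction(GRID, _psaif().values * rng.uniform(0.5, 2.0))
            for i in range(6)
        }
        grand = np.mean([c.values for c in curves.values()], axis=0)
        loo_mean = np.mean(
            [build_pbif(curves, exclude=k, scheme=NormScheme.AUC).mean for k in curves], axis=0
        )
        assert np.allclose(loo_mean, grand, rtol=1e-12, atol=1e-15)


class TestRescaleWeightDose:
    def _model(self, curves=None):
        curves = curves or {f"S{i:02d}": _psaif() for i in range(4)}
        norm = {
            k: normalize_psaif(c, _subject(k), NormScheme.WEIGHT_DOSE)
            for k, c in curves.items()
        }
        return build_pbif(norm, exclude="S00", scheme=NormScheme.WEIGHT_DOSE)

    def test_zero_variability_reproduces_excluded_psaif(self):
        model = self._model()
        out = rescale_weight_dose(model, _subject("S00"))
        assert np.allclose(out.values, _psaif().values, rtol=1e-12)
        assert out.provenance == "PBIF_scaled"

    def test_bilinearity_in_weight_and_dose(self):
        model = self._model()
        base = rescale_weight_dose(model, _subject(weight=70.0, dose=500.0))
        heavy = rescale_weight_dose(model, _subject(weight=140.0, dose=500.0))
        both = rescale_weight_dose(model, _subject(weight=140.0, dose=1000.0))
        assert np.allclose(heavy.values, 2.0 * base.values)
        assert np.allclose(both.values, 4.0 * base.values)

    def test_weight_dose_product_invariance(self):
        # rescaled output depends on weight*dose only: c and 1/c cancel
        model = self._model()
        a = rescale_weight_dose(model, _subject(weight=70.0 * 3, dose=500.0 / 3))
        b = rescale_weight_dose(model, _subject(weight=70.0, dose=500.0))
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_scheme_mismatch_rejected(self):
        curves = {f"S{i:02d}": _psaif() for i in range(4)}
        model = build_pbif(curves, exclude="S00", scheme=NormScheme.AUC)
        with pytest.raises(ValueError):
            rescale_weight_dose(model, _subject())


class TestTailScale:
    def _auc_model(self):
        norm = {
            f"S{i:02d}": normalize_psaif(_psaif(), _subject(), NormScheme.AUC) for i in range(4)
        }
        return build_pbif(norm, exclude="S00", scheme=NormScheme.AUC)

    def test_doubled_samples_give_factor_two(self):
        model = self._auc_model()
        times = np.array([60.0, 90.0])
        tail = 2.0 * np.interp(times * 60.0, model.times_s, model.mean)
        scaled, factor = tail_scale(model, TimeSeries(times, tail))
        assert factor == pytest.approx(2.0)
        assert np.allclose(scaled.values, 2.0 * model.mean)

    def test_matching_samples_give_identity(self):
        model = self._auc_model()
        times = np.array([60.0, 90.0])
        tail = np.interp(times * 60.0, model.times_s, model.mean)
        scaled, factor = tail_scale(model, TimeSeries(times, tail))
        assert factor == pytest.approx(1.0)
        assert np.allclose(scaled.values, model.mean)

    def test_exact_for_shape_identical_psaif(self):
        """A subject whose PSAIF is an exact scalar multiple of the
        population shape is rescaled with zero area error."""
        model = self._auc_model()
        subject_if = _psaif(scale=1.7)
        times = np.array([60.0, 90.0])
        late = TimeSeries(times, subject_if.value_at(times))
        scaled, _ = tail_scale(model, late)
        assert auc_percent_error(scaled, subject_if) < 1e-6

    def test_weight_dose_scheme_rejected(self):
        norm = {
            f"S{i:02d}": normalize_psaif(_psaif(), _subject(), NormScheme.WEIGHT_DOSE)
            for i in range(4)
        }
        model = build_pbif(norm, exclude="S00", scheme=NormScheme.WEIGHT_DOSE)
        with pytest.raises(ValueError):
            tail_scale(model, TimeSeries([60.0, 90.0], [1.0, 1.0]))

    def test_empty_window_rejected(self):
        model = self._auc_model()
        with pytest.raises(ValueError):
            tail_scale(model, TimeSeries([60.0, 90.0], [1.0, 1.0]), window=(80.0, 80.0))
        with pytest.raises(ValueError):
            tail_scale(model, TimeSeries([10.0, 20.0], [1.0, 1.0]), window=(60.0, 90.0))


class TestTailTimepointScreen:
    def test_screen_layout_and_pseudo_samples(self):
        norm = {f"S{i:02d}": normalize_psaif(_psaif(), _subject(), NormScheme.AUC) for i in range(4)}
        model = build_pbif(norm, exclude="S00", scheme=NormScheme.AUC)
        psaif = _psaif(scale=2.0)
        table = evaluate_tail_timepoints(model, psaif)
        assert len(table) == 7
        assert set(table.loc[table.pseudo, "time_min"]) == {37.5, 52.5, 75.0}
        # pseudo sample at 75 min = mean of the 60- and 90-min PSAIF values,
        # matched against the same average of the population curve
        pseudo75 = 0.5 * (float(psaif.value_at(60.0)) + float(psaif.value_at(90.0)))
        pop75 = 0.5 * float(
            np.interp(60.0 * 60.0, model.times_s, model.mean)
            + np.interp(90.0 * 60.0, model.times_s, model.mean)
        )
        row = table[table.time_min == 75.0]
        assert float(row.scale_factor.iloc[0]) == pytest.approx(pseudo75 / pop75)

    def test_zero_error_for_proportional_psaif(self):
        norm = {f"S{i:02d}": normalize_psaif(_psaif(), _subject(), NormScheme.AUC) for i in range(4)}
        model = build_pbif(norm, exclude="S00", scheme=NormScheme.AUC)
        table = evaluate_tail_timepoints(model, _psaif(scale=3.0))
        assert np.all(table.auc_pct_error < 1e-9)


class TestAUCPercentError:
    def test_identical_curves(self):
        f = _psaif()
        assert auc_percent_error(f, f) == 0.0

    def test_one_percent_difference(self):
        a = InputFunction(GRID, np.full_like(GRID, 1.01))
        b = InputFunction(GRID, np.full_like(GRID, 1.00))
        assert auc_percent_error(a, b) == pytest.approx(1.0, rel=1e-9)

    def test_scalar_multiple_relationship(self):
        f = _psaif()
        for c in (0.5, 1.3, 2.0):
            scaled = f.scaled(c)
            assert auc_percent_error(scaled, f) == pytest.approx(abs(c - 1) * 100.0, rel=1e-9)
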