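"""Spectral pretreatments: exact algebraic properties and composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grainspec as gs
from grainspec.pretreat import PretreatmentSpec, baseline, detrend, msc, \
    normalise, savgol, snv


spectra_strategy = st.lists(
    st.floats(-5, 5, allow_nan=False), min_size=8, max_size=32).map(np.array)


class TestSNV:
    def test_known_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(spectra_strategy)
    def test_output_standardised(self, x):
        if np.std(x, ddof=1) < 1e-6:
            return
        out = snv(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1) < 1e-10

    def test_idempotent(self):
        x = np.sin(np.linspace(0, 5, 40))
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.array([5.0, 5.0, 5.0]))


class TestMSC:
    def test_affine_distortion_removed(self):
        """Hand least-squares oracle: x = 0.5 + 2 ref recovers ref exactly."""
        ref = np.sin(np.linspace(0, 4, 30)) + 2
        x = 0.5 + 2.0 * ref
        np.testing.assert_allclose(msc(x, ref), ref, atol=1e-10)

    def test_reference_is_fixed_point(self):
        ref = np.linspace(0.1, 1.0, 20)
        np.testing.assert_allclose(msc(ref, ref), ref, atol=1e-12)

    def test_corrected_batch_regresses_to_identity(self):
        """Normal-equations oracle: corrected spectra regress on the
        reference with intercept 0 and slope 1."""
        rng = np.random.default_rng(1)
        ref = np.abs(np.cumsum(rng.normal(0, 0.1, 40))) + 1
        X = rng.uniform(0.5, 2, (5, 1)) * ref + rng.uniform(-1, 1, (5, 1))
        out = msc(X, ref)
        design = np.column_stack([np.ones_like(ref), ref])
        for row in out:
            a, b = np.linalg.lstsq(design, row, rcond=None)[0]
            assert abs(a) < 1e-10 and abs(b - 1) < 1e-10

    def test_vanishing_slope_rejected(self):
        ref = np.linspace(0.1, 1.0, 20)
        flat = np.full(20, 3.0)
        with pytest.raises(ValueError, match="slope"):
            msc(flat, ref)


class TestDetrend:
    def test_removes_polynomials_exactly(self):
        wl = np.linspace(1000, 2500, 50)
        ramp = 0.3 + 0.001 * wl
        np.testing.assert_allclose(detrend(ramp, wl, order=1), 0, atol=1e-9)
        quad = 1 + 0.002 * wl - 1e-6 * wl ** 2
        np.testing.assert_allclose(detrend(quad, wl, order=2), 0, atol=1e-9)

    def test_residual_orthogonal_to_basis(self):
        """Orthogonality oracle: the residual of quadratic + peak has zero
        projection on {1, lambda, lambda^2}."""
        wl = np.linspace(1000, 2500, 80)
        x = 0.5 + 1e-4 * wl + 2e-7 * wl ** 2 \
            + 0.4 * np.exp(-((wl - 1900) / 60) ** 2)
        resid = detrend(x, wl, order=2)
        t = (wl - wl.mean()) / ((wl.max() - wl.min()) / 2)
        for basis in (np.ones_like(t), t, t ** 2):
            assert abs(resid @ basis) < 1e-8

    def test_order_validation(self):
        wl = np.linspace(1000, 2000, 5)
        with pytest.raises(ValueError):
            detrend(np.ones(5), wl, order=5)


class TestSavgol:
    def test_first_derivative_of_quadratic(self):
        """Analytic oracle: d/di of i^2 is 2i at interior points."""
        x = np.arange(30.0) ** 2
        d = savgol(x, window=5, polyorder=2, deriv=1)
        np.testing.assert_allclose(d, 2 * np.arange(30.0), atol=1e-8)

    def test_constant_derivative_is_zero(self):
        np.testing.assert_allclose(
            savgol(np.full(20, 3.0), deriv=1), 0, atol=1e-12)

    def test_smoothing_reproduces_low_degree_polynomials(self):
        i = np.arange(25.0)
        x = 1 + 0.5 * i - 0.02 * i ** 2
        np.testing.assert_allclose(savgol(x, 5, 2, 0), x, atol=1e-8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            savgol(np.ones(20), window=4)
        with pytest.raises(ValueError):
            savgol(np.ones(20), window=5, polyorder=2, deriv=3)
        with pytest.raises(ValueError):
            savgol(np.ones(3), window=5)


class TestNormaliseBaseline:
    def test_unit_area_example(self):
        np.testing.assert_allclose(normalise(np.array([1.0, 3.0])),
                                   [0.5, 1.5])

    def test_offset_min_example(self):
        np.testing.assert_allclose(
            baseline(np.array([2.0, 5.0, 4.0])), [0.0, 3.0, 2.0])

    @pytest.mark.parametrize("mode", ["unit_area", "unit_length", "max_one"])
    def test_normalise_idempotent(self, mode):
        x = np.abs(np.sin(np.linspace(0.1, 3, 25))) + 0.1
        once = normalise(x, mode)
        np.testing.assert_allclose(normalise(once, mode), once, atol=1e-12)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            normalise(np.zeros(10))


class TestRestrictRange:
    def test_enumeration_oracle(self, calibration_table):
        _, table, _ = calibration_table
        out = gs.restrict_range(table, 1060.0, 2494.0)
        expected = np.sum((table.grid.values >= 1060)
                          & (table.grid.values <= 2494))
        assert len(out.grid) == expected
        assert out.spectra.shape == (len(table), expected)
        assert out.records is table.records

    def test_inclusive_bounds(self):
        grid = gs.WavelengthGrid(np.array([1000.0, 1500.0, 1800.0]))
        table = gs.SpectraTable(np.ones((1, 3)), grid,
                                [gs.KernelRecord(kernel_id=0)])
        out = gs.restrict_range(table, 1000.0, 1700.0)
        np.testing.assert_array_equal(out.grid.values, [1000.0, 1500.0])

    def test_full_span_is_identity(self, calibration_table):
        _, table, _ = calibration_table
        out = gs.restrict_range(table, table.grid.values[0],
                                table.grid.values[-1])
        np.testing.assert_array_equal(out.spectra, table.spectra)

    def test_empty_selection_rejected(self, calibration_table):
        _, table, _ = calibration_table
        with pytest.raises(ValueError):
            gs.restrict_range(table, 2495.0, 2499.0)


class TestPretreatmentSpec:
    def test_empty_spec_is_identity(self, calibration_table):
        _, table, _ = calibration_table
        out = PretreatmentSpec([]).apply(table)
        np.testing.assert_array_equal(out.spectra, table.spectra)

    def test_composition_matches_manual_chain(self, calibration_table):
        """Composition oracle: [snv, savgol d1] equals applying the two
        operations by hand in order."""
        _, table, _ = calibration_table
        spec = PretreatmentSpec([
            {"step": "snv"},
            {"step": "savgol", "window": 5, "polyorder": 2, "deriv": 1}])
        out = spec.apply(table)
        manual = savgol(snv(table.spectra), 5, 2, 1)
        np.testing.assert_allclose(out.spectra, manual, atol=1e-12)

    def test_order_sensitivity(self, calibration_table):
        _, table, _ = calibration_table
        a = PretreatmentSpec([{"step": "snv"}, {"step": "detrend"}]).apply(table)
        b = PretreatmentSpec([{"step": "detrend"}, {"step": "snv"}]).apply(table)
        assert np.max(np.abs(a.spectra - b.spectra)) > 1e-6

    def test_msc_training_mean_frozen_and_serialised(self, calibration_table):
        _, table, _ = calibration_table
        cal = table.subset(np.arange(0, len(table), 2))
        other = table.subset(np.arange(1, len(table), 2))
        spec = PretreatmentSpec([{"step": "msc"}]).fit(cal)
        reloaded = PretreatmentSpec.from_json(spec.to_json())
        np.testing.assert_allclose(reloaded.apply(other).spectra,
                                   spec.apply(other).spectra, atol=1e-12)
        # the frozen reference is the calibration mean, not the new data's
        frozen = np.asarray(spec.steps[0]["frozen_reference"])
        np.testing.assert_allclose(frozen, cal.spectra.mean(axis=0))

    def test_unfitted_msc_rejected(self, calibration_table):
        _, table, _ = calibration_table
        with pytest.raises(ValueError, match="fit"):
            PretreatmentSpec([{"step": "msc"}]).apply(table)

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            PretreatmentSpec([{"step": "fourier"}])
        with pytest.raises(ValueError):
            PretreatmentSpec([{"step": "savgol", "window": 4}])
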