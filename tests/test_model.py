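"""Forward model and inversion of the cell-covered electrode impedance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecisbarrier.model import (
    BarrierParameters,
    ComplexSpectrum,
    ElectrodeModel,
    covered_impedance,
    fit_barrier_parameters,
    fit_electrode_model,
    membrane_impedance,
    naked_impedance,
    series_capacitance,
    series_resistance,
)


class TestMembraneImpedance:
    def test_magnitude_at_4khz(self):
        # two 1 µF/cm² membranes in series: |Zm| = 2/(2*pi*4000*1e-6)
        zm = membrane_impedance(4000.0, 1.0)
        assert zm.real == pytest.approx(0.0, abs=1e-12)
        assert abs(zm) == pytest.approx(79.5774715459, rel=1e-9)
        assert zm.imag < 0

    @given(
        f=st.floats(1.0, 1e6),
        cm=st.floats(0.05, 50.0),
    )
    def test_purely_capacitive_and_reciprocal_in_cm(self, f, cm):
        zm = membrane_impedance(f, cm)
        assert zm.real == 0.0
        assert abs(membrane_impedance(f, 2 * cm)) == pytest.approx(abs(zm) / 2, rel=1e-12)

    @pytest.mark.parametrize("f,cm", [(0.0, 1.0), (-5.0, 1.0), (4000.0, 0.0), (4000.0, -1.0)])
    def test_domain_errors(self, f, cm):
        with pytest.raises(ValueError):
            membrane_impedance(f, cm)


class TestNakedImpedance:
    def test_ideal_capacitor_limit(self, electrode):
        el = ElectrodeModel(electrode.R_solution, 2e-6, 1.0, electrode.electrode_area)
        f = 4000.0
        expected = el.R_solution + 1.0 / (1j * 2 * np.pi * f * 2e-6)
        assert naked_impedance(f, el) == pytest.approx(expected, rel=1e-12)

    def test_high_frequency_approaches_solution_resistance(self, electrode):
        z = naked_impedance(1e12, electrode)
        assert z.real == pytest.approx(electrode.R_solution, rel=1e-3)

    def test_real_part_decreasing_in_frequency_for_cpe(self, electrode):
        f = np.logspace(2, 5, 40)
        re = naked_impedance(f, electrode).real
        assert np.all(np.diff(re) < 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ElectrodeModel(-1.0, 1e-6, 0.9, 0.02)
        with pytest.raises(ValueError):
            ElectrodeModel(1.0, 1e-6, 1.2, 0.02)


class TestCoveredImpedance:
    def test_reduces_to_naked_for_open_barrier(self, electrode, grid):
        """Rb = alpha = 0 short-circuits the cell layer at every frequency."""
        zn = naked_impedance(grid, electrode)
        zc = covered_impedance(grid, (0.0, 0.0, 1.0), electrode)
        assert np.max(np.abs(zc - zn) / np.abs(zn)) < 1e-10

    def test_high_frequency_limit_approaches_naked(self, electrode, baseline, grid):
        # the transcellular path shorts once f >> 1/(2 pi Zn Cm); with Cm = 8
        # the roll-off begins inside the grid, so the tail must decrease
        zc = covered_impedance(grid, (4.0, 8.0, 8.0), electrode)
        zn = naked_impedance(grid, electrode)
        rel = np.abs(zc - zn) / np.abs(zn)
        assert np.all(np.diff(rel[5:]) < 0)
        # for the baseline Cm the same limit holds beyond the grid
        f_far = np.array([6.4e4, 2.56e5, 1.024e6, 4.096e6])
        rel_far = np.abs(
            covered_impedance(f_far, baseline, electrode) - naked_impedance(f_far, electrode)
        ) / np.abs(naked_impedance(f_far, electrode))
        assert np.all(np.diff(rel_far) < 0)
        assert rel_far[-1] < 0.05

    def test_monotone_in_rb_at_4khz(self, electrode, baseline):
        re = [
            covered_impedance(4000.0, (rb, baseline.alpha, baseline.Cm), electrode).real
            for rb in np.linspace(0.0, 50.0, 51)
        ]
        assert np.all(np.diff(re) > 0)

    def test_monotone_in_alpha_at_4khz(self, electrode, baseline):
        re = [
            covered_impedance(4000.0, (baseline.Rb, a, baseline.Cm), electrode).real
            for a in np.linspace(0.0, 32.0, 33)
        ]
        assert np.all(np.diff(re) >= 0)

    def test_large_alpha_uses_asymptotic_bessel_ratio(self, electrode):
        # |s| far beyond the overflow point of I0/I1 must stay finite and
        # continuous across the asymptotic switch-over
        z_big = covered_impedance(64000.0, (4.0, 5000.0, 1.0), electrode)
        assert np.isfinite(z_big.real) and np.isfinite(z_big.imag)
        za = covered_impedance(250.0, (4.0, 29.0, 1.0), electrode)
        zb = covered_impedance(250.0, (4.0, 31.0, 1.0), electrode)
        assert abs(za - zb) / abs(za) < 0.1

    def test_invalid_parameters(self, electrode):
        with pytest.raises(ValueError):
            covered_impedance(4000.0, (-1.0, 8.0, 1.0), electrode)
        with pytest.raises(ValueError):
            covered_impedance(4000.0, (4.0, 8.0, 0.0), electrode)


class TestSeriesReadouts:
    def test_closed_form_example(self):
        z = 100.0 - 1000.0j
        assert series_resistance(z) == pytest.approx(100.0)
        # C = 1/(2*pi*64000*1000) = 2.4868 nF
        assert series_capacitance(z, 64000.0) == pytest.approx(2.48680, rel=1e-4)

    def test_non_capacitive_impedance_flagged_nan(self):
        assert np.isnan(series_capacitance(100.0 + 0.0j, 4000.0))
        assert np.isnan(series_capacitance(100.0 + 50.0j, 4000.0))

    @given(im=st.floats(-1e6, -1e-3), f=st.floats(10.0, 1e5))
    def test_reciprocal_in_reactance(self, im, f):
        c1 = series_capacitance(100.0 + 1j * im, f)
        c2 = series_capacitance(100.0 + 0.5j * im, f)
        assert c2 == pytest.approx(2 * c1, rel=1e-9)


class TestSpectrumAndParameterTypes:
    def test_spectrum_invariants_enforced(self, grid):
        z = np.full(grid.size, 10.0 - 5.0j)
        ComplexSpectrum(grid, z)
        with pytest.raises(ValueError):
            ComplexSpectrum(grid[::-1], z)
        with pytest.raises(ValueError):
            ComplexSpectrum(grid, np.full(grid.size, -1.0 - 5.0j))

    def test_rb_zero_forces_invalid_flags(self):
        with pytest.raises(ValueError):
            BarrierParameters(0.0, 5.0, 1.0)  # flags must be false when Rb == 0
        p = BarrierParameters(0.0, 5.0, 1.0, alpha_valid=False, Cm_valid=False)
        assert not p.alpha_valid and not p.Cm_valid


class TestElectrodeFit:
    def test_exact_recovery_from_forward_model(self, electrode, grid):
        zn = naked_impedance(grid, electrode)
        fitted = fit_electrode_model(
            ComplexSpectrum(grid, zn), electrode.electrode_area
        )
        assert fitted.R_solution == pytest.approx(electrode.R_solution, rel=1e-6)
        assert fitted.Q_cpe == pytest.approx(electrode.Q_cpe, rel=1e-6)
        assert fitted.n_cpe == pytest.approx(electrode.n_cpe, rel=1e-6)

    def test_recovery_under_one_percent_noise(self, electrode, grid):
        rng = np.random.default_rng(42)
        zn = naked_impedance(grid, electrode)
        noisy = zn * np.exp(0.01 * rng.standard_normal(grid.size))
        fitted = fit_electrode_model(ComplexSpectrum(grid, noisy), electrode.electrode_area)
        assert fitted.R_solution == pytest.approx(electrode.R_solution, rel=0.05)
        assert fitted.Q_cpe == pytest.approx(electrode.Q_cpe, rel=0.05)
        assert fitted.n_cpe == pytest.approx(electrode.n_cpe, rel=0.05)

    def test_underdetermined_input_rejected(self, electrode):
        spec = ComplexSpectrum([4000.0], [10.0 - 5.0j])
        with pytest.raises(ValueError):
            fit_electrode_model(spec, electrode.electrode_area)


class TestBarrierFit:
    def test_noise_free_recovery(self, electrode, grid):
        truth = (4.0, 8.0, 2.0)
        zc = covered_impedance(grid, truth, electrode)
        res = fit_barrier_parameters(ComplexSpectrum(grid, zc), electrode)
        assert res.converged
        assert res.params.Rb == pytest.approx(truth[0], rel=1e-3)
        assert res.params.alpha == pytest.approx(truth[1], rel=1e-3)
        assert res.params.Cm == pytest.approx(truth[2], rel=1e-3)

    def test_cell_free_spectrum_reports_rb_zero_with_invalid_flags(self, electrode, grid):
        zn = naked_impedance(grid, electrode)
        res = fit_barrier_parameters(ComplexSpectrum(grid, zn), electrode)
        assert res.params.Rb == 0.0
        assert not res.params.alpha_valid
        assert not res.params.Cm_valid

    def test_warm_start_cheaper_than_cold(self, electrode, grid):
        truth = (4.0, 8.0, 2.0)
        zc = covered_impedance(grid, truth, electrode)
        spec = ComplexSpectrum(grid, zc)
        cold = fit_barrier_parameters(spec, electrode)
        warm = fit_barrier_parameters(spec, electrode, init=truth)
        assert warm.n_iterations < cold.n_iterations

    def test_too_few_frequencies_rejected(self, electrode):
        spec = ComplexSpectrum([250.0, 500.0], [10.0 - 5.0j, 9.0 - 4.0j])
        with pytest.raises(ValueError):
            fit_barrier_parameters(spec, electrode)
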