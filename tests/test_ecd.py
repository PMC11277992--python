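"""Band shapes, averaging, UV shift, peak scaling and enantiomer calls."""

import numpy as np
import pytest

from chirokit import (
    BandShapeParams,
    ConformerRecord,
    Ensemble,
    SpectrumGrid,
    TransitionRecord,
    UndecidableError,
    WeightVector,
    apply_uv_shift,
    assign_enantiomer,
    boltzmann_weights,
    compare_spectra,
    default_grid,
    ensemble_spectrum,
    scale_spectrum,
    stick_to_spectrum,
    theoretical_spectrum,
)
from chirokit.conformers import EV_NM


def band_integral(transitions, zeta):
    """Quadrature oracle: ∫ Δε/E dE over a wide window, fine grid."""
    grid = default_grid(120, 900, 0.02)
    s = stick_to_spectrum(transitions, BandShapeParams(zeta=zeta, uv_shift=0), grid)
    E = EV_NM / s.wavelengths
    order = np.argsort(E)
    return np.trapezoid((s.values / E)[order], E[order])


class TestStickToSpectrum:
    def test_single_positive_band_position_and_sign(self, grid):
        t = TransitionRecord(4.275, 10.0)
        s = stick_to_spectrum([t], BandShapeParams(zeta=0.36, uv_shift=0), grid)
        peak = s.wavelengths[np.argmax(s.values)]
        assert peak == pytest.approx(EV_NM / 4.275, abs=1.0)
        assert s.values.max() > 0

    def test_linearity_in_rotatory_strength(self, grid, single_band_params):
        ts = [TransitionRecord(4.275, 10.0), TransitionRecord(5.2, -6.0)]
        scaled = [TransitionRecord(t.energy_ev, 3.0 * t.rotatory_strength) for t in ts]
        a = stick_to_spectrum(ts, single_band_params, grid)
        b = stick_to_spectrum(scaled, single_band_params, grid)
        np.testing.assert_allclose(b.values, 3.0 * a.values, rtol=1e-12)

    def test_enantiomer_negates_pointwise(self, grid, single_band_params):
        ts = [TransitionRecord(4.275, 10.0), TransitionRecord(5.2, -6.0)]
        mirror = [TransitionRecord(t.energy_ev, -t.rotatory_strength) for t in ts]
        a = stick_to_spectrum(ts, single_band_params, grid)
        b = stick_to_spectrum(mirror, single_band_params, grid)
        np.testing.assert_allclose(b.values, -a.values, rtol=1e-12)

    @pytest.mark.parametrize("zeta", [0.36, 0.24, 0.05])
    @pytest.mark.parametrize("r", [10.0, -4.5])
    def test_band_integral_closed_form(self, zeta, r):
        """∫Δε/E dE = R/22.97 for any bandwidth (R in 1e-40 cgs)."""
        got = band_integral([TransitionRecord(4.275, r)], zeta)
        assert got == pytest.approx(r / 22.97, rel=5e-3)

    def test_band_integral_additive_over_transitions(self):
        ts = [TransitionRecord(4.0, 7.0), TransitionRecord(5.5, -3.0)]
        assert band_integral(ts, 0.1) == pytest.approx((7.0 - 3.0) / 22.97, rel=5e-3)


class TestEnsembleSpectrum:
    def test_single_conformer_weight_one(self, grid, single_band_params):
        ts = (TransitionRecord(4.275, 10.0),)
        e = Ensemble([ConformerRecord("c0", 0.0, None, ts)])
        s = ensemble_spectrum(e, boltzmann_weights(e), single_band_params, grid)
        ref = stick_to_spectrum(ts, single_band_params, grid)
        np.testing.assert_allclose(s.values, ref.values, rtol=1e-12)

    def test_convexity_of_identical_conformers(self, grid, single_band_params):
        ts = (TransitionRecord(4.275, 10.0),)
        e = Ensemble(
            [ConformerRecord("a", 0.0, None, ts), ConformerRecord("b", 0.0, None, ts)]
        )
        s = ensemble_spectrum(e, boltzmann_weights(e), single_band_params, grid)
        ref = stick_to_spectrum(ts, single_band_params, grid)
        np.testing.assert_allclose(s.values, ref.values, rtol=1e-12)

    def test_enantiomeric_pair_cancels(self, grid, single_band_params):
        e = Ensemble(
            [
                ConformerRecord("a", 0.0, None, (TransitionRecord(4.275, 10.0),)),
                ConformerRecord("b", 0.0, None, (TransitionRecord(4.275, -10.0),)),
            ]
        )
        s = ensemble_spectrum(e, boltzmann_weights(e), single_band_params, grid)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-15)

    def test_weight_mismatch_rejected(self, grid, single_band_params):
        ts = (TransitionRecord(4.275, 10.0),)
        e = Ensemble([ConformerRecord("c0", 0.0, None, ts)])
        with pytest.raises(ValueError, match="weights"):
            ensemble_spectrum(e, WeightVector({"other": 1.0}), single_band_params, grid)

    def test_averaging_commutes_with_broadening(self, grid, single_band_params):
        """Weighted sum of conformer spectra equals spectrum of weighted sticks."""
        e = Ensemble(
            [
                ConformerRecord("a", 0.0, None, (TransitionRecord(4.2, 10.0),)),
                ConformerRecord("b", 0.7, None, (TransitionRecord(5.1, -8.0),)),
            ]
        )
        w = boltzmann_weights(e)
        s = ensemble_spectrum(e, w, single_band_params, grid)
        merged = [
            TransitionRecord(4.2, w["a"] * 10.0),
            TransitionRecord(5.1, w["b"] * -8.0),
        ]
        ref = stick_to_spectrum(merged, single_band_params, grid)
        np.testing.assert_allclose(s.values, ref.values, rtol=1e-10)


class TestUvShift:
    def test_zero_shift_identity(self, grid, single_band_params):
        s = stick_to_spectrum([TransitionRecord(4.275, 10.0)], single_band_params, grid)
        np.testing.assert_array_equal(apply_uv_shift(s, 0.0).values, s.values)

    def test_peak_translates(self, grid):
        t = TransitionRecord.from_wavelength(286.0, 10.0)
        s = stick_to_spectrum([t], BandShapeParams(zeta=0.36, uv_shift=0), grid)
        shifted = apply_uv_shift(s, 4.0)
        assert shifted.wavelengths[np.argmax(shifted.values)] == pytest.approx(290.0, abs=1.0)

    def test_shift_roundtrip(self, grid, single_band_params):
        s = stick_to_spectrum([TransitionRecord(4.275, 10.0)], single_band_params, grid)
        back = apply_uv_shift(apply_uv_shift(s, 4.0), -4.0)
        interior = slice(10, -10)
        np.testing.assert_allclose(back.values[interior], s.values[interior], atol=1e-4)


class TestScaleSpectrum:
    def test_unit_peak_and_idempotence(self, grid, single_band_params):
        s = stick_to_spectrum([TransitionRecord(4.275, 10.0)], single_band_params, grid)
        sc = scale_spectrum(s)
        assert sc.values.max() == pytest.approx(1.0, abs=1e-12)
        sc2 = scale_spectrum(sc)
        np.testing.assert_allclose(sc2.values, sc.values, rtol=1e-12)
        assert sc.scale_peak_nm == pytest.approx(EV_NM / 4.275, abs=1.0)

    def test_amplitude_invariance(self, grid, single_band_params):
        s = stick_to_spectrum([TransitionRecord(4.275, 10.0)], single_band_params, grid)
        boosted = SpectrumGrid(s.wavelengths, 7.3 * s.values, "experimental")
        np.testing.assert_allclose(
            scale_spectrum(boosted).values, scale_spectrum(s).values, rtol=1e-12
        )

    def test_selects_band_nearest_reference(self, grid):
        """Two positive maxima at ~208 and ~295 nm; reference 290 picks 295."""
        ts = [
            TransitionRecord.from_wavelength(208.0, 30.0),
            TransitionRecord.from_wavelength(295.0, 8.0),
        ]
        s = stick_to_spectrum(ts, BandShapeParams(zeta=0.24, uv_shift=0), grid)
        sc = scale_spectrum(s, reference_band=290.0)
        assert sc.scale_peak_nm == pytest.approx(295.0, abs=1.5)
        assert sc.interp(np.array([sc.scale_peak_nm]))[0] == pytest.approx(1.0, abs=1e-9)

    def test_no_positive_band_reports_window(self, grid, single_band_params):
        s = stick_to_spectrum([TransitionRecord(4.275, -10.0)], single_band_params, grid)
        with pytest.raises(ValueError, match="265"):
            scale_spectrum(s, reference_band=290.0)


class TestCompareAndAssign:
    def make(self, grid):
        ts = [TransitionRecord(4.275, 10.0), TransitionRecord(5.4, -12.0)]
        return stick_to_spectrum(ts, BandShapeParams(zeta=0.36, uv_shift=0), grid)

    def test_self_similarity_and_mirror(self, grid):
        s = self.make(grid)
        assert compare_spectra(s, s) == pytest.approx(1.0, abs=1e-12)
        assert compare_spectra(s, -s) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_by_gram_schmidt(self, grid):
        s = self.make(grid)
        other = stick_to_spectrum(
            [TransitionRecord(4.8, 9.0)], BandShapeParams(zeta=0.3, uv_shift=0), grid
        )
        window = (200.0, 400.0)
        mask = (grid >= 200) & (grid <= 400)
        v, u = s.values[mask], other.values[mask]
        t = u - (v @ u) / (v @ v) * v  # Gram-Schmidt on the window
        ortho = SpectrumGrid(grid[mask], t)
        masked_s = SpectrumGrid(grid[mask], v)
        assert compare_spectra(masked_s, ortho, window) == pytest.approx(0.0, abs=1e-9)

    def test_resampling_stability(self):
        coarse = default_grid(190, 400, 1.0)
        fine = default_grid(190, 400, 0.5)
        a1, b1 = self.make(coarse), self.make(fine)
        ref = compare_spectra(a1, a1)
        cross = compare_spectra(a1, b1)
        assert abs(cross - ref) < 1e-3

    def test_assign_enantiomer_labels(self, grid):
        s = self.make(grid)
        rng = np.random.default_rng(11)
        noisy = SpectrumGrid(
            grid, s.values + 0.02 * np.abs(s.values).max() * rng.standard_normal(grid.size)
        )
        label, score = assign_enantiomer(s, noisy)
        assert label == "as-modeled" and score > 0.95
        label, score = assign_enantiomer(s, -s)
        assert label == "mirror" and score == pytest.approx(1.0, abs=1e-12)

    def test_tie_is_undecidable(self, grid):
        s = self.make(grid)
        window = (200.0, 400.0)
        mask = (grid >= 200) & (grid <= 400)
        v = s.values[mask]
        u = np.ones_like(v)
        t = u - (v @ u) / (v @ v) * v
        ortho = SpectrumGrid(grid[mask], t)
        with pytest.raises(UndecidableError):
            assign_enantiomer(SpectrumGrid(grid[mask], v), ortho, window)


class TestEndToEndMirrorSymmetry:
    def test_negating_rotatory_strengths_negates_pipeline_output(self, grid):
        ts = (TransitionRecord(4.275, 10.0), TransitionRecord(5.2, -15.0))
        mirror_ts = tuple(TransitionRecord(t.energy_ev, -t.rotatory_strength) for t in ts)
        e = Ensemble([ConformerRecord("a", 0.0, None, ts), ConformerRecord("b", 0.8, None, ts)])
        em = Ensemble(
            [ConformerRecord("a", 0.0, None, mirror_ts), ConformerRecord("b", 0.8, None, mirror_ts)]
        )
        params = BandShapeParams(zeta=0.36, uv_shift=4.0)
        s = theoretical_spectrum(e, params, grid)
        sm = theoretical_spectrum(em, params, grid)
        np.testing.assert_allclose(sm.values, -s.values, rtol=1e-10, atol=1e-12)
        # identical scaling-band choice on the mirrored positive band
        sc = scale_spectrum(s)
        sc_m = scale_spectrum(-sm)
        np.testing.assert_allclose(sc_m.values, sc.values, rtol=1e-10)
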