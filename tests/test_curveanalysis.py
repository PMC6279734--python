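"""Fourier fitting and functional-parameter extraction.

Closed-form oracle: V(t) = 300 + 100 cos(2 pi t / 0.2) has EDV = 400 at
t = 0, ESV = 200 at t = 0.1, EF = 50%, peak dV/dt = 2 pi 100 / 0.2 at
t = 0.15 giving PFR = 7.854 EDV/s, TPFR = 50 ms, and a first-third chord
of (250 - 200) / (1/30) / 400 = 3.75 EDV/s.
"""

import numpy as np
import pytest

from gatedpet.curveanalysis import (VolumeCurveModel, analyze, compute_ef,
                                    compute_pfr, compute_tpfr,
                                    compute_third_mfr, find_ed_es,
                                    fit_fourier, measure_continuous)
from gatedpet.curves import ContinuousVolumeCurve, VolumeCurve
from gatedpet.errors import DataError, DegenerateCurveError
from gatedpet.phantom import sample_gate_volumes

PFR_COS = 2.0 * np.pi * 100.0 / 0.2 / 400.0  # 7.854 EDV/s


def _sample(curve, n=16):
    return sample_gate_volumes(curve, n_gates=n, mode="point")


class TestFitFourier:
    def test_recovers_cosine_coefficients_exactly(self, cosine_curve):
        fit = fit_fourier(_sample(cosine_curve), n_harmonics=7)
        assert fit.dc == pytest.approx(300.0, abs=1e-9)
        np.testing.assert_allclose(fit.harmonics[0], (100.0, 0.0), atol=1e-9)
        np.testing.assert_allclose(np.asarray(fit.harmonics[1:]), 0.0,
                                   atol=1e-9)

    def test_constant_samples_give_dc_only(self):
        vc = VolumeCurve(np.linspace(0.01, 0.19, 16), np.full(16, 250.0), 0.2)
        fit = fit_fourier(vc, n_harmonics=4)
        assert fit.dc == pytest.approx(250.0)
        np.testing.assert_allclose(np.asarray(fit.harmonics), 0.0, atol=1e-9)

    def test_band_limited_interpolation_is_exact(self, zl_curve):
        """<=7-harmonic curves are fully determined by 16 point samples."""
        fit = fit_fourier(_sample(zl_curve), n_harmonics=7)
        t = np.linspace(0.0, zl_curve.period, 123)
        np.testing.assert_allclose(fit.volume(t), zl_curve.volume(t),
                                   rtol=1e-8, atol=1e-6)

    def test_too_many_harmonics_rejected(self, cosine_curve):
        with pytest.raises(DataError):
            fit_fourier(_sample(cosine_curve), n_harmonics=8)

    def test_white_noise_residual_fraction(self, rng):
        """LSQ projection onto 9 of 16 dims leaves ~7/16 of the variance."""
        t = (np.arange(16) + 0.5) * 0.2 / 16
        ratios = []
        for _ in range(300):
            y = rng.normal(size=16)
            fit = fit_fourier(VolumeCurve(t, y + 300.0, 0.2), n_harmonics=4)
            resid = y + 300.0 - fit.volume(t)
            ratios.append((resid @ resid / 16.0) / np.var(y, ddof=1))
        assert np.mean(ratios) == pytest.approx(7.0 / 16.0, rel=0.15)


class TestParameters:
    def test_cosine_extrema(self, cosine_curve):
        ed, edv, es, esv = find_ed_es(cosine_curve)
        assert edv == pytest.approx(400.0, abs=1e-6)
        assert esv == pytest.approx(200.0, abs=1e-6)
        assert ed == pytest.approx(0.0, abs=1e-6) or ed == pytest.approx(0.2, abs=1e-6)
        assert es == pytest.approx(0.1, abs=1e-6)

    def test_flat_curve_is_degenerate(self):
        flat = ContinuousVolumeCurve(period=0.2, dc=300.0,
                                     harmonics=((0.1, 0.0),))
        with pytest.raises(DegenerateCurveError):
            find_ed_es(flat)

    def test_offset_moves_volumes_not_phases(self, cosine_curve):
        shifted = ContinuousVolumeCurve(0.2, 350.0, ((100.0, 0.0),))
        ed0, edv0, es0, esv0 = find_ed_es(cosine_curve)
        ed1, edv1, es1, esv1 = find_ed_es(shifted)
        assert (ed1, es1) == pytest.approx((ed0, es0), abs=1e-6)
        assert edv1 - edv0 == pytest.approx(50.0, abs=1e-6)

    def test_time_shift_equivariance(self, cosine_curve):
        dt = 0.042
        shifted = cosine_curve.shifted(dt)
        m0 = measure_continuous(cosine_curve)
        m1 = measure_continuous(shifted)
        assert ((m0.es_phase - dt) % 0.2) == pytest.approx(m1.es_phase % 0.2,
                                                           abs=1e-6)
        for par in ("ef", "pfr", "tpfr", "third_mfr"):
            assert getattr(m1, par) == pytest.approx(getattr(m0, par),
                                                     rel=1e-6)

    def test_ef_examples(self):
        assert compute_ef(410.8, 155.1) == pytest.approx(62.24, abs=0.01)
        assert compute_ef(321.0, 0.0) == 100.0
        assert compute_ef(321.0, 321.0) == 0.0
        with pytest.raises(DataError):
            compute_ef(0.0, 0.0)
        with pytest.raises(DataError):
            compute_ef(100.0, 150.0)

    def test_pfr_closed_form(self, cosine_curve):
        pfr, t_pfr = compute_pfr(cosine_curve, 400.0, 0.1, 0.0)
        assert pfr == pytest.approx(PFR_COS, rel=1e-6)
        assert t_pfr == pytest.approx(0.15, abs=1e-6)

    def test_pfr_scale_invariant(self, cosine_curve):
        doubled = ContinuousVolumeCurve(0.2, 600.0, ((200.0, 0.0),))
        p0, _ = compute_pfr(cosine_curve, 400.0, 0.1, 0.0)
        p1, _ = compute_pfr(doubled, 800.0, 0.1, 0.0)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_tpfr_closed_form_and_wraparound(self):
        assert compute_tpfr(0.10, 0.15, 0.2) == pytest.approx(50.0)
        assert compute_tpfr(0.10, 0.10, 0.2) == 0.0
        # ES late in the cycle, peak filling after the wrap
        assert compute_tpfr(0.18, 0.03, 0.2) == pytest.approx(50.0)
        assert 0.0 < compute_tpfr(0.18, 0.03, 0.2) < 200.0

    def test_third_mfr_closed_form(self, cosine_curve):
        mfr = compute_third_mfr(cosine_curve, 400.0, 0.1, 0.0)
        # V(0.1333) - V(0.1) = 50 over one third of 0.1 s filling
        assert mfr == pytest.approx(3.75, rel=1e-4)

    def test_third_mfr_never_exceeds_pfr(self, rng):
        """The first-third mean of dV/dt cannot exceed its max over the
        containing filling interval, whatever the curve."""
        for _ in range(25):
            harmonics = tuple(
                (rng.normal(0, 40.0 / k), rng.normal(0, 40.0 / k))
                for k in range(1, rng.integers(2, 8)))
            curve = ContinuousVolumeCurve(0.2, 300.0, harmonics)
            try:
                ed, edv, es, esv = find_ed_es(curve)
            except DegenerateCurveError:
                continue
            pfr, _ = compute_pfr(curve, edv, es, ed)
            mfr = compute_third_mfr(curve, edv, es, ed)
            assert mfr <= pfr + 1e-9 * abs(pfr)


class TestAnalyze:
    def test_matches_analytic_oracle_on_band_limited_curve(self, zl_curve):
        from gatedpet.phantom import measure_curve

        truth = measure_curve(zl_curve)
        rec = analyze(_sample(zl_curve), n_harmonics=6)
        for par in ("edv", "esv", "ef", "pfr", "tpfr", "third_mfr"):
            assert getattr(rec, par) == pytest.approx(getattr(truth, par),
                                                      rel=5e-3)

    def test_constant_curve_degenerate(self):
        vc = VolumeCurve(np.linspace(0.01, 0.19, 16), np.full(16, 250.0), 0.2)
        with pytest.raises(DegenerateCurveError):
            analyze(vc)

    def test_model_results_object(self, cosine_curve):
        model = VolumeCurveModel(_sample(cosine_curve), hr=300.0)
        fit = model.fit(n_harmonics=4)
        assert fit.result.ef == pytest.approx(50.0, abs=1e-6)
        assert fit.result.hr == 300.0
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        text = fit.summary()
        assert "EF (%)" in text and "PFR" in text

    def test_model_plot_returns_axis(self, cosine_curve):
        import matplotlib

        matplotlib.use("Agg")
        fit = VolumeCurveModel(_sample(cosine_curve), hr=300.0).fit(4)
        ax = fit.plot()
        assert ax is not None
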