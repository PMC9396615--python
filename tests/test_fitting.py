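"""Tests of trace decomposition, k_obs([CO]) and Hill-plot estimators."""

import numpy as np
import pytest

from ngbkin.exceptions import DomainError, IdentifiabilityError
from ngbkin.fitting import (
    ObservedBinding,
    TitrationPoint,
    fit_hill_affinity,
    fit_kobs_curve,
    fit_multiexponential,
)
from ngbkin.kinetic_core import ProgressCurve, RateConstants, kobs_hexacoordinate


def exp_curve(t, components, offset=0.0, noise_sd=0.0, seed=0):
    y = np.full_like(t, offset, dtype=float)
    for amp, rate in components:
        y = y + amp * np.exp(-rate * t)
    if noise_sd:
        span = y.max() - y.min()
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd * span, t.size)
    return ProgressCurve(t, y)


class TestMultiexponential:
    # a typical stopped-flow acquisition: 2000 samples over ~12 lifetimes
    t_lin = np.linspace(1e-3, 20.0, 2000)

    def test_noiseless_single_exponential_recovered(self):
        curve = exp_curve(self.t_lin, [(0.96, 0.13)], offset=0.04)
        dec = fit_multiexponential(curve, max_components=3)
        assert len(dec.components) == 1
        assert dec.rates[0] == pytest.approx(0.13, rel=1e-6)
        assert dec.amplitudes[0] == pytest.approx(0.96, rel=1e-6)

    def test_noiseless_biexponential_recovered(self):
        curve = exp_curve(self.t_lin, [(0.73, 1.2), (0.27, 0.62)], offset=0.02)
        dec = fit_multiexponential(curve, max_components=3)
        assert len(dec.components) == 2
        assert dec.rates[0] == pytest.approx(1.2, rel=1e-4)
        assert dec.rates[1] == pytest.approx(0.62, rel=1e-4)
        assert dec.amplitude_fractions[0] == pytest.approx(0.73, abs=1e-4)

    def test_constant_trace_flagged_degenerate(self):
        curve = ProgressCurve(self.t_lin, np.full_like(self.t_lin, 0.5))
        dec = fit_multiexponential(curve, max_components=2)
        assert dec.degenerate and not dec.components
        assert dec.offset == pytest.approx(0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            fit_multiexponential(ProgressCurve([0.0, 1.0], [1.0, 0.5]), 1)

    def test_selected_model_never_fits_worse_than_lower_orders(self):
        curve = exp_curve(self.t_lin, [(0.7, 1.2), (0.3, 0.62)], noise_sd=0.01)
        dec = fit_multiexponential(curve, max_components=4)
        selected_rss = dec.fit_quality.rss
        for n, rss, _ in dec.candidates:
            if n < len(dec.components):
                assert selected_rss <= rss + 1e-12

    def test_noisy_parameter_recovery_medians(self):
        """1% noise, 20 seeds: median rates within 5%, amplitude fractions
        within 3 points, for one- and two-component traces."""
        mono_rates, bi_fast, bi_slow, bi_frac = [], [], [], []
        for seed in range(20):
            mono = fit_multiexponential(
                exp_curve(self.t_lin, [(1.0, 0.13)], noise_sd=0.01, seed=seed), 2
            )
            mono_rates.append(mono.rates[0])
            bi = fit_multiexponential(
                exp_curve(self.t_lin, [(0.73, 1.2), (0.27, 0.62)], noise_sd=0.01, seed=seed), 2
            )
            if len(bi.components) == 2:
                bi_fast.append(bi.rates[0])
                bi_slow.append(bi.rates[1])
                bi_frac.append(bi.amplitude_fractions[0])
        assert np.median(mono_rates) == pytest.approx(0.13, rel=0.05)
        assert np.median(bi_fast) == pytest.approx(1.2, rel=0.05)
        assert np.median(bi_slow) == pytest.approx(0.62, rel=0.05)
        assert np.median(bi_frac) == pytest.approx(0.73, abs=0.03)

    def test_no_second_component_invented_on_monoexponential_data(self):
        """Conservative selection: at 2% noise the two-component model is
        never chosen for truly monoexponential traces (20 seeds)."""
        for seed in range(20):
            curve = exp_curve(self.t_lin, [(1.0, 0.5)], noise_sd=0.02, seed=seed)
            dec = fit_multiexponential(curve, max_components=2)
            assert len(dec.components) == 1


class TestKobsCurve:
    rates = RateConstants(k_his_on=3000.0, k_his_off=1.2, k_co_on=1e8)

    def binding(self, concs):
        return ObservedBinding(
            points=tuple((c, kobs_hexacoordinate(self.rates, c), 1.0) for c in concs)
        )

    def test_exact_recovery_from_noiseless_points(self):
        fit = fit_kobs_curve(self.binding([1e-6, 1e-5, 3e-5, 1e-4, 1e-3]))
        assert fit.k_his_off == pytest.approx(1.2, rel=1e-8)
        assert fit.c_half == pytest.approx(3e-5, rel=1e-8)
        assert not fit.plateau_only

    def test_plateau_regime_flagged(self):
        # all concentrations far above c_half; 1% noise leaves c_half
        # unconstrained and the fit must say so
        concs = [5e-3, 1e-2, 2e-2]
        gen = np.random.default_rng(3)
        pts = tuple(
            (c, kobs_hexacoordinate(self.rates, c) * (1 + gen.normal(0, 0.01)), 1.0)
            for c in concs
        )
        with pytest.warns(UserWarning):
            fit = fit_kobs_curve(ObservedBinding(points=pts))
        assert fit.plateau_only
        assert fit.k_his_off == pytest.approx(1.2, rel=0.05)

    def test_single_concentration_unidentifiable(self):
        with pytest.raises(IdentifiabilityError):
            fit_kobs_curve(
                ObservedBinding(points=((1e-4, 1.0, 0.5), (1e-4, 1.1, 0.5)))
            )

    def test_joint_rate_scaling_leaves_kobs_unchanged(self):
        # only k_his_off and the ratio k_his_on/k_co_on are identifiable
        scaled = RateConstants(k_his_on=6000.0, k_his_off=1.2, k_co_on=2e8)
        for c in (1e-6, 1e-5, 1e-4):
            assert kobs_hexacoordinate(scaled, c) == pytest.approx(
                kobs_hexacoordinate(self.rates, c), rel=1e-12
            )

    def test_amplitude_fractions_must_sum_to_one(self):
        with pytest.raises(DomainError):
            ObservedBinding(points=((1e-4, 1.0, 0.6), (1e-4, 0.5, 0.6)))


class TestHillAffinity:
    def titration(self, c50, concs, factor=1.0):
        return [
            TitrationPoint(co_conc=c * factor, bound_fraction=c / (c + c50))
            for c in concs
        ]

    def test_exact_single_site_recovery(self):
        c50 = 2.06e-5
        concs = np.logspace(-6, -3.5, 8)
        res = fit_hill_affinity(self.titration(c50, concs))
        assert res.c50 == pytest.approx(c50, rel=1e-6)
        assert res.hill_slope == pytest.approx(1.0, abs=1e-6)

    def test_half_saturation_maps_to_zero_log_odds(self):
        p = TitrationPoint(co_conc=2.06e-5, bound_fraction=0.5)
        assert np.log10(p.bound_fraction / (1 - p.bound_fraction)) == 0.0

    def test_scale_equivariance(self):
        concs = np.logspace(-6, -4, 6)
        res1 = fit_hill_affinity(self.titration(2e-5, concs))
        res10 = fit_hill_affinity(
            [
                TitrationPoint(co_conc=p.co_conc * 10.0, bound_fraction=p.bound_fraction)
                for p in self.titration(2e-5, concs)
            ]
        )
        assert res10.c50 == pytest.approx(10.0 * res1.c50, rel=1e-9)
        assert res10.hill_slope == pytest.approx(res1.hill_slope, rel=1e-9)

    def test_saturated_point_rejected_by_name(self):
        pts = self.titration(2e-5, np.logspace(-6, -4, 4))
        pts[2] = TitrationPoint(co_conc=pts[2].co_conc, bound_fraction=1.0)
        with pytest.raises(DomainError, match="point 2"):
            fit_hill_affinity(pts)

    def test_needs_three_points(self):
        with pytest.raises(DomainError):
            fit_hill_affinity(self.titration(2e-5, [1e-5, 2e-5]))
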