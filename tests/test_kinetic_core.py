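"""Unit and property tests for the gated reaction network."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm

from ngbkin.exceptions import DomainError, UnsupportedConfigurationError
from ngbkin.fitting import fit_multiexponential
from ngbkin.kinetic_core import (
    PopulationMixture,
    RateConstants,
    SpeciesState,
    c50_overall,
    closed_form_two_state,
    equilibrium_bound_fraction,
    kobs_hexacoordinate,
    rate_matrix,
    rhs,
    simulate_progress_curve,
)

rate_values = st.floats(min_value=0.0, max_value=1e8, allow_nan=False)


def random_two_state_rates(rng):
    """Random rate set in the two-state (deoxy/hexa + irreversible capture) limit."""
    return RateConstants(
        k_his_on=10.0 ** rng.uniform(0, 4),
        k_his_off=10.0 ** rng.uniform(-2, 2),
        k_co_on=10.0 ** rng.uniform(5, 8),
    )


class TestRates:
    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            RateConstants(k_his_on=-1.0)

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(DomainError):
            RateConstants(k_co_on=float("nan"))

    def test_state_fractions_must_sum_to_one(self):
        with pytest.raises(DomainError):
            SpeciesState(deoxy=0.5, hexa=0.6)

    def test_mixture_fraction_sum(self):
        r = RateConstants()
        with pytest.raises(DomainError):
            PopulationMixture(components=((0.5, r), (0.4, r)))


class TestRhs:
    def test_all_rates_zero_gives_zero_derivative(self):
        state = SpeciesState(deoxy=0.2, hexa=0.3, co=0.1, pair=0.25, trap=0.15)
        assert np.allclose(rhs(state, RateConstants(), 1e-3), 0.0)

    def test_his_step_detailed_balance_is_stationary(self):
        # k_his_on * deoxy == k_his_off * hexa, no CO flux -> equilibrium
        rates = RateConstants(k_his_on=100.0, k_his_off=25.0)
        state = SpeciesState(deoxy=0.2, hexa=0.8)
        assert np.allclose(rhs(state, rates, 0.0), 0.0, atol=1e-12)

    @given(
        st.tuples(*(st.floats(0.01, 1.0) for _ in range(5))),
        st.tuples(*(st.floats(0.0, 1e6) for _ in range(8))),
        st.floats(0.0, 1e-2),
    )
    def test_mass_conservation(self, raw_state, raw_rates, co_conc):
        fractions = np.array(raw_state) / sum(raw_state)
        state = SpeciesState.from_array(fractions / fractions.sum())
        rates = RateConstants(*raw_rates)
        deriv = rhs(state, rates, co_conc)
        assert abs(deriv.sum()) < 1e-12 * max(1.0, np.abs(deriv).max())

    def test_rate_matrix_columns_sum_to_zero(self):
        rates = RateConstants(3e3, 0.5, 5e7, 0.02, 3.5e6, 2.6e7, 1e6, 1e5)
        A = rate_matrix(rates, 2e-4)
        assert np.allclose(A.sum(axis=0), 0.0, atol=1e-9)

    def test_derivative_matches_finite_difference_of_exact_trajectory(self):
        """rhs agrees with a centered finite difference of an independently
        built matrix-exponential trajectory of the same network."""
        rates = RateConstants(3e3, 0.5, 5e7, 0.0, 3.5e6, 2.6e7, 0.0, 0.0)
        co = 2e-4
        kon_c = rates.k_co_on * co
        # hand-written generator, term by term (independent of rate_matrix)
        A = np.zeros((5, 5))
        A[0, 0] = -(rates.k_his_on + kon_c)
        A[1, 0] = rates.k_his_on
        A[2, 0] = kon_c
        A[0, 1] = rates.k_his_off
        A[1, 1] = -rates.k_his_off
        A[0, 2] = rates.k_co_off
        A[2, 2] = -rates.k_co_off
        A[2, 3] = rates.k_gem_rebind
        A[0, 3] = rates.k_out
        A[3, 3] = -(rates.k_gem_rebind + rates.k_out)
        y0 = SpeciesState(pair=1.0).as_array()
        for t in (1e-8, 1e-6, 1e-4):
            h = t * 1e-4
            y_mid = expm(A * t) @ y0
            fd = (expm(A * (t + h)) @ y0 - expm(A * (t - h)) @ y0) / (2 * h)
            deriv = rhs(SpeciesState.from_array(np.clip(y_mid, 0, 1)), rates, co)
            assert np.allclose(deriv, fd, rtol=1e-6, atol=1e-6 * np.abs(fd).max())


class TestClosedFormTwoState:
    def test_no_his_gives_single_exponential(self):
        rates = RateConstants(k_his_on=0.0, k_his_off=0.0, k_co_on=1e6)
        t = np.linspace(0.0, 1e-3, 50)
        curve = closed_form_two_state(rates, 1e-3, t, SpeciesState(deoxy=1.0))
        assert np.allclose(curve.values, np.exp(-1e6 * 1e-3 * t), rtol=1e-12)

    def test_starts_at_unliganded_fraction(self):
        rates = RateConstants(k_his_on=500.0, k_his_off=0.5, k_co_on=5e7)
        t = np.r_[0.0, np.logspace(-6, 0, 20)]
        curve = closed_form_two_state(rates, 1e-4, t, SpeciesState(deoxy=0.3, hexa=0.7))
        assert curve.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_rejects_off_rate_and_pair_occupancy(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(UnsupportedConfigurationError):
            closed_form_two_state(
                RateConstants(k_co_on=1e6, k_co_off=0.1), 1e-4, t, SpeciesState(deoxy=1.0)
            )
        with pytest.raises(UnsupportedConfigurationError):
            closed_form_two_state(
                RateConstants(k_co_on=1e6), 1e-4, t, SpeciesState(deoxy=0.5, pair=0.5)
            )

    def test_matches_numeric_integration_on_random_rate_sets(self, rng):
        """Analytic eigen-solution vs stiff ODE integration, 50 random rate
        sets over six decades of time, agreement to 1e-8."""
        for _ in range(50):
            rates = random_two_state_rates(rng)
            co = 10.0 ** rng.uniform(-6, -3)
            t = np.logspace(-4, 2, 60) / (rates.k_co_on * co)
            t = t[t < 1e6]
            init = SpeciesState(deoxy=0.4, hexa=0.6)
            exact = closed_form_two_state(rates, co, t, init)
            # integrate tighter than the 1e-8 agreement being certified
            numeric = simulate_progress_curve(
                PopulationMixture.single(rates), co, t, init, rtol=1e-10, atol=1e-13
            )
            assert np.abs(exact.values - numeric.values).max() < 1e-8


class TestSimulate:
    def test_mixture_of_identical_halves_equals_single(self):
        rates = RateConstants(500.0, 0.13, 5e7, 0.04, 3.5e6, 2.6e7)
        t = np.logspace(-9, 0, 100)
        init = SpeciesState(pair=1.0)
        one = simulate_progress_curve(PopulationMixture.single(rates), 2e-4, t, init)
        two = simulate_progress_curve(
            PopulationMixture(components=((0.5, rates), (0.5, rates))), 2e-4, t, init
        )
        assert np.allclose(one.values, two.values, atol=1e-12)

    def test_noiseless_output_non_increasing_without_off_rate(self):
        rates = RateConstants(500.0, 0.13, 5e7, 0.0, 3.5e6, 2.6e7)
        t = np.logspace(-9, 1, 150)
        curve = simulate_progress_curve(
            PopulationMixture.single(rates), 2e-4, t, SpeciesState(pair=1.0)
        )
        assert np.all(np.diff(curve.values) <= 1e-9)

    def test_trap_adds_third_geminate_region_exponential(self):
        """With bimolecular capture and His binding switched off, enabling
        the docking site adds a resolvable third exponential (geminate,
        trap return, constant) to the early-time curve."""
        base = RateConstants(k_co_on=1e6, k_gem_rebind=8.6e6, k_out=4.5e7)
        with_trap = base.replace(k_trap_in=1.5e7, k_trap_out=1.0 / 7e-6)
        t = np.logspace(-9, -4, 300)
        init = SpeciesState(pair=1.0)
        for rates, expected in ((base, 1), (with_trap, 2)):
            curve = simulate_progress_curve(PopulationMixture.single(rates), 0.0, t, init)
            dec = fit_multiexponential(curve, max_components=3)
            assert len(dec.components) == expected


class TestKobs:
    def test_zero_co_gives_zero(self):
        rates = RateConstants(k_his_on=500.0, k_his_off=0.5, k_co_on=5e7)
        assert kobs_hexacoordinate(rates, 0.0) == 0.0

    def test_high_co_limit_approaches_his_off_rate(self):
        rates = RateConstants(k_his_on=500.0, k_his_off=0.5, k_co_on=5e7)
        co = 1e6 * rates.k_his_on / rates.k_co_on
        assert kobs_hexacoordinate(rates, co) / rates.k_his_off > 0.999

    @given(
        st.floats(1.0, 1e5),
        st.floats(1e-3, 1e3),
        st.floats(1e5, 1e9),
        st.lists(st.floats(1e-8, 1e-2), min_size=2, max_size=8),
    )
    def test_monotone_and_bounded(self, kh, kmh, kon, concs):
        rates = RateConstants(k_his_on=kh, k_his_off=kmh, k_co_on=kon)
        values = [kobs_hexacoordinate(rates, c) for c in sorted(concs)]
        assert all(0.0 <= v <= kmh for v in values)
        assert all(b >= a - 1e-15 for a, b in zip(values, values[1:]))

    def test_steady_state_form_is_smaller(self):
        rates = RateConstants(k_his_on=500.0, k_his_off=50.0, k_co_on=5e7)
        c = 1e-5
        assert kobs_hexacoordinate(rates, c, form="steady_state") < kobs_hexacoordinate(
            rates, c, form="pre_equilibrium"
        )

    def test_matches_slowest_rate_of_simulated_relaxation(self):
        """Mid-range k_obs agrees within 5% with a single-exponential fit of
        the simulated approach to saturation from the hexacoordinate state."""
        rates = RateConstants(k_his_on=500.0, k_his_off=0.5, k_co_on=5e7)
        co = 1e-5  # k_co_on*co = k_his_on: mid-range
        expected = kobs_hexacoordinate(rates, co)
        t = np.logspace(-5, 1.5, 200) / expected * expected  # span past 5 lifetimes
        t = np.logspace(np.log10(1e-3 / expected), np.log10(8.0 / expected), 200)
        kh_eq = rates.his_equilibrium
        init = SpeciesState(deoxy=1 / (1 + kh_eq), hexa=kh_eq / (1 + kh_eq))
        curve = simulate_progress_curve(PopulationMixture.single(rates), co, t, init)
        dec = fit_multiexponential(curve, max_components=1)
        assert dec.rates[0] == pytest.approx(expected, rel=0.05)


class TestC50:
    def test_no_his_competition(self):
        rates = RateConstants(k_co_on=5e7, k_co_off=0.05)
        assert c50_overall(rates) == pytest.approx(1e-9, rel=1e-12)

    def test_his_binding_weakens_affinity(self):
        base = dict(k_his_off=0.5, k_co_on=5e7, k_co_off=0.05)
        c1 = c50_overall(RateConstants(k_his_on=500.0, **base))
        c2 = c50_overall(RateConstants(k_his_on=1000.0, **base))
        assert c2 > c1

    def test_zero_off_rate_is_infinite_affinity_error(self):
        with pytest.raises(DomainError):
            c50_overall(RateConstants(k_his_on=500.0, k_his_off=0.5, k_co_on=5e7))

    def test_agrees_with_detailed_balance_equilibrium(self, rng):
        """c50 formula vs the independently derived equilibrium isotherm:
        bound fraction at [CO] = c50 equals 1/2 (20 random rate sets)."""
        for _ in range(20):
            rates = RateConstants(
                k_his_on=10.0 ** rng.uniform(0, 4),
                k_his_off=10.0 ** rng.uniform(-2, 2),
                k_co_on=10.0 ** rng.uniform(5, 8),
                k_co_off=10.0 ** rng.uniform(-3, 0),
            )
            c50 = c50_overall(rates)
            assert equilibrium_bound_fraction(rates, c50) == pytest.approx(0.5, abs=1e-12)

    def test_agrees_with_equilibrium_simulation_by_bisection(self, rng):
        """The [CO] at which the long-time simulated N settles at 1/2,
        found by bisection, matches c50_overall to 0.1%."""
        for _ in range(2):
            rates = RateConstants(
                k_his_on=10.0 ** rng.uniform(1, 3),
                k_his_off=10.0 ** rng.uniform(-1, 1),
                k_co_on=10.0 ** rng.uniform(6, 8),
                k_co_off=10.0 ** rng.uniform(-2, 0),
            )
            expected = c50_overall(rates)

            def n_inf(co):
                slow = max(
                    kobs_hexacoordinate(rates, co), rates.k_co_off * 1e-2
                )
                t = np.logspace(-6, np.log10(50.0 / slow), 80)
                kh_eq = rates.his_equilibrium
                init = SpeciesState(deoxy=1 / (1 + kh_eq), hexa=kh_eq / (1 + kh_eq))
                return simulate_progress_curve(
                    PopulationMixture.single(rates), co, t, init
                ).values[-1]

            lo, hi = expected * 0.2, expected * 5.0
            for _ in range(14):
                mid = np.sqrt(lo * hi)
                if n_inf(mid) > 0.5:  # less than half bound: need more CO
                    lo = mid
                else:
                    hi = mid
            assert np.sqrt(lo * hi) == pytest.approx(expected, rel=1e-3)
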