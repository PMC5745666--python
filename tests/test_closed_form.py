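import math
from dataclasses import FrozenInstanceError

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from gsacc.closed_form import (
    DesignSpec,
    adjust_for_marker_coverage,
    daetwyler_basic,
    daetwyler_corrected,
    first_order,
    goddard_comparator,
    second_order_from_variances,
    second_order_uniform,
    second_order_ushape,
    single_variance_first_order,
)
from gsacc.freq_models import FreqDistribution, expected_inv_variance, expected_variance_uniform, sample_freqs

# Published grid at N=5000, M=500: (fmin, h2) -> printed cells.
# Uniform-frequency grid columns: eq2, eq3, eq5, eq7.
TABLE2 = {
    (0.05, 0.1): (0.500, 0.513, 0.526, 0.513),
    (0.05, 0.3): (0.750, 0.798, 0.811, 0.798),
    (0.05, 0.5): (0.833, 0.901, 0.909, 0.902),
    (0.05, 0.7): (0.875, 0.955, 0.959, 0.955),
    (0.025, 0.1): (0.500, 0.513, 0.526, 0.513),
    (0.025, 0.3): (0.750, 0.798, 0.811, 0.798),
    (0.025, 0.5): (0.833, 0.901, 0.909, 0.902),
    (0.025, 0.7): (0.875, 0.955, 0.959, 0.955),
}
# U-shape grid columns: eq8, goddard (the eq3 column repeats TABLE2's).
TABLE3 = {
    (0.05, 0.1): (0.513, 0.491),
    (0.05, 0.3): (0.798, 0.759),
    (0.05, 0.5): (0.902, 0.867),
    (0.05, 0.7): (0.955, 0.930),
    (0.025, 0.1): (0.513, 0.537),
    (0.025, 0.3): (0.798, 0.791),
    (0.025, 0.5): (0.901, 0.886),
    (0.025, 0.7): (0.955, 0.941),
}
# MC "true" column of the uniform grid (used for ordering checks here).
TABLE2_TRUE = {
    (0.05, 0.1): 0.514, (0.05, 0.3): 0.798, (0.05, 0.5): 0.901, (0.05, 0.7): 0.955,
    (0.025, 0.1): 0.513, (0.025, 0.3): 0.797, (0.025, 0.5): 0.901, (0.025, 0.7): 0.955,
}
TABLE3_TRUE = {
    (0.05, 0.1): 0.513, (0.05, 0.3): 0.798, (0.05, 0.5): 0.901, (0.05, 0.7): 0.955,
    (0.025, 0.1): 0.513, (0.025, 0.3): 0.798, (0.025, 0.5): 0.901, (0.025, 0.7): 0.955,
}
# half a printed ULP plus slack for the source's own rounding (one published
# goddard cell sits 2e-5 past the 3-decimal rounding boundary)
TOL3 = 6e-4

N0, M0 = 5000, 500


def design(h2: float) -> DesignSpec:
    return DesignSpec(N=N0, M=M0, h2=h2)


class TestDesignSpec:
    def test_lambda_exact(self):
        assert design(0.3).lam == pytest.approx((1 - 0.3) / 0.3, abs=0)
        assert design(1.0).lam == 0.0

    @pytest.mark.parametrize("kwargs", [
        dict(N=0, M=500, h2=0.3),
        dict(N=5000, M=0, h2=0.3),
        dict(N=5000, M=500, h2=0.0),
        dict(N=5000, M=500, h2=1.2),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)

    def test_frozen(self):
        with pytest.raises(FrozenInstanceError):
            design(0.3).h2 = 0.5


class TestPublishedCells:
    @pytest.mark.parametrize("key,cells", TABLE2.items())
    def test_uniform_grid(self, key, cells):
        fmin, h2 = key
        d = design(h2)
        assert daetwyler_basic(d).value == pytest.approx(cells[0], abs=TOL3)
        assert daetwyler_corrected(d).value == pytest.approx(cells[1], abs=TOL3)
        assert first_order(d).value == pytest.approx(cells[2], abs=TOL3)
        assert second_order_uniform(d, fmin).value == pytest.approx(cells[3], abs=TOL3)

    @pytest.mark.parametrize("key,cells", TABLE3.items())
    def test_ushape_grid(self, key, cells):
        fmin, h2 = key
        d = design(h2)
        assert second_order_ushape(d).value == pytest.approx(cells[0], abs=TOL3)
        assert goddard_comparator(d, fmin).value == pytest.approx(cells[1], abs=TOL3)

    @pytest.mark.parametrize("key", TABLE2)
    def test_eq3_eq7_agree_to_three_decimals(self, key):
        fmin, h2 = key
        e3 = daetwyler_corrected(design(h2)).value
        e7 = second_order_uniform(design(h2), fmin).value
        assert abs(e3 - e7) < 1.1e-3

    @pytest.mark.parametrize("h2", [0.1, 0.3, 0.5, 0.7])
    def test_goddard_underestimates_at_fmin_005(self, h2):
        assert goddard_comparator(design(h2), 0.05).value < TABLE2_TRUE[(0.05, h2)]


class TestLimits:
    def test_eq2_large_N(self):
        assert daetwyler_basic(DesignSpec(10**13, 500, 0.3)).value == pytest.approx(1.0, abs=1e-9)

    def test_eq3_h2_one(self):
        # (M + N - (N - M)) / (2 M) = 1 for N > M
        assert daetwyler_corrected(DesignSpec(5000, 500, 1.0)).value == pytest.approx(1.0, abs=1e-12)

    def test_eq5_h2_one_exact(self):
        assert first_order(DesignSpec(5000, 500, 1.0)).value == 1.0

    @pytest.mark.parametrize("fn", [second_order_ushape,
                                    lambda d: second_order_uniform(d, 0.05),
                                    lambda d: goddard_comparator(d, 0.05),
                                    lambda d: single_variance_first_order(d, 0.05)])
    def test_second_orders_h2_one(self, fn):
        assert fn(DesignSpec(5000, 500, 1.0)).value == 1.0

    def test_eq8_tends_to_eq5(self):
        d = DesignSpec(10**8, 500, 0.3)
        assert abs(second_order_ushape(d).value - first_order(d).value) < 1e-6


class TestSecondOrderFromVariances:
    def test_all_half_variances(self):
        d = design(0.3)
        est = second_order_from_variances(d, np.full(M0, 0.5))
        assert est.value == pytest.approx(0.7983732454148815, abs=1e-12)
        # with sigma^2 = 0.5 everywhere the mean inverse variance is exactly 2,
        # which coincides with the ushape approximation's correction factor
        assert est.value == pytest.approx(second_order_ushape(d).value, abs=1e-12)

    def test_substitution_identity_with_uniform_moment(self):
        # constant sigma chosen so (1/M) sum 1/sigma^2 equals the uniform moment
        fmin = 0.05
        e_inv = expected_inv_variance(FreqDistribution("uniform", fmin))
        sig = np.full(M0, 1.0 / e_inv)
        d = design(0.3)
        assert second_order_from_variances(d, sig).value == pytest.approx(
            second_order_uniform(d, fmin).value, abs=1e-12
        )

    def test_law_of_large_numbers(self):
        fmin = 0.05
        f = sample_freqs(FreqDistribution("uniform", fmin), 200_000, seed=13)
        sig = 2 * f * (1 - f)
        d = DesignSpec(N0, f.size, 0.3)
        inv = 1.0 / sig
        se_mean_inv = inv.std(ddof=1) / np.sqrt(f.size)
        # both formulas share the same leading term; the difference is driven
        # by the sampled mean inverse variance, so propagate its MC error
        lam = d.lam
        sens = lam * d.N * d.M / (d.N + d.M * lam) ** 3
        got = second_order_from_variances(d, sig).value
        want = second_order_uniform(d, fmin).value
        assert abs(got - want) < 3 * sens * se_mean_inv + 1e-12

    def test_lambda_zero(self):
        assert second_order_from_variances(DesignSpec(100, 10, 1.0), np.full(10, 0.4)).value == 1.0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6])
    def test_invalid_variances(self, bad):
        sig = np.full(M0, 0.4)
        sig[3] = bad
        with pytest.raises(ValueError):
            second_order_from_variances(design(0.3), sig)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            second_order_from_variances(design(0.3), np.full(10, 0.4))


class TestSingleVarianceFirstOrder:
    def test_matches_quadrature_of_first_order_trace(self):
        # independent evaluation of 1 - lam M E_f[sigma^2/(N sigma^2 + lam_b)]
        for h2 in (0.3, 0.5):
            d = design(h2)
            fmin = 0.05
            lam_b = d.M * expected_variance_uniform(fmin) * d.lam
            val, _ = integrate.quad(
                lambda f: (2 * f * (1 - f)) / (d.N * 2 * f * (1 - f) + lam_b) / (1 - 2 * fmin),
                fmin, 1 - fmin, epsabs=1e-13,
            )
            assert single_variance_first_order(d, fmin).value == pytest.approx(
                1 - d.lam * d.M * val, abs=1e-10
            )

    def test_finite_and_in_unit_interval(self):
        v = single_variance_first_order(design(0.5), 0.05).value
        assert 0.0 < v <= 1.0

    def test_log_argument_stays_positive(self):
        # sqrt(1 + 2 lam_b/N) >= 1 keeps the log argument positive even for
        # extreme designs; the value itself may leave [0, 1] there
        v = single_variance_first_order(DesignSpec(2, 100000, 0.01), 0.3).value
        assert np.isfinite(v)


class TestMarkerCoverage:
    def test_identity_at_b_one(self):
        d = design(0.3)
        assert adjust_for_marker_coverage(d, 1.0, first_order).value == pytest.approx(
            first_order(d).value, abs=1e-15
        )

    def test_zero_coverage(self):
        assert adjust_for_marker_coverage(design(0.3), 0.0, first_order).value == 0.0

    def test_plug_in_value(self):
        got = adjust_for_marker_coverage(design(0.3), 0.8, first_order).value
        assert got == pytest.approx(0.6075949367088608, abs=1e-12)

    def test_works_with_kwargs_methods(self):
        got = adjust_for_marker_coverage(design(0.3), 0.9, second_order_uniform, f_min=0.05)
        assert 0.0 < got.value < 1.0

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            adjust_for_marker_coverage(design(0.3), 1.5, first_order)


GRID = [
    DesignSpec(N, M, h2)
    for N in (1000, 2000, 5000, 10000)
    for M in (500, 1000)
    for h2 in (0.1, 0.3, 0.5, 0.7)
]


class TestOrderingAndMonotonicity:
    @pytest.mark.parametrize("d", GRID)
    def test_eq2_below_eq5(self, d):
        assert daetwyler_basic(d).value <= first_order(d).value + 1e-15

    @pytest.mark.parametrize("d", GRID)
    def test_eq7_below_eq5(self, d):
        assert second_order_uniform(d, 0.05).value <= first_order(d).value

    @pytest.mark.parametrize("d", GRID)
    def test_all_methods_in_unit_interval(self, d):
        for v in (
            daetwyler_basic(d).value,
            daetwyler_corrected(d).value,
            first_order(d).value,
            second_order_uniform(d, 0.05).value,
            second_order_ushape(d).value,
            goddard_comparator(d, 0.05).value,
            single_variance_first_order(d, 0.05).value,
        ):
            assert 0.0 <= v <= 1.0

    @pytest.mark.parametrize("fn", [
        daetwyler_basic, daetwyler_corrected, first_order,
        lambda d: second_order_uniform(d, 0.05), second_order_ushape,
        lambda d: goddard_comparator(d, 0.05),
    ])
    def test_monotone_in_N_and_h2_antitone_in_M(self, fn):
        for M in (500, 1000):
            for h2 in (0.1, 0.3, 0.5, 0.7):
                vals = [fn(DesignSpec(N, M, h2)).value for N in range(1000, 10001, 1000)]
                assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        for N in (1000, 5000, 10000):
            for M in (500, 1000):
                vals = [fn(DesignSpec(N, M, h2)).value for h2 in (0.1, 0.3, 0.5, 0.7)]
                assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
            for h2 in (0.1, 0.4, 0.7):
                assert fn(DesignSpec(N, 1000, h2)).value <= fn(DesignSpec(N, 500, h2)).value + 1e-12


@settings(max_examples=100, deadline=None)
@given(
    N=st.integers(1000, 10000),
    M=st.sampled_from([500, 1000]),
    h2=st.floats(0.1, 0.7),
    fmin=st.floats(0.025, 0.10),
)
def test_property_unit_interval_on_paper_grid(N, M, h2, fmin):
    d = DesignSpec(N, M, h2)
    for v in (
        daetwyler_basic(d).value,
        daetwyler_corrected(d).value,
        first_order(d).value,
        second_order_uniform(d, fmin).value,
        second_order_ushape(d).value,
        goddard_comparator(d, fmin).value,
    ):
        assert 0.0 <= v <= 1.0


@settings(max_examples=60, deadline=None)
@given(N=st.integers(1000, 10000), M=st.sampled_from([500, 1000]), h2=st.floats(0.1, 0.99))
def test_property_eq3_is_the_root_in_unit_interval(N, M, h2):
    d = DesignSpec(N, M, h2)
    a = M + N * h2
    disc = math.sqrt(a * a - 4 * N * M * h2 * h2)
    minus = (a - disc) / (2 * M * h2)
    plus = (a + disc) / (2 * M * h2)
    assert daetwyler_corrected(d).value == pytest.approx(minus, rel=1e-12)
    assert plus > 1.0
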