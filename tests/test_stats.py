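"""Regression, Fisher and effect-size layer against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oracle_helpers import fisher_two_sided_rational, ols_normal_equations
from ctkit.stats import (
    fisher_exact,
    fold_change,
    linear_regression,
    percent_change,
    percent_reduction,
    size_regression,
)


def test_perfect_linear_fit():
    x = np.arange(5.0)
    fit = linear_regression(x, 2 * x + 1)
    assert fit.m == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_constant_y_is_degenerate_flat_fit():
    fit = linear_regression([1, 2, 3, 4], [5, 5, 5, 5])
    assert fit.m == 0.0 and fit.r_squared == 0.0 and fit.p_value == 1.0
    assert fit.degenerate


def test_constant_x_and_short_input_rejected():
    with pytest.raises(ValueError):
        linear_regression([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        linear_regression([1, 2], [1, 2])


def test_regression_matches_normal_equations_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(5, 30))
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        fit = linear_regression(x, y)
        m, b, r2, p = ols_normal_equations(x, y)
        assert fit.m == pytest.approx(m, abs=1e-10)
        assert fit.intercept == pytest.approx(b, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-10)


def test_fisher_balanced_table_gives_p_one():
    assert fisher_exact([[5, 5], [5, 5]]) == 1.0


def test_fisher_extreme_table_exact_value():
    # p = 2 / C(20, 10): only the two perfectly-separated tables qualify
    from math import comb

    assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / comb(20, 10), rel=1e-12)


def test_fisher_empty_margin_returns_one():
    assert fisher_exact([[0, 0], [3, 4]]) == 1.0


def test_fisher_matches_rational_enumeration_oracle(rng):
    for _ in range(100):
        a, b, c, d = (int(v) for v in rng.integers(0, 50, size=4))
        p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided_rational(a, b, c, d), abs=1e-12)


def test_fisher_agrees_with_scipy_convention(rng):
    for _ in range(50):
        a, b, c, d = (int(v) for v in rng.integers(0, 40, size=4))
        ours = fisher_exact([[a, b], [c, d]])
        _, theirs = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
def test_fisher_invariant_under_transposition_and_swaps(a, b, c, d):
    p = fisher_exact([[a, b], [c, d]])
    assert fisher_exact([[a, c], [b, d]]) == pytest.approx(p, abs=1e-12)  # transpose
    assert fisher_exact([[c, d], [a, b]]) == pytest.approx(p, abs=1e-12)  # row swap
    assert fisher_exact([[b, a], [d, c]]) == pytest.approx(p, abs=1e-12)  # column swap


def test_percent_reduction_worked_example():
    # 16.7% -> 10.9% total translocation frequency is a 35% reduction
    assert percent_reduction(16.7, 10.9) == 35
    assert percent_reduction(16.7, 10.9, round_whole=False) == pytest.approx(34.73, abs=0.01)


@pytest.mark.parametrize("control,treated,expected", [(10, 5, 50), (8, 8, 0), (10, 0, 100)])
def test_percent_reduction_arithmetic(control, treated, expected):
    assert percent_reduction(control, treated) == expected


def test_percent_reduction_zero_control_rejected():
    with pytest.raises(ValueError):
        percent_reduction(0.0, 1.0)


def test_fold_and_percent_change():
    assert fold_change(10.0, 12.0) == pytest.approx(1.2)
    assert percent_change(10.0, 12.0) == pytest.approx(20.0)
    assert percent_change(10.0, 8.0) == pytest.approx(-20.0)


def test_size_regression_recovers_length_effect(rng):
    lengths = {"X": 22.4, "2": 44.2, "3": 52.5}
    pairs = [("X", "2"), ("X", "3"), ("2", "3")]
    a = 1e-3  # frequency per Mb
    points = []
    for rep in range(5):
        for p in pairs:
            x = lengths[p[0]] + lengths[p[1]]
            points.append((p, a * x + rng.normal(0, 0.005)))
    fit = size_regression(points, lengths)
    assert abs(fit.m - a) < 3 * fit.stderr


def test_size_regression_missing_length_errors():
    with pytest.raises(KeyError):
        size_regression([(("X", "4"), 0.1)] * 3, {"X": 22.4})
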