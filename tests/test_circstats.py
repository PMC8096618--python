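"""Circular statistics: estimators, tests, von Mises utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from vectornav.circstats import (
    CircularSample,
    chisq_independence,
    concentration_homogeneity,
    mardia_classification_f,
    mean_ci95,
    mean_vector,
    rayleigh_test,
    vonmises_A,
    vonmises_kappa,
    watson_u2,
    watson_u2_statistic,
)


def test_mean_vector_symmetry_and_uniform():
    alpha, r = mean_vector(CircularSample([0.0, 90.0]))
    assert alpha == pytest.approx(45.0)
    assert r == pytest.approx(np.cos(np.radians(45.0)))
    alpha, r = mean_vector(CircularSample([0.0, 90.0, 180.0, 270.0]))
    assert alpha is None and r == 0.0


def test_mean_vector_parameter_recovery():
    """n=1000 von Mises draws at mu=114, kappa=A^-1(0.61) recover the
    generator parameters."""
    rng = np.random.default_rng(2005)
    draws = np.degrees(rng.vonmises(np.radians(114.0), vonmises_kappa(0.61), 1000))
    alpha, r = mean_vector(CircularSample(draws))
    assert abs((alpha - 114.0 + 180.0) % 360.0 - 180.0) < 3.0
    assert r == pytest.approx(0.61, abs=0.04)


@settings(derandomize=True, max_examples=40)
@given(delta=st.floats(0.0, 360.0))
def test_mean_vector_rotation_equivariance(delta):
    base = np.array([10.0, 40.0, 355.0, 80.0, 120.0, 33.0])
    a0, r0 = mean_vector(CircularSample(base))
    a1, r1 = mean_vector(CircularSample(base + delta))
    assert r1 == pytest.approx(r0, abs=1e-12)
    assert abs((a1 - a0 - delta + 180.0) % 360.0 - 180.0) < 1e-6


def test_rayleigh_printed_group_values():
    assert rayleigh_test(16, 0.61).p_value < 0.002
    assert round(rayleigh_test(45, 0.32).p_value, 2) == 0.01
    assert rayleigh_test(20, 0.0).p_value == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        rayleigh_test(3, 0.9)


def test_ci95_tight_for_high_concentration():
    rng = np.random.default_rng(3)
    draws = np.degrees(rng.vonmises(np.radians(200.0), 200.0, 16))
    s = CircularSample(draws)
    lo, hi = mean_ci95(s)
    alpha, _ = mean_vector(s)
    half = (hi - alpha) % 360.0
    assert half < 5.0
    assert abs((alpha - 200.0 + 180.0) % 360.0 - 180.0) < half


def test_ci95_undefined_for_dispersed_sample():
    with pytest.raises(ValueError, match="CI undefined"):
        mean_ci95(CircularSample(np.arange(0.0, 360.0, 24.0)))


def test_watson_u2_identical_samples_near_minimum():
    a = CircularSample([0, 35, 80, 120, 160, 200, 260, 300])
    res = watson_u2(a, CircularSample(a.bearings.copy()))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.5


def test_watson_u2_separated_samples_significant():
    rng = np.random.default_rng(11)
    a = CircularSample(np.degrees(rng.vonmises(0.0, 2.0, 20)))
    b = CircularSample(np.degrees(rng.vonmises(np.pi, 2.0, 20)))
    res = watson_u2(a, b, n_perm=2000, rng=0)
    assert res.p_value < 0.01
    assert res.extra["p_permutation"] < 0.01


def test_watson_u2_midranks_handle_five_degree_ties():
    """5-degree-granular data produce heavy ties; the statistic stays
    finite, symmetric, and zero for identical pooled samples."""
    a = np.array([0.0, 5.0, 5.0, 10.0, 15.0, 15.0, 20.0, 25.0])
    b = np.array([5.0, 5.0, 10.0, 10.0, 20.0, 25.0, 25.0, 30.0])
    u_ab = watson_u2_statistic(a, b)
    u_ba = watson_u2_statistic(b, a)
    assert u_ab == pytest.approx(u_ba, abs=1e-12)
    assert watson_u2_statistic(a, a) == pytest.approx(0.0, abs=1e-12)


def test_mardia_f_zero_for_identical_samples():
    a = CircularSample([10, 30, 50, 55, 70, 90, 110, 140])
    res = mardia_classification_f(a, CircularSample(a.bearings.copy()))
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value > 0.99
    assert res.df == (1, 14)


def test_two_sample_tests_symmetric_under_swap():
    rng = np.random.default_rng(5)
    a = CircularSample(np.degrees(rng.vonmises(0.3, 2.0, 15)))
    b = CircularSample(np.degrees(rng.vonmises(1.0, 3.0, 18)))
    f_ab = mardia_classification_f(a, b)
    f_ba = mardia_classification_f(b, a)
    assert f_ab.statistic == pytest.approx(f_ba.statistic, rel=1e-12)
    # concentrated samples land in the variance-ratio regime: the F
    # statistic inverts under swap while the two-sided p is unchanged
    t_ab = concentration_homogeneity(a, b)
    t_ba = concentration_homogeneity(b, a)
    assert t_ab.statistic == pytest.approx(1.0 / t_ba.statistic, rel=1e-9)
    assert t_ab.p_value == pytest.approx(t_ba.p_value, rel=1e-9)
    # dispersed samples use the arcsine transform: sign flips under swap
    c = CircularSample(np.degrees(rng.vonmises(0.0, 0.7, 15)))
    d = CircularSample(np.degrees(rng.vonmises(0.0, 0.5, 18)))
    t_cd = concentration_homogeneity(c, d)
    t_dc = concentration_homogeneity(d, c)
    assert "arcsin" in t_cd.extra["regime"]
    assert t_cd.statistic == pytest.approx(-t_dc.statistic, rel=1e-9)
    assert t_cd.p_value == pytest.approx(t_dc.p_value, rel=1e-9)


def test_concentration_homogeneity_zero_for_identical_dispersed_samples():
    # dispersed sample -> pooled rbar < 0.45 -> arcsine regime, statistic 0
    a = CircularSample([0, 70, 140, 200, 260, 330, 30, 100, 170, 240, 310, 15])
    res = concentration_homogeneity(a, CircularSample(a.bearings.copy()))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)
    assert "arcsin" in res.extra["regime"]


def test_concentration_homogeneity_detects_kappa_difference():
    rng = np.random.default_rng(9)
    a = CircularSample(np.degrees(rng.vonmises(0.0, 1.0, 30)))
    b = CircularSample(np.degrees(rng.vonmises(0.0, 8.0, 30)))
    assert concentration_homogeneity(a, b).p_value < 0.05


def test_chisq_hand_computed_2x2():
    res = chisq_independence([[10, 40], [40, 10]])
    assert res.statistic == pytest.approx(36.0)
    assert res.df == (1,)


def test_chisq_matches_pearson_formula_on_random_tables():
    """Agreement with the textbook Pearson formula computed directly."""
    rng = np.random.default_rng(21)
    for _ in range(10):
        table = rng.integers(5, 40, size=(6, 2)).astype(float)
        res = chisq_independence(table)
        expected = table.sum(1, keepdims=True) * table.sum(0, keepdims=True) / table.sum()
        chi2 = np.sum((table - expected) ** 2 / expected)
        assert res.statistic == pytest.approx(chi2, abs=1e-8)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(chi2, 5)), abs=1e-10)
    with pytest.raises(ValueError):
        chisq_independence([[0, 0], [1, 2]])


def test_proportional_rows_give_zero_chisq():
    res = chisq_independence([[10, 20], [30, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_vonmises_kappa_round_trip_against_bessel_oracle():
    for r in np.arange(0.1, 0.95, 0.1):
        k = vonmises_kappa(r)
        assert special.i1(k) / special.i0(k) == pytest.approx(r, abs=1e-8)
    assert vonmises_kappa(0.0) == 0.0
    assert vonmises_A(vonmises_kappa(0.61)) == pytest.approx(0.61, abs=1e-8)
    with pytest.raises(ValueError):
        vonmises_kappa(1.0)
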