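"""Circular statistics for orientation-cage data.

Mean vector, Rayleigh test, 95% confidence interval of a mean direction,
Watson's two-sample U-squared test, Mardia's one-way classification
(F) test for equal mean directions, Mardia's two-sample test for
homogeneity of concentration parameters, Pearson chi-square contingency
tests, and von Mises concentration utilities.

Conventions: bearings in degrees clockwise from geographic north,
normalized to [0, 360); all p-values two-sided unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special, stats

__all__ = [
    "CircularSample",
    "TestResult",
    "mean_vector",
    "rayleigh_test",
    "mean_ci95",
    "watson_u2",
    "watson_u2_statistic",
    "mardia_classification_f",
    "concentration_homogeneity",
    "chisq_independence",
    "vonmises_A",
    "vonmises_kappa",
]


@dataclass(frozen=True)
class CircularSample:
    """A set of individual bearings (degrees) with a free-text label."""

    bearings: np.ndarray
    label: str = ""

    def __post_init__(self):
        b = np.mod(np.asarray(self.bearings, dtype=float).ravel(), 360.0)
        if b.size < 1:
            raise ValueError("a circular sample needs at least one bearing")
        object.__setattr__(self, "bearings", b)

    @property
    def n(self) -> int:
        return int(self.bearings.size)

    def resultant_length(self) -> float:
        """Unnormalized resultant length R = n * r."""
        rad = np.radians(self.bearings)
        return float(np.hypot(np.sum(np.cos(rad)), np.sum(np.sin(rad))))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a circular or contingency test."""

    test_name: str
    statistic: float
    df: tuple
    p_value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def mean_vector(sample: CircularSample) -> tuple[Optional[float], float]:
    """Sample mean direction alpha (degrees) and mean vector length r.

    Returns (None, 0.0) when the resultant vanishes and the mean
    direction is undefined.
    """
    rad = np.radians(sample.bearings)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return None, 0.0
    alpha = float(np.mod(np.degrees(np.arctan2(s, c)), 360.0))
    return alpha, r


def rayleigh_p(n: int, r: float) -> float:
    """Rayleigh uniformity p-value from n and r (second-order series)."""
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(np.clip(p, 0.0, 1.0))


def rayleigh_test(n: int, r: float) -> TestResult:
    """Rayleigh test of circular uniformity, Z = n r^2."""
    if n < 4:
        raise ValueError("Rayleigh series approximation unreliable for n < 4; use exact tables")
    z = n * r * r
    return TestResult("rayleigh", float(z), (int(n),), rayleigh_p(n, r))


_CHI2_95_1 = float(stats.chi2.ppf(0.95, 1))


def mean_ci95(sample: CircularSample) -> tuple[float, float]:
    """Symmetric 95% confidence arc (lower, upper) of the mean direction.

    Chi-square-based large-sample approximation (with the separate high-r
    variant for r > 0.9).  Requires a Rayleigh-significant sample; raises
    ValueError (flagged 'CI undefined') for samples too dispersed or too
    small for the approximation.
    """
    alpha, r = mean_vector(sample)
    n = sample.n
    if alpha is None:
        raise ValueError("CI undefined: mean direction undefined (r = 0)")
    if n < 8:
        raise ValueError("CI undefined: n < 8")
    if rayleigh_p(n, r) >= 0.05:
        raise ValueError("CI undefined: sample not significantly directed (Rayleigh p >= 0.05)")
    big_r = n * r
    chi2 = _CHI2_95_1
    if r <= 0.9:
        arg = 2.0 * n * (2.0 * big_r**2 - n * chi2) / (4.0 * n - chi2)
        if arg < 0:
            raise ValueError("CI undefined: dispersion too large for the approximation")
        cosd = np.sqrt(arg) / big_r
    else:
        arg = n * n - (n * n - big_r**2) * np.exp(chi2 / n)
        if arg < 0:
            raise ValueError("CI undefined: degenerate high-concentration case")
        cosd = np.sqrt(arg) / big_r
    cosd = min(cosd, 1.0)
    delta = float(np.degrees(np.arccos(cosd)))
    return (np.mod(alpha - delta, 360.0), np.mod(alpha + delta, 360.0))


def direction_in_ci(sample: CircularSample, direction: float) -> bool:
    """Whether a fixed direction lies inside the 95% CI of the sample mean."""
    lo, hi = mean_ci95(sample)
    alpha, _ = mean_vector(sample)
    half = np.mod(hi - alpha, 360.0)
    dev = abs((direction - alpha + 180.0) % 360.0 - 180.0)
    return bool(dev <= half)


def watson_u2_statistic(a, b) -> float:
    """Two-sample Watson U^2 from pooled ordered bearings (midrank ties)."""
    a = np.mod(np.asarray(a, dtype=float).ravel(), 360.0)
    b = np.mod(np.asarray(b, dtype=float).ravel(), 360.0)
    n, m = a.size, b.size
    big_n = n + m
    pooled = np.concatenate([a, b])
    uniq, inv = np.unique(pooled, return_inverse=True)
    ca = np.bincount(inv[:n], minlength=uniq.size)
    cb = np.bincount(inv[n:], minlength=uniq.size)
    fa = np.cumsum(ca) / n
    fb = np.cumsum(cb) / m
    d = fa - fb
    w = ca + cb  # pooled multiplicity at each distinct bearing
    dbar = np.sum(w * d) / big_n
    return float(n * m / big_n**2 * np.sum(w * (d - dbar) ** 2))


def _watson_asymptotic_p(u2: float, max_terms: int = 10000) -> float:
    """P(U^2 > u2) from the limiting alternating series; 1.0 at u2 -> 0."""
    if u2 <= 1e-10:
        return 1.0
    total = 0.0
    for k in range(1, max_terms + 1):
        term = np.exp(-2.0 * k**2 * np.pi**2 * u2)
        total += term if k % 2 else -term
        if term < 1e-12:
            break
    return float(np.clip(2.0 * total, 0.0, 1.0))


def watson_u2(a: CircularSample, b: CircularSample, n_perm: int = 0,
              rng=None) -> TestResult:
    """Watson's two-sample U^2 test of a common circular distribution.

    p-value from the asymptotic series; if ``n_perm`` > 0, a permutation
    p-value over that many pooled shuffles is reported alongside in
    ``extra['p_permutation']``.
    """
    if a.n < 8 or b.n < 8:
        raise ValueError("Watson U2 requires n >= 8 per sample")
    u2 = watson_u2_statistic(a.bearings, b.bearings)
    p = _watson_asymptotic_p(u2)
    extra = {}
    if n_perm > 0:
        rng = np.random.default_rng(rng)
        pooled = np.concatenate([a.bearings, b.bearings])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if watson_u2_statistic(perm[: a.n], perm[a.n:]) >= u2:
                count += 1
        extra["p_permutation"] = (count + 1) / (n_perm + 1)
    return TestResult("watson_u2", u2, (a.n, b.n), p, extra)


def mardia_classification_f(a: CircularSample, b: CircularSample) -> TestResult:
    """Mardia's one-way classification test for equal mean directions.

    F = (N - 2) (R_a + R_b - R) / (N - R_a - R_b) on (1, N - 2) degrees
    of freedom, with R the pooled resultant length, improved by the
    standard concentration correction factor 1 + 3/(8 kappa_hat).
    Intended for two individually concentrated samples.
    """
    ra, rb = a.resultant_length(), b.resultant_length()
    pooled = CircularSample(np.concatenate([a.bearings, b.bearings]))
    rr = pooled.resultant_length()
    big_n = a.n + b.n
    denom = big_n - ra - rb
    if denom < 1e-9:
        raise ValueError("degenerate concentration: N - R_a - R_b ~ 0")
    f = (big_n - 2) * max(ra + rb - rr, 0.0) / denom
    rbar = (ra + rb) / big_n
    kappa_hat = vonmises_kappa(min(rbar, 1.0 - 1e-12))
    if kappa_hat > 1e-9:
        f *= 1.0 + 3.0 / (8.0 * kappa_hat)
    p = float(stats.f.sf(f, 1, big_n - 2))
    return TestResult("mardia_classification_f", float(f), (1, big_n - 2), p)


def concentration_homogeneity(a: CircularSample, b: CircularSample) -> TestResult:
    """Mardia's two-sample test for equality of concentration parameters.

    The variance-stabilizing transformation is chosen by the pooled mean
    resultant length r_bar: arcsine below 0.45, inverse hyperbolic sine
    on [0.45, 0.70], and a variance-ratio F test above 0.70.  The arcsine
    and sinh^-1 regimes return a standard-normal ('t-type') statistic and
    two-sided normal p; the high-concentration regime returns an F
    statistic with a two-sided p.
    """
    if a.n < 10 or b.n < 10:
        raise ValueError("concentration homogeneity test requires n >= 10 per sample")
    n1, n2 = a.n, b.n
    r1 = a.resultant_length() / n1
    r2 = b.resultant_length() / n2
    rbar = (n1 * r1 + n2 * r2) / (n1 + n2)
    if rbar < 0.45:
        def g1(x):
            arg = np.sqrt(3.0 / 8.0) * x
            if abs(arg) > 1:
                raise ValueError("transform input outside [-1, 1]")
            return np.arcsin(arg)

        num = g1(2.0 * r1) - g1(2.0 * r2)
        se = np.sqrt(3.0 / (4.0 * (n1 - 4)) + 3.0 / (4.0 * (n2 - 4)))
        t = float(num / se)
        p = float(2.0 * stats.norm.sf(abs(t)))
        regime = "low (arcsin)"
    elif rbar <= 0.70:
        c1, c2, c3 = 1.089, 0.258, 0.893
        num = np.arcsinh((r1 - c1) / c2) - np.arcsinh((r2 - c1) / c2)
        se = c3 * np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        t = float(num / se)
        p = float(2.0 * stats.norm.sf(abs(t)))
        regime = "mid (asinh)"
    else:
        f = ((n1 - n1 * r1) / (n1 - 1)) / ((n2 - n2 * r2) / (n2 - 1))
        t = float(f)
        cdf = stats.f.cdf(f, n1 - 1, n2 - 1)
        p = float(2.0 * min(cdf, 1.0 - cdf))
        regime = "high (variance ratio)"
    return TestResult(
        "concentration_homogeneity", t, (n1 + n2 - 2,), min(p, 1.0), {"regime": regime}
    )


def chisq_independence(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        "chisq_independence", float(res.statistic), (int(res.dof),), float(res.pvalue)
    )


def vonmises_A(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution, A(k) = I1(k)/I0(k)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def vonmises_kappa(r: float, tol: float = 1e-8) -> float:
    """Concentration kappa solving A(kappa) = r.

    Standard piecewise initial approximation refined by Newton iterations
    to |A(kappa) - r| < tol.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("r must lie in [0, 1)")
    if r == 0.0:
        return 0.0
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    for _ in range(100):
        a = vonmises_A(k)
        if abs(a - r) < tol:
            break
        # dA/dk = 1 - A^2 - A/k
        deriv = 1.0 - a * a - a / k
        k = max(k - (a - r) / deriv, 1e-12)
    return float(k)
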